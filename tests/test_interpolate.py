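"""The six prediction engines: hand cases, dense-solve oracles, invariants."""

import warnings

import numpy as np
import pytest

from socmap.geodata import Raster
from socmap.interpolate import (
    RBF_BASES,
    ConditioningError,
    CoverageError,
    NeighborhoodSpec,
    _bootstrap_models,
    _ok_solve,
    ck_predict,
    ebk_predict,
    idw_predict,
    lpi_predict,
    ok_predict,
    rbf_predict,
)
from socmap.variogram import VariogramModel

ALL_NB = NeighborhoodSpec(max_neighbors=50, min_neighbors=1)
VM = VariogramModel("exponential", 0.3, 1.5, 400.0)


@pytest.fixture()
def scatter(rng):
    coords = rng.uniform(0, 1000, (12, 2))
    z = rng.normal(10, 3, 12)
    targets = rng.uniform(100, 900, (6, 2))
    return coords, z, targets


class TestIDW:
    def test_hand_evaluated_two_points(self):
        # values 10 at distance 1, 20 at distance 2, beta = 2:
        # (10/1 + 20/4) / (1/1 + 1/4) = 15 / 1.25 = 12
        coords = np.array([[1.0, 0.0], [2.0, 0.0]])
        s = idw_predict(coords, [[0.0, 0.0]], beta=2.0,
                        nb=NeighborhoodSpec(2, 1), values=[10.0, 20.0])
        assert s.estimates[0] == pytest.approx(12.0)

    def test_coincident_target_snaps_to_site_value(self, scatter):
        coords, z, _ = scatter
        s = idw_predict(coords, coords[3], nb=ALL_NB, values=z)
        assert s.estimates[0] == z[3]

    def test_constant_data_any_beta(self, scatter):
        coords, _, targets = scatter
        for beta in (0.5, 2.0, 5.0):
            s = idw_predict(coords, targets, beta=beta, nb=ALL_NB,
                            values=np.full(12, 4.2))
            np.testing.assert_allclose(s.estimates, 4.2)

    def test_convex_bounds(self, scatter):
        coords, z, targets = scatter
        s = idw_predict(coords, targets, nb=ALL_NB, values=z)
        assert np.all(s.estimates >= z.min() - 1e-12)
        assert np.all(s.estimates <= z.max() + 1e-12)

    def test_coverage_error_lists_targets(self, scatter):
        coords, z, _ = scatter
        nb = NeighborhoodSpec(5, 4, search_radius=1.0)
        with pytest.raises(CoverageError, match="target"):
            idw_predict(coords, [[5000.0, 5000.0]], nb=nb, values=z)


class TestLPI:
    def test_reproduces_exact_plane(self, scatter):
        coords, _, targets = scatter
        z = 2 * coords[:, 0] + 3 * coords[:, 1] + 1
        s = lpi_predict(coords, targets, order=1, nb=ALL_NB, values=z)
        expect = 2 * targets[:, 0] + 3 * targets[:, 1] + 1
        np.testing.assert_allclose(s.estimates, expect, atol=1e-8)

    def test_order0_equals_kernel_weighted_mean(self, scatter):
        coords, z, targets = scatter
        bw = 2000.0
        s = lpi_predict(coords, targets, order=0, nb=ALL_NB,
                        kernel_bandwidth=bw, values=z)
        for t, x0 in enumerate(targets):
            h = np.linalg.norm(coords - x0, axis=1)
            w = (1 - h / bw) ** 2
            assert s.estimates[t] == pytest.approx(np.dot(w, z) / w.sum(), rel=1e-9)

    def test_collinear_sites_fall_back_with_warning(self, caplog):
        coords = np.column_stack([np.linspace(0, 100, 8), np.zeros(8)])
        z = np.linspace(1, 2, 8)
        with caplog.at_level("WARNING", logger="socmap.interpolate"):
            s = lpi_predict(coords, [[50.0, 10.0]], order=2,
                            nb=NeighborhoodSpec(8, 1), values=z)
        assert np.isfinite(s.estimates[0])
        assert any("fall" in r.message or "order" in r.message for r in caplog.records)

    def test_order0_convex_bounds(self, scatter):
        coords, z, targets = scatter
        s = lpi_predict(coords, targets, order=0, nb=ALL_NB, values=z)
        assert np.all((s.estimates >= z.min() - 1e-12) & (s.estimates <= z.max() + 1e-12))


class TestRBF:
    @pytest.mark.parametrize("basis", RBF_BASES)
    def test_passes_through_training_points(self, scatter, basis):
        coords, z, _ = scatter
        s = rbf_predict(coords, coords, basis=basis, nb=ALL_NB, values=z)
        np.testing.assert_allclose(s.estimates, z, atol=1e-6)

    @pytest.mark.parametrize("basis", RBF_BASES)
    def test_constant_data_gives_constant_surface(self, scatter, basis):
        coords, _, targets = scatter
        s = rbf_predict(coords, targets, basis=basis, nb=ALL_NB,
                        values=np.full(12, 3.3))
        np.testing.assert_allclose(s.estimates, 3.3, atol=1e-8)

    def test_multiquadric_matches_dense_solve_oracle(self):
        """1-D cross-section: small multiquadric system solved densely."""
        x = np.array([0.0, 1.0, 2.5, 4.0, 6.0])
        coords = np.column_stack([x, np.zeros(5)])
        z = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        target = np.array([[3.0, 0.0]])
        c = 1.5
        s = rbf_predict(coords, target, basis="multiquadric", shape_param=c,
                        nb=NeighborhoodSpec(5, 1), values=z)
        # oracle: textbook augmented system in the same scaled coordinates
        scale = np.mean(np.abs(x - 3.0))
        u = (x - 3.0) / scale
        r = np.abs(u[:, None] - u[None, :])
        Phi = np.sqrt(r ** 2 + c ** 2)
        A = np.zeros((6, 6))
        A[:5, :5] = Phi
        A[:5, 5] = 1
        A[5, :5] = 1
        sol = np.linalg.solve(A, np.concatenate([z, [0.0]]))
        expect = sol[:5] @ np.sqrt(u ** 2 + c ** 2) + sol[5]
        assert s.estimates[0] == pytest.approx(expect, abs=1e-8)

    def test_duplicate_sites_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ConditioningError, match="duplicate"):
            rbf_predict(coords, [[0.5, 0.5]], nb=NeighborhoodSpec(3, 1),
                        values=[1.0, 1.0, 2.0])


class TestOK:
    def test_weights_sum_to_one(self, rng):
        coords = rng.uniform(0, 1000, (10, 2))
        h = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        d0 = np.linalg.norm(coords - np.array([400.0, 600.0]), axis=1)
        _, _, lam, _ = _ok_solve(VM(h), VM(d0), rng.normal(size=10))
        assert lam.sum() == pytest.approx(1.0, abs=1e-10)

    def test_exact_at_training_site_with_zero_nugget(self, scatter):
        coords, z, _ = scatter
        vm0 = VariogramModel("exponential", 0.0, 1.5, 400.0)
        s = ok_predict(coords, coords, vm0, nb=ALL_NB, values=z)
        np.testing.assert_allclose(s.estimates, z, atol=1e-8)
        np.testing.assert_allclose(s.variance, 0.0, atol=1e-8)

    def test_matches_dense_full_system_solve(self, rng):
        coords = rng.uniform(0, 1000, (5, 2))
        z = rng.normal(0, 1, 5)
        targets = rng.uniform(0, 1000, (4, 2))
        s = ok_predict(coords, targets, VM, nb=ALL_NB, values=z)
        for t, x0 in enumerate(targets):
            h = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            A = np.zeros((6, 6))
            A[:5, :5] = VM(h)
            A[:5, 5] = A[5, :5] = 1.0
            rhs = np.concatenate([VM(np.linalg.norm(coords - x0, axis=1)), [1.0]])
            sol = np.linalg.solve(A, rhs)
            assert s.estimates[t] == pytest.approx(float(sol[:5] @ z), abs=1e-8)

    def test_variance_nonnegative(self, scatter):
        coords, z, targets = scatter
        s = ok_predict(coords, targets, VM, nb=ALL_NB, values=z)
        assert np.all(s.variance >= 0)


class TestCK:
    def test_zero_secondary_collapses_to_ok(self, scatter):
        coords, z, targets = scatter
        zero = Raster(np.zeros((60, 60)), 0.0, 0.0, 20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ck = ck_predict(coords, [zero], targets, vm_primary=VM, nb=ALL_NB, values=z)
        ok = ok_predict(coords, targets, VM, nb=ALL_NB, values=z)
        np.testing.assert_allclose(ck.estimates, ok.estimates, atol=1e-6)
        np.testing.assert_allclose(ck.variance, ok.variance, atol=1e-6)

    def test_informative_secondary_never_increases_variance(self, scatter):
        coords, z, targets = scatter
        X, Y = np.meshgrid((np.arange(60) + 0.5) * 20, (np.arange(60) + 0.5) * 20)
        num = np.zeros_like(X)
        den = np.zeros_like(X)
        for (cx, cy), zv in zip(coords, z):
            w = np.exp(-np.hypot(X - cx, Y - cy) / 300)
            num += zv * w
            den += w
        sec = Raster(num / den, 0.0, 0.0, 20.0)
        ck = ck_predict(coords, [sec], targets, vm_primary=VM, nb=ALL_NB, values=z)
        ok = ok_predict(coords, targets, VM, nb=ALL_NB, values=z)
        assert np.all(ck.variance <= ok.variance + 1e-8)

    def test_translation_equivariance(self, scatter):
        coords, z, targets = scatter
        sec = Raster(np.linspace(0, 1, 3600).reshape(60, 60), 0.0, 0.0, 20.0)
        a = ck_predict(coords, [sec], targets, vm_primary=VM, nb=ALL_NB, values=z)
        b = ck_predict(coords, [sec], targets, vm_primary=VM, nb=ALL_NB, values=z + 7.5)
        np.testing.assert_allclose(b.estimates - a.estimates, 7.5, atol=1e-6)

    def test_too_many_secondaries(self, scatter):
        coords, z, targets = scatter
        r = Raster(np.zeros((60, 60)), 0.0, 0.0, 20.0)
        with pytest.raises(ValueError, match="1 to 4"):
            ck_predict(coords, [r] * 5, targets, vm_primary=VM, nb=ALL_NB, values=z)


class TestEBK:
    def test_collapses_to_ok_with_one_subset_one_simulation(self, rng):
        coords = rng.uniform(0, 2000, (40, 2))
        z = rng.normal(5, 2, 40)
        targets = rng.uniform(200, 1800, (5, 2))
        nb = NeighborhoodSpec(15, 4)
        ebk = ebk_predict(coords, targets, subset_size=40, overlap=0.0,
                          n_simulations=1, seed=9, nb=nb, values=z)
        vm = _bootstrap_models(coords, z, 1, np.random.default_rng(9))[0]
        ok = ok_predict(coords, targets, vm, nb=nb, values=z)
        np.testing.assert_allclose(ebk.estimates, ok.estimates, atol=1e-8)

    def test_deterministic_per_seed(self, rng):
        coords = rng.uniform(0, 2000, (60, 2))
        z = rng.normal(5, 2, 60)
        targets = rng.uniform(200, 1800, (4, 2))
        a = ebk_predict(coords, targets, subset_size=30, n_simulations=20,
                        seed=4, values=z)
        b = ebk_predict(coords, targets, subset_size=30, n_simulations=20,
                        seed=4, values=z)
        np.testing.assert_array_equal(a.estimates, b.estimates)
        np.testing.assert_array_equal(a.variance, b.variance)
        c = ebk_predict(coords, targets, subset_size=30, n_simulations=20,
                        seed=5, values=z)
        assert not np.array_equal(a.estimates, c.estimates)

    def test_subset_too_small(self, rng):
        coords = rng.uniform(0, 100, (20, 2))
        with pytest.raises(ValueError, match="subset_size"):
            ebk_predict(coords, [[50.0, 50.0]], subset_size=5, values=np.ones(20))


class TestSharedInvariants:
    def test_translation_equivariance_all_methods(self, scatter):
        coords, z, targets = scatter
        c = 11.0
        runs = {
            "idw": lambda v: idw_predict(coords, targets, nb=ALL_NB, values=v),
            "lpi": lambda v: lpi_predict(coords, targets, nb=ALL_NB, values=v),
            "rbf": lambda v: rbf_predict(coords, targets, nb=ALL_NB, values=v),
            "ok": lambda v: ok_predict(coords, targets, VM, nb=ALL_NB, values=v),
            "ebk": lambda v: ebk_predict(coords, targets, subset_size=12,
                                         n_simulations=5, seed=1,
                                         nb=NeighborhoodSpec(12, 1), values=v),
        }
        for name, fn in runs.items():
            base = fn(z).estimates
            shifted = fn(z + c).estimates
            np.testing.assert_allclose(shifted - base, c, atol=1e-6, err_msg=name)

    def test_duplicate_sites_averaged_with_warning(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0]])
        z = np.array([1.0, 3.0, 5.0])
        with pytest.warns(UserWarning, match="duplicate"):
            s = ok_predict(coords, [[0.0, 0.0]],
                           VariogramModel("exponential", 0.0, 1.0, 50.0),
                           nb=NeighborhoodSpec(3, 1), values=z)
        assert s.estimates[0] == pytest.approx(2.0)  # averaged duplicate

    def test_ok_beats_idw_on_strongly_autocorrelated_field(self, rng):
        """Dense sampling relative to the range: kriging must win."""
        vm = VariogramModel("exponential", 0.05, 1.0, 2000.0)  # range >> spacing
        n = 220
        pts = rng.uniform(0, 2000, (n, 2))  # ~140 m spacing, range 2 km
        h = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        C = vm.sill - vm(h)
        L = np.linalg.cholesky(C + 1e-9 * np.eye(n))
        z = L @ rng.normal(size=n)
        tr, te = np.arange(180), np.arange(180, n)
        nb = NeighborhoodSpec(15, 4)
        ok = ok_predict(pts[tr], pts[te], vm, nb=nb, values=z[tr])
        idw = idw_predict(pts[tr], pts[te], nb=nb, values=z[tr])
        rmse_ok = np.sqrt(np.mean((ok.estimates - z[te]) ** 2))
        rmse_idw = np.sqrt(np.mean((idw.estimates - z[te]) ** 2))
        assert rmse_ok <= rmse_idw
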