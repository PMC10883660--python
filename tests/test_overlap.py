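"""Matching score / matching index machinery and its oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from olivemap.overlap import (KdeConfig, axis_density, bootstrap_mi_null,
                              decide_significance, kde2d, match_analysis,
                              matching_index, matching_score, mirror_pool,
                              pairing_claim, shared_grid, skeleton_endpoints)

CFG = KdeConfig()


class TestMirrorPool:
    def test_symmetric_pair_coincides(self):
        pts = np.array([[3.0, 2.0], [3.0, 8.0]])
        pooled = mirror_pool(pts, midline=5.0)
        assert np.allclose(pooled, [[3.0, 2.0], [3.0, 2.0]])

    def test_identity_when_all_on_kept_side(self):
        pts = np.array([[1.0, 1.0], [2.0, 4.0]])
        assert np.allclose(mirror_pool(pts, midline=5.0), pts)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(5.0, 3.0, (30, 2))
        once = mirror_pool(pts, midline=5.0)
        assert np.allclose(mirror_pool(once, midline=5.0), once)

    def test_preserves_point_count(self):
        pts = np.random.default_rng(1).normal(0, 2, (17, 2))
        assert mirror_pool(pts, midline=0.0).shape == pts.shape


class TestKde2d:
    def test_single_point_peaks_there_and_integrates_to_one(self):
        d = kde2d([[12.0, 7.0]], CFG)
        assert d.integral == pytest.approx(1.0, abs=1e-9)
        iy, ix = np.unravel_index(np.argmax(d.values), d.values.shape)
        assert d.x[ix] == pytest.approx(12.0, abs=CFG.spacing)
        assert d.y[iy] == pytest.approx(7.0, abs=CFG.spacing)

    def test_symmetric_points_give_symmetric_density(self):
        g = shared_grid([np.array([[-10.0, 0.0], [10.0, 0.0]])], CFG)
        d = kde2d([[-10.0, 0.0], [10.0, 0.0]], CFG, grid=g)
        assert np.allclose(d.values, d.values[:, ::-1], atol=1e-12)

    def test_integral_contract(self):
        rng = np.random.default_rng(2)
        d = kde2d(rng.normal(0, 20, (40, 2)), CFG)
        assert d.integral == pytest.approx(1.0, abs=1e-6)

    def test_empty_point_set_rejected(self):
        with pytest.raises(ValueError):
            kde2d(np.empty((0, 2)), CFG)


class TestMatchingScore:
    def test_self_match_is_one(self):
        d = kde2d([[0.0, 0.0], [15.0, 5.0], [2.0, 30.0]], CFG)
        assert matching_score(d, d) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports_near_zero(self):
        g = shared_grid([np.array([[0.0, 0.0]]), np.array([[500.0, 0.0]])],
                        CFG)
        p = kde2d([[0.0, 0.0]], CFG, grid=g)
        q = kde2d([[500.0, 0.0]], CFG, grid=g)
        assert matching_score(p, q) < 1e-3

    def test_two_points_two_sd_apart_closed_form(self):
        """Two unit Gaussians separated by 2 SD overlap by 2*Phi(-1)."""
        sep = 2.0 * CFG.kernel_sd
        g = shared_grid([np.array([[0.0, 0.0]]), np.array([[sep, 0.0]])], CFG)
        p = kde2d([[0.0, 0.0]], CFG, grid=g)
        q = kde2d([[sep, 0.0]], CFG, grid=g)
        assert matching_score(p, q) == pytest.approx(2.0 * norm.cdf(-1.0),
                                                     abs=0.005)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 10, (6, 2)), rng.normal(5, 10, (4, 2))
        g = shared_grid([a, b], CFG)
        p, q = kde2d(a, CFG, grid=g), kde2d(b, CFG, grid=g)
        assert matching_score(p, q) == matching_score(q, p)

    def test_grid_mismatch_rejected(self):
        p = kde2d([[0.0, 0.0]], CFG)
        q = kde2d([[50.0, 50.0]], CFG)
        with pytest.raises(ValueError):
            matching_score(p, q)

    def test_small_instance_double_loop_oracle(self):
        """On tiny point sets and a coarse grid the separable evaluation
        agrees with a direct per-point per-cell min-integral oracle."""
        cfg = KdeConfig(kernel_sd=3.0, spacing=2.0)
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 20, (4, 2))
        b = rng.uniform(5, 25, (5, 2))
        g = shared_grid([a, b], cfg)
        ms = matching_score(kde2d(a, cfg, grid=g), kde2d(b, cfg, grid=g))

        def oracle_density(pts, x, y):
            dens = np.zeros((len(y), len(x)))
            for iy, yy in enumerate(y):
                for ix, xx in enumerate(x):
                    s = 0.0
                    for px, py in pts:
                        s += np.exp(-((xx - px) ** 2 + (yy - py) ** 2)
                                    / (2 * cfg.kernel_sd ** 2))
                    dens[iy, ix] = s
            cell = (x[1] - x[0]) * (y[1] - y[0])
            return dens / (dens.sum() * cell), cell

        x, y = g
        pa, cell = oracle_density(a, x, y)
        pb, _ = oracle_density(b, x, y)
        ms_oracle = np.minimum(pa, pb).sum() * cell
        assert ms == pytest.approx(ms_oracle, abs=1e-8)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 15, (5, 2))
        b = rng.normal(10, 15, (5, 2))
        g = shared_grid([a, b], CFG)
        ms = matching_score(kde2d(a, CFG, grid=g), kde2d(b, CFG, grid=g))
        assert 0.0 <= ms <= 1.0 + 1e-9


class TestMatchingIndex:
    def test_all_equal_scores_give_zero(self):
        ms = {(a, f): 0.4 for a in "AB" for f in "FG"}
        assert matching_index(ms, ("A", "B"), ("F", "G")) == 0.0

    def test_antisymmetric_under_label_swap(self):
        ms = {("A", "F"): 0.9, ("B", "G"): 0.8, ("A", "G"): 0.2,
              ("B", "F"): 0.1}
        mi = matching_index(ms, ("A", "B"), ("F", "G"))
        mi_swapped = matching_index(ms, ("A", "B"), ("G", "F"))
        assert mi_swapped == pytest.approx(-mi)

    def test_identical_separated_classes_give_mi_near_one(self):
        rng = np.random.default_rng(5)
        c1 = rng.normal(0, 5, (20, 2))
        c2 = rng.normal(200, 5, (20, 2))
        anat = {"a1": c1, "a2": c2}
        func = {"f1": c1.copy(), "f2": c2.copy()}
        g = shared_grid([c1, c2], CFG)
        ms = {(a, f): matching_score(kde2d(pa, CFG, grid=g),
                                     kde2d(pf, CFG, grid=g))
              for a, pa in anat.items() for f, pf in func.items()}
        mi = matching_index(ms, ("a1", "a2"), ("f1", "f2"))
        assert mi == pytest.approx(1.0, abs=0.01)

    def test_missing_entry_rejected(self):
        with pytest.raises(ValueError):
            matching_index({("A", "F"): 0.5}, ("A", "B"), ("F", "G"))


class TestBootstrapNull:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        anat = {"a1": rng.normal(0, 5, (8, 2)), "a2": rng.normal(3, 5, (8, 2))}
        func = {"f1": rng.normal(0, 5, (9, 2)), "f2": rng.normal(3, 5, (9, 2))}
        a = bootstrap_mi_null(anat, func, n=50, seed=3)
        b = bootstrap_mi_null(anat, func, n=50, seed=3)
        assert np.array_equal(a, b)

    def test_null_centered_near_zero_for_exchangeable_classes(self):
        rng = np.random.default_rng(7)
        pool = rng.normal(0, 10, (40, 2))
        anat = {"a1": pool[:20], "a2": pool[20:]}
        func = {"f1": rng.normal(0, 10, (20, 2)),
                "f2": rng.normal(0, 10, (20, 2))}
        null = bootstrap_mi_null(anat, func, n=400, seed=8)
        assert abs(null.mean()) < 0.05

    def test_degenerate_class_rejected(self):
        anat = {"a1": np.array([[0.0, 0.0]]), "a2": np.zeros((3, 2))}
        func = {"f1": np.zeros((3, 2)), "f2": np.zeros((3, 2))}
        with pytest.raises(ValueError):
            bootstrap_mi_null(anat, func, n=10, seed=0)


class TestSignificance:
    def test_bonferroni_percentile_is_99_17(self):
        null = np.linspace(0.0, 1.0, 100_001)  # uniform grid on [0, 1]
        _, threshold = decide_significance(0.5, null, alpha=0.05,
                                           n_comparisons=6)
        assert threshold == pytest.approx(1.0 - 0.05 / 6, abs=1e-6)
        assert 100 * (1 - 0.05 / 6) == pytest.approx(99.1667, abs=1e-4)

    def test_strict_exceedance_at_threshold(self):
        null = np.linspace(0.0, 1.0, 1001)
        _, threshold = decide_significance(0.0, null)
        sig, _ = decide_significance(threshold, null)
        assert not sig  # equality is not enough

    def test_pairing_requires_both_regions(self):
        assert pairing_claim([True, True])
        assert not pairing_claim([True, False])
        with pytest.raises(ValueError):
            pairing_claim([])

    def test_false_positive_control_under_null(self):
        """Classes resampled from one distribution: the Bonferroni rule
        fires rarely (well below alpha per region)."""
        rng = np.random.default_rng(9)
        fired = 0
        n_sim = 40
        for i in range(n_sim):
            pool_a = rng.normal(0, 8, (24, 2))
            pool_f = rng.normal(0, 8, (24, 2))
            anat = {"a1": pool_a[:12], "a2": pool_a[12:]}
            func = {"f1": pool_f[:12], "f2": pool_f[12:]}
            res = match_analysis(anat, func, n_boot=400, seed=100 + i)
            fired += res.significant
        assert fired / n_sim <= 0.1


class TestSkeletonEndpoints:
    def test_straight_line_two_endpoints(self):
        mask = np.zeros((5, 9), dtype=bool)
        mask[2, 1:8] = True
        eps = skeleton_endpoints(mask)
        assert sorted(map(tuple, eps)) == [(2, 1), (2, 7)]

    def test_isolated_pixel_is_its_own_endpoint(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert list(map(tuple, skeleton_endpoints(mask))) == [(2, 2)]

    def test_y_shape_three_endpoints(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 0:5] = True           # stem
        for k in range(1, 5):         # two diagonal arms
            mask[4 - k, 4 + k] = True
            mask[4 + k, 4 + k] = True
        eps = skeleton_endpoints(mask)
        brute = []
        for r, c in np.argwhere(mask):
            n = mask[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2].sum() - 1
            if n <= 1:
                brute.append((r, c))
        assert sorted(map(tuple, eps)) == sorted(brute)
        assert len(eps) == 3

    def test_thick_blob_warns_and_thins(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:8, 3:8] = True
        with pytest.warns(UserWarning, match="thin"):
            eps = skeleton_endpoints(mask)
        assert len(eps) >= 1


class TestAxisDensity:
    def test_single_point_unimodal_peak(self):
        grid, dens = axis_density(np.array([[5.0, 0.0]]), axis=0,
                                  kernel_sd=3.0)
        assert grid[np.argmax(dens)] == pytest.approx(5.0, abs=1.0)
        step = grid[1] - grid[0]
        assert dens.sum() * step == pytest.approx(1.0, abs=1e-9)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_two_clusters_bimodal(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[60.0, 0.0]] * 5)
        grid, dens = axis_density(pts, axis=0, kernel_sd=4.0)
        peaks = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        assert peaks.sum() == 2

    def test_class_offset_orders_modes(self, small_dataset):
        gt = small_dataset.ground_truth
        fwd = gt[gt["class_label"] == "forward"][["rc_um", "lr_um"]].to_numpy()
        bwd = gt[gt["class_label"] == "backward"][["rc_um",
                                                   "lr_um"]].to_numpy()
        grid = np.arange(-20.0, 90.0, 1.0)
        _, df = axis_density(fwd, axis=0, kernel_sd=8.0, grid=grid)
        _, db = axis_density(bwd, axis=0, kernel_sd=8.0, grid=grid)
        assert grid[np.argmax(df)] < grid[np.argmax(db)]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            axis_density(np.empty((0, 2)))
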