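"""Projection statistics: KS permutation, focal distance, retrograde
tracing, reconstruction, subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from axonmap.analysis import (
    InjectionMask,
    LaminarProfile,
    cortical_rolony_prep,
    focal_distance,
    fraction_different,
    ks_permutation,
    reconstruct,
    simulated_retrograde,
    soma_depth_groups,
    subsampling_error_curve,
)


class TestLaminarProfile:
    def test_histogram_normalized_cdf_monotone(self, rng):
        p = LaminarProfile.from_depths(rng.uniform(0, 100, 500))
        assert p.histogram.sum() == pytest.approx(1.0)
        assert (np.diff(p.cdf) >= 0).all()
        assert p.cdf[-1] == pytest.approx(1.0)


class TestPrep:
    def _rolonies(self):
        return pd.DataFrame({
            "ml": [100.0, 100.0, 5000.0, -100.0],
            "ap": [100.0, 100.0, 5000.0, 100.0],
            "depth": [50.0, 96.0, 50.0, 50.0],
        })

    def test_depth_above_95_dropped(self):
        out = cortical_rolony_prep(self._rolonies())
        assert (out["depth"] <= 95.0).all() and len(out) == 3

    def test_injection_disk_and_mirror_dropped(self):
        mask = InjectionMask(center=(100.0, 100.0), radius=50.0,
                             mirrored_center=(-100.0, 100.0))
        out = cortical_rolony_prep(self._rolonies(), mask)
        assert len(out) == 1 and out["ml"].iloc[0] == 5000.0

    def test_mask_from_somata_radius_is_95th_percentile(self, rng):
        pts = rng.normal(0, 100, (500, 2))
        mask = InjectionMask.from_somata(pts)
        d = np.linalg.norm(pts - np.median(pts, axis=0), axis=1)
        assert mask.radius == pytest.approx(np.percentile(d, 95))


class TestKsPermutation:
    def test_identical_samples(self):
        a = np.array([10.0, 20.0, 30.0])
        ks, p = ks_permutation(a, a.copy(), rng=0)
        assert ks == 0.0 and p == 1.0

    def test_separated_supports_significant(self, rng):
        a = rng.uniform(0, 50, 100)
        b = rng.uniform(50, 100, 100)
        ks, p = ks_permutation(a, b, rng=1)
        assert ks > 0.9 and p <= 0.001

    def test_empty_sample_undefined(self):
        ks, p = ks_permutation(np.array([]), np.array([1.0]))
        assert np.isnan(ks) and np.isnan(p)

    def test_null_type_I_calibration(self):
        rng = np.random.default_rng(9)
        n_cells, rej = 300, 0
        for c in range(n_cells):
            pool = rng.uniform(0, 100, 80)
            _, p = ks_permutation(pool[:40], pool[40:], 500,
                                  rng=np.random.default_rng(c))
            rej += p <= 0.05
        from scipy import stats

        lo, hi = stats.binom.interval(0.999, n_cells, 0.05)
        assert lo <= rej <= hi

    def test_seeded_reproducible(self, rng):
        a = rng.uniform(0, 100, 40)
        b = rng.uniform(0, 100, 40)
        assert ks_permutation(a, b, rng=7) == ks_permutation(a, b, rng=7)


class TestFractionDifferent:
    def test_all_significant(self):
        pct, (lo, hi) = fraction_different(np.full(50, 0.01), rng=0)
        assert pct == 100.0 and lo == hi == 100.0

    def test_half_significant_ci_covers(self):
        p = np.array([0.01] * 50 + [0.5] * 50)
        pct, (lo, hi) = fraction_different(p, rng=0)
        assert pct == 50.0 and lo < 50.0 < hi

    def test_single_cell_degenerate(self):
        with pytest.warns(UserWarning):
            pct, (lo, hi) = fraction_different(np.array([0.01]), rng=0)
        assert pct == lo == hi == 100.0


class TestSomaDepthGroups:
    @pytest.mark.parametrize("depth,group", [
        (35.0, "upper"), (35.1, "middle"), (60.0, "middle"),
        (60.1, "deep"), (0.0, "upper"), (100.0, "deep"),
    ])
    def test_boundaries(self, depth, group):
        assert soma_depth_groups(np.array([depth]))[0] == group

    def test_missing_soma_excluded(self):
        assert soma_depth_groups(np.array([np.nan]))[0] == ""


def _focal_oracle(pts, fraction=0.33):
    n = len(pts)
    k = int(np.ceil(fraction * (n - 1)))
    per_rolony = []
    for i in range(n):
        d = sorted(np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
                   for j in range(n) if j != i)
        per_rolony.append(float(np.mean(d[:k])))
    return float(np.mean(per_rolony))


class TestFocalDistance:
    def test_identical_points_zero(self):
        assert focal_distance(np.zeros((60, 2))) == 0.0

    def test_line_matches_brute_force_exactly(self):
        pts = np.column_stack([np.arange(60.0), np.zeros(60)])
        assert focal_distance(pts) == pytest.approx(_focal_oracle(pts), abs=1e-12)

    def test_random_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1000, (80, 2))
        assert focal_distance(pts) == pytest.approx(_focal_oracle(pts), abs=1e-9)

    def test_below_min_n_excluded(self, rng):
        assert np.isnan(focal_distance(rng.uniform(0, 100, (54, 2))))

    def test_tight_disk_smaller_than_dispersed(self, rng):
        tight = rng.normal(0, 50, (100, 2))
        loose = rng.normal(0, 500, (100, 2))
        assert focal_distance(tight) < focal_distance(loose)


class TestSubsampling:
    def test_full_size_zero_error(self, rng):
        pts = rng.uniform(0, 500, (60, 2))
        out = subsampling_error_curve(pts, [60], reps=5, rng=0)
        assert out[60] == 0.0

    def test_oversize_skipped(self, rng):
        pts = rng.uniform(0, 500, (60, 2))
        assert 100 not in subsampling_error_curve(pts, [100], reps=2, rng=0)

    def test_error_decreases_with_size(self, rng):
        errs = {10: [], 40: []}
        for _ in range(20):
            pts = rng.normal(0, 300, (80, 2))
            out = subsampling_error_curve(pts, [10, 40], reps=30, rng=rng)
            for s in errs:
                errs[s].append(out[s])
        assert np.median(errs[40]) < np.median(errs[10])

    def test_reproducible(self, rng):
        pts = rng.uniform(0, 500, (60, 2))
        assert subsampling_error_curve(pts, [20], reps=1, rng=3) == \
            subsampling_error_curve(pts, [20], reps=1, rng=3)


class TestRetrograde:
    def _data(self):
        cells = pd.DataFrame({
            "cell_id": [0, 1, 2, 3],
            "cell_class": ["ITc", "CF", "ITc", "ITi"],
            "has_soma": [True, True, False, True],
        })
        rows = []
        for cid, n_patch in [(0, 12), (1, 12), (2, 12), (3, 9)]:
            for _ in range(n_patch):
                rows.append((cid, 0.0, 0.0, "AudC"))
            rows.append((cid, 5000.0, 5000.0, "AudC"))
        rolonies = pd.DataFrame(rows, columns=["cell_id", "ml", "ap", "region"])
        return cells, rolonies

    def test_criteria(self):
        cells, rolonies = self._data()
        out = simulated_retrograde(cells, rolonies, (0.0, 0.0))
        assert set(out["cell_id"]) == {0}  # IT + soma + >= 10 in patch

    def test_specificity_ratio(self):
        cells, rolonies = self._data()
        out = simulated_retrograde(cells, rolonies, (0.0, 0.0))
        assert bool(out["specific"].iloc[0])  # 12/13 >= 0.75
        extra = pd.DataFrame([(0, 5000.0, 5000.0, "AudC")] * 10,
                             columns=rolonies.columns)
        out2 = simulated_retrograde(cells, pd.concat([rolonies, extra]), (0.0, 0.0))
        assert not bool(out2["specific"].iloc[0])  # 12/23 < 0.75

    def test_radius_monotonicity(self, rng):
        cells = pd.DataFrame({"cell_id": np.arange(30), "cell_class": "ITi",
                              "has_soma": True})
        rows = []
        for cid in range(30):
            pts = rng.normal(0, 400, (20, 2))
            rows += [(cid, x, y, "AudI") for x, y in pts]
        rolonies = pd.DataFrame(rows, columns=["cell_id", "ml", "ap", "region"])
        n_prev = None
        for radius in (500.0, 400.0, 300.0, 200.0):
            n = len(simulated_retrograde(cells, rolonies, (0.0, 0.0), radius=radius))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestReconstruct:
    def test_two_points_one_edge(self):
        edges = reconstruct(np.array([[0.0, 0.0, 0.0], [500.0, 0.0, 0.0]]))
        assert edges == [(0, 1)]

    def test_distant_clusters_stay_separate(self):
        pts = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                        [1210.0, 0.0, 0.0], [1220.0, 0.0, 0.0]])
        edges = reconstruct(pts)
        assert len(edges) == 2
        assert all(np.linalg.norm(pts[i] - pts[j]) <= 1000 for i, j in edges)

    def test_tree_per_component_and_mst_bound(self, rng):
        pts = rng.uniform(0, 800, (40, 3))
        edges = reconstruct(pts)
        assert len(edges) == 39  # spanning tree (all within the cap)
        total = sum(np.linalg.norm(pts[i] - pts[j]) for i, j in edges)
        D = cdist(pts, pts)
        mst = minimum_spanning_tree(D).sum()
        assert total >= mst - 1e-9
        assert total == pytest.approx(mst, rel=1e-9)  # greedy merge = MST here

    def test_collinear_equals_mst(self):
        pts = np.column_stack([np.arange(10.0) * 50, np.zeros(10), np.zeros(10)])
        edges = reconstruct(pts)
        total = sum(np.linalg.norm(pts[i] - pts[j]) for i, j in edges)
        assert total == pytest.approx(9 * 50.0)

    def test_single_point(self):
        assert reconstruct(np.zeros((1, 3))) == []
        with pytest.raises(ValueError):
            reconstruct(np.zeros((0, 3)))
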