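import math

import numpy as np
import pytest

from vdpkit import (
    CavityMask,
    KMeansParams,
    ThresholdParams,
    VDPResult,
    VentilationKMeans,
    VolumeGrid,
    compute_adaptive_threshold,
    compute_vdp,
    segment_kmeans,
    segment_threshold,
)
from vdpkit.io import GridMismatchError


# --------------------------------------------------------------------------
# independent oracles

def threshold_oracle(values, factor=0.5, lower=5, upper=80):
    """Brute-force rank-window mean: sort, keep ranks lower%*N < r <= upper%*N.

    Rank bounds evaluated in exact rational arithmetic.
    """
    from fractions import Fraction

    s = np.sort(np.asarray(values, dtype=float))
    n = s.size
    lo = Fraction(lower) * n / 100
    hi = Fraction(upper) * n / 100
    kept = [s[r - 1] for r in range(1, n + 1) if lo < r <= hi]
    return factor * float(np.mean(kept))


def dp_kmeans_wcss(values, k):
    """Exact optimal 1-D k-means WCSS by DP over contiguous partitions."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def cost(a, b):  # cost of cluster x[a:b]
        m = b - a
        s = pref[b] - pref[a]
        return (pref2[b] - pref2[a]) - s * s / m

    INF = float("inf")
    D = [[INF] * (n + 1) for _ in range(k + 1)]
    D[0][0] = 0.0
    for j in range(1, k + 1):
        for i in range(j, n + 1):
            D[j][i] = min(D[j - 1][a] + cost(a, i) for a in range(j - 1, i))
    return D[k][n]


def _grid_pair(values, shape, spacing=(1.0, 1.0, 1.0)):
    vol = VolumeGrid(np.asarray(values, dtype=float).reshape(shape),
                     voxel_spacing=spacing)
    cav = CavityMask(np.ones(shape, dtype=bool), voxel_spacing=spacing)
    return vol, cav


# --------------------------------------------------------------------------
# adaptive threshold

class TestAdaptiveThreshold:
    def test_hundred_voxel_example(self, hundred_voxel_pair):
        """10 zeros + 90 ones: window = ranks 6..80 -> mean 70/75."""
        vol, cav = hundred_voxel_pair
        thr = compute_adaptive_threshold(vol, cav)
        assert thr == pytest.approx(0.5 * 70.0 / 75.0, abs=1e-12)

    def test_uniform_field(self, uniform_pair):
        vol, cav = uniform_pair
        assert compute_adaptive_threshold(vol, cav) == pytest.approx(1.5)

    def test_homogeneity(self, hundred_voxel_pair):
        vol, cav = hundred_voxel_pair
        thr = compute_adaptive_threshold(vol, cav)
        vol7 = VolumeGrid(vol.intensities * 7.0, vol.voxel_spacing,
                          modality=vol.modality)
        assert compute_adaptive_threshold(vol7, cav) == pytest.approx(7 * thr, rel=1e-12)

    def test_matches_bruteforce_oracle_on_random_cavities(self):
        """Exact agreement with the sort-and-average oracle, 120 random cavities."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = int(rng.integers(50, 501))
            # half the cavities heavily tied (integer intensities)
            vals = (rng.normal(size=n) if rng.random() < 0.5
                    else rng.integers(0, 20, n).astype(float))
            shape = (n, 1, 1)
            vol, cav = _grid_pair(vals, shape)
            got = compute_adaptive_threshold(vol, cav)
            assert got == pytest.approx(threshold_oracle(vals), abs=1e-12)

    def test_small_cavity_rejected(self):
        vol, cav = _grid_pair(np.arange(10.0), (10, 1, 1))
        with pytest.raises(ValueError, match="too small"):
            compute_adaptive_threshold(vol, cav)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ThresholdParams(lower_percentile=80, upper_percentile=5)
        with pytest.raises(ValueError):
            ThresholdParams(factor=0.0)


class TestThresholdSegmentation:
    def test_hundred_voxel_defects(self, hundred_voxel_pair):
        vol, cav = hundred_voxel_pair
        seg = segment_threshold(vol, cav)
        assert seg.defect_mask.sum() == 10
        assert np.all(vol.intensities[seg.defect_mask] == 0.0)
        assert seg.threshold_value == pytest.approx(0.5 * 70.0 / 75.0)

    def test_uniform_field_empty_defect(self, uniform_pair):
        vol, cav = uniform_pair
        seg = segment_threshold(vol, cav)
        assert seg.defect_mask.sum() == 0

    def test_voxel_at_threshold_is_ventilated(self):
        """Strictly-below convention: a voxel exactly at the threshold is kept."""
        vals = np.full(27, 2.0)
        vals[0] = 1.0  # threshold = 0.5 * mean-window; set one voxel to it
        vol, cav = _grid_pair(vals, (3, 3, 3))
        thr = compute_adaptive_threshold(vol, cav)
        vals2 = vals.copy()
        vals2[1] = thr  # exactly at threshold
        vol2, _ = _grid_pair(vals2, (3, 3, 3))
        seg = segment_threshold(vol2, cav)
        assert not seg.defect_mask.ravel()[1]


# --------------------------------------------------------------------------
# k-means

class TestVentilationKMeans:
    def test_separated_groups_fixed_point(self):
        """Five separated constant groups: centers at the group values."""
        x = np.array([0] * 5 + [10] * 10 + [20] * 20 + [30] * 30 + [40] * 35, float)
        km = VentilationKMeans().fit(x)
        np.testing.assert_allclose(km.cluster_centers_, [0, 10, 20, 30, 40])
        assert km.converged_
        assert km.defect_labels().sum() == 5

    def test_degenerate_uniform_rejected(self, uniform_pair):
        vol, cav = uniform_pair
        with pytest.raises(ValueError, match="degenerate intensity"):
            segment_kmeans(vol, cav)

    def test_twelve_point_instance_is_dp_optimal(self):
        """Lloyd's fixed point matches the DP-exact contiguous optimum."""
        x = np.array([0, 1, 2, 10, 11, 20, 21, 30, 31, 40, 41, 42], float)
        km = VentilationKMeans(n_clusters=5).fit(x)
        assert km.inertia_ == pytest.approx(dp_kmeans_wcss(x, 5), abs=1e-9)

    def test_fixed_point_conditions_random_instances(self):
        """Every returned fit satisfies both Lloyd fixed-point conditions,
        and on well-separated instances it attains the DP optimum."""
        rng = np.random.default_rng(7)
        n_match = 0
        n_sep = 0
        for trial in range(60):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(k + 2, 61))
            separated = trial % 2 == 0
            if separated:
                centers = np.sort(rng.uniform(0, 100, k))
                while np.min(np.diff(centers)) < 15 if k > 1 else False:
                    centers = np.sort(rng.uniform(0, 100, k))
                x = np.concatenate([
                    c + rng.uniform(-1, 1, size=max(1, n // k)) for c in centers
                ])
            else:
                x = rng.uniform(0, 100, n)
            if np.unique(x).size < k:
                continue
            km = VentilationKMeans(n_clusters=k).fit(x)
            c = km.cluster_centers_
            lab = km.labels_
            # condition 1: every point assigned to its nearest center
            d = np.abs(x[:, None] - c[None, :])
            assert np.all(np.abs(d[np.arange(x.size), lab] - d.min(axis=1)) < 1e-9)
            # condition 2: every non-empty center equals its cluster mean
            for j in range(k):
                if np.any(lab == j):
                    assert c[j] == pytest.approx(x[lab == j].mean(), abs=1e-6)
            opt = dp_kmeans_wcss(x, k)
            assert km.inertia_ >= opt - 1e-9
            if separated:
                n_sep += 1
                if km.inertia_ <= opt + 1e-6 * max(opt, 1.0):
                    n_match += 1
        assert n_sep >= 20
        assert n_match == n_sep  # exact optimality on the separated subset

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(m, 2, 200) for m in (0, 10, 25, 40, 70)])
        km = VentilationKMeans().fit(x)
        path = np.asarray(km.objective_path_)
        assert np.all(np.diff(path) <= 1e-9)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            KMeansParams(k=1)
        with pytest.raises(ValueError):
            KMeansParams(defect_clusters=5, k=5)


# --------------------------------------------------------------------------
# VDP

class TestComputeVdp:
    def test_full_and_empty(self, hundred_voxel_pair):
        vol, cav = hundred_voxel_pair
        seg = segment_threshold(vol, cav)
        seg.defect_mask = cav.mask.copy()
        assert compute_vdp(seg, cav, vol).vdp_percent == 100.0
        seg.defect_mask = np.zeros_like(cav.mask)
        assert compute_vdp(seg, cav, vol).vdp_percent == 0.0

    def test_ten_percent_with_volumes(self, hundred_voxel_pair):
        """10/100 defect voxels at 4.42 mm isotropic: 10% and ~8.64 mL cavity."""
        vol, cav = hundred_voxel_pair
        seg = segment_threshold(vol, cav)
        res = compute_vdp(seg, cav, vol)
        assert res.vdp_percent == pytest.approx(10.0)
        assert res.cavity_volume_ml == pytest.approx(100 * 4.42 ** 3 / 1000.0)
        assert res.defect_volume_ml == pytest.approx(10 * 4.42 ** 3 / 1000.0)

    def test_defect_outside_cavity_rejected(self, hundred_voxel_pair):
        vol, cav = hundred_voxel_pair
        cav2 = CavityMask(cav.mask.copy(), cav.voxel_spacing)
        cav2.mask[0, 0, 0] = False
        seg = segment_threshold(vol, cav)
        seg.defect_mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            compute_vdp(seg, cav2, vol)

    def test_grid_mismatch_fails_before_compute(self, hundred_voxel_pair):
        vol, cav = hundred_voxel_pair
        bad_cav = CavityMask(np.ones((5, 5, 4), dtype=bool), voxel_spacing=(1, 1, 1))
        with pytest.raises(GridMismatchError):
            segment_threshold(vol, bad_cav)

    def test_vdp_result_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            VDPResult(vdp_percent=50.0, defect_volume_ml=1.0,
                      cavity_volume_ml=4.0, method="threshold", modality="SPECT")


# --------------------------------------------------------------------------
# scale invariance of both methods

@pytest.mark.parametrize("scale", [0.001, 0.5, 7.0, 1234.5])
def test_vdp_scale_invariance(scale):
    """Multiplying all intensities by c > 0 changes neither VDP_T nor VDP_K."""
    rng = np.random.default_rng(11)
    vals = np.concatenate([rng.uniform(0, 0.2, 40), rng.normal(1.0, 0.2, 160)])
    rng.shuffle(vals)
    vol, cav = _grid_pair(vals, (10, 5, 4))
    vol_s, _ = _grid_pair(vals * scale, (10, 5, 4))
    for fn in (segment_threshold, segment_kmeans):
        v1 = compute_vdp(fn(vol, cav), cav, vol).vdp_percent
        v2 = compute_vdp(fn(vol_s, cav), cav, vol_s).vdp_percent
        assert v1 == pytest.approx(v2, abs=1e-12)
        assert 0.0 <= v1 <= 100.0
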