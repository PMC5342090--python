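"""GLCM/GLRLM construction and measures against exhaustive brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from radrepro import (
    GeometrySet,
    glcm_features,
    glcm_slice,
    glrlm_features,
    glrlm_slice,
    normalize_by_volume,
)
from radrepro.texture import GLCM, GLRLM, VALUE_TYPES, _DIRECTIONS, aggregate
from radrepro.channels import ChannelConfig, DiscretizedRegion

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_glcm(levels, n_bins, distance=1):
    """Exhaustive enumeration over every pixel and every direction offset."""
    counts = np.zeros((n_bins, n_bins))
    n0, n1 = levels.shape
    for i in range(n0):
        for j in range(n1):
            if levels[i, j] == 0:
                continue
            for di, dj in _DIRECTIONS:
                for sign in (1, -1):
                    ni, nj = i + sign * di * distance, j + sign * dj * distance
                    if 0 <= ni < n0 and 0 <= nj < n1 and levels[ni, nj] > 0:
                        counts[levels[i, j] - 1, levels[ni, nj] - 1] += 1
    return counts


def brute_force_glrlm(levels, n_bins, max_run):
    """Exhaustive maximal-run enumeration along every line of each direction."""
    counts = np.zeros((n_bins, max_run))
    n0, n1 = levels.shape
    n_runs = 0
    for di, dj in _DIRECTIONS:
        starts = []
        for i in range(n0):
            for j in range(n1):
                pi, pj = i - di, j - dj
                if not (0 <= pi < n0 and 0 <= pj < n1):
                    starts.append((i, j))
        for i0, j0 in starts:
            line = []
            i, j = i0, j0
            while 0 <= i < n0 and 0 <= j < n1:
                line.append(levels[i, j])
                i, j = i + di, j + dj
            run_level, run_len = 0, 0
            for v in line + [0]:
                if v == run_level:
                    run_len += 1
                else:
                    if run_level > 0:
                        counts[run_level - 1, run_len - 1] += 1
                        n_runs += 1
                    run_level, run_len = v, 1
    return counts, n_runs


def naive_glcm_features(p):
    """All 20 co-occurrence measures via literal double loops (log base 2)."""
    ng = p.shape[0]

    def xlog2(v):
        return v * math.log2(v) if v > 0 else 0.0

    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    out = {}
    out["glcm_energy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    out["glcm_contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    autoc = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    out["glcm_correlation"] = (
        (autoc - mu_x * mu_y) / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
    )
    out["glcm_variance"] = sum(
        (i + 1 - mu_x) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["glcm_homogeneity"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    sa = sum(k * p_sum[k] for k in p_sum)
    out["glcm_sum_average"] = sa
    out["glcm_sum_variance"] = sum((k - sa) ** 2 * p_sum[k] for k in p_sum)
    out["glcm_sum_entropy"] = -sum(xlog2(p_sum[k]) for k in p_sum)
    hxy = -sum(xlog2(p[i, j]) for i in range(ng) for j in range(ng))
    out["glcm_entropy"] = hxy
    da = sum(k * p_diff[k] for k in p_diff)
    out["glcm_difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in p_diff)
    out["glcm_difference_entropy"] = -sum(xlog2(p_diff[k]) for k in p_diff)
    hx = -sum(xlog2(v) for v in px)
    hy = -sum(xlog2(v) for v in py)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0 and p[i, j] > 0
    )
    hxy2 = -sum(xlog2(px[i] * py[j]) for i in range(ng) for j in range(ng))
    out["glcm_imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["glcm_imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["glcm_dissimilarity"] = sum(
        abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["glcm_idn"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["glcm_idmn"] = sum(
        p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    out["glcm_cluster_shade"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["glcm_cluster_prominence"] = sum(
        (i + j + 2 - mu_x - mu_y) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
    )
    out["glcm_maximum_probability"] = max(p[i, j] for i in range(ng) for j in range(ng))
    out["glcm_autocorrelation"] = autoc
    return out


def naive_glrlm_features(r, n_runs, n_pixels, n_directions=4):
    """All 11 run-length measures via literal double loops."""
    ng, mr = r.shape
    nr = r.sum()
    out = {
        "glrlm_short_run_emphasis": sum(
            r[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
        "glrlm_long_run_emphasis": sum(
            r[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
        "glrlm_gray_level_nonuniformity": sum(
            sum(r[i, j] for j in range(mr)) ** 2 for i in range(ng)
        ),
        "glrlm_run_length_nonuniformity": sum(
            sum(r[i, j] for i in range(ng)) ** 2 for j in range(mr)
        ),
        "glrlm_low_gray_run_emphasis": sum(
            r[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
        "glrlm_high_gray_run_emphasis": sum(
            r[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
        "glrlm_short_run_low_gray_emphasis": sum(
            r[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(mr)
        ),
        "glrlm_short_run_high_gray_emphasis": sum(
            r[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
        "glrlm_long_run_low_gray_emphasis": sum(
            r[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
        "glrlm_long_run_high_gray_emphasis": sum(
            r[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(mr)
        ),
    }
    out = {k: v / nr for k, v in out.items()}
    out["glrlm_run_percentage"] = n_runs / (n_directions * n_pixels)
    return out


random_slices = hnp.arrays(
    dtype=np.int32,
    shape=st.tuples(st.integers(2, 12), st.integers(2, 12)),
    elements=st.integers(0, 4),  # 0 = out of mask, levels 1..4
)


# ---------------------------------------------------------------------------
# GLCM


class TestGLCM:
    def test_two_by_two_example(self):
        """levels [[1,2],[1,2]] full mask: counts verified by exhaustive
        enumeration over all direction/offset pairs."""
        levels = np.array([[1, 2], [1, 2]], dtype=np.int32)
        g = glcm_slice(levels, n_bins=2)
        np.testing.assert_array_equal(g.counts, brute_force_glcm(levels, 2))
        # 0deg: 2x (1,2) pairs both ways; 90deg: (1,1) and (2,2); diagonals:
        # one (1,2) pair each
        assert g.counts[0, 1] == g.counts[1, 0] == 4
        assert g.counts[0, 0] == g.counts[1, 1] == 2

    @given(random_slices)
    def test_matches_exhaustive_enumeration(self, levels):
        if (levels > 0).sum() < 2:
            return
        g = glcm_slice(levels, n_bins=4)
        oracle = brute_force_glcm(levels, 4)
        if g is None:
            assert oracle.sum() == 0
        else:
            np.testing.assert_array_equal(g.counts, oracle)
            assert g.counts.T.tolist() == g.counts.tolist()  # symmetric
            assert g.probabilities.sum() == pytest.approx(1.0)

    def test_constant_slice_mass_on_diagonal(self):
        levels = np.ones((5, 5), dtype=np.int32)
        g = glcm_slice(levels, n_bins=3)
        off_diag = g.counts - np.diag(np.diag(g.counts))
        assert off_diag.sum() == 0

    def test_transpose_invariance_of_accumulated_matrix(self, rng):
        for _ in range(5):
            levels = rng.integers(0, 5, size=(8, 8)).astype(np.int32)
            if (levels > 0).sum() < 4:
                continue
            a = glcm_slice(levels, n_bins=4)
            b = glcm_slice(levels.T.copy(), n_bins=4)
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_rotation_coherence(self, rng):
        """90-degree in-plane rotation leaves 4-direction GLCM features unchanged."""
        levels = rng.integers(1, 5, size=(9, 7)).astype(np.int32)
        a = glcm_features(glcm_slice(levels, n_bins=4))
        b = glcm_features(glcm_slice(np.rot90(levels).copy(), n_bins=4))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_mask_boundary_pairs_excluded(self):
        levels = np.array([[1, 0, 2]], dtype=np.int32)  # gap breaks adjacency
        assert glcm_slice(levels, n_bins=2) is None

    def test_distance_two(self):
        levels = np.array([[1, 2, 1, 2]], dtype=np.int32)
        g = glcm_slice(levels, n_bins=2, distance=2)
        np.testing.assert_array_equal(g.counts, brute_force_glcm(levels, 2, distance=2))


class TestGLCMFeatures:
    def test_constant_slice_degenerate_values(self):
        g = glcm_slice(np.ones((4, 4), dtype=np.int32), n_bins=4)
        f = glcm_features(g)
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert f["glcm_maximum_probability"] == 1.0

    def test_hand_evaluated_contrast(self):
        """Symmetric P(1,2)=P(2,1)=0.5 gives contrast 1 by the band-sum form."""
        counts = np.array([[0.0, 1.0], [1.0, 0.0]])
        f = glcm_features(GLCM(counts=counts, n_pairs=2))
        assert f["glcm_contrast"] == pytest.approx(1.0)

    def test_contrast_band_sum_identity(self, rng):
        """The n-indexed band sum over |i-j| = n equals the direct (i-j)^2
        moment (the two printed forms of contrast are algebraically equal)."""
        for _ in range(10):
            counts = rng.random((6, 6))
            counts = counts + counts.T
            p = counts / counts.sum()
            ng = 6
            band = sum(
                n**2 * sum(
                    p[i, j]
                    for i in range(ng)
                    for j in range(ng)
                    if abs(i - j) == n
                )
                for n in range(ng)
            )
            f = glcm_features(GLCM(counts=counts, n_pairs=counts.sum()))
            assert f["glcm_contrast"] == pytest.approx(band, abs=1e-12)

    def test_all_20_match_naive_reference(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 20, size=(5, 5)).astype(float)
            counts = counts + counts.T
            if counts.sum() == 0:
                continue
            f = glcm_features(GLCM(counts=counts, n_pairs=int(counts.sum())))
            ref = naive_glcm_features(counts / counts.sum())
            assert set(f) == set(ref)
            for k in ref:
                assert f[k] == pytest.approx(ref[k], abs=1e-12), k


# ---------------------------------------------------------------------------
# GLRLM


class TestGLRLM:
    def test_row_of_paired_levels(self):
        """(1,1,2,2) along 0 degrees: one run of each level, length 2."""
        levels = np.array([[1, 1, 2, 2]], dtype=np.int32)
        g = glrlm_slice(levels, n_bins=2, max_run=4)
        oracle, n_runs = brute_force_glrlm(levels, 2, 4)
        np.testing.assert_array_equal(g.counts, oracle)
        assert g.counts[0, 1] == 1 and g.counts[1, 1] == 1  # 0-degree runs
        assert g.n_runs == n_runs

    @given(random_slices)
    def test_matches_exhaustive_enumeration(self, levels):
        if not (levels > 0).any():
            return
        max_run = max(levels.shape)
        g = glrlm_slice(levels, n_bins=4, max_run=max_run)
        oracle, n_runs = brute_force_glrlm(levels, 4, max_run)
        np.testing.assert_array_equal(g.counts, oracle)
        assert g.n_runs == n_runs

    def test_no_equal_neighbors_all_runs_length_one(self):
        """A 4-level 2x2 tiling has no equal neighbors along any of the four
        directions (a plain 2-color checkerboard is constant along its
        diagonals), so every run has length 1."""
        ii, jj = np.indices((6, 6))
        levels = ((ii % 2) * 2 + (jj % 2) + 1).astype(np.int32)
        g = glrlm_slice(levels, n_bins=4, max_run=6)
        assert g.counts[:, 1:].sum() == 0

    def test_two_color_checkerboard_rows_and_columns(self):
        """On a 2-color board the axis-aligned directions see only length-1
        runs; the diagonals see full-length constant runs."""
        from radrepro.texture import _accumulate_runs, _direction_lines

        levels = (np.indices((6, 6)).sum(axis=0) % 2 + 1).astype(np.int32)
        for d in ((0, 1), (1, 0)):
            counts = np.zeros((2, 6))
            _accumulate_runs(_direction_lines(levels, *d), counts)
            assert counts[:, 1:].sum() == 0
        counts = np.zeros((2, 6))
        _accumulate_runs(_direction_lines(levels, 1, 1), counts)
        assert counts[:, 5].sum() == 1  # the main diagonal is one constant run
        assert counts[:, 4].sum() == 2  # its two length-5 neighbours

    @given(random_slices)
    def test_length_conservation_per_direction(self, levels):
        """Runs of one direction partition the in-mask pixels."""
        if not (levels > 0).any():
            return
        from radrepro.texture import _accumulate_runs, _direction_lines

        n_px = int((levels > 0).sum())
        for di, dj in _DIRECTIONS:
            counts = np.zeros((4, max(levels.shape)))
            _accumulate_runs(_direction_lines(levels, di, dj), counts)
            lengths = np.arange(1, counts.shape[1] + 1)
            assert int((counts * lengths).sum()) == n_px


class TestGLRLMFeatures:
    def test_all_length_one_runs_give_unit_emphases(self):
        ii, jj = np.indices((6, 6))
        levels = ((ii % 2) * 2 + (jj % 2) + 1).astype(np.int32)
        f = glrlm_features(glrlm_slice(levels, n_bins=4, max_run=6))
        assert f["glrlm_run_percentage"] == pytest.approx(1.0)
        assert f["glrlm_short_run_emphasis"] == pytest.approx(1.0)
        assert f["glrlm_long_run_emphasis"] == pytest.approx(1.0)

    def test_constant_row_long_run_emphasis(self):
        """A single run of length n contributes n^2 to LRE in its direction."""
        n = 7
        levels = np.ones((1, n), dtype=np.int32)
        counts = np.zeros((1, n))
        from radrepro.texture import _accumulate_runs

        n_runs = _accumulate_runs(levels[0], counts)
        f = naive_glrlm_features(counts, n_runs, n, n_directions=1)
        assert f["glrlm_long_run_emphasis"] == pytest.approx(n**2)

    def test_all_11_match_naive_reference(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 10, size=(5, 7)).astype(float)
            if counts.sum() == 0:
                continue
            n_runs = int(counts.sum())
            n_pixels = int((counts * np.arange(1, 8)).sum())  # consistent pixel count
            g = GLRLM(counts=counts, n_runs=n_runs, n_pixels=n_pixels)
            f = glrlm_features(g)
            ref = naive_glrlm_features(counts, n_runs, n_pixels)
            for k in ref:
                assert f[k] == pytest.approx(ref[k], abs=1e-12), k


# ---------------------------------------------------------------------------
# aggregation and normalization


def _region_from_levels(levels3d, n_bins):
    levels3d = np.asarray(levels3d, dtype=np.int32)
    return DiscretizedRegion(
        levels=levels3d, mask=levels3d > 0, n_bins=n_bins, level_edges=np.array([0, 1])
    )


class TestAggregate:
    CFG = ChannelConfig(log_sigmas_mm=(), wavelets=("original",))

    def test_single_slice_all_value_types_identical(self, rng):
        levels = rng.integers(1, 5, size=(6, 6, 1))
        values, _ = aggregate(_region_from_levels(levels, 4), 1.0, self.CFG)
        for measure, per_type in values.items():
            assert len(set(per_type[vt] for vt in VALUE_TYPES)) == 1, measure

    def test_identical_slices_collapse_extrema(self, rng):
        base = rng.integers(1, 5, size=(6, 6))
        levels = np.stack([base, base, base], axis=2)
        values, _ = aggregate(_region_from_levels(levels, 4), 1.0, self.CFG)
        for measure, per_type in values.items():
            assert per_type["max"] == per_type["min"] == per_type["max_slice"]
            assert per_type["average"] == pytest.approx(per_type["max"], rel=1e-12)

    def test_aggregation_ordering(self, rng):
        levels = rng.integers(0, 5, size=(8, 8, 5))
        levels[2:6, 2:6, :] = rng.integers(1, 5, size=(4, 4, 5))
        values, _ = aggregate(_region_from_levels(levels, 4), 1.0, self.CFG)
        for measure, per_type in values.items():
            assert per_type["min"] <= per_type["average"] + 1e-12
            assert per_type["average"] <= per_type["max"] + 1e-12
            assert per_type["min"] - 1e-12 <= per_type["max_slice"] <= per_type["max"] + 1e-12

    def test_matrix_sum_equals_pooled_pair_distribution(self, rng):
        """Summed-then-normalized GLCM equals pooling every slice's pairs in
        one exhaustive brute-force pass."""
        levels = rng.integers(0, 5, size=(7, 7, 4))
        levels[3, 3, :] = 1
        levels[3, 4, :] = 2
        region = _region_from_levels(levels, 4)
        values, _ = aggregate(region, 1.0, self.CFG)
        pooled = np.zeros((4, 4))
        for k in range(4):
            lv = region.levels[:, :, k]
            if (lv > 0).sum() >= 2 and brute_force_glcm(lv, 4).sum() > 0:
                pooled += brute_force_glcm(lv, 4)
        ref = naive_glcm_features(pooled / pooled.sum())
        for measure in self.CFG.measures_glcm:
            assert values[measure]["matrix_sum"] == pytest.approx(ref[measure], abs=1e-12)

    def test_degenerate_slices_excluded_and_counted(self):
        levels = np.zeros((6, 6, 3), dtype=np.int32)
        levels[2:4, 2:4, 0] = 1  # valid slice
        levels[3, 3, 1] = 1  # single pixel: excluded everywhere
        values, diag = aggregate(_region_from_levels(levels, 4), 1.0, self.CFG)
        assert diag["slices_skipped_small"] == 1
        assert diag["glcm_slices"] == 1 and diag["glrlm_slices"] == 1
        assert np.isfinite(values["glcm_contrast"]["average"])


class TestNormalization:
    GEO = GeometrySet(volume_mm3=846.4, area_mm2=537.28, v_over_a_mm=846.4 / 537.28)

    def test_arithmetic(self):
        assert normalize_by_volume(10.0, self.GEO) == pytest.approx(10.0 / 846.4)

    def test_linearity(self):
        a, b = 3.7, -1.2
        assert normalize_by_volume(a + b, self.GEO) == pytest.approx(
            normalize_by_volume(a, self.GEO) + normalize_by_volume(b, self.GEO)
        )

    def test_doubling_volume_halves_value(self):
        double = GeometrySet(volume_mm3=2 * 846.4, area_mm2=537.28, v_over_a_mm=1.0)
        assert normalize_by_volume(10.0, double) == pytest.approx(
            normalize_by_volume(10.0, self.GEO) / 2
        )

    def test_nonpositive_volume_rejected(self):
        bad = GeometrySet(volume_mm3=0.0, area_mm2=1.0, v_over_a_mm=0.0)
        with pytest.raises(ValueError):
            normalize_by_volume(1.0, bad)
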