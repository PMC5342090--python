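"""Per-slice co-occurrence / run-length texture and the five value types.

Matrices
--------
GLCM: pair counts of discretized gray levels at a fixed pixel distance
(default 1), accumulated over the four in-plane directions (0, 45, 90,
135 degrees) into a single symmetric matrix per slice. Each ordered pair is
counted both ways; pairs crossing the mask boundary are excluded.

GLRLM: counts of maximal same-level pixel runs by (level, length),
accumulated over the same four directions; runs are truncated at mask
boundaries.

Measures
--------
20 GLCM measures (the Haralick catalogue plus the normalized-inverse and
cluster statistics) and 11 GLRLM measures (Galloway emphasis/nonuniformity,
run percentage, and the Chu / Dasarathy-Holder gray-level-weighted
variants). Entropies use log base 2 with 0*log0 = 0. Degenerate inputs
(zero-variance marginals, vanishing entropies) return 0 for the affected
correlation-type measures rather than NaN.

Value types
-----------
Per-slice measures are condensed to one patient-level value five ways:
``max_slice`` (the slice with the largest in-mask area), ``max``, ``min``
and ``average`` elementwise over contributing slices, and ``matrix_sum``
(measures recomputed on the slice-summed matrix). Volume-normalized
counterparts divide by the tumor volume in mm^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .channels import (
    ChannelConfig,
    DiscretizedRegion,
    discretize,
    log_filter,
    wavelet_subbands,
)
from .volumes import GeometrySet, ImageVolume, ROIMask

logger = logging.getLogger(__name__)

__all__ = [
    "GLCM",
    "GLRLM",
    "VALUE_TYPES",
    "glcm_slice",
    "glcm_features",
    "glrlm_slice",
    "glrlm_features",
    "aggregate",
    "normalize_by_volume",
    "extract_scan_features",
]

VALUE_TYPES: tuple[str, ...] = ("max_slice", "max", "min", "average", "matrix_sum")

#: in-plane offsets for 0, 45, 90, 135 degrees in (row, col) index space
_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class GLCM:
    counts: np.ndarray  # n_bins x n_bins, symmetric
    n_pairs: int  # total (ordered) pair count = counts.sum()

    @property
    def probabilities(self) -> np.ndarray:
        if self.n_pairs == 0:
            return np.zeros_like(self.counts)
        return self.counts / self.n_pairs


@dataclass
class GLRLM:
    counts: np.ndarray  # n_bins x max_run
    n_runs: int
    n_pixels: int  # in-mask pixels of the contributing slice(s)
    n_directions: int = len(_DIRECTIONS)


# ---------------------------------------------------------------------------
# matrix construction


def glcm_slice(
    levels: np.ndarray, n_bins: int, distance: int = 1
) -> GLCM | None:
    """Symmetric 4-direction GLCM of one slice (levels: 0 = out of mask).

    Returns ``None`` when no valid in-mask pair exists at the given
    distance (degenerate slice).
    """
    levels = np.asarray(levels)
    n0, n1 = levels.shape
    counts = np.zeros((n_bins, n_bins), dtype=np.float64)
    for di, dj in _DIRECTIONS:
        di, dj = di * distance, dj * distance
        a_i = slice(max(0, -di), n0 - max(0, di))
        b_i = slice(max(0, di), n0 - max(0, -di))
        a_j = slice(max(0, -dj), n1 - max(0, dj))
        b_j = slice(max(0, dj), n1 - max(0, -dj))
        la, lb = levels[a_i, a_j], levels[b_i, b_j]
        if la.size == 0:
            continue
        valid = (la > 0) & (lb > 0)
        if not valid.any():
            continue
        np.add.at(counts, (la[valid] - 1, lb[valid] - 1), 1.0)
        np.add.at(counts, (lb[valid] - 1, la[valid] - 1), 1.0)
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        return None
    return GLCM(counts=counts, n_pairs=n_pairs)


def _accumulate_runs(line: np.ndarray, counts: np.ndarray) -> int:
    """Count maximal runs of positive levels in a 1D line (0 breaks runs)."""
    if line.size == 0:
        return 0
    change = np.flatnonzero(line[1:] != line[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [line.size - 1]))
    lengths = ends - starts + 1
    lev = line[starts]
    ok = lev > 0
    if ok.any():
        np.add.at(counts, (lev[ok] - 1, lengths[ok] - 1), 1.0)
    return int(ok.sum())


def _direction_lines(levels: np.ndarray, di: int, dj: int) -> np.ndarray:
    """All grid lines of a slice along one direction, 0-separated, flattened."""
    if (di, dj) == (0, 1):
        lines = [levels[i, :] for i in range(levels.shape[0])]
    elif (di, dj) == (1, 0):
        lines = [levels[:, j] for j in range(levels.shape[1])]
    elif (di, dj) == (1, 1):
        lines = [levels.diagonal(o) for o in range(-levels.shape[0] + 1, levels.shape[1])]
    elif (di, dj) == (1, -1):
        f = np.fliplr(levels)
        lines = [f.diagonal(o) for o in range(-f.shape[0] + 1, f.shape[1])]
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {(di, dj)}")
    sep = np.zeros(1, dtype=levels.dtype)
    parts = []
    for ln in lines:
        parts.append(ln)
        parts.append(sep)
    return np.concatenate(parts)


def glrlm_slice(levels: np.ndarray, n_bins: int, max_run: int | None = None) -> GLRLM:
    """4-direction GLRLM of one slice (levels: 0 = out of mask)."""
    levels = np.asarray(levels)
    if max_run is None:
        max_run = max(levels.shape)
    counts = np.zeros((n_bins, max_run), dtype=np.float64)
    n_runs = 0
    for di, dj in _DIRECTIONS:
        n_runs += _accumulate_runs(_direction_lines(levels, di, dj), counts)
    return GLRLM(counts=counts, n_runs=n_runs, n_pixels=int((levels > 0).sum()))


# ---------------------------------------------------------------------------
# measures


def _xlog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """The 20 co-occurrence measures of a (symmetric, normalized) GLCM."""
    p = glcm.probabilities
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))
    diff = ii - jj
    absdiff = np.abs(diff)

    # diagonal-band and anti-diagonal-band marginals
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(k_sum.size)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())

    autocorr = float(np.sum(ii * jj * p))
    contrast = float(np.sum(diff**2 * p))
    if sd_x > 0 and sd_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0  # degenerate marginal sentinel
        logger.debug("zero-variance GLCM marginal; correlation set to 0")

    entropy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxpy = np.outer(px, py)
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log2(pxpy[nz])
    hxy1 = float(-np.sum(p * log_pxpy))
    hxy2 = float(-_xlog2(pxpy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    sum_average = float(np.sum(k_sum * p_sum))
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    diff_average = float(np.sum(k_diff * p_diff))

    return {
        "glcm_energy": float(np.sum(p**2)),
        "glcm_contrast": contrast,
        "glcm_correlation": float(correlation),
        "glcm_variance": float(np.sum((ii - mu_x) ** 2 * p)),
        "glcm_homogeneity": float(np.sum(p / (1.0 + diff**2))),
        "glcm_sum_average": sum_average,
        "glcm_sum_variance": sum_variance,
        "glcm_sum_entropy": float(-_xlog2(p_sum).sum()),
        "glcm_entropy": entropy,
        "glcm_difference_variance": float(np.sum((k_diff - diff_average) ** 2 * p_diff)),
        "glcm_difference_entropy": float(-_xlog2(p_diff).sum()),
        "glcm_imc1": float(imc1),
        "glcm_imc2": imc2,
        "glcm_dissimilarity": float(np.sum(absdiff * p)),
        "glcm_idn": float(np.sum(p / (1.0 + absdiff / ng))),
        "glcm_idmn": float(np.sum(p / (1.0 + diff**2 / ng**2))),
        "glcm_cluster_shade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "glcm_cluster_prominence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "glcm_maximum_probability": float(p.max()),
        "glcm_autocorrelation": autocorr,
    }


def glrlm_features(glrlm: GLRLM) -> dict[str, float]:
    """The 11 run-length measures of an (accumulated) GLRLM.

    Run percentage divides total runs by (pixels per direction x number of
    directions), which equals the per-direction run percentages averaged
    over directions.
    """
    r = glrlm.counts
    nr = r.sum()
    if nr == 0:
        raise ValueError("GLRLM has no runs")
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(np.float64)
    j = np.arange(1, r.shape[1] + 1)[None, :].astype(np.float64)
    r_i = r.sum(axis=1)
    r_j = r.sum(axis=0)
    return {
        "glrlm_short_run_emphasis": float(np.sum(r / j**2) / nr),
        "glrlm_long_run_emphasis": float(np.sum(r * j**2) / nr),
        "glrlm_gray_level_nonuniformity": float(np.sum(r_i**2) / nr),
        "glrlm_run_length_nonuniformity": float(np.sum(r_j**2) / nr),
        "glrlm_run_percentage": float(nr / (glrlm.n_directions * glrlm.n_pixels)),
        "glrlm_low_gray_run_emphasis": float(np.sum(r / i**2) / nr),
        "glrlm_high_gray_run_emphasis": float(np.sum(r * i**2) / nr),
        "glrlm_short_run_low_gray_emphasis": float(np.sum(r / (i**2 * j**2)) / nr),
        "glrlm_short_run_high_gray_emphasis": float(np.sum(r * i**2 / j**2) / nr),
        "glrlm_long_run_low_gray_emphasis": float(np.sum(r * j**2 / i**2) / nr),
        "glrlm_long_run_high_gray_emphasis": float(np.sum(r * i**2 * j**2) / nr),
    }


# ---------------------------------------------------------------------------
# aggregation over slices


def _aggregate_family(
    per_slice: list[dict[str, float]],
    areas: list[float],
    pooled_features: dict[str, float],
    measures: tuple[str, ...],
) -> dict[str, dict[str, float]]:
    """Fold per-slice measure dicts into the five value types."""
    out: dict[str, dict[str, float]] = {m: {} for m in measures}
    best = int(np.argmax(areas))  # np.argmax returns the first (lowest) index on ties
    for m in measures:
        vals = np.array([d[m] for d in per_slice])
        out[m]["max_slice"] = float(per_slice[best][m])
        out[m]["max"] = float(vals.max())
        out[m]["min"] = float(vals.min())
        out[m]["average"] = float(vals.mean())
        out[m]["matrix_sum"] = float(pooled_features[m])
    return out


def aggregate(
    region: DiscretizedRegion,
    pixel_area_mm2: float,
    config: ChannelConfig,
    distance: int = 1,
) -> tuple[dict[str, dict[str, float]], dict[str, int]]:
    """Compute all 31 measures x 5 value types for one discretized channel.

    Slices with fewer than 2 in-mask pixels are excluded; slices without a
    valid pixel pair are additionally excluded from the GLCM family. Returns
    ``(values, diagnostics)`` where ``values[measure][value_type]`` is a
    float (NaN when a family had no valid slice) and diagnostics counts the
    exclusions.
    """
    n_bins = region.n_bins
    max_run = max(region.levels.shape[0], region.levels.shape[1])
    glcm_feats: list[dict[str, float]] = []
    glcm_areas: list[float] = []
    glcm_counts = np.zeros((n_bins, n_bins))
    glrlm_feats: list[dict[str, float]] = []
    glrlm_areas: list[float] = []
    glrlm_counts = np.zeros((n_bins, max_run))
    glrlm_runs = 0
    glrlm_pixels = 0
    n_skipped_small = 0
    n_skipped_pairs = 0

    for k in range(region.levels.shape[2]):
        lv = region.levels[:, :, k]
        npx = int((lv > 0).sum())
        if npx < 2:
            if npx > 0:
                n_skipped_small += 1
            continue
        area = npx * pixel_area_mm2
        g = glcm_slice(lv, n_bins, distance=distance)
        if g is None:
            n_skipped_pairs += 1
        else:
            glcm_feats.append(glcm_features(g))
            glcm_areas.append(area)
            glcm_counts += g.counts
        rl = glrlm_slice(lv, n_bins, max_run=max_run)
        glrlm_feats.append(glrlm_features(rl))
        glrlm_areas.append(area)
        glrlm_counts += rl.counts
        glrlm_runs += rl.n_runs
        glrlm_pixels += rl.n_pixels

    values: dict[str, dict[str, float]] = {}
    if glcm_feats:
        pooled = glcm_features(GLCM(counts=glcm_counts, n_pairs=int(glcm_counts.sum())))
        values.update(
            _aggregate_family(glcm_feats, glcm_areas, pooled, config.measures_glcm)
        )
    else:
        values.update({m: dict.fromkeys(VALUE_TYPES, float("nan")) for m in config.measures_glcm})
    if glrlm_feats:
        pooled = glrlm_features(
            GLRLM(counts=glrlm_counts, n_runs=glrlm_runs, n_pixels=glrlm_pixels)
        )
        values.update(
            _aggregate_family(glrlm_feats, glrlm_areas, pooled, config.measures_glrlm)
        )
    else:
        values.update({m: dict.fromkeys(VALUE_TYPES, float("nan")) for m in config.measures_glrlm})

    diagnostics = {
        "slices_skipped_small": n_skipped_small,
        "slices_skipped_no_pairs": n_skipped_pairs,
        "glcm_slices": len(glcm_feats),
        "glrlm_slices": len(glrlm_feats),
    }
    return values, diagnostics


def normalize_by_volume(value: float, geometry: GeometrySet) -> float:
    """Divide a feature value by the tumor volume (units: per mm^3)."""
    if geometry.volume_mm3 <= 0:
        raise ValueError("volume must be positive for normalization")
    return value / geometry.volume_mm3


# ---------------------------------------------------------------------------
# per-scan driver


def extract_scan_features(
    image: ImageVolume,
    mask: ROIMask,
    config: ChannelConfig = ChannelConfig(),
    distance: int = 1,
):
    """Extract the full feature table for one scan.

    Returns ``(frame, diagnostics)`` where ``frame`` is a long-format
    DataFrame with columns (feature_id, value_type, raw_value) covering
    every manifest identifier, and ``diagnostics`` maps channel names to
    slice-exclusion counts. Channels whose mask collapses below 2 voxels
    are skipped (values NaN) with a logged reason.
    """
    import pandas as pd

    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    rows: list[dict] = []
    diagnostics: dict[str, dict[str, int]] = {}

    for filt in config.filters:
        if filt == "original":
            fimg = image
        else:
            sigma = float(filt.removeprefix("log_").removesuffix("mm"))
            fimg = log_filter(image, sigma)
        subbands = None
        for wav in config.wavelets:
            if wav == "original":
                cimg, cmask = fimg, mask
            else:
                if subbands is None:
                    subbands = wavelet_subbands(fimg, mask, family=config.wavelet_family)
                cimg, cmask = subbands[wav]
            channel = f"{filt}/{wav}"
            if cmask.n_voxels < 2:
                logger.info("channel %s skipped: mask below 2 voxels", channel)
                values = {
                    m: dict.fromkeys(VALUE_TYPES, float("nan")) for m in config.measures
                }
                diagnostics[channel] = {"skipped_channel": 1}
            else:
                dx, dy, _ = cimg.spacing_mm
                disc = discretize(cimg.values, cmask.flags, n_bins=config.n_bins)
                values, diag = aggregate(disc, dx * dy, config, distance=distance)
                diagnostics[channel] = diag
            for m in config.measures:
                for vt in VALUE_TYPES:
                    rows.append(
                        {
                            "feature_id": f"{filt}/{wav}/{m}",
                            "value_type": vt,
                            "raw_value": values[m][vt],
                        }
                    )
    return pd.DataFrame(rows), diagnostics
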