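"""Image channels for texture measurement.

A *channel* is one (filter, wavelet) combination of the image on which the
31 texture measures are evaluated:

* filter: the original HU image or a per-slice 2D Laplacian-of-Gaussian
  (LoG) response at a width given in millimetres;
* wavelet: the filter output itself ("original") or one of the four
  sub-bands (LL, LH, HL, HH) of a single-level per-slice 2D discrete
  wavelet transform.

Filtering and wavelets are strictly 2D (per slice): with 5 mm slices and
sub-millimetre pixels a 3D kernel would be severely anisotropic, and the
five slice-aggregation value types are intrinsically slice-wise.

The default configuration — 5 filter channels (original + 4 LoG widths)
x 5 wavelet channels x 31 texture measures — enumerates the canonical
775-feature manifest. Gray levels are discretized per channel into
``n_bins`` (default 32) equal-width bins spanning the in-mask range of that
channel, since filter responses have unrelated dynamic ranges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .volumes import ImageVolume, ROIMask

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelConfig",
    "DiscretizedRegion",
    "FeatureManifest",
    "MEASURES_GLCM",
    "MEASURES_GLRLM",
    "log_filter",
    "wavelet_subbands",
    "discretize",
    "enumerate_manifest",
]

#: the 20 gray-level co-occurrence measures (Haralick and descendants)
MEASURES_GLCM: tuple[str, ...] = (
    "glcm_energy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_variance",
    "glcm_homogeneity",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_dissimilarity",
    "glcm_idn",
    "glcm_idmn",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_maximum_probability",
    "glcm_autocorrelation",
)

#: the 11 gray-level run-length measures (Galloway + Chu + Dasarathy-Holder)
MEASURES_GLRLM: tuple[str, ...] = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_gray_level_nonuniformity",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
    "glrlm_low_gray_run_emphasis",
    "glrlm_high_gray_run_emphasis",
    "glrlm_short_run_low_gray_emphasis",
    "glrlm_short_run_high_gray_emphasis",
    "glrlm_long_run_low_gray_emphasis",
    "glrlm_long_run_high_gray_emphasis",
)

WAVELET_CHANNELS: tuple[str, ...] = ("original", "LL", "LH", "HL", "HH")


@dataclass(frozen=True)
class ChannelConfig:
    """Which channels to compute and how to discretize them."""

    log_sigmas_mm: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5)
    wavelet_family: str = "coif1"
    wavelets: tuple[str, ...] = WAVELET_CHANNELS
    n_bins: int = 32
    measures_glcm: tuple[str, ...] = MEASURES_GLCM
    measures_glrlm: tuple[str, ...] = MEASURES_GLRLM

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigmas must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 gray-level bins")
        unknown = set(self.wavelets) - set(WAVELET_CHANNELS)
        if unknown:
            raise ValueError(f"unknown wavelet channels: {sorted(unknown)}")

    @property
    def filters(self) -> tuple[str, ...]:
        return ("original",) + tuple(f"log_{s:g}mm" for s in self.log_sigmas_mm)

    @property
    def measures(self) -> tuple[str, ...]:
        return self.measures_glcm + self.measures_glrlm

    @classmethod
    def reduced(cls) -> "ChannelConfig":
        """Fast profile: one LoG width, no wavelet sub-bands (62 features)."""
        return cls(log_sigmas_mm=(1.5,), wavelets=("original",))


@dataclass
class DiscretizedRegion:
    """In-mask gray levels in 1..n_bins on the full grid (0 outside)."""

    levels: np.ndarray  # int array, 0 = out of mask
    mask: np.ndarray
    n_bins: int
    level_edges: np.ndarray


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature identifiers ``filter/wavelet/measure``."""

    ids: tuple[str, ...]
    filters: tuple[str, ...]
    wavelets: tuple[str, ...]
    measures: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fid in self.ids:
            fam = "GLCM" if fid.rsplit("/", 1)[1].startswith("glcm_") else "GLRLM"
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def to_frame(self):
        import pandas as pd

        rows = []
        for fid in self.ids:
            filt, wav, meas = fid.split("/")
            fam = "GLCM" if meas.startswith("glcm_") else "GLRLM"
            rows.append(
                {"feature_id": fid, "filter": filt, "wavelet": wav, "family": fam, "measure": meas}
            )
        return pd.DataFrame(rows)


def enumerate_manifest(config: ChannelConfig = ChannelConfig()) -> FeatureManifest:
    """Enumerate feature identifiers: filter outer, wavelet middle, measure inner.

    The default configuration yields exactly 5 x 5 x 31 = 775 identifiers.
    """
    ids = tuple(
        f"{filt}/{wav}/{meas}"
        for filt in config.filters
        for wav in config.wavelets
        for meas in config.measures
    )
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature identifiers in configuration")
    return FeatureManifest(
        ids=ids, filters=config.filters, wavelets=config.wavelets, measures=config.measures
    )


# ---------------------------------------------------------------------------
# filters


def log_filter(image: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Per-slice 2D Laplacian-of-Gaussian response at width ``sigma_mm``.

    Sigma is converted to pixels per in-plane axis from the image spacing;
    widths below half a pixel are clamped (with a warning) to avoid an
    effectively empty kernel. Output grid and spacing are unchanged.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    dx, dy, _ = image.spacing_mm
    sigma_px = [sigma_mm / dx, sigma_mm / dy]
    if min(sigma_px) < 0.5:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below half a pixel; clamping", stacklevel=2
        )
        sigma_px = [max(s, 0.5) for s in sigma_px]
    def operator(sl: np.ndarray) -> np.ndarray:
        # second derivatives are taken per pixel; divide by spacing^2 so the
        # response is a physical Laplacian in mm^-2 (spacing-comparable)
        return (
            ndimage.gaussian_filter(sl, sigma=sigma_px, order=(2, 0)) / dx**2
            + ndimage.gaussian_filter(sl, sigma=sigma_px, order=(0, 2)) / dy**2
        )

    # the truncated discrete kernel has a small DC bias; subtract it so the
    # operator annihilates constants exactly
    probe = int(np.ceil(8 * max(sigma_px))) | 1
    dc_bias = operator(np.ones((probe, probe)))[probe // 2, probe // 2]
    out = np.empty_like(image.values)
    for k in range(image.shape[2]):
        sl = image.values[:, :, k]
        out[:, :, k] = operator(sl) - dc_bias * sl
    return ImageVolume(values=out, spacing_mm=image.spacing_mm)


def _downsample_mask(mask2d: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """2x2 parent-block mask rule: a sub-band pixel is in-mask iff >= 2 of
    its (up to) 4 parent pixels are in-mask."""
    n0, n1 = out_shape
    padded = np.zeros((2 * n0, 2 * n1), dtype=bool)
    padded[: mask2d.shape[0], : mask2d.shape[1]] = mask2d
    counts = (
        padded[0::2, 0::2].astype(np.int8)
        + padded[0::2, 1::2]
        + padded[1::2, 0::2]
        + padded[1::2, 1::2]
    )
    return counts >= 2


def wavelet_subbands(
    image: ImageVolume, mask: ROIMask, family: str = "coif1"
) -> dict[str, tuple[ImageVolume, ROIMask]]:
    """Single-level per-slice 2D DWT: LL, LH, HL, HH at half in-plane resolution.

    Uses periodized boundary handling so each sub-band has exactly
    ``ceil(n/2)`` samples per axis, which makes the 2x2 parent-block mask
    downsampling rule well defined. In-plane spacing doubles; slice spacing
    is unchanged. Channels whose downsampled mask keeps fewer than 2 pixels
    anywhere are still returned; the texture stage skips them with a log.
    """
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    nx, ny, nz = image.shape
    if nx < 2 or ny < 2:
        raise ValueError("slices must be at least 2x2 for a wavelet level")
    out_xy = (int(np.ceil(nx / 2)), int(np.ceil(ny / 2)))
    bands = {name: np.empty(out_xy + (nz,)) for name in ("LL", "LH", "HL", "HH")}
    for k in range(nz):
        ll, (lh, hl, hh) = pywt.dwt2(image.values[:, :, k], family, mode="periodization")
        bands["LL"][:, :, k] = ll
        bands["LH"][:, :, k] = lh
        bands["HL"][:, :, k] = hl
        bands["HH"][:, :, k] = hh

    sub_mask = np.empty(out_xy + (nz,), dtype=bool)
    for k in range(nz):
        sub_mask[:, :, k] = _downsample_mask(mask.flags[:, :, k], out_xy)

    dx, dy, dz = image.spacing_mm
    spacing = (2 * dx, 2 * dy, dz)
    roi = ROIMask(flags=sub_mask, spacing_mm=spacing)
    return {
        name: (ImageVolume(values=arr, spacing_mm=spacing), roi) for name, arr in bands.items()
    }


# ---------------------------------------------------------------------------
# discretization


def discretize(values: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> DiscretizedRegion:
    """Equal-width discretization of in-mask values into levels 1..n_bins.

    Bins span [in-mask min, in-mask max]; the maximum maps to level
    ``n_bins``; a constant region maps entirely to level 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.asarray(values, dtype=np.float64)[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels to discretize")
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values inside the mask")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        edges = np.array([lo, hi])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        binned = np.floor((np.asarray(values) - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
        levels[mask] = np.clip(binned[mask], 1, n_bins)
    return DiscretizedRegion(levels=levels, mask=mask, n_bins=n_bins, level_edges=edges)
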