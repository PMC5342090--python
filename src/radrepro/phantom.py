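"""Paired repeat-scan phantom generator.

Emulates a test-retest CT cohort: each "patient" is a quasi-ellipsoidal
tumor with spatially correlated HU texture, imaged twice. The second scan is
the first one's continuous fields resampled under a small rigid shift and an
isotropic radial dilation (volume growth), plus independent additive noise.

Model
-----
* Tumor shape: level set ``L(x) = 1 - r(x)/R + a*G_s(x)`` where ``r`` is the
  physical distance to the tumor centre, ``R`` the nominal radius, ``G_s`` a
  unit-variance Gaussian random field with correlation length
  ``shape_corr_len_mm`` and ``a = shape_irregularity``. The mask is
  ``L > 0``; with ``a = 0`` it is an exact digital sphere (debug shape).
  Irregularity makes run-length/co-occurrence statistics non-degenerate,
  like clinical GTVs.
* Texture: stationary Gaussian random field built by Gaussian smoothing of
  white noise with correlation length ``texture_corr_len_mm`` (mm-aware, so
  it respects anisotropic spacing), rescaled to moments
  ``(hu_mean, hu_sd)``. Background is constant ``background_hu``.
* Rescan: coordinates are scaled by ``factor**(1/3)`` about the tumor centre
  (so mask volume scales by ``factor``) and jittered by a rigid shift drawn
  uniformly within ``rescan_shift_mm`` per axis; the level set and texture
  fields are linearly resampled under that map and independent Gaussian
  noise of SD ``rescan_noise_sd`` is added. The grown mask is taken as the
  top-k voxels of the resampled level set with ``k = round(factor * k1)``,
  which pins the realized volume ratio to ``factor`` within one voxel.

Seed discipline: every stochastic component draws from its own
``numpy.random.SeedSequence([master_seed, patient_index, stream_id])``
stream, so cohorts are bit-reproducible and the scan-2 noise realization is
invariant under changes of the noise SD (the SD only scales a fixed
unit-variance field — useful for noise-ladder experiments).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, ROIMask, write_nifti

__all__ = [
    "PhantomConfig",
    "PhantomPair",
    "PhantomSizingError",
    "generate_phantom",
    "perturb_rescan",
    "generate_cohort",
    "write_cohort",
]

# stream ids for SeedSequence([seed, patient, stream])
_STREAM_SHAPE = 0
_STREAM_TEXTURE = 1
_STREAM_PATIENT = 2  # radius / growth-factor jitter
_STREAM_RESCAN = 3  # shift draw, then unit-variance noise field


class PhantomSizingError(ValueError):
    """Tumor (including growth and shift margin) does not fit in the grid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic patient / cohort.

    Defaults reproduce the imaging geometry of the emulated protocol
    (0.92 x 0.92 mm pixels, 5 mm slices) with a ~33 cm3 nominal tumor, soft
    tissue HU statistics, and a mean between-scan volume growth of 5.8%.
    """

    grid_shape: tuple[int, int, int] = (84, 84, 20)
    spacing_mm: tuple[float, float, float] = (0.92, 0.92, 5.0)
    tumor_radius_mm: float = 20.0
    shape_irregularity: float = 0.15  # 0 -> exact sphere (debug)
    shape_corr_len_mm: float = 8.0
    texture_corr_len_mm: float = 3.0
    hu_mean: float = 40.0
    hu_sd: float = 30.0
    background_hu: float = -1000.0
    rescan_volume_factor: float = 1.058
    rescan_volume_log_sd: float = 0.10  # per-patient lognormal jitter of the factor
    rescan_noise_sd: float = 10.0
    rescan_shift_mm: float = 1.0
    radius_log_sd: float = 0.20  # per-patient lognormal jitter of the radius
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive")
        if self.rescan_volume_factor <= 0:
            raise ValueError("rescan_volume_factor must be positive")
        if self.hu_sd < 0 or self.rescan_noise_sd < 0 or self.rescan_shift_mm < 0:
            raise ValueError("noise/shift amplitudes must be nonnegative")


@dataclass
class PhantomPair:
    """One patient's repeat-scan pair on a shared grid."""

    patient_id: str
    scan1: ImageVolume
    mask1: ROIMask
    scan2: ImageVolume
    mask2: ROIMask


def _rng(seed: int, patient: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(patient), int(stream)]))


def _correlated_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    corr_len_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance stationary Gaussian field, correlation length in mm."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_len_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _check_fits(config: PhantomConfig, radius_mm: float) -> None:
    # margin covers irregularity wobble, maximal growth and the rigid shift
    margin = radius_mm * (1.0 + 2.5 * config.shape_irregularity)
    margin *= max(config.rescan_volume_factor, 1.0) ** (1.0 / 3.0)
    margin += config.rescan_shift_mm
    half_extent = [n * s / 2.0 - s for n, s in zip(config.grid_shape, config.spacing_mm)]
    if any(margin > h for h in half_extent):
        raise PhantomSizingError(
            f"tumor radius {radius_mm:.1f} mm (with growth/shift margin "
            f"{margin:.1f} mm) exceeds grid half-extents {[round(h, 1) for h in half_extent]} mm"
        )


def _phys_coords(config: PhantomConfig) -> list[np.ndarray]:
    return [
        np.arange(n) * s for n, s in zip(config.grid_shape, config.spacing_mm)
    ]


def generate_phantom(
    config: PhantomConfig,
    seed: int | None = None,
    patient_index: int = 0,
    radius_mm: float | None = None,
) -> tuple[ImageVolume, ROIMask]:
    """Generate one baseline scan: textured tumor on a flat background.

    Returns an :class:`ImageVolume` (whose ``aux`` carries the continuous
    level-set and texture fields needed by :func:`perturb_rescan`) and the
    tumor :class:`ROIMask`.
    """
    seed = config.seed if seed is None else seed
    radius = float(config.tumor_radius_mm if radius_mm is None else radius_mm)
    _check_fits(config, radius)

    ax = _phys_coords(config)
    center = [a[-1] / 2.0 for a in ax]
    dist2 = (
        (ax[0][:, None, None] - center[0]) ** 2
        + (ax[1][None, :, None] - center[1]) ** 2
        + (ax[2][None, None, :] - center[2]) ** 2
    )
    sphere_ls = 1.0 - np.sqrt(dist2) / radius
    n_target = int((sphere_ls > 0.0).sum())
    if n_target == 0:
        raise PhantomSizingError("tumor radius below voxel resolution")
    if config.shape_irregularity > 0:
        g = _correlated_field(
            config.grid_shape, config.spacing_mm, config.shape_corr_len_mm,
            _rng(seed, patient_index, _STREAM_SHAPE),
        )
        levelset = sphere_ls + config.shape_irregularity * g
        # volume-preserving irregularity: keep the digital-sphere voxel count
        # so the nominal radius still controls tumor volume exactly
        flat = levelset.ravel()
        top = np.argpartition(flat, flat.size - n_target)[flat.size - n_target:]
        mask_flags = np.zeros(flat.size, dtype=bool)
        mask_flags[top] = True
        mask_flags = mask_flags.reshape(config.grid_shape)
        # re-anchor the level set so mask == {levelset > 0} for the rescan step
        threshold = flat[top].min()
        levelset = levelset - threshold
    else:
        levelset = sphere_ls
        mask_flags = levelset > 0.0

    texture = config.hu_mean + config.hu_sd * _correlated_field(
        config.grid_shape, config.spacing_mm, config.texture_corr_len_mm,
        _rng(seed, patient_index, _STREAM_TEXTURE),
    )
    values = np.where(mask_flags, texture, config.background_hu)

    image = ImageVolume(values=values, spacing_mm=config.spacing_mm)
    image.aux["levelset"] = levelset
    image.aux["texture"] = texture
    image.aux["center_mm"] = tuple(center)
    return image, ROIMask(flags=mask_flags, spacing_mm=config.spacing_mm)


def _resample(field: np.ndarray, coords: list[np.ndarray]) -> np.ndarray:
    grid = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(field, np.stack(grid), order=1, mode="nearest")


def perturb_rescan(
    pair_base: tuple[ImageVolume, ROIMask],
    config: PhantomConfig,
    seed: int | None = None,
    patient_index: int = 0,
    volume_factor: float | None = None,
) -> tuple[ImageVolume, ROIMask]:
    """Simulate the second scan from a baseline scan.

    The base level-set and texture fields are resampled under an isotropic
    dilation by ``factor**(1/3)`` about the tumor centre composed with a
    random rigid shift, then independent Gaussian noise is added. The
    returned mask has ``round(factor * n1)`` voxels by construction.
    """
    image1, mask1 = pair_base
    seed = config.seed if seed is None else seed
    factor = float(config.rescan_volume_factor if volume_factor is None else volume_factor)
    if factor <= 0:
        raise ValueError("volume factor must be positive")

    levelset = image1.aux.get("levelset")
    texture = image1.aux.get("texture")
    if levelset is None or texture is None:
        # stand-alone use on a plain image: treat the mask indicator as the
        # level set and extend in-mask texture into the background by
        # nearest-neighbour fill so interpolation never mixes background in
        levelset = mask1.flags.astype(float) - 0.5
        _, nearest = ndimage.distance_transform_edt(
            ~mask1.flags, sampling=image1.spacing_mm, return_indices=True
        )
        texture = image1.values[tuple(nearest)]
    center = image1.aux.get(
        "center_mm",
        tuple((n - 1) * s / 2.0 for n, s in zip(image1.shape, image1.spacing_mm)),
    )

    rng = _rng(seed, patient_index, _STREAM_RESCAN)
    shift = rng.uniform(-config.rescan_shift_mm, config.rescan_shift_mm, size=3)
    noise_unit = rng.standard_normal(image1.shape)  # drawn before scaling: ladder-stable

    scale = factor ** (1.0 / 3.0)
    n1 = mask1.n_voxels
    n2 = int(round(factor * n1))
    if n2 < 1:
        raise PhantomSizingError("volume factor collapses the mask")

    identity = factor == 1.0 and not shift.any()
    if identity:
        levelset2, texture2 = levelset, texture
        mask2_flags = mask1.flags.copy()
    else:
        # inverse map: position x in scan 2 reads the base field at
        # (x - c - shift)/scale + c, expressed in voxel coordinates
        coords = []
        for a in range(3):
            x = np.arange(image1.shape[a]) * image1.spacing_mm[a]
            src_mm = (x - center[a] - shift[a]) / scale + center[a]
            coords.append(src_mm / image1.spacing_mm[a])
        levelset2 = _resample(levelset, coords)
        texture2 = _resample(texture, coords)
        flat = levelset2.ravel()
        if n2 > flat.size:
            raise PhantomSizingError("grown tumor exceeds the grid")
        top = np.argpartition(flat, flat.size - n2)[flat.size - n2:]
        mask2_flags = np.zeros(flat.size, dtype=bool)
        mask2_flags[top] = True
        mask2_flags = mask2_flags.reshape(image1.shape)
        border = (
            mask2_flags[0].any() or mask2_flags[-1].any()
            or mask2_flags[:, 0].any() or mask2_flags[:, -1].any()
            or mask2_flags[:, :, 0].any() or mask2_flags[:, :, -1].any()
        )
        if border:
            raise PhantomSizingError("grown tumor touches the grid border")

    if config.rescan_noise_sd > 0:
        texture2 = texture2 + config.rescan_noise_sd * noise_unit
    values2 = np.where(mask2_flags, texture2, config.background_hu)

    image2 = ImageVolume(values=values2, spacing_mm=image1.spacing_mm)
    image2.aux["levelset"] = levelset2
    image2.aux["texture"] = texture2
    return image2, ROIMask(flags=mask2_flags, spacing_mm=image1.spacing_mm)


def generate_cohort(
    n_patients: int, config: PhantomConfig, seed: int | None = None
) -> list[PhantomPair]:
    """Generate ``n_patients`` independent repeat-scan pairs.

    Per-patient nominal radii and growth factors are lognormally jittered
    around the configured values (clipped so every tumor fits the grid);
    all randomness derives from the master seed.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients for agreement statistics")
    seed = config.seed if seed is None else seed
    pairs: list[PhantomPair] = []
    for i in range(n_patients):
        prng = _rng(seed, i, _STREAM_PATIENT)
        max_radius = _max_radius(config)
        # truncated lognormal via rejection so clipping never collides patients
        radius = None
        for _ in range(100):
            draw = config.tumor_radius_mm * float(
                np.exp(config.radius_log_sd * prng.standard_normal())
            )
            if 8.0 <= draw <= max_radius:
                radius = draw
                break
        if radius is None:
            radius = float(np.clip(config.tumor_radius_mm, 8.0, max_radius))
        factor = config.rescan_volume_factor * float(
            np.exp(config.rescan_volume_log_sd * prng.standard_normal())
        )
        factor = float(np.clip(factor, 0.7, 1.5))
        scan1, mask1 = generate_phantom(config, seed=seed, patient_index=i, radius_mm=radius)
        scan2, mask2 = perturb_rescan(
            (scan1, mask1), config, seed=seed, patient_index=i, volume_factor=factor
        )
        pairs.append(
            PhantomPair(patient_id=f"P{i:03d}", scan1=scan1, mask1=mask1, scan2=scan2, mask2=mask2)
        )
    return pairs


def _max_radius(config: PhantomConfig) -> float:
    half_extent = min(n * s / 2.0 - s for n, s in zip(config.grid_shape, config.spacing_mm))
    denom = (1.0 + 2.5 * config.shape_irregularity) * max(config.rescan_volume_factor, 1.0) ** (
        1.0 / 3.0
    )
    return (half_extent - config.rescan_shift_mm) / denom - 1e-6


def write_cohort(pairs: list[PhantomPair], out_dir: str | Path) -> Path:
    """Write a cohort as NIfTI image/mask files plus a CSV manifest.

    Returns the manifest path; columns are
    (patient_id, scan, image_path, mask_path).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        for scan_no, (img, msk) in (
            (1, (pair.scan1, pair.mask1)),
            (2, (pair.scan2, pair.mask2)),
        ):
            img_path = out_dir / f"{pair.patient_id}_scan{scan_no}_image.nii.gz"
            msk_path = out_dir / f"{pair.patient_id}_scan{scan_no}_mask.nii.gz"
            write_nifti(img, img_path)
            write_nifti(msk, msk_path)
            rows.append(
                {
                    "patient_id": pair.patient_id,
                    "scan": scan_no,
                    "image_path": str(img_path),
                    "mask_path": str(msk_path),
                }
            )
    manifest = out_dir / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
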