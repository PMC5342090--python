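# Methods

This note records the models, parameter choices and numerical conventions
behind `radrepro`, and what the synthetic experiments do and do not
demonstrate about patient data.

## Paired-phantom model

Each synthetic patient is one tumor imaged twice on a shared grid
(default 84 × 84 × 20 voxels at 0.92 × 0.92 × 5 mm, the CT protocol
geometry the package targets).

**Shape.** The tumor is the superlevel set of
`L(x) = 1 − r(x)/R + a·G_s(x)`, where `r` is the distance to the grid
centre, `R` the nominal radius, and `G_s` a unit-variance Gaussian random
field with correlation length `shape_corr_len_mm`. The irregularity is
volume-preserving: the mask keeps exactly the digital-sphere voxel count
of radius `R` (the top-k voxels of `L`), so `R` controls volume while the
boundary wobbles like a clinical GTV. `a = 0` gives an exact digital
sphere (debug shape). Irregularity matters because run-length and
co-occurrence statistics on perfect spheres are degenerate along the grid
axes.

**Texture.** In-mask intensities are a stationary Gaussian random field —
white noise smoothed with a Gaussian kernel whose width is specified in mm
(so the correlation structure respects the anisotropic spacing) — rescaled
to mean `hu_mean` and SD `hu_sd`. Background is constant −1000 HU
(air-like); it never enters any statistic because all computation is
mask-restricted, but it does enter the LoG/wavelet neighbourhoods at the
tumor boundary, as tissue contrast does in real CT.

**Rescan.** Scan 2 resamples the continuous level-set and texture fields
under an isotropic dilation by `factor^(1/3)` about the tumor centre
composed with a rigid shift drawn uniformly within ±`rescan_shift_mm` per
axis, then adds independent Gaussian noise of SD `rescan_noise_sd`. The
grown mask takes the top `round(factor · n₁)` voxels of the resampled
level set, pinning the realized volume ratio to `factor` within one voxel.
Dilating the field (rather than morphologically dilating the mask) keeps
the texture statistics of the two scans comparable. When factor = 1 and
shift = 0 the resampling short-circuits to an exact copy, so the
zero-perturbation cohort is bit-identical by construction.

**Seed discipline.** Every stochastic component draws from
`SeedSequence([master_seed, patient_index, stream_id])`. Two consequences
are load-bearing: cohorts are bit-reproducible, and the scan-2 noise is
`sd · ε` with `ε` a fixed unit-variance field, so a noise ladder varies
only the magnitude of an identical perturbation.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| spacing | 0.92, 0.92, 5 mm | target CT protocol (pixel size / collimation) |
| nominal radius | 20 mm | median GTV ≈ 38 cm³ → r ≈ 20.9 mm |
| radius jitter (log-SD) | 0.20 | wide cohort volume spread (reported range spans ~75×); truncated-lognormal by rejection so tumors always fit the grid |
| hu_mean / hu_sd | 40 / 30 HU | soft-tissue tumor intensity statistics |
| texture corr. length | 3 mm | a few pixels: visible texture, not noise |
| shape irregularity / corr. | 0.15 / 8 mm | GTV-like lobulation without topology changes |
| rescan volume factor | 1.058 | ratio of the reported mean volumes (scan 2 / scan 1) |
| factor jitter (log-SD) | 0.10 | per-patient growth variability (only the mean is reported; this is a free parameter) |
| rescan noise | 10 HU | typical soft-tissue CT noise |
| rescan shift | 1 mm | sub-voxel-to-voxel repositioning |

The cohort size used by the experiments follows the experiment (5–10
patients for the controlled perturbation studies; 40 for nothing, since no
quantity here needs the full cohort size to be meaningful).

### What the generator does not emulate

No anatomy, no CBCT/beam-hardening artifacts, no contouring variability
(masks are transformed exactly, whereas real repeat scans are re-contoured
by a human), and no physiological change beyond bulk volume growth — the
between-scan perturbation is a smooth deformation plus noise. Passing
tests therefore demonstrate that the *pipeline arithmetic* behaves as
specified (perfect agreement in the identity limit, graceful degradation
with noise, the direction of the volume-normalization effect), not that
any particular feature is stable in patients. Headline patient-data
percentages are consequently checked only as classification/summary
arithmetic on the reported counts, never "reproduced" from phantoms.

## Channels and discretization

Filtering and wavelets are strictly 2D (per slice): with 5 mm slices and
0.92 mm pixels a 3D kernel would be severely anisotropic, and the five
value types are intrinsically slice-wise.

**LoG.** σ is specified in mm and converted to pixels per axis; the
response is assembled from per-axis Gaussian second derivatives divided by
spacing², i.e. a physical Laplacian in mm⁻², so a fixed σ_mm gives
comparable responses across pixel sizes. The truncated discrete kernel's
small DC bias is measured on a constant probe and subtracted, making the
operator annihilate constants exactly. σ below half a pixel is clamped
with a warning. The default ladder {0.5, 1.5, 2.5, 3.5} mm spans
sub-pixel to coarse texture at 0.92 mm pixels; the exact widths used in
the original study are not recoverable, so they are configuration, not
ground truth.

**Wavelets.** Single-level `pywt.dwt2` per slice, coiflet-1 by default
(the study's wavelet is unnamed; the family is a config key). Boundary
handling is periodization, chosen because it yields exactly ⌈n/2⌉
coefficients per axis and therefore a clean 2×2 parent-block mapping for
the mask: a sub-band pixel is in-mask iff ≥ 2 of its 4 parent pixels are
(ties at 2 count as in). Symmetric padding with coiflet-1 would produce
(n+5)//2 coefficients and no such mapping. Wavelet sub-bands are computed
for every filter channel (full 5 × 5 cross-product), which is the unique
factorization of 775 as filters × wavelets × measures consistent with the
four feature groups.

**Discretization** is per channel: 32 equal-width bins spanning the
in-mask min/max of that channel's response (filter responses have
unrelated dynamic ranges). The maximum maps to bin 32; a constant channel
maps to bin 1 everywhere.

## Texture measures

The GLCM accumulates symmetrized pair counts over the four in-plane
directions at distance 1 (configurable) into a single matrix per slice —
required for a well-defined matrix-sum value type — with pairs crossing
the mask boundary excluded. The GLRLM accumulates maximal runs over the
same directions, truncated at the mask boundary. The 20 + 11 measures are
the canonical Haralick / Galloway–Chu–Dasarathy catalogue; every formula
is unit-tested against a literal double-loop reference to 1e-12 and the
matrices against exhaustive enumeration.

Numerical conventions: logarithms base 2 with 0·log 0 ≡ 0; zero-variance
marginals make correlation-type measures (correlation, IMC1) return 0
rather than NaN, with the degeneracy logged; run percentage divides total
runs by (pixels × directions), which equals the per-direction run
percentages averaged. Slices with < 2 in-mask pixels are excluded from all
aggregations; slices with pixels but no valid pair are additionally
excluded from the GLCM family; exclusion counts are reported per patient.
`max_slice` ties break to the lowest slice index. A channel whose
downsampled mask keeps < 2 voxels is skipped whole (values NaN, logged).

Volume normalization is division by the tumor volume in mm³ (each scan by
its own volume). The rationale is pixel-count scaling: with fixed-count
binning, adding pixels reshapes the discretized distribution, coupling
many measures to size; dividing by volume removes the first-order
dependence. Whether the original analysis used division or another
transform is not stated; division is this package's choice.

## Geometry

Volume is voxel count × voxel volume. Surface area counts exposed voxel
faces (in-mask voxels' faces against out-of-mask or border), which is
exact on the grid but systematically larger than mesh-based areas for
smooth shapes — reported area/V-over-A values are therefore comparable
within this package, not across area algorithms.

## Agreement scoring

CCC uses population (1/n) moments (Lin's original definition); the (n−1)
variant is flag-selectable for cross-checks against other packages. ICC is
the single-measure *consistency* coefficient from the two-way mixed ANOVA
(ICC(3,1)): MS_R the between-subject mean square, MS_W the residual after
removing the scan effect, k = 2. The absolute-agreement variant, which
charges a systematic scan offset against agreement, is available behind a
flag. The residual sum of squares is computed from explicit residuals
(not by subtraction of sums of squares), so the identity cohort yields
MS_W = 0 and ICC = 1 exactly. Negative ICCs are reported as computed and
classified low; ICC's textbook description as ranging 0–1 is treated as
descriptive. Series that are constant in both scans are undefined and
recorded as missing; missing records are excluded from summary
denominators and counted separately.

The feature–volume association is the same consistency ICC applied to
(feature, volume) pairs across patients after a scale alignment —
z-standardization by default, rank optional — because a raw ICC across
incommensurate scales is dominated by the scale gap. With both series
z-scored, this ICC converges to the Pearson correlation; the tiering then
reads as a correlation-strength classification.

## Experiment design notes

The noise ladder (0/5/10/20 HU) holds seeds, base scans, growth factors
and the unit noise field fixed, so median ICC is non-increasing up to
sampling error by construction of the perturbation, not by chance. The
normalization-direction experiment uses growth-factor jitter (log-SD 0.10)
with modest noise (5 HU) so the between-scan perturbation is dominated by
volume change — the regime in which volume normalization is expected to
help: across patients most feature variance rides on tumor size, and
dividing by a highly reproducible, strongly varying volume both removes
the within-patient size jitter and anchors the between-patient spread.
Problem sizes (5–10 patients, the 62-feature reduced profile) are the
package's default experiment scale; the full 775-feature manifest is
exercised on a single phantom where channel coverage, not cohort
statistics, is the question.

## Known limitations

* 2D-only texture (no 26-neighbour 3D co-occurrence, no size-zone or
  NGTDM families), by scope.
* The synthetic cohort shares one texture model across patients, which
  deflates between-patient variance of intensive (scale-free) measures and
  hence their raw ICC; patient cohorts are more heterogeneous.
* Masks are inputs; there is no contour parsing, registration or
  resampling between scans (each scan is analyzed in its native grid).
* Area is face-count area (see Geometry); V/A summaries are means of
  per-patient ratios, and reported cohort tables built with an unknown
  area algorithm cannot be recomputed exactly even with the data.
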