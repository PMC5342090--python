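# radrepro

Test–retest reproducibility of CT radiomics texture features.

Radiomics pipelines extract hundreds of texture features from tumor CT;
before any of them can be used for treatment monitoring or prognosis, one
has to know which survive a repeat scan of the same patient. `radrepro`
implements that stability analysis end to end for co-occurrence and
run-length texture on rectal-cancer-like CT geometry (0.92 × 0.92 mm
pixels, 5 mm slices): feature extraction under five slice-aggregation
strategies, with and without tumor-volume normalization, scored for
test–retest agreement and sorted into stability tiers. Because no patient
images are distributed, a paired-phantom generator produces synthetic
repeat-scan cohorts with controlled texture, noise, rigid jitter and
between-scan volume growth (~6% on average, matching the reported cohort
geometry), so every result in this repository is recomputable from a seed.

It is aimed at imaging scientists who want a transparent, fully testable
reference implementation of the feature battery and the agreement
statistics, rather than a black-box radiomics toolkit.

## The feature battery

775 features = 5 filter channels × 5 wavelet channels × 31 texture
measures:

* **filters** — original HU image, plus per-slice 2D Laplacian-of-Gaussian
  responses at σ ∈ {0.5, 1.5, 2.5, 3.5} mm;
* **wavelet channels** — the filter output itself plus the LL/LH/HL/HH
  sub-bands of a single-level per-slice 2D DWT (coiflet-1);
* **measures** — 20 gray-level co-occurrence (GLCM) measures (energy,
  contrast, correlation, entropy, information correlations, cluster
  statistics, …) and 11 gray-level run-length (GLRLM) measures (run
  emphases, nonuniformities, run percentage, gray-level-weighted variants).

Each channel is discretized into 32 equal-width gray levels over its
in-mask range. Per slice, the GLCM accumulates symmetric level pairs over
the four in-plane directions at distance 1 and the GLRLM accumulates
maximal runs over the same directions, both truncated at the mask
boundary. Per-slice measures are condensed to one patient value five ways:
the largest slice (`max_slice`), elementwise `max`/`min`/`average` over
slices, and `matrix_sum` (measures recomputed on slice-summed matrices).
Each value is reported raw and divided by the tumor volume in mm³.

## Agreement statistics

For each feature, the per-patient values at the two scans (x, y) are
scored with

* Lin's concordance correlation coefficient
  `CCC = 2ρσₓσᵧ / (σₓ² + σᵧ² + (μₓ − μᵧ)²)` (population moments), and
* the single-measure consistency ICC from a two-way mixed ANOVA,
  `ICC = (MS_R − MS_W) / (MS_R + (k − 1)·MS_W)` with k = 2 scans,

and classified as **high** (ICC ≥ 0.8), **medium** (0.8 > ICC ≥ 0.5) or
**low** (ICC < 0.5).

## Worked example

The numbered drivers under `analysis/` run the study on a 10-patient
synthetic cohort (reduced 62-feature profile for speed):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_extract_features.py
python analysis/03_score_agreement.py
python analysis/04_summarize_stability.py
python analysis/05_perturbation_experiments.py
```

which prints, among other things:

```
mean scan-1 volume 34909 mm^3, mean between-scan growth +6.7% (per-patient range -2.9% to +23.7%)
...
                raw: mean CCC 0.405, mean ICC 0.549, high tier 23.2%
  volume-normalized: mean CCC 0.740, mean ICC 0.813, high tier 68.1%
volume-normalized features, stability by value type:
value_type  n  pct_high  pct_medium  pct_low  mean_ccc  mean_icc
   average 62      77.4        17.7      4.8  0.785315  0.868275
matrix_sum 62      74.2        21.0      4.8  0.779616  0.863846
 max_slice 62      66.1        30.6      3.2  0.784180  0.854626
       max 62      69.4        21.0      9.7  0.764108  0.838153
       min 62      53.2        16.1     30.6  0.586059  0.639834
most stable value type on this cohort: average
```

Reading this: the cohort grew ~6–7% in volume between scans; raw features
agree poorly across scans (mean ICC 0.55) while volume-normalized features
are far more stable (mean ICC 0.81, 68% in the high tier); and among the
five slice-aggregation strategies the `average` type is the most
reproducible — the same qualitative ordering reported for patient data.
The perturbation driver additionally verifies the identity-cohort limit
(ICC = CCC = 1 exactly when scan 2 equals scan 1), the monotone decay of
median ICC as rescan noise rises 0 → 20 HU, and the direction of the
volume-normalization effect.

The same pipeline runs from a shell on synthetic or user-supplied cohorts
(NIfTI images/masks listed in a manifest CSV):

```sh
radrepro run --seed 7 --n-patients 10 --reduced --out results/run
radrepro extract --manifest my_cohort.csv --out results/mine
```

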