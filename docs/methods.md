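# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the synthetic-data generators the test suite relies on, and the
design choices made where the procedure was genuinely open.

## 3D focus detection (`foci3d`)

A DNA-damage focus is a maximal connected set of in-nucleus voxels with
intensity strictly above a criterion threshold — the voxel-set equivalent of
an isosurface enclosing suprathreshold signal. Choices:

- **Connectivity**: 26-neighborhood by default (6 and 18 available). Blob
  detection conventionally uses the full neighborhood; the detector is
  verified voxel-for-voxel against an independent breadth-first flood fill
  at every setting.
- **Threshold rule**: `F0 + k·sd(F0)`, with the background level `F0` and
  its spread estimated as the median and `1.4826 × MAD` of in-mask
  intensities. The robust pair is insensitive to the focus voxels, which
  occupy a small fraction of nuclear volume. `k = 3` by default; the
  criterion is deliberately exposed because it stands in for an
  operator-adjusted setting — under heavy noise (e.g. noise at 10% of the
  focus/background contrast) a 4-sigma criterion is the appropriate
  stringency, and the recovery experiments use it there.
- **`min_voxels = 2`**: suppresses single-voxel noise exceedances.
- **Volumes** are voxel counts × voxel volume (μm³) — no marching-cubes
  surface integration — so ground-truth comparisons can be exact.
- **Merged foci are not split** (no watershed): when two physical foci touch,
  the count underestimates, which is why *total focus volume per nucleus* is
  carried as the robust companion statistic throughout.
- **Degenerate inputs**: an empty mask is an error; a zero-spread background
  with `k > 0` degenerates the threshold to `F0 + ε` with a warning; if
  nearly no in-mask voxels lie at or below the threshold support
  (fewer than `min_background_voxels = 8`), background estimation errors
  out. A uniformly bright mask is indistinguishable from uniform background
  without an external intensity reference, so that case follows the
  degenerate-threshold path rather than erroring.

**Pan-staining** (the diffuse p-Chk2 phenotype) is classified by the
suprathreshold fraction of nuclear voxels, cutoff 0.5 by default.

**Co-localization** is strict ≥1-voxel 3D intersection between an A-focus
and the union of B-foci, reported as a percentage of A-foci. With zero
A-foci the fraction is undefined and reported as missing, not 0. A proximity
variant (centroid distance) is intentionally not defaulted: the biological
criterion "closely associated" has no quantitative definition, and strict
overlap is the reproducible reading.

## Vessel and lumen segmentation (`vasc2d`)

CD31-positive wall pixels come from a fixed or Otsu threshold (the
interactive, user-adjusted threshold of manual workflows is replaced by a
recorded rule for reproducibility). Lumens are enclosed interior holes of
the wall mask after a morphological closing with a disk whose diameter is
the maximum closable gap (1 μm default): interruptions up to that width are
sealed, so the interior still counts as a lumen; wider gaps leave the
interior connected to the outside and it is excluded. Operationally, gap
width is the maximum structuring-element diameter that seals the
interruption, measured to within one pixel. Walls use 8-connectivity,
background flood fill 4-connectivity (the standard duality). Vessels
touching the field border contribute wall area but their interiors are never
counted as lumens (enclosure cannot be verified). The per-field readout
decomposes exactly: `vascular % = CD31 % + lumen %`. Per-tumor summaries are
mean ± SEM over fields (five peripheral fields in the emulated design).

## ABR thresholds (`audiometry`)

Input is a tidy intensity–amplitude table on the 0–100 dB SPL grid in 5 dB
steps with ≥2 replicate series per frequency. "Well-defined and
reproducible" is operationalized as: amplitude > `criterion_multiplier ×
noise_floor` (default 4×) in *every* replicate at the candidate intensity
*and every higher intensity* — the sustained-response clause prevents an
isolated noise blip from setting a threshold. No qualifying intensity yields
the ceiling sentinel (`inf`, printed `>100`), which band means exclude and
count rather than imputing 100 dB — imputation would bias group means
downward exactly where hearing loss is worst. Waveform peak-picking from raw
traces is out of scope: wave amplitude is an input column.

## Cytocochleograms and SGN density (`cochleogram`)

The place–frequency map is an exact 4-point lookup (1.1 mm → 8 kHz, 2.6 →
16, 3.5 → 25, 4.1 → 32); no interpolation is offered because the full
mouse place–frequency function is a separate model with its own
assumptions. Survival is `100 × count / control`, clipped to [0, 100] with
a warning (sampling noise can push counts above control). Control counts
default to per-position control-group means; matched-contralateral
normalization can be substituted by supplying those counts directly.
Xenograft mode drops the 4.1-mm segment, where massive basal hair-cell loss
occurs independent of treatment in the nude-mouse background. SGN density is
neurons per μm² of the 3,600 μm² calibrated grid; pooling across grids is
exactly invariant.

## Dose–response fitting (`dose_response`)

Four-parameter logistic, `y = bottom + (top − bottom)/(1 + (d/EC50)^h)`,
with dose 0 evaluated as the hill-sign limit so the zero-dose controls
enter the fit without log-dose tricks. `h > 0` means loss at high dose
(survival orientation). Fitting is bounded trust-region least squares
(`scipy.optimize.least_squares`) multi-started over both hill signs and
four log-spaced EC50 initials (8 starts); bounds: `top ∈ [0, 200]`,
`bottom ∈ [0, 100]`, EC50 within two decades of the sampled dose range,
`|h| ≤ 10`. The free fit is the default; `{"top": 100, "bottom": 0}` gives
the constrained variant. A flat response returns `converged=False` with a
NaN EC50 rather than an arbitrary number.

The EC50 interval is a **residual bootstrap** (default 1,000 resamples,
seed-controlled): residuals from the point fit are pooled, resampled onto
the fitted curve, and the model refit from a warm start; the percentile
interval is taken on log-EC50. With only a handful of replicates per dose,
case-resampling within dose understates variability and the plain
percentile interval undercovers, while BCa's bias/acceleration estimates
are too noisy at n = 25; the residual bootstrap — appropriate here because
the mean model is correctly specified — measured 91–93% empirical coverage
at nominal 95% in the calibration experiments that the acceptance script
re-runs.

## Group statistics (`endpoint_stats`)

The branching rule: Shapiro–Wilk per group and Levene's test across groups,
both at α = 0.05, select the parametric branch (one-way ANOVA, then Tukey
HSD when the omnibus P < α) or the nonparametric branch (Kruskal–Wallis,
then Dunn's rank-based pairwise z-tests with tie correction). Dunn p-values
are Holm-adjusted — a uniformly more powerful choice than Bonferroni that
still controls the family-wise error rate; the adjustment method is
configurable. Post hoc tests are gated on the omnibus test, mirroring the
stepwise convention. Data constant across all groups short-circuits to
P = 1. Dunn's test is implemented in-package (pooled mid-ranks,
`z = (R̄_i − R̄_j)/√((N(N+1)/12 − ΣT/(12(N−1)))(1/n_i + 1/n_j))`); Tukey HSD
comes from statsmodels.

Endpoint arithmetic is exact: `V = (π/6)·d1²·d2` with auto-swap (and
warning) if the diameters arrive in the wrong order; a zero tumor-cell area
in the scar ratio is a complete-response sentinel (NaN + flag), never
infinity; densitometry is target/actin. SEM is the dispersion convention
throughout.

## Synthetic-data generators (`synthetic_data`)

The generators define the study conditions the tests run under:

- **Foci stacks**: hard spheres (radius 0.3 μm default) of uniform intensity
  120 over Gaussian background (mean 10, SD per scenario) inside an
  ellipsoidal nucleus, voxel size 0.3 × 0.1 × 0.1 μm (typical confocal
  sampling, coarser axially). Ground truth records *voxelized* sphere
  volumes, so exact recovery is a meaningful assertion. Placement is
  rejection sampling with pairwise physical separation; infeasible requests
  raise rather than silently overlapping. The two-channel variant renders
  overlapping pairs at identical centers (guaranteeing ≥1 shared voxel) and
  everything else separated, so the designed overlap fraction is exact.
- **Vessel fields**: annular walls of stated outer radius and thickness at
  intensity 200, pixel 0.32 μm default (0.2 μm in the test geometries); a
  gap is a straight slot of stated physical width cut through the wall, so
  the gap-rule boundary case is controlled to within one pixel.
- **ABR series**: amplitudes are folded-Gaussian noise below the programmed
  threshold; from threshold upward the mean is `snr × noise_floor` growing
  50% per 5 dB step, plus Gaussian measurement noise (`noise_sd`, μV). SNR
  here means amplitude-at-threshold over noise floor. Two replicates, nine
  frequencies 4–32 kHz by default. `threshold = inf` emulates the
  non-responsive (ceiling) ear.
- **Dose–response**: 4PL (top 100, bottom 0, hill 2) plus Gaussian noise
  clipped to [0, 100]; the default design is 0/5/7.5/10/20 μM × 5
  replicates with generating EC50 9.4 μM — the emulated study's design.
  Recovery experiments use noise SD 8 percentage points, a realistic
  replicate scatter for hair-cell counts.
- **Grouped endpoints**: i.i.d. Gaussian per group with recorded
  truly-differing pairs.

Determinism: all randomness flows from `SimulationConfig.seed` through
per-stage `numpy` substreams; identical configuration gives byte-identical
output.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: optical point-spread blur and anisotropic
resolution coupling between neighboring foci, intensity falloff within real
foci, photobleaching, multi-nucleus scenes and segmentation errors in the
input masks, irregular (non-annular) vessel cross-sections, tissue
autofluorescence, ABR waveform morphology (only amplitudes are modeled),
and non-Gaussian replicate scatter. The suite demonstrates algorithmic
correctness against controlled truth, not robustness to every acquisition
artifact.

## Problem sizes

The recovery and calibration experiments run at: 50 random stacks (≤16³
voxels) for oracle equivalence; 100 synthetic nuclei per noise condition;
100 seeded datasets for EC50 recovery/coverage (300 bootstrap resamples per
fit — the percentile interval is stable well below the 1,000-resample
default); 200 ABR series; 2,000 null simulations per statistical branch.
These sizes make the empirical rates in the acceptance report reproducible
to within ordinary Monte-Carlo error.
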