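# Methods

This note documents the models, defaults and numerical choices behind
`olfbold`, and what the synthetic phantom does and does not establish about
real data.

## Signal model of the phantom

A voxel's value is

```
S(x, t) = S0 · d(x) · (1 + r(x, t)) + drift(t) + w(x) · resp(t) + ε(x, t)
```

with baseline intensity `S0` (default 1000 a.u.), a static multiplicative
dropout field `d(x) ∈ [0, 1]` per acquisition condition, the fractional
response `r`, global scanner drift, a respiratory component with spatially
varying weight `w(x) ∈ [0.5, 1.5]`, and white Gaussian thermal noise
`ε ~ N(0, σ²)`.  Thermal noise is deliberately *not* attenuated by dropout —
it is receiver noise — so tSNR and CNR degrade inside the dropout zone the
way they do in real EPI.

**Response.**  Within stimulation block *b* the response of a positive voxel

```
r(t) = a · h_b · [g(t; t1, w) + ρ · g(t; t2, w)] / m_b
```

uses unit-peak Gaussian bumps `g` centered `t1 = 15 s` and `t2 = 45 s` into
the block with SD `w = 8 s`: a bi-phasic shape with two peaks in the first
and second half of a 60 s block.  `ρ ∈ [0, 1]` is the second-peak ratio
(≈1 in cortical regions; 0.2 in the bulb-like ROI, where the second peak is
strongly suppressed — no quantitative estimate of this suppression exists,
so 0.2 is a package choice).  `m_b` normalizes the shape to
unit mean over block *b*'s ON volumes, so that `100·a·h_b` **is** the true
block-*b* ΔS/S under the analysis baseline rule — this makes ground truth
exact rather than approximate.  Habituation multipliers default to
`h = (1, 0.35, 0.15)` for positive voxels (calibrated to relative-difference
ranges of roughly −40 to −110 % reported for human olfactory cortex) and
`h_neg = (1, 1, 0.8)` for negative voxels, whose magnitudes (0.4–0.5 %)
are smaller and barely habituate.  Individual 1 s odor pulses are not
modelled as separate hemodynamic events: with a 2 s inter-pulse interval
their responses overlap into one sustained envelope.

**Post-stimulus transition.**  After block cessation the response decays
exponentially with `τ = 15 s`, truncated to exactly zero 45 s after block
end.  The transition therefore occupies 75 % of the stimulus-on duration
(inside the reported 50–100 % range) and — by construction — never reaches
the second half of the following off period.  This truncation is what makes
the noiseless ΔS/S recovery exact to machine precision; the smooth
(untruncated) tail it discards is below 5 % of the end-of-block value.

**Drift.**  Scanner drift is a smooth aperiodic curve: a random combination
of the slow discrete-cosine modes with periods down to `drift_period_s`
(default 300 s), scaled to the RMS of a sinusoid of amplitude `drift_amp`
(default 0.5 % of baseline).  This is the class of signal a high-pass at the
paradigm-cycle frequency is designed to remove, and the projection removes
it exactly.  A strictly periodic drift of arbitrary phase is *not* in the
span of a small cosine basis; such a component would be only partially
attenuated (up to ~50 % residual) and, amplified ~8× relative to thermal
noise by spatial smoothing, can masquerade as stimulus-locked signal.  This
is a limitation of any projection-based drift removal, and the reason the
drift model and the filter are kept consistent.

**Geometry.**  Default grid 40×40×24 voxels at 1.5 mm isotropic with an
ellipsoidal brain mask and 8 ROIs, including a 15-voxel bulb-like slab
inside the dropout zone — a desk-scale stand-in for a whole-brain scan
with 15 anatomical ROIs.  The EPI-like dropout field is a flat-cored
super-Gaussian well (floor 0.05, σ = 9 mm) centered on the bulb ROI; the
T2prep-like condition has no dropout.  Geometric distortion and subject
motion are not modelled (no implementable description exists for them at
this scale); the respiratory trace is emitted so nuisance regression can be
exercised in their place.

## Preprocessing

Fixed order: spatial smoothing → high-pass → nuisance regression →
(optional) low-pass.  All temporal operations act on mean-centered series
and restore the mean, so ΔS/S denominators survive; voxels outside the
brain mask are never touched.

- **Smoothing**: isotropic Gaussian, FWHM 4 mm
  (`σ = FWHM/(2√(2 ln 2))` converted to voxels per axis).
- **High-pass**: projection onto the complement of the DCT-II basis with
  frequencies below 1/180 Hz — the reciprocal of one full 180 s on+off
  paradigm cycle (6 regressors at the default 300×2 s series).  Chosen over
  a recursive filter for exact, dialect-free reproducibility.  The rolloff
  is that of a 6-dim projection: on-grid cosine content is removed exactly,
  off-grid stop-band sinusoids keep up to ~20–30 % residual, and the
  habituating response envelope (which has sub-cutoff content) loses a
  little power.
- **Nuisance regression**: least squares on mean-centered recorded traces
  (the phantom emits its respiratory trace); collinear columns are dropped
  with a logged warning.  This stands in for component-based physiological
  denoising, whose selection criterion is correlation with those same
  recorded traces.
- **Low-pass**: order-4 Butterworth applied forward–backward (zero phase),
  corner widened by `(√2 − 1)^(−1/8) ≈ 1.117` so the squared response has
  half-power at the nominal 0.03 Hz cutoff.

**Where testing taps the chain.**  The KS test consumes the series *after*
nuisance regression and *before* the low-pass.  A 0.03 Hz low-pass at TR 2 s
leaves ~12 % of the spectrum, collapsing the effective temporal degrees of
freedom ~8-fold; the ON/OFF samples of a low-passed series are so strongly
dependent that voxelwise KS p-values (computed under exchangeability) become
meaningless and false-positive control is lost.  The low-pass is therefore
reserved for ΔS/S time-course quantification and display
(`preprocess_bold(..., lowpass=False)` is the testing path).  tSNR is
computed on whatever series it is given; the pipeline computes it on the
testing-path output.

## Activation testing

ON samples are the volumes acquired during stimulus-on periods, OFF samples
everything else (including transitions — the transition-exclusion rule
applies only to the ΔS/S baseline).  The window assignment can be shifted by
a hemodynamic delay; the default is 0 s for phantom data because the
template's peak timing (t1 = 15 s) already embodies the hemodynamic lag, so
analysis and ground-truth windows coincide.  For real acquisitions a 6 s
shift (3 volumes at TR 2 s) is the conventional choice and is exposed as
`hemodynamic_delay_s`.

p-values: the exact null distribution of the two-sample `D` for tie-free
data is computed once per `(n_ON, n_OFF)` via the lattice-path recursion
(probability-space DP with hypergeometric transition weights; numerically
stable, ~0.2 s for the default 90/210 split) and cached.  Samples with ties
fall back to full enumeration (≤ 20 observations) or the asymptotic
Kolmogorov distribution with effective size `n₁n₂/(n₁+n₂)`.  Multiplicity is
controlled by Benjamini–Hochberg across in-mask voxels (valid under the
positive dependence induced by spatial smoothing); "adjusted P < 0.01"
means BH-adjusted q < 0.01 throughout.  Voxels with zero temporal SD are
excluded from testing and summaries.  Activated voxels are classified
positive/negative by the sign of their pooled ΔS/S; an exactly zero pooled
ΔS/S leaves the voxel unclassified (logged).

**GLM comparator.**  Per voxel, least squares on a non-habituating
regressor — the stimulus boxcar convolved with a Gaussian response kernel
peaking 15 s after onset — with a two-sided t test (n−2 dof) and the same
BH level.  When the data were high-passed, the regressor is projected by
the same basis (`filter_hp_cutoff_hz`).  Under strong habituation the true
ON-period signal is block-1-heavy and high-variance; the fixed-shape
regressor cannot represent that, while the KS statistic responds to any
distributional difference.  In the packaged sensitivity study (bulb-scale
amplitude 2.2 %, tSNR 60, mid-range operating point) KS sensitivity exceeds
the GLM's under `h = (1, 0.35, 0.15)`, and the two essentially tie (both
saturated) without habituation.

## ΔS/S, tSNR, CNR

`ΔS/S_b` compares block *b*'s ON mean against the mean over the second half
of the *preceding* off period (the initial 60 s off precedes block 1).
The preceding-off convention avoids post-stimulus transition contamination;
a following-off variant is available.  `block='all'` pools all ON volumes
against the union of the baseline windows; this pooled value also drives
sign classification.  tSNR uses the n−1 SD; constant series get an infinity
sentinel and are excluded from ROI means.  CNR = tSNR × block-1 ΔS/S as a
fraction.  Condition comparisons evaluate CNR over the *union* of
positively activated voxels from either condition — the identical voxel set
for both — because the high-dropout condition alone detects almost nothing
in the bulb.  Note this union selection induces a winner's-curse bias that
can favor either condition in dropout-free ROIs; it is the standard
procedure for this comparison and is kept as such.

## Group statistics and reproducibility

Habituation across blocks: one-way repeated-measures ANOVA (statsmodels
`AnovaRM`), subjects as random blocks.  Relative difference of block k vs 1
uses the *group-mean* block-1 denominator, which keeps single low-responders
from exploding the ratio.  Condition contrasts:
paired t per ROI, BH-FDR across ROIs at adjusted P < 0.05, Cohen's
`d = (mean_a − mean_b)/s` with `s = √((s_a² + s_b²)/2)` (the paper states
only "pooled standard deviation"; this is the equal-n paired convention).

Reproducibility: Dice `2|A∩B|/(|A|+|B|)` per ROI per sign on binarized
activation masks; two empty masks are defined as Dice 1 (perfect agreement
of absence, logged).  ICC is the two-way random-effects,
absolute-agreement, single-measure ICC(2,1) from the mean-squares
decomposition, with scan/rescan as random raters (ICC(3,1) by flag);
the rating table contains the voxelwise ΔS/S pairs of the voxels activated
in the *first* scan overlaid on the second.  In the phantom, block-1 ICC medians land around 0.6–0.85 while
habituated blocks 2–3 are voxel-noise-dominated (their true ΔS/S is near
zero) and show low ICC — a real property of weak signals, not an estimator
defect.

## Validation studies and problem sizes

All studies run on one CPU; sizes were chosen so the full suite and the
acceptance script each finish comfortably within minutes.

- **Specificity** (`null_false_positive_study`): 30 activation-free
  phantoms at full size (40×40×24×300), testing-path preprocessing, KS map
  at q < 0.01; reports the mean declared-active fraction.  Observed: 0.
- **Recovery** (`delta_recovery_study`): 100 positive voxels, a = 2.2 %,
  tSNR 60, `h = (1, 0.35, 0.15)`, thermal noise only, no preprocessing —
  it validates the ΔS/S windowing rule itself; filtering interactions are
  exercised separately.  Observed errors: ≲ 0.03 pp on block 1, ≲ 0.02 on
  the habituation ratios.
- **KS vs GLM** (`ks_vs_glm_study`): 12 replicates per condition on a
  20×20×12 grid, amplitude 2.2 %, tSNR 60.
- **Habituation power** (`habituation_power_study`): 14 subjects ×
  50 replicates; block means (2.2, 0.8, −0.2) %, between-subject SD 2.4,
  within-subject SD 1.0 — chosen so the marginal SD (~2.6) matches group
  standard errors of ~0.7 at n = 14, the scale reported for bulb ΔS/S in
  human cohorts.
- **Dropout CNR** (`dropout_cnr_study`): 5 subjects × 2 conditions at full
  size, paired comparison across subjects.
- **Retest** (`retest_study`): scan/re-scan pairs with shared truth and
  independent noise.

## What the phantom does not establish

The phantom has no subject motion, no geometric distortion, no cardiac
component, Gaussian stationary noise, spatially uniform response amplitude
within each ROI, and a response template that exactly matches the analysis
windows in timing.  Passing tests therefore demonstrate correctness and
calibration of the estimators under their stated assumptions — not
robustness to motion artifacts, non-Gaussian physiological noise, or
hemodynamic timing mismatch.  Real-data group values (CNR per region,
Dice/ICC levels of a specific cohort) are cohort properties and are not
reproduced here; directional and structural properties are.
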