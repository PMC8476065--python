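# olfbold

Analysis toolkit for **block-design olfactory fMRI** with strong habituation,
plus a ground-truthed synthetic 4-D BOLD phantom to validate every stage.

Olfactory BOLD responses are awkward for standard task-fMRI analysis: the
response to a sustained odor block habituates sharply (later blocks can evoke
almost nothing), the within-block time course is bi-phasic, a sizeable subset
of voxels responds *negatively*, and the most interesting region — the
olfactory bulb — sits next to the sinonasal air cavities where EPI images
lose signal. `olfbold` implements the analysis chain built for exactly this
regime and the simulation machinery to test it:

- **Paradigm**: pulsed odor block schedules (default: 60 s off +
  3 × [60 s pulsed-on + 120 s off] at TR 2 s; 20 × 1 s odor pulses per block).
- **Phantom**: 4-D BOLD series with bi-phasic habituating responses
  (second peak suppressed in a 15-voxel bulb-like ROI), negative voxels,
  smooth scanner drift, a respiratory component with a recorded trace,
  white thermal noise, and per-condition susceptibility-dropout fields
  emulating an EPI-like vs a T2prep-like acquisition — with exact per-voxel
  ground truth.
- **Preprocessing**: 4 mm Gaussian smoothing, drift removal below 1/180 Hz
  (discrete-cosine projection), nuisance-trace regression, zero-phase 0.03 Hz
  low-pass (for time-course quantification; kept *off* the testing path).
- **Activation mapping**: the voxelwise two-sample **Kolmogorov–Smirnov
  statistic** `D = sup_x |F_ON(x) − F_OFF(x)|`, with the *exact* tie-free null
  distribution computed by a lattice-path recursion (one cached table per
  ON/OFF split), full permutation enumeration for small samples, and the
  asymptotic Kolmogorov distribution at effective size `n₁n₂/(n₁+n₂)`;
  Benjamini–Hochberg FDR across voxels; sign classification by pooled ΔS/S;
  a conventional GLM (non-habituating boxcar regressor, t statistic) as
  comparator.
- **Quantification**: block-wise `ΔS/S_b = (S̄_on,b − B_b)/B_b` where `B_b`
  is the mean over the *second half* of the stimulus-off period preceding
  block b (the first half is contaminated by the post-stimulus transition);
  tSNR = temporal mean/SD; CNR = tSNR × block-1 ΔS/S.
- **Group metrics**: one-way repeated-measures ANOVA across blocks, paired
  t tests with BH-FDR, Cohen's d with pooled SD, relative differences,
  ROI-visibility counting (mean − 2 SD rule), Dice overlap and ICC(2,1)
  scan–rescan reproducibility.

## Worked example

`examples/03_activation_map.py` simulates a default phantom, preprocesses it
and maps activation:

```text
voxel counts: {'tested': 17200, 'active': 210, 'positive': 164, 'negative': 46}
              roi  n_active  delta_pct_block1  delta_pct_block2  delta_pct_block3   tsnr  cnr
   olfactory_bulb         6              0.46              0.12              0.05 357.58 1.62
         piriform        46              0.42              0.09              0.03 404.20 1.65
    orbitofrontal         1              0.31              0.11             -0.03 435.63 1.36
         thalamus        56              0.41              0.11              0.05 397.02 1.62
control_posterior        22              0.37              0.11              0.02 414.11 1.51
       neg_insula         0               NaN               NaN               NaN    NaN  NaN
```

Reading it: 210 of 17 200 in-mask voxels pass adjusted P < 0.01, split into
positively and negatively responding sets; per-ROI mean ΔS/S falls from
block 1 to block 3 (the habituation cascade the phantom was given), and the
negative/quiet ROIs contribute no positively activated voxels.  Amplitudes
are partial-volume diluted and tSNR boosted relative to the generating values
because both are measured on the smoothed data, as in a standard pipeline.

The other examples cover the paradigm arithmetic (`01`), ground-truth
recovery (`02`), group habituation statistics (`04`), the paired CNR
comparison between acquisition conditions (`05`), and scan–rescan
reproducibility (`06`).  A thin CLI mirrors the stages:

```bash
olfbold paradigm --out schedule.tsv
olfbold phantom --seed 1 --out phantom/
olfbold preprocess --bold phantom/bold.nii --nuisance phantom/traces.tsv \
    --no-lowpass --out clean.nii
olfbold activate --bold clean.nii --schedule phantom/schedule.tsv --out maps/
olfbold run-all --seed 1 --out report/
```

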