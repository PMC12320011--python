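# eegfmri

Temporal coupling between fMRI resting-state networks and EEG band power.

Simultaneous EEG–fMRI lets us ask which electrophysiological rhythms track
the slow hemodynamic fluctuations of the brain's resting-state networks
(RSNs) — visual, somatomotor, attention, default-mode and related systems.
The published literature on these correlations is strikingly inconsistent,
and much of the disagreement traces to methodology: which hemodynamic
delay was assumed, whether EEG was analyzed at the scalp or at cortical
sources, how motion was handled, and how many subjects and minutes of data
went into each estimate.  This package implements that analysis as a
tested, reusable pipeline for researchers who want to run it on their own
RSN/EEG time series — or to study its statistical behavior on synthetic
data with known ground truth.

## What it computes

For each subject, EEG channel or source region *c*, frequency band *b*,
RSN *k*, and HRF overshoot delay *d*, the pipeline computes the Pearson
correlation

    r(c, k, b, d) = corr( (BP_cb * h_d)(t) , y_k(t) )

where `BP_cb` is relative band power — band-integrated squared Morlet
wavelet magnitude (temporal FWHM 3 s at 1 Hz, scaling 1/f) normalized by
total 1–60 Hz power, low-pass filtered and sampled per TR epoch — `h_d` is
a double-gamma HRF whose overshoot peaks at delay *d* ∈ {2, 4, 5, 6, 8,
10} s (undershoot delay and dispersions scaled linearly with *d*), and
`y_k` is the RSN time series, with motion-contaminated epochs (DVARS >
Q3 + 1.5·IQR for fMRI volumes; any channel ≥ 4 SD from its mean for EEG
epochs) excluded from the correlation only, never from the filtering.

On top of the correlation tensor it provides: spatial averaging, dataset
and grand averaging (scalp maps restricted to the common channel labels),
scalp/source pooling, best-delay selection by maximum |r̄|; group
consistency statistics (Shapiro–Wilk, two-sided one-sample t-tests,
Benjamini–Hochberg FDR, split-plot repeated-measures ANOVA with Bonferroni
post hocs); and resampling analyses of how significance depends on the
number of subjects and the scan duration.  A synthetic generator produces
coupled EEG–fMRI groups — slow RSN drivers, band-limited EEG carriers with
signed envelope coupling, HRF-delayed BOLD, scalp mixing, injectable
motion — so every stage is verifiable without real recordings.  Dice-based
template matching and stage-1 dual regression are included for users
starting from IC maps and voxel matrices.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small coupled group and run every stage:

```
$ eegfmri simulate demo/group --n-subjects 3 --duration 300 --seed 42
wrote 3 subjects to demo/group
$ eegfmri run-all demo/out --data-dir demo/group --fast
results in demo/out
```

`demo/out/` now holds one directory per stage: per-subject band-power
regressors (`features/`), scrub masks (`scrub/`), the long-format
correlation tensor and its spatial averages (`correlate/`), consistency
statistics (`stats/`), and subject-resampling curves (`resample/`).  The
visual-network rows of the pooled consistency table at the 6-s delay:

```
rsn  band  delay  n  mean_r       t      p  fdr_significant
 VN alpha    6.0  3  0.2135  5.6816 0.0296            False
 VN  beta    6.0  3 -0.2117 -2.9868 0.0962            False
 VN delta    6.0  3  0.0699  1.3100 0.3204            False
 VN gamma    6.0  3  0.2688  8.3462 0.0141            False
 VN theta    6.0  3 -0.1974 -3.3491 0.0788            False
```

`mean_r` is the scalp/source-pooled, spatially averaged correlation
averaged over the three subjects; its signs (+, −, +, −... across bands)
reproduce the coupling matrix planted by the simulator, and `t`/`p` test
each cell against zero across subjects.  With only three subjects nothing
survives FDR correction within the 2×5×6-cell family — exactly the
sample-size behavior the resampling analysis (`resample/subjects_curve.tsv`)
quantifies.  Library users can do the same in a few lines with
`eegfmri.features.extract_features`, `eegfmri.coupling.correlation_maps`,
and `eegfmri.groupstats.consistency_report`.

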