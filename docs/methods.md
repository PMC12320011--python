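# Methods

This package implements a delay-resolved correlation analysis between fMRI
resting-state network (RSN) activity and EEG frequency-band power, together
with a synthetic generator of coupled EEG–fMRI groups that gives every
stage a recoverable ground truth.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not show about real data.

## The analysis model

The pipeline treats each subject's recording as a pair of simultaneous
views of the same underlying slow neural fluctuations:

- **fMRI view.** Per-subject RSN time series at the repetition time (TR),
  either supplied directly or extracted from a voxels×time matrix by
  stage-1 dual regression (per-volume OLS of the voxel vector on the group
  spatial maps plus an intercept).  Group IC maps are associated with
  canonical RSN templates by thresholding the IC z-maps at Z = 3,
  binarizing, and assigning each template the component with the highest
  Dice overlap (ties to the lowest component index).
- **EEG view.** Per-channel (scalp) and per-region (source) relative band
  power in the five canonical bands — delta 2–4, theta 5–7, alpha 8–12,
  beta 15–29, gamma 30–60 Hz — normalized by total 1–60 Hz power, from a
  complex Morlet time–frequency decomposition, low-pass filtered and read
  at the centers of TR epochs, then convolved with a family of
  hemodynamic response functions (HRFs).

Pearson correlation between each HRF-convolved band-power series and each
RSN series, over the epochs retained by joint motion scrubbing, yields a
correlation tensor indexed by (space, unit, RSN, band, delay).  Reductions
follow: an unweighted spatial mean over units; subject means per dataset
and a grand mean over all subjects (scalp maps restricted to the channel
labels common to all datasets); pooling of scalp and source values; and
best-delay selection as the argmax of the absolute spatially averaged
correlation (ties to the smallest delay).  Missing values stay missing
through every reduction — zero-filling would bias the averages toward the
null.

## Time–frequency decomposition

Wavelets are complex exponentials under a Gaussian envelope whose temporal
FWHM is 3 s at 1 Hz and scales as 1/f, each normalized to unit energy.
Convolution is computed by FFT with one forward transform per signal and
one inverse transform per frequency row; samples within four envelope
standard deviations of either recording edge are flagged invalid at that
row and excluded from correlation downstream rather than zeroed.

Band power is the band-integrated squared magnitude: a trapezoid-weighted
sum of |coefficient|² over the band's frequency rows, divided by the same
sum over 1–60 Hz.  With unit-energy wavelets this makes the value
contributed by a narrowband oscillation independent of its frequency, so
equal-power carriers in different bands produce equal band values, and the
result is stable under refinement of the frequency grid.  The default grid
is spaced 0.25 Hz below 4 Hz, 0.5 Hz from 4–10 Hz and 1 Hz from
10–60 Hz, because the wavelet's spectral response narrows toward low
frequencies (σ ≈ 0.088·f Hz) and a coarser grid under-resolves it there;
band edges always fall on grid rows.  A per-epoch normalization
alternative and uniform grids are available through function arguments.

Band-power traces are brought to the fMRI volume grid by a zero-phase
(forward–backward) windowed-sinc FIR low-pass at 1/(2·TR) Hz with
4·fs/cutoff taps (rounded odd) and edge-replicated padding (so constants
pass exactly), then sampled at epoch centers (k + ½)·TR.  Epochs are
0-based and half-open.

## HRF family

The HRF is the SPM-convention difference of two gamma densities: overshoot
delay 6 s, undershoot delay 16 s, both dispersions 1 s, peak:undershoot
ratio 6, length 32 s, normalized to unit peak (Pearson correlation is
scale-invariant; unit peak eases inspection).  To sweep the hemodynamic
lag, the overshoot delay takes values {2, 4, 5, 6, 8, 10} s (extended
sweep: 0–20 s in steps of 2), and the undershoot delay and both
dispersions are scaled linearly by delay/6 so the response keeps its
shape; the amplitude ratio is deliberately left fixed.  Delay 0 would
degenerate both gammas and is implemented as a Kronecker delta — "no
hemodynamic lag".  Convolution is causal, zero-padded in the past, and
truncated to the input length; features are convolved at the TR stage with
the kernel sampled at TR (convolution and linear downsampling commute up
to filter edge effects, and this keeps the sweep cheap).

## Motion scrubbing

Band power and HRF convolution always run on the continuous recording
first; scrubbing removes epochs only at the correlation step, preserving
the temporal continuity that the time–frequency analysis needs.  fMRI
volumes are flagged by DVARS (RMS volume-to-volume intensity difference
normalized by the median intensity × 1000) above Q3 + 1.5·IQR
(linear-interpolation quartiles; the volume after the offending transition
is flagged, never the first volume).  EEG epochs are flagged when any
channel deviates from its whole-recording mean by ≥ 4 SD; zero-variance
channels are excluded with a warning.  The interactive visual confirmation
used with real recordings is replaced by the automatic rule.  The joint
mask is the union, with per-modality discard counts reported.  For
synthetic data without voxel volumes, DVARS runs on the RSN-by-time matrix
as the voxel proxy; the generator therefore places BOLD fluctuations on a
baseline intensity of 100 a.u., since a median-normalized measure is
meaningless for zero-mean signals.

## Group statistics

Per dataset (and for the pooled all-subject group), each (RSN, band,
delay) cell's spatially averaged correlations are tested against zero with
a two-sided one-sample t-test; Shapiro–Wilk normality is reported
alongside but never gates the test.  Benjamini–Hochberg FDR at q = 0.05
runs within each (group, space) family of (RSN, band, delay) cells —
BH rather than Benjamini–Yekutieli, following field convention — and both
corrected and uncorrected flags are kept.

The factorial analysis is a repeated-measures ANOVA with RSN, band, and
delay as within-subject factors and (when several datasets are present)
dataset as a between-subject factor.  Because subjects are nested in
datasets, the design is a split-plot: every within-involving effect is
tested against its interaction with subjects-within-groups, and the
dataset effect against subjects-within-groups.  Sums of squares are
computed from marginal means by inclusion–exclusion (balanced designs
only; unbalanced input is rejected naming the offending cells).  No
sphericity correction is applied.  The implementation reduces exactly to
the squared paired t in the one-factor two-level case and reproduces
statsmodels' AnovaRM (fully within) and pingouin's mixed ANOVA (one
within, one between) to eight digits in the test suite.  Post hoc
comparisons are pairwise t-tests (paired for within factors) Bonferroni-
adjusted by the number of cells in the effect crossing — e.g. 105 for a
3-dataset × 7-RSN × 5-band interaction.

## Resampling analyses

Two sensitivity analyses accompany the group tests.  Subject subsampling
draws n subjects without replacement (subsets, not bootstrap) and
recomputes the group t-tests per cell, for n from 1 (no t; reported
missing) to the full sample.  Duration subsampling draws windows of
consecutive minutes with uniformly random start and recomputes the
correlations on retained epochs inside the window.  Default 5000
iterations with a fast 500-iteration mode; curves report, per grid point
and (RSN, band), the mean and the standard error over iterations of the
per-iteration delay-mean — a convention chosen so that the spread is
exactly zero when every draw is the full sample.

## The synthetic generator

The generator encodes the minimal structure the analysis assumes.  Each
RSN k has a neural driver z_k(t): band-limited (0.01–0.1 Hz by default)
Gaussian noise, standardized per row, sampled at 0.1 s.  BOLD is the
causal convolution of z_k with a double-gamma kernel at the true delay,
read at TR epoch centers, plus white noise and a baseline intensity.
Each cortical region belongs to one RSN and emits one sinusoidal carrier
per band at the band's geometric-center frequency with random phase,
amplitude-modulated as max(0, 1 + c[k,b]·z_k(t)) — rectified to keep
amplitudes physical; with |c| ≤ 1 rectification is rarely active — summed
over bands, plus 1/f background noise.  Scalp channels are nonnegative
random row-normalized mixtures of the regions plus sensor noise, standing
in for volume conduction without a leadfield.  Motion is injected
additively: a half-sine burst of a stated amplitude (in units of each
channel's SD) across all channels of chosen EEG epochs, and a constant
offset on chosen fMRI volumes.

Default study conditions: 10 subjects, 10 minutes at TR 2 s, EEG at
250 Hz, 7 RSNs, true delay 6 s, signed couplings of magnitude 0.5
alternating over the (RSN, band) grid, unit-SD EEG background and BOLD
noise.  The montage is deliberately compact — 16 channels, 2 regions per
RSN — because the analysis spatially averages over units, so extra units
increase cost, not recoverable information.  All randomness derives from
one master seed through numpy SeedSequence; regeneration is
byte-identical.

What the benchmark shows: signs and delays planted in the generator
propagate through wavelet band power, FIR downsampling, HRF convolution,
scrubbing, correlation, and averaging, and are recovered at the group
level (all 35 coupling signs in the default benchmark; best delay within
one grid step of the truth in ~95% of single-subject analyses).  What it
does not show: the generator has no gradient/pulse artifacts, no volume
conduction physics, no regionally varying HRFs, no 1/f non-stationarity,
and its carriers are pure sinusoids — so passing recovery here verifies
the pipeline's correctness, not the detectability of coupling in real
recordings.  A structural property worth noting: with region-specific
coupling, spatial averaging dilutes each RSN's correlation by the fraction
of units carrying it (2 of 14 here), so subject-level spatially averaged
correlations sit around 0.1–0.35 — the same order as real EEG–fMRI
band-power studies report.  Relative-power normalization also couples
bands: raising one band's absolute power lowers the relative power of the
others, which slightly reshapes (but, for the default coupling pattern,
never flips) the planted effect.

## Numerical choices and degenerate inputs

- Pearson correlation requires ≥ 3 retained samples and non-constant
  inputs; a constant vector yields a missing value, never 0.
- Subjects with < 3 retained epochs abort correlation with a diagnostic.
- All-zero wavelet coefficients (zero total power) are flagged invalid and
  excluded, not silently zeroed.
- Quartiles for the DVARS rule use linear interpolation (R type 7);
  flag sets depend on this convention.
- Dice of two empty masks is defined as 0; template-matching ties break
  toward the lowest IC index and are logged.
- Motion-injection templates are stored as the realized float difference,
  so subtraction restores the original signals bit-for-bit outside the
  burst samples.
- Stage outputs are cached by configuration hash; deleting one stage's
  directory recomputes that stage and everything downstream.

## Problem sizes

The test suite and the verification script run the full default benchmark
(10 subjects × 10 min × both EEG spaces, ≈ 2 minutes), 50 single-subject
delay-recovery analyses (≈ 6 minutes), 2000-family t calibration and
200-repetition FDR calibration (seconds), and fast-mode (500-iteration)
resampling.  These sizes were chosen to keep a complete verification run
under ten minutes on one CPU while leaving every statistical check enough
replicates to be sharp.

## Known limitations

- The ANOVA handles balanced designs only; real cohorts of unequal size
  require equal-n subsampling before use.
- Scalp-space analysis assumes consistent channel labels within a dataset;
  only the cross-dataset intersection enters grand-average maps.
- The EEG amplitude rule is global (whole-recording mean/SD); slow drifts
  could mask local artifacts.
- The delay sweep is a grid search; no continuous HRF fitting or
  deconvolution is attempted, and region-specific HRFs are out of scope.
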