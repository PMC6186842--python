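# Methods

This note records the statistical conventions, the synthetic-data
models, and the numerical choices behind the package, in the order a
user meets them.

## Clinical rank statistics

All rank tests use mid-ranks for ties and large-sample reference
distributions, matching the conventions of SPSS-style clinical reports.

**Friedman.** Scores are ranked within each subject's row across the k
time points; the uncorrected statistic
`χ² = 12/(n·k·(k+1))·ΣR_j² − 3n(k+1)` is divided by the tie-correction
divisor `C = 1 − Σ(t³−t)/(n(k³−k))` over within-row tie groups and
referred to χ² with k−1 df. Only the corrected form reproduces the
bundled table's per-group values, so the correction is not optional.
Rows with a missing time point are dropped (complete-case analysis);
fully tied input (C = 0) raises a degenerate-data error rather than
returning 0/0.

**Wilcoxon signed-rank.** Differences d = later − earlier; zero
differences are excluded before ranking; |d| is mid-ranked; S is the
sum of ranks of the *negative* differences, so Z < 0 when scores
improve. The variance is tie-corrected
(`m(m+1)(2m+1)/24 − Σ(t³−t)/48`) and no continuity correction is
applied. Pairs with a missing value are dropped, so the post-hoc
contrasts involving the 6-month endpoint run on the pairwise-available
subjects. An exact-enumeration reference (`wilcoxon_exact_p`, all 2^m
sign assignments) backs the approximation in tests; the achievable
agreement is limited by the lattice step of the discrete null, about
0.8/σ by the local CLT, and the tests assert at exactly that bound.

**Mann–Whitney U.** Pooled mid-ranks, U reported for the first sample,
tie-corrected variance, two-tailed normal p without continuity
correction. The baseline between-group comparison uses this test; the
reported p is reproduced at three decimals on the bundled table.

**Scheirer–Ray–Hare.** All observations are pooled and mid-ranked; the
two-way sums of squares are computed on the ranks with cell-total
formulas (valid for unbalanced cells); each effect's H = SS/MS_total is
referred to χ² with the effect's df. The bundled table is unbalanced
(two subjects lack the 6-month score) and the original software's
handling of that imbalance is unknown, so only the direction of the
conclusions (all three effects non-significant) is asserted, not the
exact p-values.

**Paired t.** `t = mean(d)/(sd(d)/√n)` on complete pairs. Identical
pairs (every d = 0) return the null result t = 0, p = 1; constant
non-zero differences (sd = 0, mean ≠ 0) raise, since the statistic is
infinite.

**MCID responders.** A responder's change is ≥ 4 FMA-UE points (the
threshold is inclusive — the bundled counts confirm ≥, not >).
Subjects missing the later endpoint are excluded from the denominator.
Percentages round half away from zero to one decimal.

## EEG spectral pipeline

Preprocessing is a zero-phase 4th-order Butterworth band-pass
(2–60 Hz) followed by a 4th-order band-stop (48–52 Hz), applied
forward–backward with `sosfiltfilt`; segments shorter than the filter
warm-up raise. Band power is a single Hann-tapered FFT periodogram over
the whole segment (not Welch averaging), normalised by the window
energy; a bin contributes when its centre frequency lies in the closed
band interval. The mu band defaults to 8–13 Hz and is overridable.

Per-trial MSS uses the rest segment immediately preceding the task
window as baseline by default; a running-average baseline over all rest
segments so far is available (`rest_baseline="running"`) since online
systems differ on this point. The trigger rule is strict: MSS must
*exceed* the threshold (score 20.0 at threshold 20 does not fire). The
sham trigger is a Bernoulli draw at the configured success rate (0.8)
from a caller-supplied seeded generator.

## Discriminant rate

Electrode lateralisation follows the 10–20 convention (odd digits left,
even right; Cz/FCz midline, in neither set), giving 7-channel
ipsilesional and contralesional sets. Features are the four band powers
averaged over the set, one vector per trial per state. The classifier
is an in-repo linear discriminant: class means, pooled within-class
covariance with a relative ridge (1e-6 × trace/d) added only when the
condition number exceeds 1e8 (or the covariance is exactly singular, in
which case an absolute ridge of the same magnitude is used), equal
class priors by default. sklearn's LDA serves as an independent
cross-check in the tests, never as the implementation.

The session protocol draws 2 training + 2 testing sessions from the
four sessions of a stage (first four = early, last four = late). A
single 2+2 split is noisy, so the pipeline reports the mean DR over 10
seeded splits by default; `n_splits=1` reproduces a single-split
protocol. Feature handling defaults to trial-level vectors; a
per-session averaging mode exists because averaging trials within a
session is defensible for bias reduction but leaves too few vectors to
fit a 4-dimensional classifier reliably, and neither mode is claimed as
canonical.

## Temporal variability

Windows start at t = 0 and the trailing remainder is discarded; the
window count is ⌊T/L⌋ and at least 2 windows are required. Region k's
profile in a window is its adjacency row with the self-entry removed —
keeping the constant unit diagonal would shrink all profile
correlations toward each other. The pair mean runs over unordered
window pairs (equivalent to the symmetric i≠j mean). Degenerate cases
are defined rather than propagated: a constant region within a window
gets zero correlations (with a warning), and a zero-variance profile
contributes zero to each of its pair correlations. V is averaged with
equal weights over window lengths 10, 12, …, 30 time points (20–60 s at
TR = 2 s).

The window-length consistency diagnostic correlates the per-region V
vectors between lengths. On the heterogeneous synthetic generator the
adjacent-length correlation averages ≈ 0.97 over seeds. One caveat the
tests document: this correlation is driven by any shared structure,
including permutation-invariant static heterogeneity, so shuffling the
time axis does not send it to zero; only unrelated data do.

The midline flip exchanges paired L/R region values for left-lesion
subjects (suffix `_L`/`_R` or prefix `L_`/`R_` labels), so group maps
have all lesions on the right. Subnetwork aggregation is an unweighted
mean over member regions. The bundled 84-region six-subnetwork map is a
synthetic stand-in assembled from AAL naming conventions and standard
functional groupings — the original study's region list was never
published in machine-readable form — and analyses accept any
user-supplied JSON map. The pre/post contrast is a per-region paired t
at α = 0.01 without multiple-testing correction, matching how such
region-level contrasts are usually reported; Benjamini–Hochberg is
available off by default.

## Synthetic data

**EEG.** Every channel carries a sinusoidal mu oscillator (10 Hz,
random phase per segment) over 1/f background noise (unit-variance,
spectrally shaped, scaled by amplitude SNR 10 by default). On the
affected channels the oscillator amplitude is multiplied by
√erd_ratio during task segments, so the task/rest mu *power* ratio
equals erd_ratio and the expected MSS is analytic:
(1 − erd_ratio)·100. Defaults mirror the emulated recording: 16
channels of the sensorimotor montage, 256 Hz, 6 s segments,
erd_ratio 0.8. Not emulated: artifacts, electrode drift, volume
conduction, non-sinusoidal mu morphology — so passing tests show the
pipeline recovers a constructed effect, not that it is robust to real
recording pathology.

**BOLD.** 84 regions × 230 time points at TR 2 s. A hidden state
sequence (K = 2 states, geometric dwell with mean 15 TRs) selects a
factor-model covariance (3 factors); the 16 flexible regions mix their
base loadings with state-specific loadings at graded weights 0.6–1.0
(heterogeneous flexibility), stable regions keep one loading vector;
white observation noise sd 0.4 relative to loading scale 1.2. This
yields mean V(flexible) − V(stable) ≈ 0.13 and ranking AUC ≈ 0.93 at
the study's dimensions. Not emulated: hemodynamic smoothing, motion,
physiological noise, spatial autocorrelation.

**Clinical.** Baselines ~ Normal(24, 8) rounded and clipped to 0–66
(the bundled table's mean ± SD); per-group Normal change distributions
at post (guided 4 ± 4, sham 1 ± 4) and 6 months; two guided subjects
missing the 6-month endpoint, mirroring the bundled table. Under a
zero-change null the Friedman and Wilcoxon type-I error rates calibrate
to 0.05 ± 0.02 over 2,000 seeds.

All generators are pure functions of (spec, seed) and are
hash-reproducible.

## Problem sizes in the test suite

The suite runs the property battery at the sizes the claims state: 20
seeds for the BOLD recovery and consistency checks, 50 seeds for the
hemispheric DR margin (32 trials over 8 sessions, 3 splits per
hemisphere), 200 label permutations for the chance-level check, and
2,000 seeds for the null calibration. The full suite completes in
about 70 s on one core.

## Known limitations

- The Scheirer–Ray–Hare p-values on unbalanced designs are
  implementation-sensitive; this package's cell-total formulation is
  exact for the statistic it defines but may differ from spreadsheet
  implementations in the third decimal.
- The discriminant rate has no published machine-readable reference
  values, so its correctness rests on construction (simulated ground
  truth, symmetry properties, sklearn cross-check), not on numeric
  reproduction.
- The bundled subnetwork map is non-canonical (see above); subnetwork
  means on real data should use the study-specific map.
- The sign convention of the Wilcoxon Z for the post vs 6-month
  contrast is asserted in absolute value only; the source tables print
  it with an inconsistent sign.
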