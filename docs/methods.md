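# Methods

`seizdyn` implements an analysis chain for classifying seizure transitions
in surface EEG by their *bifurcation morphology* (BifM): the amplitude and
inter-spike-interval (ISI) signature that identifies which dynamical
bifurcation carries the brain into or out of the ictal oscillation.  Onset
classes are SupH (amplitude growing from zero), SNIC (spiking frequency
rising from zero, i.e. ISIs shrinking from infinity) and SN/SubH (no
prescribed scaling); offset classes are SupH (amplitude shrinking to
zero), SNIC/SH (frequency falling to zero) and FLC (no prescribed
scaling).  Without a DC channel, SN and SubH, and likewise SNIC and SH,
are indistinguishable and are modeled as merged categories throughout.

## Segment extraction and preprocessing

A seizure segment is the annotated interval plus a margin of 30% of the
seizure length on each side; a control segment of identical duration is
the earliest window whose every sample lies at least 300 s from any
annotated seizure (deterministic placement; a seizure with no admissible
control window is excluded and reported).  Segments near the recording
edge keep their seizure but are flagged as clipped.

The fixed chain is: polyphase resampling to 256 Hz → 1 Hz high-pass →
artifact correction → average re-reference → 40 Hz low-pass.  Filters are
zero-phase and applied spectrally with raised-cosine transitions (0.2 Hz
below the high-pass cutoff is fully stopped; the low-pass transition
spans 40–40.5 Hz by default).  Near-rectangular responses were chosen
over windowed FIR designs because repeated application must leave
already-preprocessed data essentially unchanged (correlation > 0.999 on
the central 80%); transition bands wide enough for a cheap FIR violate
that stability criterion on 1/f-spectrum input.  The artifact stage is
pluggable: the default is sliding-window robust clipping (1 s windows
whose RMS exceeds 20× the channel's median window RMS are shrunk to the
threshold), with a no-op option and an adapter slot for an external
artifact-subspace-reconstruction implementation.  A full ASR
reimplementation is out of scope.

## Standardization, PCA and ICA

Each channel is standardized (mean 0, variance 1) over the *full*
segment, margins included, so the ictal amplitude rise relative to the
channel's own baseline survives scaling.  Standardization is per channel;
a zero-variance channel gets unit scale and a provenance flag.

PCA uses the exact eigendecomposition of the channel covariance
(channel counts are small); the top eight principal components are kept
by default — the dimensionality at which seizure information concentrates
in this kind of data — and the count is configurable.  Extended infomax
ICA (MNE implementation) unmixes the PC traces: annealed learning rate,
at most 512 iterations, weight-change tolerance 1e-7 as an early-exit
criterion.  Because extended infomax updates weights in randomly permuted
blocks, the per-iteration weight change rarely crosses a tight tolerance
even after the solution has settled, so the convergence flag instead
asserts the trained unmixing matrix is finite and well-conditioned;
separation quality is verified in tests by source recovery (mixed
super-Gaussian sources recovered with |corr| > 0.95).

Electrode weights are the product of the ICA unmixing and PCA loadings;
topographies are weights normalized to unit maximum absolute value per
component.  ICs are ordered by descending back-projected scalp variance
and signed so the largest-weight electrode is positive — both purely
conventions to make decompositions reproducible.

## Synthetic data generator

The generator is the test bed for every downstream stage and encodes the
study conditions directly:

* **Scaling laws.**  Square-root normal-form laws: SupH onset envelope
  `A(t) = peak·min(1, √((t−t_on)/τ))` (mirrored at offset); SNIC onset
  ISI `base·max(1, √(τ/(t−t_on)))` (mirrored for SNIC/SH offsets);
  constant amplitude and ISI with ≤ 2% jitter for SN/SubH and FLC.
  Defaults: τ = 5 s, base ISI = 0.25 s (4 Hz plateau spiking), seizure
  duration ~ N(60, 15²) s clipped to [25, 240] s — typical focal-seizure
  scales.  Spikes are biphasic ~70 ms transients over a slow oscillation
  at the plateau rate with random phase.
* **Scalp model.**  19-channel 10–20 montage with schematic 2-D
  coordinates; sources project through smooth focal topographies; pink
  background noise scaled to the requested SNR (RMS ratio, default
  10 dB); frontal eye-blink transients (~0.3 s raised-sine, Fp-dominant)
  and lateral temporal muscle bursts (20–45 Hz, 0.5–1.5 s).
* **Cohorts.**  Patient covariates follow the demographics typical of
  presurgical focal-epilepsy series (ages 13–65; ~52% male; temporal
  lobe ~74%; hippocampal sclerosis / cryptogenic / cortical dysplasia as
  the leading etiologies).  Baseline class probabilities keep the
  constant-law classes dominant on both sides (onset SN/SubH 0.66,
  SNIC 0.17, SupH 0.17; offset FLC 0.60, SNIC/SH 0.37, SupH 0.03); the
  scaling-law classes are deliberately more frequent than in real surface
  data so that classifier and model-recovery benchmarks have enough
  positive examples at cohort sizes a desk run can afford.  Requested
  effects (factor, level, class, Δp) are injected exactly per seizure and
  the remaining classes renormalized proportionally; infeasible deltas
  fail loudly.
* **Reviewer labels.**  Two simulated reviewers label each seizure's ICs
  against the truth: the number of truly clear ICs per seizure is drawn
  uniformly from 0–4 (per-seizure variation is what makes within-seizure
  permutation nulls exceed overall nulls), each reviewer misses a clear
  IC with rate 0.1, confuses the class with rate 0.05, and false-alarms
  on noise ICs at rate 0.05.
* **Brain score.**  A logistic function of the fraction of 1–40 Hz power
  lying in 1–13 Hz stands in for automated brain/artifact IC classifiers,
  which are not reimplemented.

What the generator does *not* emulate: volume conduction through a head
model, propagation between sources, DC shifts, non-stationary background
(sleep architecture), electrode artifacts beyond blinks/muscle, and
annotation error.  Passing benchmarks on this ground truth therefore
demonstrates correctness of the machinery and ceiling behavior under
clean conditions — not expected performance on clinical recordings, which
is known to be substantially lower.

## Transition features

Offset traces are flipped in time so both transitions read "into the
seizure".  A single variance change-point anchors the windows: within a
10 s window centered on the annotation, the best two-segment split
minimizes `n₁·log σ̂₁² + n₂·log σ̂₂²`; a change-point is declared when the
improvement over the no-split model exceeds a penalty calibrated by
simulation to a ≤ 5% false-positive rate on stationary Gaussian noise
(penalty = 6.32 + 0.908·ln n, fitted to the 95th null percentile at
window lengths 2–20 s with a small conservative margin).  Splits within
0.25 s of the window edge are not considered, so a step closer than that
to the edge cannot be detected; the anchor then falls back to the
annotation time, and the window is deliberately not extended (to avoid
non-stationarity bias).

Features per IC and side: peak amplitude and Hilbert-envelope RMS over
the first 2 s; ISIs from peaks in the 5 s window (prominence ≥ 3× the
window's median absolute deviation — falling back to the standard
deviation on silent-floor spike trains — minimum spacing 40 ms; fewer
than 3 peaks flags all ISI features missing); least-squares fits of four
morphological families (constant, linear, √t, 1/√t) to peak amplitudes
and to ISIs against peak time, each scored by RMSE; signal mean, median,
SD and skewness; a linear fit to the log 1–40 Hz periodogram (intercept,
slope, slope CI, RMSE, adjusted R²) with the dominant frequency taken as
the most positive residual; normalized spectral entropy; approximate
entropy (m = 2, r = 0.2·SD, computed on the window decimated to ~128 Hz —
embedding statistics are unstable on heavily oversampled signals and the
cost is quadratic); autocorrelation peak-interval mean/SD, ACF entropy,
and ACF width (twice the first lag below 0.5, the critical-slowing-down
proxy); the brain score; the change-point-found flag; and the
onset/offset indicator.  Every feature is either finite or
missing-flagged; extraction never raises.  ISI curves are fitted against
peak *time* (not index) — an interpretation choice.

Feature matrices drop columns missing in strictly more than 5% of rows,
per task; the side indicator is always retained; remaining gaps stay NaN
for fold-wise imputation.

## Classification

Two binary tasks: clear-transition detection over all ICs × sides, and
ISI slowing (SNIC onsets and SNIC/SH offsets, the frequency-to-zero
classes) among the clear ICs.  Per training fold: median imputation,
median/IQR robust scaling (IQR 0 → divisor 1), then a random forest with
500 trees capped at depth 3 and class weights inverse to class frequency.
Evaluation is leave-one-subject-out: per-patient balanced accuracy (for a
single-class patient this degrades to the recall of the present class and
is flagged as non-balanced), per-patient AUC only when both classes
occur, and pooled BA/AUC over all concatenated test predictions.  One
master seed spawns per-fold seeds.

## Agreement

Cohen's kappa with marginal-product chance agreement, computed on the
binary clear/not labels over all ICs, on 4-category labels over all ICs
(not-clear as its own category), and restricted to ICs both raters gave
some class.  Two permutation nulls shuffle one reviewer's labels: overall
or within each seizure; both leave the shuffled reviewer's marginals
unchanged, so only observed agreement varies and the null kappa can be
computed vectorized.  The p-value uses the add-one estimator
`(1 + #{κ_perm ≥ κ_emp})/(n_perm + 1)`.  Reconciliation keeps an IC only
when both reviewers marked it clear with the same class.  The
seizure-level class is the unanimous class, else the class of the IC
with the earliest change-point anchor; anchors within 0.5 s are broken by
the higher brain score.

## Prevalence modeling

Onsets: categorical logistic regression over SN/SubH (reference), SNIC
and SupH.  Offsets: Bernoulli over FLC vs SNIC/SH, with the rare SupH
offsets excluded before fitting.  Fixed effects: vigilance (reference
Awake), seizure classification (reference FIAS), standardized length and
age, gender, lobe (reference temporal) and etiology (reference
hippocampal sclerosis); single-level covariates are dropped
automatically.  Patients contribute per-class random intercepts
(non-centered, scale Half-Normal(1)).  Intercept priors are Normal with
SD 1 centered at the logit of the overall class prevalence — deviations
from the pooled distribution need evidence — and coefficients are
Normal(0, 1.5).

Sampling is Hamiltonian Monte Carlo written against the model's
closed-form gradients (validated to 2e-8 against finite differences):
up to 64 leapfrog steps with jittered length, dual-averaged step size
targeting 0.8 acceptance, and a diagonal mass matrix estimated from the
middle warmup third.  Each chain starts at a random overdispersed offset
(SD 0.25) around the posterior mode (L-BFGS), so short runs genuinely
disagree between chains and split R-hat (arviz) detects under-sampling.
The full-size configuration is 6 chains × 6,000 iterations (2,000
warmup); benchmarks in this repository run 2 chains × 2,000 with 500–800
warmup, which reaches R̂ ≤ 1.01 on the problem sizes used.  A posterior
predictive check compares observed class frequencies with the 95%
interval of replicated frequencies.

Contrasts between two levels of a factor recompute, per draw, the class
probability with the factor forced to each level while every other
covariate (and each row's patient intercept) keeps its observed value,
then average over rows — observed-design standardization.  The
difference draws are summarized by median, MAP (mode of a Gaussian KDE,
Silverman bandwidth), equal-tailed 95% credible interval, probability of
direction (pd, the fraction of draws sharing the median's sign) and the
ROPE fraction, whose half-width defaults to 10% of the overall
minority-class prevalence (the "10% change in the minority class" read
relatively).  pd > 0.97 is reported as a strong effect; ROPE < 0.03 as
practically meaningful.

## Problem sizes and benchmarks

The bundled benchmarks (test suite and `scripts/acceptance.py`) use: a
30-patient × 5-seizure cohort at 10 dB SNR with 6 ICs per seizure for the
classifiers; 1,000 stationary draws for the change-point false-positive
rate and 200 draws for scaling-law discrimination; 10,000 permutations
for the agreement nulls; n = 600 (intercept-only) and n = 800 (injected
wake-vs-NREM3 SupH shift of +0.15) for model recovery, with the scaled
2 × 2,000 MCMC configuration.  These sizes were chosen so a full run
completes in minutes on one core while leaving the statistical criteria
(BA ≥ 0.9, FP ≤ 5%, family recovery ≥ 95%, recovery error ≤ 0.05,
pd > 0.97, R̂ ≤ 1.01) well-powered.

## Known limitations

* Exact reproduction of the published inter-rater agreement tables needs
  the original reviewers' label workbook, which ships with the source
  article and is not redistributable here; the import adapter and all
  statistics are in place and unit-tested on constructed fixtures.
* The generator's bifurcation laws are the canonical square-root normal
  forms; real transitions deviate (noise, propagation, finite-size
  effects), so classifier ceilings here overstate clinical performance.
* The ISI-vs-time (rather than ISI-vs-index) curve-fit convention, the
  0.5 s seizure-level tie-break, and the relative ROPE reading are
  documented interpretation choices; all are configurable.
* SHAP-based feature attribution is exposed only as an optional hook and
  is untested; artifact correction defaults to robust clipping, not ASR.
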