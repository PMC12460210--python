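# Methods

This note documents the models and procedures the package implements,
the defaults it chooses where a procedure admits variants, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing its outputs.

## Signal conditioning

EEG trials are filtered per channel with an 8th-order Butterworth
band-pass (0.5–100 Hz) followed by a 4th-order Butterworth band-stop
over 48–52 Hz for the 50 Hz power line.  "Order" here means the order
of the final band-pass/band-stop transfer function (so the band-pass is
designed as a 4th-order low/high prototype).  Both filters are applied
forward-backward (`sosfiltfilt`), which squares the magnitude response
and cancels group delay — mandatory for phase-based connectivity, where
a causal filter's frequency-dependent delay would masquerade as phase
lag.  The narrow notch rings for several seconds at its band edges;
analyses that care about steady-state amplitudes should discard a few
seconds at each end of a filtered record (the test suite trims 4 s).

Artifact removal by independent component analysis and surface-Laplacian
re-referencing are intentionally not part of the pipeline: both are
manual or montage-geometry dependent.  A nearest-neighbour (Hjorth)
Laplacian with a fixed, hand-written neighbour map for the 16-channel
montage is available behind `preprocess(..., laplacian=True)`; it is a
coarse spatial high-pass, documented as non-faithful, and off by
default.

## Windowing

Trials are cut into 4 s windows with a 2 s stride; only full-length
windows are kept, so a record of T seconds yields
floor((T − 4)/2) + 1 windows (a 60 s trial yields 29).  By default the
windows of all trials of one session are pooled before estimating that
session's connectivity; per-trial estimation followed by averaging
(`average_sessions`) is available via `pool_trials: false`.  The two
orderings are deliberately both supported because the window count a
session "should" contain depends on this choice, and the package does
not guess which one an external protocol intended.

## ciPLV

Per window, each channel's spectrum is a single Hann-tapered rfft at
the native frequency grid of the window (0.25 Hz at 4 s).  For a
channel pair the unit-normalized cross-spectrum U = Sxy/|Sxy| is formed
per frequency bin, the expectation E[U] is taken across windows, and

    ciPLV = |E[Im U]| / sqrt(1 − |E[Re U]|²)

is computed per bin, then averaged over the bins of the band (bins
selected with low ≤ f < high so shared band edges are not counted
twice).  Bands: theta 3–7, alpha 7–13, beta 13–35, gamma 35–50 Hz.

Estimator choices worth stating:

* Single Hann taper rather than multitaper: with 4 s windows the theta
  band already has 16 native bins, and averaging across windows and
  bins supplies the variance reduction a multitaper would.
* Bin-then-average rather than filtering to the band first: the
  per-bin formulation keeps the denominator's zero-lag correction
  exact at each frequency.
* Degenerate denominator: when |E[Re U]| = 1 (purely real coupling —
  e.g. a channel against its own copy) the imaginary part is
  identically zero and the bin is assigned 0, which is the correct
  limit.  The threshold is 1 − |E[Re]|² < 1e−12.
* Bins where |Sxy| = 0 exactly (numerically silent channels) contribute
  0 rather than NaN.

ciPLV is amplitude-invariant (the normalization discards magnitude),
symmetric, zero on the diagonal, and confined to [0, 1].  The classical
PLV |E[U]| is kept alongside as the zero-lag-sensitive contrast: a
strength-1 zero-lag pair scores PLV ≈ 1 but ciPLV ≈ 0, which is the
volume-conduction artifact the corrected estimator exists to reject.

On noiseless single-frequency fixtures only the bins carrying signal
are meaningful (off-signal bins hold numerical noise of magnitude
~1e−16), so analytic endpoint checks evaluate ciPLV at the signal bin;
with any broadband noise present, whole-band averages are well defined.

## Percolation thresholding and closeness

Edges are removed in ascending weight order — equal weights as one
batch, so the result is order-independent — and the last state before
disconnection is kept.  The surviving minimum weight τ equals the
maximin bottleneck (the minimum edge on a maximum spanning tree), which
the tests use as an independent oracle.  Closeness centrality is
C(i) = (N−1)/Σⱼ l(i,j) with edge length 1/weight and l from Dijkstra's
algorithm, so multi-hop routes through strong edges may beat weak
direct edges.  Closeness is computed on the thresholded graph by
default (`percolation=True`); raw-matrix closeness is available for
sensitivity analyses.  Under the reciprocal-length convention, scaling
all weights by c > 0 scales every C(i) by c, so comparisons across
sessions are meaningful only with a common estimation protocol.

## Network-based statistic

The session contrast is a paired t per unique edge on the
within-subject (post − pre) differences; edges with zero-variance
differences are assigned t = 0 with a logged note rather than an
unbounded statistic.  Components are connected sets of supra-threshold
edges (|t| beyond T = 2.75 in the configured tail; component size =
edge count).  The permutation scheme flips the sign of each subject's
difference matrix — the exchangeability-correct relabeling for repeated
measures of one cohort, as opposed to the generic group relabeling of a
two-sample design.  When 2ⁿ ≤ k the flip space is enumerated exactly
and p = (#null ≥ observed)/2ⁿ with the identity included; otherwise k
seeded Monte-Carlo flips are drawn and p = (1 + #null ≥ observed)/(k+1),
so p > 0 always.  One-sided contrasts are the default (tail
"decrease"), with "both" thresholding |t|.

A property of sign-flip nulls worth knowing when interpreting p-values
under strong effects: flipping only j of n subjects leaves a planted
component supra-threshold whenever (n−2j)/sqrt(4j(n−j)·n/(n−1)) exceeds
T/√n — a ratio independent of effect magnitude — so the null
max-extent distribution retains a small mass at the observed extent and
the attainable p saturates around Σⱼ≤j* C(n,j)/2ⁿ (about 6·10⁻³ at
n = 20, T = 2.75) rather than 1/(k+1).  This does not affect error
control or power at conventional α.

## Behavior and the bimanual score

Tracks follow g(y,t) = Σᵢ₌₁²⁰ Aᵢ sin(fᵢ(y + t/6) + φᵢ) with
Aᵢ ~ U(1,10), φᵢ ~ U(−180,180) interpreted as degrees, and fᵢ uniform
on (0.01, 0.5 / 0.75 / 1.0) for easy / moderate / hard.  Units the task
definition leaves open are fixed as conventions: y is a normalized
screen coordinate and a trial's trace is g evaluated at the cursor's
row (y = 0), sampled at 50 Hz; fᵢ is in radians per normalized unit.
Only the frequency range varies with difficulty.

Performance is the Pearson r of cursor against track, clipped below at
0; it is invariant to positive affine transforms of either series and
undefined (an explicit error) for zero-variance inputs.  Trial scores
are averaged per subject × session × hand, and the (left, right) means
— standardized per column over the pooled pre+post rows, i.e. 2×
subjects observations — are reduced to their first principal component.
Pooling both sessions in one PCA keeps the two sessions on a common
scale and gives the regression its n = 2·subjects observations.  The
component's sign is fixed to correlate positively with the mean of the
two hands (the task defines no natural sign).

## Screening, PCR and LOOCV

Partial Spearman correlation is computed as: rank-transform x and y
(average ranks on ties), residualize both rank vectors on the
dummy-coded controls (session: one dummy; participant: n−1 dummies;
plus intercept), and correlate the residuals.  The p-value uses the t
approximation with df = n − 2 − q (q control columns), and the 95% CI
the Fisher z transform with se = 1/√(n − q − 3).  These are the
package's documented defaults among the common conventions for partial
rank correlations, chosen for transparency; the screening decision is
Bonferroni over the 16 nodes at α = 0.05.  Controlling for participant
as a fixed effect means the surviving correlations reflect
within-subject covariation, not between-subject skill differences.

VIF per feature is 1/(1 − R²ⱼ) from regressing feature j on the
remaining features with intercept; perfect collinearity reports inf.

The regression collapses the selected (standardized) nodes to one
principal component — exactly one, matching the one-dimensional summary
the screening is meant to feed — with sign fixed positive with the
outcome, residualizes component and outcome on the controls, and fits
y′ = β₀x′ + β₁ by OLS.  Leave-one-out cross-validation refits the
entire chain per fold: fold-specific standardization moments, PCA
loadings, control coefficients and OLS line, with the held-out
observation's residualized outcome predicted from fold-fitted
quantities only (the test suite audits that fold statistics differ).
By default the node set is fixed before LOOCV and only the
PCA-plus-OLS chain is refit per fold; `rescreen=True` additionally
re-runs screening inside every fold (falling back to the minimum-p node
when nothing survives) and reports per-fold selections.  Cross-validated
R² is 1 − SSE/SST over the held-out residualized outcomes; folds with a
degenerate PCA are excluded with a warning.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis
assumes: narrow-band phase coupling at controlled lag and strength
(band-pass-filtered Gaussian carriers shared between channels, the
second copy rotated through the analytic signal — for a noiseless
constant-lag pair this yields ciPLV = 1 exactly, and lag 0 reproduces
the volume-conduction trap), 1/f background spectra, paired cohorts
with planted additive edge effects, and tracking behavior whose score
degrades monotonically with motor noise.  Defaults mirror the study
conditions: 16 channels in the fixed montage order, 512 Hz EEG, 50 Hz
behavior, 60 s tracks, 20 subjects with two sessions for calibration
cohorts, T = 2.75 and α = 0.05 for the NBS.

It does not emulate: realistic head geometry or source mixing (beyond
the zero-lag trap), non-stationarity within trials, artifacts (ocular,
muscle, line transients beyond the stationary 50 Hz line the notch
targets), inter-channel correlated noise, or learning dynamics within
a session.  Passing tests therefore demonstrate that the estimators
recover the structures they target under stationary, well-specified
conditions — not that real recordings satisfy those conditions.

Cohort generation supports a fast matrix mode (subject-specific base
connectivity U(0.15, 0.6) per edge, within-subject session noise of SD
0.05, values clipped to [0, 1]) used for permutation-test calibration
at hundreds of replicates, and a raw-EEG mode exercising the full
estimation chain.  The 0.05 within-subject SD is a deliberate,
documented choice of "realistic" session-to-session variability for
window-averaged ciPLV; no external dataset pins it, so effect sizes in
power checks are stated in multiples of this SD (a "5 SD" planted
effect is 0.25 in ciPLV units).

The pipeline's synthetic run can additionally tie a latent per
subject × session state to both theta-band coupling strength and
tracking noise (`latent_gain`), planting the within-subject
metric/performance association the screening-and-regression chain is
designed to detect.

## Problem sizes and reproducibility

Simulation-based checks are sized to establish their property with
margin on a single CPU: family-wise error and sensitivity use 200
replicates of a 20-subject cohort at 1000 permutations (binomial SE
≈ 0.015 at α = 0.05); oracle equivalences use 100 random graphs or
seeds; full-pipeline integration runs use 6–12 subjects with 12–16 s
trials.  Every stochastic component takes an explicit seed, pipeline
stage seeds derive deterministically from the run's global seed, and
rerunning a config reproduces all CSV artifacts byte for byte.

## Known limitations

* ciPLV is bivariate and undirected; it cannot separate direct from
  indirect coupling nor give directionality.
* The percolation threshold is a global graph property: one weak
  bridge node determines τ for the whole matrix.
* With 2·subjects observations and participant fixed effects, the
  screening has few residual degrees of freedom (e.g. 18 at 20
  subjects); correlations must be strong to survive Bonferroni, and
  the pipeline reports an explicit note instead of fitting a PCR when
  nothing survives.
* The Fisher-z CI and t-approximation p for partial Spearman are
  asymptotic conventions; at small n they are approximate.
* File-based input accepts columnar CSV + JSON sidecar recordings; no
  binary EEG container formats are read or written.
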