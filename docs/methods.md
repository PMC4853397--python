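# Methods

`cortvowel` re-creates, on synthetic data, a complete covert-speech decoding
analysis: cortical current time courses are estimated from scalp EEG with a
hierarchical Bayesian inverse model whose current-variance prior comes from
fMRI contrast maps, and a sparse multinomial logistic classifier discriminates
three covert-articulation tasks (/a/, /i/, no-imagery) from the reconstructed
currents. This note documents the models, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish.

## Observation model and inverse estimation

Sensor data in an analysis window are modelled as

    B_t = G J_t + eps,   eps ~ N(0, Sigma_noise),   J_t ~ N(0, diag(nu)),

with `G` the lead field restricted to the prior's area vertices, `J_t` the
dipole currents, and `Sigma_noise` the pooled pre-onset baseline covariance
(-1.0..-0.5 s, diagonally loaded by `1e-6 * trace/n`). The per-vertex
variances `nu` carry a conjugate prior with mean

    nu0_v = nu_base * (1 + (m0 - 1) * that_v),

where `that_v in [0, 1]` is the normalized fMRI activity value at vertex v.
The estimation iterates the Gaussian current posterior with the variance
fixed point

    nu_v <- [ sum_t Jhat_{v,t}^2 + T*K*S_vv + 2*gamma0*nu0_v ] / (T*K + 2*gamma0)

over pooled training samples (T samples x K trials), stopping when the
maximum relative change drops below `tol` (default 1e-4) or after `max_iter`
(default 100) iterations. The two hyper-parameters have their conventional
semantics: the magnification `m0` scales prior current variance at
fMRI-active vertices (larger m0, larger estimated amplitude there), and the
reliability `gamma0` pins the estimate to the prior (as `gamma0 -> inf`,
`nu -> nu0` exactly — a property asserted in the tests). The grid searched by
model selection is `m0 in {10, 100, 1000} x gamma0 in {1, 10, 100}`.

This is a conjugate fixed-point re-specification of fMRI-constrained
variational source imaging; parity with any particular toolbox implementation
is not claimed — the behavioural properties in the test suite are the
contract.

Choices worth knowing:

- `nu_base` equates expected to observed sensor power: (mean sensor variance
  over the analysis range minus the noise power) divided by the mean squared
  lead-field column norm, floored at 1e-12. Nothing in the problem fixes the
  absolute current scale, so it is set from the data.
- Vertices outside the area prior are excluded from the model entirely rather
  than given a floor variance: the area prior defines *which* vertices are
  estimated.
- Variances and filters are estimated from training trials only; the filters
  are then applied to all trials. This is the conservative, leakage-free
  choice for cross-validation.
- Windows (default -0.5..3 s, 0.5 s long, 0.25 s shift; the decoding runs use
  0.5..2.5 s, which covers the 1-2 s feature window) are estimated
  independently; reconstructions are stitched with a linear cross-fade whose
  weights are proportional to the distance from each window's edges and form
  a partition of unity. A nearest-window variant would be a one-line change
  in `reconstruct_currents`.
- Dipole reduction keeps `ceil(ratio * n)` vertices (default ratio 0.2),
  stratified within ROIs by largest-remainder quotas, so no sufficiently
  large region loses all of its dipoles.

## fMRI priors

A mass-univariate OLS GLM regresses each vertex's volume series on
double-gamma-HRF-convolved task boxcars (peak 6 s, undershoot 16 s, ratio
1:6; convolution is per run — responses do not cross acquisition breaks) plus
one intercept per run. The two direction-specific contrasts (/a/ > /i/ and
its negation) are thresholded one-sidedly at an uncorrected p in
{0.001, 0.005, 0.01, 0.05, 0.1}; kept t-values are normalized by the maximum
kept t so activity values are scale-free; and the two directions are merged
by area union and per-vertex maximum (re-normalized). One-sided thresholding
per direction plus the merge restores two-sidedness. Group and leave-one-out
group priors run a one-sample t-test across subjects' effect maps (df = n-1)
with the same thresholding; the label-randomized control condition reuses the
LOOgroup prior unchanged and shuffles labels at classifier training instead.

## Classifier

The decoder is a softmax classifier with one weight vector per class and a
per-weight automatic-relevance prior `w_ck ~ N(0, 1/alpha_ck)` (alphas
initialized at 1). Training alternates simultaneous per-class block-Newton
steps — all class steps computed from the current weights and applied with a
single shared backtracking factor, which makes the update exactly symmetric
under class relabelling and keeps the penalized likelihood monotone — with
the MacKay evidence update `alpha <- (1 - alpha*Sigma) / w^2`. Weights whose
precision exceeds 1e8 are clamped to zero permanently. The class biases carry
a fixed tiny ridge (1e-6) instead of an ARD precision and are never pruned,
so the bias-only fit reproduces empirical class frequencies. When active
features outnumber trials the Newton solve and the inverse-Hessian diagonal
go through the Woodbury identity (cost O(n^2 d)).

Features are standardized with training-set statistics before fitting; ARD
behaves poorly across heterogeneous feature scales.

Sparsity behaviour: on 150 trials with 100 standardized features of which 3
are informative at 2 SD, the fitted models retain all informative features
and prune 91-96% of the noise *weights* (class-row entries). Counted at the
whole-feature level (pruned in every class row) the rate plateaus near 74%
under both block and full-Hessian Laplace approximations — with n of this
size some noise weights are genuinely well-determined. The per-weight count
is the unit ARD operates on and is what the test suite asserts.

## Features and evaluation

Sensor or current epochs are low-pass filtered at 45 Hz (4th-order
Butterworth, forward-backward), cut to 4-s epochs (1 s pre-onset), and the
1.0-2.0 s post-onset window is reduced per channel to 32 non-overlapping
8-sample bin means (256 samples at 256 Hz); "8-point moving average" is
implemented as binning with decimation 8 because only that yields 32 points
per channel, with a sliding non-decimating variant available as an option.

Current decoding uses nested cross-validation: 10 groups (5 trials per task
each under the 50-trial design), 9 inner train(8)/validate(1) rotations per
hyper-parameter pair, selection of the best pair (ties toward smaller m0,
then gamma0), retraining on all 9 non-test groups, and scoring of the
held-out group; the whole procedure repeats with reshuffled groups. Inverse
filters are fitted on each rotation's training trials ("inner" scope,
conforming); a faster "outer" scope fits them once per pair on the 9 non-test
groups — filters depend on trials, not labels, and never see the test group,
but validation trials do inform them, so this mode is an explicitly flagged
approximation. Sensor decoding uses 5x10-fold stratified CV.

Permutation significance uses p = (count_ge + 1) / n_perm (clamped at 1), so
the smallest attainable p at 10,000 permutations is 1.00e-04; the add-one
numerator is what makes that floor exact. Permutations reuse the label-free
feature extraction (and therefore the inverse filters) and retrain only the
classifier on a fixed stratified split — the knob that makes 10,000
permutations feasible on one CPU.

Interpretation normalizes each CV fold's weights by the fold's maximum
absolute weight, averages the 32 absolute bin values per channel (so negative
weights contribute), and flags channels that are selected (unpruned) in at
least 80% of folds *and* lie in the top decile of mean weight — both
fractions are explicit knobs. ROI aggregation averages channel weights within
each of 30 named regions (empty regions are reported missing, not zero).
Connectivity correlates task-conditioned across-trial mean current time
courses over the full reconstructed range (the 1-2 s window is an option)
and draws seed edges at |CC| > 0.6; zero-variance channels get CC = 0 with a
flag.

## Synthetic study conditions

The generator emulates the paradigm's statistical structure, not its
physiology:

- **Source space / forward model.** Quasi-uniform radial dipoles on a sphere
  of radius 0.8 (Fibonacci lattice with seeded jitter), 30 contiguous ROI
  blocks named for the speech-relevant anatomy, and an analytic
  homogeneous-medium dipole potential with average reference over a stored
  32-channel extended 10-20 layout. No BEM, no tissue conductivities.
- **EEG.** 4-s epochs at 256 Hz, 50 trials per task by default. Class signals
  are Gaussian-enveloped bursts (10 Hz for /a/, 20 Hz for /i/; sigma 0.15 s)
  centred 1.5 s post-onset on small active vertex sets drawn from the
  sensor-covered upper cortex; the control task has no burst. All vertices
  carry AR(1) background activity (coefficient 0.95). Burst amplitude equals
  the background SD (1.0) — single-trial covert-speech signal at the level of
  ongoing EEG — and white sensor noise is scaled to a requested burst-window
  SNR (default 5). Under these conditions the synthetic study lands at
  realistic accuracy magnitudes (sensors near 35-40%, currents near 45-60%),
  above chance and below ceiling.
- **fMRI.** Event-related runs (pre-task 1 s, task 3 s, rest 4/6/10 s
  permuted over trial triples; 3 runs x 10 trials per task; TR 3 s); each
  vertex's series is the HRF-convolved task boxcar weighted by its effect
  size plus white noise. Active vertices get beta = 3 against unit noise,
  which makes them reliably detectable at p = 0.01 uncorrected — the priors
  in the emulated design were evidently informative.

What the generator does not emulate: volume conduction through realistic
head tissue, eye/muscle artifacts, non-stationary background spectra,
trial-to-trial latency jitter, spatially extended sources, and fMRI
spatial preprocessing (data are generated directly in source space). Passing
tests therefore establish that the *machinery* behaves as specified under
the assumed statistical structure, not that the method attains any particular
accuracy on real recordings.

## Problem sizes used by the test and acceptance runs

Desk-scale defaults, chosen as this package's own study sizes: 20-60 vertex
source spaces, 10-20 trials per task for the cross-validated comparisons
(still 10 groups, so the nested protocol is unchanged), windows restricted to
0.5-2.5 s (covering the feature window), VB tolerance 1e-3 with at most 50
iterations and classifier Newton caps of 6-30 sweeps inside the heavy loops.
The current-vs-sensor comparison runs 10 seeded datasets in the test suite
and 5 in the acceptance script; the chance-level check averages over 5-6
independent null datasets because a single high-dimensional null dataset's
CV accuracy deviates from 33.3% by several points through chance
feature-label correlations (its across-fold SE understates that spread).

## Known limitations

- The inverse model treats windows independently; no temporal smoothness of
  variances across windows.
- The "outer" filter scope used in the heavy comparisons shares filters
  between the inner rotations of a fold (see above); the conforming "inner"
  scope is the default and is what the leakage test runs.
- ARD pruning is permanent; no weight revival.
- Group priors assume all subjects share one vertex space (inverse spatial
  normalization is the identity here).
- The one-way ANOVA helper covers the confusion-ratio comparison only;
  multi-factor designs are out of scope.
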