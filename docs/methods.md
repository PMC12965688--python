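# Methods

This note records the models implemented in `dynexpect`, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the problem sizes the test suite uses.

## Leaky-integration expectation model

Strength is the recency-weighted mean of past same-cue pain ratings with
weights `w_k = exp(−k/ω)`, `k = 1` being the most recent same-cue trial and
ω = 8 trials by default.  Only same-cue history enters; trials under the
other cue never affect a cue's series.  Precision derives from the weighted
variance of past strength estimates: the weighted mean `Ē` and the weighted
mean squared deviation `Var` are computed over the *defined* past strengths
(the first same-cue trial has none), indexing weights by position within
that defined subsequence.  Consequences: strength is undefined on the first
same-cue trial, precision on the first two, and `Var = 0` at the third
(single past strength).  Rows entering mixed models are those with all
regressors defined.

Because the raw variance distribution is strongly right-skewed, a power
transform `v* = Var^0.25` is applied before inversion.  Two monotone maps
from `v*` to raw precision are provided:

- `reciprocal` (default): `1/(v* + ε)` with `ε = 10⁻⁶ × max(v*)` over the
  fitted data, guarding the exact-zero variances of early trials.  Note the
  guard makes those trials' precision values orders of magnitude larger
  than the rest, so after min–max scaling the normalised precision is
  strongly compressed; this is the literal reading of "inverse".
- `negated`: `−v*`, which min–max scaling renders statistically equivalent
  up to a monotone transform and which avoids the compression.

Neither is asserted to be the historically "correct" variant; both are
exposed.  Min–max normalisation of strength and precision defaults to
pooling all participants and trials of the dataset
(`normalization="pooled"`); a per-participant scope is available as a
sensitivity option.  Normalised values attain 0 and 1 exactly within the
fitted scope.

The per-trial computation uses O(1) recursive updates of the weighted sums
(`N ← d·(P + N)`, `D ← d·(1 + D)` with `d = e^{−1/ω}`), which are
algebraically identical to the full-history sums; the test suite verifies
agreement with an independent brute-force loop to 1e−10 on 10,000 random
histories.

## Synthetic paradigm generator

The design generator reproduces the cued-pain structure: 4 runs × 40
trials, two cues with equal trial counts, 75% cue–intensity contingency as
an exact per-cue count (60 valid / 20 invalid per cue per participant at
defaults), intensity coded LP = 1 / HP = 2, cue–shape assignment
counterbalanced across participants.  Sequences are drawn by rejection
resampling of within-run permutations (retry budget 10,000) until no more
than 3 consecutive trials share a cue or intensity and no more than 2
consecutive trials are invalid; constraints are checked within run, since
runs are separated by breaks.  Invalid trials are spread as evenly as
possible across runs with no further structure imposed.

The rating agent generates ratings strictly forward in time: at each trial
it computes its own strength and precision from the ratings it has already
produced, maps them to [0, 1] with *nominal* bounds — strength by dividing
by the 100-point scale, precision by `1 − Var^0.25 / 2500^0.25`, 2500 being
the maximal variance attainable on a 0–100 scale — and emits a linear
predictor plus participant intercept and Gaussian noise, clipped to
[0, 100].  Nominal (rather than empirical) bounds avoid look-ahead inside
the generator; the analysis side uses empirical min–max as above, an affine
(strength) or monotone (precision) re-mapping of the same latents.
Expectation terms contribute only once defined, so the first same-cue trial
is driven by intercept and intensity alone.

Default generative coefficients are the printed behavioural slopes for
pain-intensity ratings (intensity 18.52, strength 26.91, precision 2.72,
interaction −9.62 NRS units).  The intercept (12) and variance components
(participant SD 8, residual SD 10) were calibrated so that fewer than ~1%
of ratings touch the scale bounds: clipping is the one nonlinearity of the
generator, and keeping it negligible is what makes the generating model
refittable without bias.  The realised clipping fraction is reported in
`attrs["clip_fraction"]` and a warning is raised at ≥5%.

What the generator does *not* emulate: habituation/sensitisation drifts,
rating anchoring and discreteness, heavy-tailed or heteroscedastic noise,
run breaks as state resets, and any real EEG structure (epoch fixtures are
Gaussian bumps plus white noise; band-power features are planted linear
paths).  Passing tests therefore demonstrate correctness and calibration of
the *procedures* under the stated generative assumptions, not effect
estimates for real data.

## Competing learning models and fitting conventions

Four cue-specific accounts: the leaky integrator (decay fixed at ω = 8; one
free parameter, the observation SD; a fitted-ω variant exists for
comparison only), the Rescorla–Wagner delta rule (learning rate α, initial
expectation E0 shared across cues by default, observation SD; optionally E0
per cue), a scalar Kalman filter (prior mean and variance, diffusion and
observation variances — reported expectations are the pre-update prior
means — plus observation SD; variances optimised in log space within
[1e−4, 1e4]), and a static model with one constant per cue (closed-form ML:
the per-cue target means).

All models are scored with a Gaussian likelihood of the target series given
their one-step-ahead predictions.  The observation SD is profiled out in
closed form; remaining parameters are estimated by L-BFGS-B from 8
Latin-hypercube starts with a fixed seed.  To make evidences comparable,
the likelihood is always evaluated on trials with at least one previous
same-cue trial — the set on which the leaky prediction is defined.  Model
evidence is approximated by −BIC/2 (`logL − (k/2)·log n`), a deterministic
Laplace-style proxy for the variational free energy used by VBA-style
toolboxes; only evidence *differences* are meaningful, and absolute Bayes
factors under other priors (e.g. JZS) are not reproduced.

Model-recovery simulations generate ratings exogenously from the delivered
intensities (`rating = level(intensity) + noise`, levels 40/60, noise SD 8)
and let the generating model produce a trial-wise expectation report
(`prediction + noise`, SD 5), mirroring paradigms with pre-stimulus
expectation ratings; candidates are then fitted with the report as target.
The canonical generator settings (`RECOVERY_GENERATORS`) were chosen to
place each rule in an identifiable regime: RW at α = 0.35 (well above the
leaky integrator's effective one-step weight 1 − e^{−1/8} ≈ 0.12), the
Kalman filter as a pure learning curve (zero diffusion, large prior
variance, gain decaying towards zero — a constant-diffusion Kalman filter
converges to a constant gain and is then indistinguishable from RW), and
static constants 40/60.  A self-feeding generator (rating = own prediction
+ noise) was rejected: it renders all dynamic rules nearly
likelihood-equivalent, so the evidence penalty always selects the most
parsimonious model.

## Bayesian model selection

Fixed-effects comparison sums log evidences; pairwise differences are
log Bayes factors.  Random-effects comparison runs the standard
Dirichlet-multinomial variational update (uniform Dirichlet prior α₀ = 1,
responsibilities `u_nk ∝ exp(logE_nk + ψ(α_k) − ψ(Σα))`, convergence when
the α change falls below 1e−6, cap 500 iterations); exceedance
probabilities are Monte Carlo argmax frequencies over 10⁶ Dirichlet draws
with a fixed seed (20260302).  The dynamic-versus-static comparison of
mixed models uses `exp(ΔBIC/2)` with ΔBIC from the profiled-ML
random-intercept fits; direction and order of magnitude are the claims, not
the absolute value.

## Mixed-model inference

The random-intercept Gaussian LMM is fitted two ways.

*Gibbs (primary).*  Flat prior on fixed effects; half-Cauchy(0, 2.5·sd(y))
priors on both the residual and intercept SDs via the Huang–Wand
inverse-gamma mixture, which keeps all conditionals conjugate.  Blocked
updates (fixed effects jointly, random intercepts jointly, variances) use
grouped sufficient statistics, so iteration cost is independent of the
number of trials after a single pass.  Because the intercept and the mean
of the random intercepts are only jointly identified, each sweep resamples
their shared translation (drawn from N(mean(u), τ²/G)) — without this the
intercept chain mixes arbitrarily slowly.  Defaults: 4 chains × 1000
post-warmup draws (warmup = draws/2); split-chain R̂ is computed per fixed
effect and a warning is raised above 1.05.  Summaries: posterior mean
(*Est*), 95% HPD as the narrowest contiguous interval of the pooled sorted
draws (equal-tailed available), and *Pp* = posterior mass on the sign of
*Est* (so Pp ∈ [0.5, 1]).  The decision rule exposed as
`MixedModelResult.compelling()` is "HPD excludes 0 and Pp > 0.975".  Its
false-positive rate on pure-noise outcomes is verified ≤ 7% in the
acceptance suite.

*Profiled ML (+ parametric bootstrap).*  For a fixed variance ratio
λ = τ²/σ², each group's inverse covariance is `(I − λ/(1+n_g λ) J)/σ²`, so
GLS reduces to grouped sufficient statistics; the scalar log-ratio is
optimised numerically, σ² has a closed form, and the log-likelihood matches
`statsmodels` MixedLM (ML) to ~1e−3 (oracle test).  `ml_bootstrap` mode
reports percentile intervals from a parametric bootstrap, labelled
HPD-analogues.

*Mass-univariate mapping.*  The same ML solver is fitted per channel; Wald
t statistics use a normal approximation (at ≥ thousands of trials per
channel the difference from a t reference is negligible).
Benjamini–Hochberg FDR (via `statsmodels.multipletests`) is applied across
channels separately per effect within one frequency band — the FDR family
choice.  Significant channels are kept only in connected components of
size ≥ 3 under the packaged 32-channel schematic 10–20 adjacency
(neighbour = planar distance ≤ 0.62 head radii; positions are schematic,
not digitised).  This stage is a spatial screen; inferential statements
come from the Bayesian refit of cluster-averaged power.

*Power computation.*  The within-factors repeated-measures F test uses
noncentrality λ = f²·n·m·ε/(1−ρ), df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε, and
power = survival of the noncentral F at the central-F critical value; the
minimal n is found by exponential bracketing plus downward confirmation
(power is monotone in n).  Defaults ρ = 0.5 and ε = 1 are the conventional
tool assumptions.  At f = 0.25, α = 0.01, power 0.99, m = 4 this returns
n = 62.

## Multilevel mediation

Per participant, OLS gives `a_i` (M ~ X), `b_i`, `c′_i` (Y ~ M + X) and
`c_i` (Y ~ X), optionally with covariates and per-participant z-scoring.
The population indirect effect is `mean(a_i·b_i)`, which equals
`mean(a)·mean(b) + cov(a, b)` and therefore includes the across-participant
covariance correction of 1-1-1 mediation; OLS guarantees
`c_i = c′_i + a_i b_i` exactly, so the decomposition is additive at every
level.  Inference resamples participants with replacement (default 10,000
resamples, reducible): percentile CIs and two-tailed p as the doubled
proportion of bootstrap estimates crossing zero (floored at 1/n_boot).
Participants with rank-deficient within-participant designs are excluded
with a warning; fewer than 10 usable participants is an error.  Batteries
of (predictor, mediator) pairs are BH-FDR corrected.  This
per-participant-OLS + participant-bootstrap formulation targets the same
estimand as empirical-Bayes multilevel mediation toolboxes but without
shrinkage, so path estimates are noisier per participant and exact
agreement with such toolboxes is not claimed.

## EEG feature measurement

*N2/P2.*  A zero-phase FIR low-pass at 30 Hz (order 3·fs/cutoff, Hamming
design, forward-backward) precedes measurement.  Group latencies come from
the all-trials grand average at Cz — trough in 180–300 ms, peak in
250–500 ms, snapped to the sample grid, with a warning when the extremum
sits on a window boundary — and per-trial amplitudes are means over
latency ± 15 ms.  Latencies are invariant to constant offsets; NaN trials
propagate to NaN features rather than being dropped.

*Time–frequency.*  Sliding 250-ms Hanning windows centred every 10 ms
within −500…1000 ms; centres whose window would exceed the epoch are
dropped (no padding), so edge bins are absent and the time axis reports
window centres.  The FFT is zero-padded to 1 s for a 1-Hz grid
(1–100 Hz); power is scaled so a unit-amplitude sinusoid has power 1 at its
frequency.  Baseline correction subtracts the per-trial mean power over
−400…−100 ms per channel and frequency.  ROI presets: LEP 1–10 Hz,
100–400 ms, FC1/FC2/Cz; α-ERD 7–13 Hz, 500–900 ms, P3/Pz/P4; γ-ERS
60–90 Hz, 200–350 ms, FC1/FC2/Cz.

*Anticipatory band power.*  Full-epoch periodograms at the native
resolution (1/epoch duration; 0.25 Hz for 4-s epochs), averaged within
θ 4–7, α 7–13, β 13–30, γ 30–90 Hz.  The default taper is a single Hann
window; a rectangular mode exists (for which total PSD × bin width equals
the time-domain mean square — the Parseval check), and a DPSS multitaper
mode with time–bandwidth parameter `nw` is exposed.  Band averages over
≥3-Hz-wide bands are insensitive to the taper choice at this resolution,
which is why a single taper is an adequate default.

## Pipeline and reproducibility

`run_study` executes simulate → model validation → expectation effects →
mediation from one YAML-serialisable config.  The master seed fans out
per-stage child seeds through `numpy.random.SeedSequence`, every stochastic
routine takes an explicit seed, and the metrics JSON is written with sorted
keys — reruns are byte-identical.  Stage failures abort with the stage name
and leave completed outputs on disk.

## Problem sizes used by the test suite

Unit tests run at small scale (2–16 participants).  The acceptance tests
use: 1000 design seeds; 10,000 random histories for the oracle check; 100
cohorts of 72 participants (Gibbs with 2 chains × 400 draws) for slope
coverage; 200 pure-noise refits of a 63-participant cohort (~10,000
trials) for the false-positive rate; 5 recovery replicates per generating
model with 10-participant cohorts; 20 mediation cohorts of 40 participants
with 1000 bootstrap resamples; and 200 all-null mediation batteries of 8
mediators.  These sizes make the full suite complete in a few minutes on a
single CPU while keeping the Monte Carlo margins comfortably inside the
asserted thresholds.

## Known limitations

- The Kalman and RW parameterisations follow the standard textbook forms;
  the historical implementations they stand in for are under-specified in
  the source literature, so recovered parameters are comparable only within
  this package.
- BIC-based evidence approximations can misrank models at very small trial
  counts or on the boundary of parameter space.
- The reciprocal precision mode yields a highly compressed normalised
  regressor (see above); analyses sensitive to the shape of the precision
  scale should compare both modes.
- No random slopes or crossed random effects; the mixed models are
  random-intercept only.
- The mediation bootstrap resamples participants only (not trials), and
  assumes trial-level independence within participant.
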