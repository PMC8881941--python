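# Methods

## The measurement problem

The pipeline estimates how large a change in metabolic rate must be before a
walking human reliably notices it. In the underlying experimental design,
participants walk in blocks of ten 2-minute trials while a wearable device
randomizes their energetic cost; after every trial but the first they answer
a binary forced-choice question comparing the current trial's exertion with
the previous one. Ten trials therefore yield nine sequential comparisons per
block, and a participant contributing eleven blocks yields ~99 responses.

## Energetics

Breath-by-breath metabolic power approaches its steady state as a first-order
transient with cardiopulmonary time constant τ ≈ 42 s. Each trial's rate is
the steady state of a least-squares fit of

    y(t) = y_ss + (y0 − y_ss) · exp(−t/τ)

with all three parameters free. τ is bounded to [10, 120] s and initialized
at 42 s: the bound brackets the physiological constant while keeping the
problem well-conditioned on noisy 2-minute windows, and leaving y0 free
subsumes any assumption about the initial condition carried over from the
previous trial or from rest. On the rare solver failure the estimate falls
back to the mean of the final 60 s and is flagged. A 4-minute standing
recording is averaged into a baseline which is subtracted from every trial
(net rate); the psychometric stimulus is the percent change of net rate
between consecutive trials, x = 100·(B − A)/A. Pairs never span block
boundaries (rest between blocks breaks the sequential reference), and pairs
with a non-positive reference are dropped with a count rather than erroring:
noise can produce them and a ratio stimulus is undefined there. Normalization
uses net rates for both A and B; gross-rate normalization amounts to passing
a zero baseline.

## Psychometric model

Responses follow the logistic psychometric function Ψ(x) with fixed guess and
lapse rates γ = λ = 0.02, threshold α = 0, and free slope β (units: per
percentage point — x is carried in percent throughout, so the fitted JND
reads directly as a Weber fraction in percent). The JND is defined by the
quartile construction (half the spread between the x-values where Ψ crosses
0.25 and 0.75), which collapses to JND = k/β with k a closed-form constant of
(γ, λ); for γ = λ = 0.02, k ≈ 1.1550. Both the closed form and a bisection
inversion of Ψ are implemented; they agree to 1e−9 and the inversion also
covers γ ≠ λ. With γ = λ the curve satisfies 1 − Ψ(−x) = Ψ(x), so a single
JND describes both penalties and benefits.

## Inference

Each model places a uniform prior on the JND (default 0–70%) and a Bernoulli
likelihood on the responses. The JND is sampled directly (β = k/JND inside
the likelihood) because the prior is stated on JND; a floor of 0.1% on the
support prevents β → ∞ at zero, far below any plausible human threshold.

Posteriors are one-dimensional, and are sampled with the affine-invariant
ensemble sampler (emcee). Walkers stand in for chains (2 per configured
chain, minimum 4); split-R̂ is computed across walker chains and a fit is
flagged above 1.01. Ensemble moves produce autocorrelated draws, so a `thin`
setting (default 4) keeps every fourth step — the configured number of kept
draws is unchanged, only the effective sample size per kept draw improves.
Divergence counts, a Hamiltonian-sampler concept, are reported as zero for
schema parity. Default budgets are 8000 tuning steps and 4000 kept draws
(2000/2000 for the pooled model, which sees every response at once).

Three model structures are fit and compared:

* **pooled** — one JND for the whole cohort;
* **independent** — one JND per participant;
* **variable WF** — two JNDs per participant, split at the median absolute
  reference rate A, letting the Weber fraction depend on reference magnitude.
  Comparisons with A strictly below the median go to the "low" posterior
  (ties go high; if every value ties at the median the split is rejected as
  undefined).

The point estimate is the posterior mode — under a uniform prior, the
maximum-likelihood estimate on the support — extracted as the peak of a
Gaussian KDE (Silverman bandwidth) on a 1000-point grid. A KDE whose
max/mean ratio falls below 1.5 is flagged as a non-identified plateau (the
posterior is essentially the prior). Credible intervals are equal-tailed
(2.5th–97.5th percentiles): reproducible without density estimation, at the
cost of being wider than an HDI for skewed posteriors.

A brute-force oracle integrates the same unnormalized posterior on a
2000-point grid with trapezoidal quadrature; tests require MCMC and grid to
agree within 0.5 percentage points on the posterior mean and 0.3 on the SD.

WAIC is computed from the pointwise log-likelihood matrix (one column per
binary response) as elpd_waic = Σᵢ [log-mean-exp of the draws − varᵢ], with a
log-sum-exp–stable reduction and sample (ddof = 1) variances; it is reported
on the elpd scale, higher = better. All three models are scored on the
identical, canonically ordered response set so pointwise vectors align, and
the standard error of each model's gap to the best model comes from the
pointwise differences. For models composed of several posteriors
(independent, variable WF) each response's column uses the posterior that
predicts it.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, with
ground truth attached:

* **Torque profiles**: onset ~ U(25%, 50%) of stride, magnitude ~ U(15, 25) A,
  duration ~ U(d_min, 60%) with d_min = 20% when onset < 30% (device-wear
  constraint) else 10%.
* **Profile → rate surrogate**: real exoskeleton energetics have no closed
  form, so a fixed positive-weight quadratic surface in the three normalized
  profile parameters is rescaled into the configured net-rate range (default
  1.5–6.6 W/kg, the span observed in treadmill protocols of this kind), with
  a small per-participant affine deformation. It is deterministic and
  explicitly synthetic: downstream inference needs realistic rate variation,
  not biomechanical fidelity.
* **Breaths**: first-order transients at τ = 42 s sampled every 4 s with
  ±1 s jitter (~30 breaths per 2-minute trial; breath timing is not a
  published quantity, this is a physiologically plausible choice) plus
  i.i.d. Gaussian noise, default SD 8% of the local steady state — the
  simplest model consistent with noise-like metabolic variability. Blocks
  start from the standing rate.
* **Responses**: Bernoulli draws from Ψ at the participant's true JND with
  lapse 0.02, matching the analysis's fixed λ unless overridden.
* **True JNDs**: uniform over (6, 70)% by default, exercising both
  well-identified narrow posteriors and flat near-bound posteriors.

What the generator does **not** emulate: kinematics and heel-strike timing,
current/torque waveforms, respiratory-exchange-ratio conversion from raw gas
exchange, drift or autocorrelation in metabolic noise, sequential effects in
responding (anchoring, fatigue), or any dependence of perception on the
reference magnitude beyond the variable-WF model's split. Passing tests
therefore demonstrate that the pipeline recovers what it assumes — correctly
specified first-order transients and a constant-WF logistic observer — not
that real perceptual data satisfy those assumptions.

## Cohort statistics

Cohort summaries use the sample SD (n−1) and recompute SE = SD/√n rather
than carrying it separately. Normality of the JND estimates is checked with
a one-sample Kolmogorov–Smirnov test against a normal with sample-estimated
parameters; the result records that estimated parameters make the nominal
p-value approximate (the Lilliefors caveat). The perception-probability
calculator evaluates the cohort-average curve (β = k/mean JND) at a given
rate change; by construction it returns 0.75 at the mean JND itself and 0.50
at zero. Fitness-correlate regressions are simple OLS with the F-test of the
slope (one predictor, so F = t²) and a 95% confidence band for the mean
response; no multiple-testing correction is applied across the three
covariates. The prior-sensitivity sweep refits every participant's
independent model under alternative prior upper bounds (default 60/70/80%)
and reports the shift of the cohort mean.

## Problem sizes and numerical choices in the test suite

Oracle equivalence uses 5 generated participants at the protocol size (11
blocks → 99 comparisons) with 16 000 thinned draws. Calibration uses 200
simulated participants (true JND ~ U(8, 45)%, x ~ U(−40, 60)%, 99 responses)
with reduced settings (300 tune / 4000 draws / thin 2); the 95% intervals
cover truth ≥ 88% of the time and mean point-estimate bias stays within 2
percentage points. Model-structure recovery uses 20 heterogeneous and 20
homogeneous cohorts of N = 10 participants — the protocol's cohort size;
at substantially smaller cohorts the variable-WF model's overfitting noise
overtakes the parsimony gap in an appreciable fraction of replicates, which
is a property of WAIC on nested models rather than of this implementation.
Bisection tolerance for curve inversion is 1e−12; curve-fit bounds and
initialization are as above; KDE flatness threshold 1.5; R̂ threshold 1.01.

## Known limitations

The ensemble sampler replaces gradient-based samplers with identical targets
but different small-sample autocorrelation properties; draws are thinned
accordingly. Equal-tailed intervals touch the prior bound for insensitive
participants (the upper limit saturates at the bound — right-skewed
posteriors carry most of their uncertainty upward, so errors there bias the
JND downward). The KDE mode on a bounded support can sit slightly inside the
boundary for posteriors peaked exactly at it. The surrogate rate map is a
modeling convenience; none of its coefficients are estimates of real
exoskeleton dose–response.
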