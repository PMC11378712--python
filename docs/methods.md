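# Methods

This note documents the models, numerical choices, and design decisions
behind `rtseq`, in the spirit of the methods documentation of statistical
modelling packages: what is computed, under which assumptions, and where
the genuinely open choices were resolved.

## Data model and preprocessing

A trial table is a tidy frame (participant, paradigm, block, trial,
stimulus_type, stimulus_detail, response, correct, rt_ms), strictly
ordered by (participant, block, trial).  Block 0 is the practice block;
trial indices are 1-based within block; RTs are milliseconds throughout
the table layer and seconds inside the diffusion layer.

**Exclusion cascade.** Trials are removed in a fixed precedence order —
practice block, the first two (warm-up) trials of each block, post-error
trials, then RTs outside [lower, 3000] ms — and each removed trial is
charged to the first rule that catches it, so the per-rule counts plus
survivors always sum to the input count and the filter is idempotent.
Post-error status is judged by design adjacency (the trial with index
n − 1 in the same block, on the sequence remaining after practice/warm-up
removal), so an error later removed by the RT filter still poisons its
successor: the error occurred regardless of the filter.  Post-error
exclusion does not cross block boundaries.

**Adaptive lower cutoff.** Responses are binned into successive 50 ms
intervals from 0; the cutoff is the lower edge of the first of two
successive occupied bins whose per-bin accuracy *and* cumulative accuracy
(all responses at or below the bin's upper edge) strictly exceed chance
(0.5, point estimate, no significance test).  Empty bins are skipped, and
a qualifying final occupied bin needs no successor.  With few trials the
point-estimate rule is noisy: a sparsely occupied guessing band
(~25 trials/bin at 50% accuracy) triggers early in a noticeable fraction
of small samples.  At realistic sample sizes (tens of participants) the
rule settles on the boundary between the guessing band and genuine
responses.

**Sequence coding.** Repetition/alternation labels are paradigm-specific:
visual search compares the target dimension and is undefined unless both
trials are target-present; two-choice compares the stimulus–response
category (stimulus and response are yoked); interference compares
congruency; task switching compares the task.  The first trial of a block
is always undefined.  Labels are assigned *before* RT-based exclusions
(`neighbor="design"`), so an excluded predecessor still defines its
successor's history; `neighbor="surviving"` is available as the
alternative policy, since the original analyses' choice is not
documented.

**Participant exclusion.** Accuracy < .70; then > 3 sample SDs on the
arcsine-transformed error rate, with the transform fixed as
2·arcsin(√p); then > 3 sample SDs on mean log RT.  The SD rules need a
sample and are skipped with a warning for a single participant.

## Descriptive distributions

Percentile ranks use the mid-rank (L + 0.5·E)/N, computed within
participant and stimulus type but across the compared sequence
conditions; ranks are therefore invariant to any strictly monotone RT
transform, and with all-distinct values their mean is exactly 0.5.
Rank histograms default to 10 equal bins.  Vincentizing estimates each
participant's quantiles by linear interpolation of order statistics (the
"type 7" convention, fixed for reproducibility) at p = .05, .10, …, .95
(19 points) and averages across participants.  Both methods use
correct-response trials by default (`correct_only` is switchable); this
matches the package's RT analyses, where errors enter only through
accuracy.

## Ex-Gaussian

Density, CDF and sampling go through the exponentially modified normal
(log-space density evaluation for stability).  MLE is Nelder–Mead on
(μ, log σ, log τ) — positivity by reparameterization — with restarts:
restart 0 from the moment-based start (τ₀ = 0.8·sd, μ₀ = mean − τ₀,
σ₀ = √max(var − τ₀², ε)), restart 1 from a deliberately small-τ start so
near-Gaussian samples can reach the τ → 0 boundary, later restarts
perturbing the moment start by Uniform(0.9, 1.1) per parameter.  The fit
records whether the best objective over the first k − 1 restarts already
equals the best over k (restart-stability flag).

## Diffusion models

Evidence accumulates from a·w toward boundaries 0 and a with drift v and
**diffusion coefficient s = 1**; the upper boundary is the correct
response.  Fitted magnitudes (a ≈ 1–2, v ≈ 2–5) are on this scale and
must be divided by 10 to compare with the s = 0.1 convention.  The
standardized lower-boundary density uses the small-time expansion for
scaled decision time τ = t/a² < 0.2 (terms k = −7…7) and the large-time
expansion otherwise (25 terms); both truncations are far below the 1e−7
error target at the switch point, where the test suite checks smoothness.

The seven-parameter likelihood integrates the normal drift mixture
analytically,

    f(t | v, σ_v) = f₀(t) (1 + σ_v²t)^{−1/2}
                    exp[(a²w²σ_v² − 2awv − v²t) / (2(1 + σ_v²t))],

with f₀ the v-independent kernel, and averages over the uniform
starting-point and non-decision windows by 11-node Gauss–Legendre
quadrature per dimension (node count configurable; collapses exactly when
a range is zero, making the 7-parameter likelihood reduce to the
4-parameter one).  Per-trial densities are floored at 1e−10 before the
log so a contaminant cannot sink a whole cell.

Conditional decision-time moments (used by the EZ forward system and the
simulator validation) integrate the large-time series term by term:
∫ tᵐ f_lower dt = (π/a²) e^{−vaw} Σ_k k sin(kπw) m!/λ_k^{m+1} with
λ_k = (v² + k²π²/a²)/2, truncated at 20 000 terms (error ≪ 1e−6 s);
absorption probabilities use the closed form
P(upper) = expm1(−2vaw)/expm1(−2va), with the v → 0 limit w.

**Fitting** is Nelder–Mead (restarts: multiplicative Uniform(0.85, 1.15)
on a, v, t₀ and the variabilities; additive ±0.05 on w, clamped) from an
EZ-style moment-inversion start, with constraints enforced by an internal
reparameterization: log for a and σ_v, scaled logistic for t₀ (below the
minimum RT), w, σ_w and σ_t₀ (inside their feasibility windows).
Single-boundary data are refused below n = 50 (a and w unidentifiable)
and warned about otherwise.

**Simulation** is Euler–Maruyama with dt = 0.5 ms plus a Brownian-bridge
crossing correction each step (absorb with probability
exp(−2(a−x)(a−x′)/dt) for an uncrossed step), which removes the
first-passage discretization bias; without the correction the absorption
probability at a = 1 is visibly biased (~0.741 vs. the exact 0.7311 at
dt = 0.5 ms).  Residual decision-time bias is below ~3 ms at typical
parameter magnitudes, validated against the density in the tests.  An
antithetic-increment option halves the odd moments of the step noise.

**Fisher diagnostic.** The correlation matrix of (a, v, t₀, w) comes from
the numeric Hessian of the negative log-likelihood at the supplied
parameters (central differences, relative step 1e−3), inverted to a
covariance; a non-positive-definite Hessian falls back to a
pseudo-inverse with a warning.

## EZ estimation

Cell moments are accuracy (edge-corrected to 1/(2n) or 1 − 1/(2n) at the
boundaries), correct-RT mean and variance (n − 1 denominator), and mean
error RT when errors exist.  The forward mapping is the constant-parameter
biased diffusion above (s = 1, so EZ output seeds the full diffusion fits
directly).  Inversion minimizes the sum of squared *relative* residuals —
each residual divided by the observed moment, making the objective
scale-free across the heterogeneous moments — by Nelder–Mead from the
closed-form unbiased (w = 0.5) solution, with restarts that stop early
once the SSE drops below 1e−13 (an exact match).  Without an error-RT
moment, w is fixed at 0.5 with a warning: bias is not identifiable from
correct-response moments alone.  On exact forward moments the round trip
recovers parameters to ~1e−8.

## Behavioral statistics

Cell summaries use mean RT over correct trials and proportion correct
over all trials.  The 2 × 2 within-subject ANOVA is computed from
per-participant contrast scores: every effect has 1 df, so F = t² of the
paired t on the corresponding contrast, df₂ = n − 1, and
η_p² = F/(F + df₂); no sphericity question arises.  Zero error variance
is reported as degenerate (NaN) rather than an arbitrary F.  Paired
effects report the mean difference with a central-t 95% CI and
d_z = mean/sd with a CI from noncentral-t inversion (the standard
construction for standardized paired effects).

## Goodness of fit

Per participant × stimulus type × sequence cell, the fitted model
generates 10× the observed trial count (ex-Gaussian: correct-RT draws;
diffusion family: simulated RT + correctness).  Observed and predicted
data are separately converted to within-participant percentile ranks and
pooled.  The χ² statistic bins observed ranks into 50 equal bins per
sequence condition (100 cells, df = 99 — the bin count is configurable
and the df always reported); expected counts are the predicted rank
histogram rescaled to the observed total *per condition*, so conditionwise
totals match.  Zero-expected cells are merged with a neighbor, reducing
the df, with a warning.  KS tests are two-sample with asymptotic p per
condition.  Neither statistic penalizes parameter count: these are
goodness-of-fit measures, not model-selection criteria.

## Synthetic data generator

The generator defines the study conditions for all tests.  Design: 10
experimental blocks × 122 trials plus a 22-trial practice block, two
warm-up trials per block always instantiating an alternation of the
paradigm's critical feature without disturbing the balancing.
Experimental-block balancing is exact — visual search 40% absent / 60%
present with the four targets equally frequent (48/72/18 each per block);
two-choice equal majority counts; interference each color × congruency
cell equally frequent with odd positions using red/green and even
positions orange/blue; task switching each task × stimulus equally
frequent — and indivisible counts raise a design error.  The practice
block is balanced as evenly as its length allows (its cells need not
divide 20).

Ground truth is parameterized per (stimulus type × sequence) cell,
mirroring the estimation granularity; block-initial and target-absent
trials (undefined sequence) fall back to the alternation cell.  The
default conditions are a base process a = 1.5, v = 3.0, t₀ = 0.33 s,
w = 0.5, σ_v = 1.0, σ_w = 0.10, σ_t₀ = 0.08 — magnitudes typical of
fitted values in these paradigms, yielding ~95% accuracy and ~550 ms mean
RTs — with a repetition advantage of Δv = 0.5 and Δt₀ = 30 ms, the
two loci where sequential effects consistently appear.  Contaminants:
2% fast guesses (uniform RT between 100 ms and the paradigm cutoff,
random response) and 1% slow lapses (uniform RT in (3000, 6000] ms),
invented to exercise the filters and flagged as such in the ground-truth
record.

What the generator does *not* emulate: practice/fatigue drifts within a
session, higher-order (n − 2) sequence effects, response-key
counterbalancing, between-participant parameter heterogeneity beyond the
cell structure, and any attempt to match a particular empirical dataset's
values.  Passing tests therefore demonstrate that the machinery recovers
known structure of this generative family, not that any specific
empirical claim holds.

## Problem sizes and tolerances in the tests

The test-suite and acceptance-script problem sizes are deliberate
choices: ex-Gaussian recovery at n = 5000 (±3 bootstrap SEs) and RMSE
shrinkage over 100 seeds; four-parameter diffusion recovery at n = 2000
(±3 observed-information SEs); seven-parameter recovery once at n = 600
with loose bounds (variabilities are weakly identified there); the EZ
round-trip grid at 50 points to 1e−4; goodness-of-fit calibration with
30 replicates of 8 synthetic participants (rejection ≤ 10% at α = .05);
and the null-sequential-effect check with 24 replicates of 6 participants
under a sign test.  The acceptance script runs the full 10 × 122 design
with 8 participants and a 1 ms simulator step.

## Known limitations

- The constant-drift models (EZ, four-parameter) absorb generator drift
  variability into a and v; the acceptance script's EZ sequential drift
  effect (~0.3 at a generated Δv = 0.5) shows that attenuation.
- Maximum likelihood for diffusion models is fragile at ceiling accuracy
  (few or no errors); the package warns and refuses only the clearly
  unidentifiable cases.
- The adaptive lower-cutoff rule is a point-estimate criterion and is
  noisy for small samples (see above).
- No hierarchical/Bayesian estimation, no collapsing bounds, no
  across-trial variability in a, no model-selection penalties.
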