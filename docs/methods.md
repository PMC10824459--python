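# Methods

## The task

The probabilistic decision-making (PDM) task presents two options whose
reward probabilities are complementary (`p_obj_left + p_obj_right = 1`)
and whose rewards are misaligned: the more probable option always pays
strictly less. On half of the trials a mask hides a fraction
`p_a ∈ {0.4, 0.5, 0.6, 0.7, 0.8}` of the probability display, so the
decision maker sees only the visible fractions `p_obs` (summing to
`1 − p_a`); on the other half `p_a = 0` and the display is complete.
Feedback is a Bernoulli draw in the *objective* probability of the
chosen option — the masked division is real, just not visible.

The generator leaves two quantities open that the task description does
not fix, and resolves them as follows:

- `p_obj_left` is uniform on [0.15, 0.85] excluding ±0.02 around 0.5,
  so the "more probable option" is always well defined;
- rewards are integers summing to a configurable total (default 100),
  the larger one on the less probable side;
- the mask split is uniform over the positions that keep both visible
  fractions non-negative *and* preserve the visible ranking, so the
  visible and objective rankings always agree and feedback can use the
  true `p_obj`.

Session templates mirror the three study designs: 40 trials in 5-trial
blocks (scanner), 240 trials in 10-trial blocks as six 40-trial runs
with parietal (ips/ppc) or vertex stimulation labels (TMS), and 150
trials with an independent-lottery display (replication; presentation
metadata only).

## The model

On each trial the agent assigns a fraction of the hidden mass back to
the options and renormalises:

    P_as,l = p_a · τ_b · τ_i        P_as,r = p_a · (1 − τ_b) · τ_i
    P_all,l = (p_obs,l + P_as,l) / (p_obs,l + P_as,l + p_obs,r + P_as,r)

`τ_i` is the fraction of the hidden mass incorporated (0 = ignore it,
1 = objective incorporation, >1 = overestimate the uncertainty) and
`τ_b` the laterality bias of the split (0.5 = none). The terms entering
the normalisation are the *visible* fractions: using the objective
probabilities there would double-count mass that is already fully
accounted for, and with `τ_i = 1, τ_b = 0.5` the visible reading gives
the clean objective-uncertainty reduction `P_all = p_obs + p_a/2`.

Valuation is prospect-theoretic: `v(x) = x^α`, probability weighting
`π(p) = p^γ / (p^γ + (1−p)^γ)^{1/γ}` (inverse-S; identity at γ = 1;
known to lose monotonicity below roughly γ = 0.28, far outside the
fitted range), decision variable `U = v(x_l)π(P_all,l) −
v(x_r)π(P_all,r)`, and a logistic choice rule `θ = 1/(1 +
e^{−β₁(U−β₀)})` for choosing left. Choices are Bernoulli(θ); θ is
clamped to `[1e−12, 1 − 1e−12]` so log-likelihoods stay finite.

Model variants:

- **reward bias (`W_r`)** — on ambiguous trials the exponent of the
  (weakly) larger reward becomes `α + W_r`;
- **trial dependence** — the effective ratio on trial *t* is
  `τ_eff = max(0, τ_i + β_ppe·ppe(t−1) + β_val·win(t−1))` within a
  block, where `ppe = |win − P_all(chosen)|` is the unsigned
  probability prediction error of the previous trial (evaluated at that
  trial's own effective ratio) and valency is coded win = 1 / loss = 0.
  The additive-with-clamp form is a convention; the coupling's
  functional form is not uniquely determined by its verbal description;
- **discount comparator** — the ambiguity-aversion family in which each
  side receives `p_obs + (p_a/2)(1 − β_amb)`, renormalised; it nests
  the τ_i = 1 (β_amb = 0) and τ_i = 0 (β_amb = 1) allocations. β_amb
  is capped at 1 so probability masses stay non-negative;
- **TMS condition effects** — group-level additive shifts of selected
  parameters on parietal-stimulation trials (vertex = reference),
  optionally separate for the two parietal sites. Group-level (rather
  than per-subject) shifts are the implemented reading of the
  stimulation analysis;
- **null** — τ_i pinned at 0 (hidden mass ignored).

The reward prediction error is defined as `|obtained reward −
P_all(chosen)·reward(chosen)|`, i.e. deviation from the expected reward
of the chosen option (a convention; the verbal definition fixes only
"unsigned error of the obtained amount").

## Hierarchical estimation

Participant-level parameters are drawn from group distributions:
zero-truncated normals for α, γ, τ_i; plain normals for β₀, β₁, W_r,
the couplings and β_amb; a mean/dispersion Beta for τ_b. Hyperpriors:
uniform (0.01, 100) on positive-parameter means, uniform (0.001, 100)
on all group sds and on the τ_b dispersion, normal(0, 100) on
unconstrained means, Beta(1, 1) on the τ_b mean, and normal(0, 100) on
condition shifts. Disabled parameters are pinned at neutral values
(τ_b = 0.5, W_r = 0, couplings 0); τ_b is pinned in the winning
τ_i-only variant.

The sampler is an adaptive Metropolis-within-Gibbs kernel. Per sweep:

1. one Gaussian random-walk update per subject-level parameter,
   vectorised across subjects (valid because subjects are conditionally
   independent given the group level), with per-subject proposal scales
   adapted toward 0.44 acceptance during burn-in only;
2. one joint update of each subject's full parameter vector with a
   per-subject covariance learned during burn-in (Haario-style), run in
   transformed coordinates — log for α and γ, asinh for β₁/τ_i/W_r,
   logit for τ_b — where the posterior's scale ridges (e.g. the
   `β₁ · x^α` trade-off) are close to linear; the Jacobian of the
   back-transform enters the acceptance ratio;
3. Metropolis updates of the group-level hyperparameters given the
   subject values (repeated a few times per sweep; they cost no
   likelihood evaluations);
4. scalar Metropolis updates of any TMS condition shifts against the
   full-data likelihood.

Support guards far outside plausible posterior mass (e.g. α ≤ 120)
keep `x^α` finite; states that still overflow get −∞ likelihood and are
rejected.

The default protocol follows the study's convention: 3 chains with
distinct seeds, ≥10,000 burn-in iterations, 10,000 further iterations
thinned by 10 (3,000 retained draws), a Gelman–Rubin gate at R̂ ≤ 1.05
on the group-level scalars with up to three automatic burn-in doublings
before an explicit failure. The classic between/within form of R̂ is
used, floored at 1. The convergence gate is evaluated on the group-level
scalars (the reported quantities); per-subject draws are stored and
summarised but not gated, since subject-level R̂ at small cohort sizes
is dominated by Monte-Carlo noise.

Posterior summaries: the 95% HDI is the shortest contiguous interval of
the pooled post-thinning draws; `p_MCMC` is the two-sided tail
probability `2·min(Pr(x > ref), Pr(x < ref))`, floored at 1/n draws
(reported values such as 0.001 ≈ 3/3000 are consistent with this
reading) and capped at 1.

## Model comparison

DIC uses the classic plug-in form `DIC = D̄ + p_D`,
`p_D = D̄ − D(θ̄)` with θ̄ the posterior-mean parameters; which p_D
variant the original Gibbs-sampler workflow reported is not stated, so
absolute DIC values should be compared qualitatively. LOOIC is
`−2·elpd` from Pareto-smoothed importance sampling over *per-trial*
log-likelihood draws (the trial is the unit because the likelihood is
Bernoulli at trial level); points with Pareto tail-shape k above 0.7
(configurable) are flagged. Ties in the comparison table rank the model
with fewer free parameters first.

## Synthetic cohorts and calibration

`CohortSpec` mirrors the estimation hierarchy generatively: positive
parameters are zero-truncated normal draws, τ_b a Beta with the
requested mean and sd, the rest plain normals. Demo defaults are
α = 0.9, β₁ = 5, β₀ = 0, γ = 0.8, τ_i = 1.8, τ_b = 0.5.

Those demo values produce nearly deterministic choices (|β₁·U| ≈ 25),
which is useful for illustrating the model but leaves β₁ and α poorly
identified on the resulting separable data. The simulation *studies*
(recovery, model comparison, TMS-shift calibration) therefore use a
study-calibrated set — α = 0.22, β₁ = 1.8, others as above — chosen
once so that a τ_i = 1.8 cohort reproduces the observed group choice
rates of the original sample (≈0.65 without ambiguity, ≈0.51 with).
This mirrors the original recovery design, which fixed all other
parameters at the real-data posterior means; those means are not
published, so matching observed behaviour is the closest available
stand-in.

The recovery study follows that design exactly: all parameters fixed at
the calibrated means (no subject heterogeneity), the generative τ_i
swept over a grid. One boundary caveat is intrinsic to the model: the
group-mean prior support starts at 0.01, so a 95% HDI can never contain
a generative value of exactly 0 — the boundary level is assessed by
posterior concentration near zero instead. For large generative τ_i the
likelihood flattens (P_all saturates toward τ_b as τ_i grows), so
posterior means at the top of the grid are inflated relative to truth
while intervals still cover; this is a property of the model, not of
the sampler.

Problem sizes for the shipped tests and the acceptance script are
desk-scale choices: recovery at 12 subjects × 240 trials × 2 replicates
per grid value, model-comparison consistency at 6 × 120 × 10
replicates, TMS-shift recovery at 10 × 240 with a 12 × 240 × 10 null
calibration, all with a shortened protocol (≈800–1,500 burn-in and
retained iterations, 2 chains). The full protocol remains the library
default. Cohort sizes below roughly ten subjects are deliberately
avoided for the TMS analysis: with few subjects the weakly identified
subject-level τ_i can drift up its likelihood plateau while the
condition shift compensates downward, biasing the shift posterior.

## What the synthetic data does and does not show

The generator reproduces the task's probability/reward structure, the
masking levels, block structure, TMS labelling, and model-faithful
choice and feedback generation. It does not emulate reaction times,
attention or fatigue drifts, stimulus rendering, or any neural signal.
Passing recovery and selection tests therefore demonstrates internal
consistency of estimator and model family under the stated generative
assumptions — not that human data satisfy those assumptions.

One behavioural regularity deserves note: the mean probability
prediction error is *monotone* in the generative τ_i. Because the
allocation is a convex pull of the visible fractions toward τ_b = 0.5,
`P_all(chosen)` approaches 0.5 monotonically as τ_i grows, and
`E|win − q| = p + q(1 − 2p)` then rises toward 0.5 on whichever side is
chosen. The sweep therefore shows a steep rise up to τ_i ≈ 1 followed
by a plateau — not a strict interior peak with a decline beyond 1. This
saturation is what makes a negative feedback coupling (β_ppe < 0)
error-reducing for agents with τ_i above 1.

## Numerical notes

- Likelihood evaluation is fully vectorised over trials; the scalar
  reference implementation in `model_core` is the contract and the
  vectorised path is tested against it at 1e−9.
- Trial-dependent τ_i requires a sequential pass; it is vectorised
  across blocks and iterates only over within-block position.
- CSV I/O uses shortest round-trip float formatting and round-trip
  parsing, so write/read cycles are bit-exact.
- Degenerate inputs: a fully masked display with τ_i = 0 has no mass to
  normalise and raises; tied objective probabilities are excluded from
  rate statistics with a logged count.
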