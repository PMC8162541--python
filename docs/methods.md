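# Methods

## The diffusion substrate

A trial is a Wiener process with drift ν between absorbing boundaries 0 and
a, starting at z = a/2, diffusion scale σ = 1 (the scale convention under
which drift ≈ 2, boundary ≈ 2 and non-decision time ≈ 0.43 s are coherent
magnitudes for this task family). Inter-trial variabilities of drift, start
and non-decision time are fixed at zero: they are hard to estimate reliably
and are not needed for the stability questions the package answers. The
upper boundary codes the correct response, so no start-point bias is
meaningful and z stays at a/2 throughout.

The first-passage density is evaluated by switching between the small-time
and large-time series expansions of the standardized density, truncating
whichever series needs fewer terms for an absolute error of 1e-7. The
density is defective per boundary; the closed-form absorption probability
(1 − e^{−2νz})/(1 − e^{−2νa}) is used for boundary choice in simulation and
as an oracle in tests. Trials are simulated by inverse-CDF sampling on a
cached per-parameter-set time grid (geometric, 2048 points, horizon doubled
until the tail mass is below 1e-9); decision times are clamped at 0.1 ms.
An Euler–Maruyama path simulator (step 1e-4 s, with the
Broadie–Glasserman–Kou boundary correction 0.5826·σ·√dt) lives in the test
suite as an independent brute-force oracle and is never used by the package
itself.

Error responses carry τ⁻ = τ⁺ + c: in the emulated task the software
records only the time of the *corrected* response, so the correction time
is modelled as an additive constant inside the error non-decision time.
The default c = 0.3 s is a package choice (no canonical value exists);
it makes error RTs visibly slower, as observed in such data.

## Synthetic cohort

The generator emulates the study design the analysis chain targets: five
subgroups of sizes (113, 109, 26, 63, 58) — young/old × student/non-student,
ages Normal(21.57, 2.20²) and Normal(67.76, 5.31²) — observed at months
0, 6, 12, 24 with nested retention (369, 358, 327, 327). The published
description assigns 369 of its 382 initial participants to subgroups; the
generator uses the subgroup total as the wave-1 N. Dropout is completely at
random by default; an optional mode weights dropout toward persons with
higher ν, a and τ (the pattern reported for real droppers).

Person trajectories follow value_t = I + S·λ_t + e_t per parameter, with
the latent means/variances, slope loadings and residual variances of the
fitted longitudinal models used as generating defaults (drift: μ_I = 2.104,
σ²_I = 0.164, μ_S = 0.112, σ²_S = 0.026, λ = (0, 1, 1.142, 1.297),
ε = 0.020/0.036/0.060/0.082; boundary and non-decision time analogous with
zero slope variance). Non-decision residual variances printed as 0.000 are
realized as 1e-4 — the printed values are rounded, and exact zeros would
make all τ change deterministic. Whole-person draws violating a > 0.2 or
τ⁺ > 0.05 are redrawn. Condition effects default to Δν = ±0.2 (congruent
advantage) and Δa = ∓0.05 per block type; the magnitudes are package
choices (only the existence of such effects is established) and are
configurable.

What the generator does **not** emulate: lexical stimulus content,
sequential (trial-order) effects, slow drifts in attention, inter-trial
parameter variability, non-nested missingness. Passing tests therefore
demonstrate correctness of the estimation and analysis machinery under the
stated generative model, not robustness to every idiosyncrasy of real data.

## Preprocessing

Fixed order: non-recorded trials → RT window (keep 0.3 s ≤ RT ≤ 3.0 s,
boundaries retained — "below/above" is read strictly) → low-accuracy
participants (accuracy < Q1 − 3·IQR across participants, independently per
time point, linear-interpolation quantiles; the rule needs ≥ 4 persons) →
one warm-up trial per block. Participant accuracy for the 3-IQR rule is
computed on recorded trials *before* RT filtering (it indexes raw task
accuracy across all five trait blocks); a switch computes it after instead.
Every step logs counts by reason, and retained + excluded reconciles with
the input per step.

## Hierarchical fit

22 free person-level parameters per person: ν and a intercepts, 9 free
effect-coded condition offsets each (the 10th is the negated sum), τ⁺, τ⁻.
Person parameters are Gaussian draws from group-level distributions;
condition effects are hierarchical (group effect mean + person deviation
with one shared spread per family). Non-decision-time priors are Gaussians
restricted to [0, ∞) without renormalizing the truncated mass — at the
relevant group means (≈ 0.4 s, spread ≈ 0.1 s) the truncation factor is
numerically 1, and this keeps the joint density self-consistent between the
sampler and the verifiable `log_density` contract.

Hyperpriors (package defaults, weakly informative, all recorded in the
pipeline config): group ν mean ~ Normal(2, 3), group a mean ~ Gamma(4,
scale 0.5), group τ means ~ Normal(0.4, 0.3) truncated at 0, all spreads
half-normal (scale 1 for ν and a, 0.2 for τ, 0.5 for effect spreads),
group condition effects ~ Normal(0, 1).

The sampler is Metropolis-within-Gibbs, chosen because persons are
conditionally independent given the group level so per-person blocks can be
evaluated in a compiled sweep:

- per person, two joint random-walk updates per iteration of (ν, a, τ⁺,
  τ⁻) with a per-person covariance-adapted proposal (Haario-style,
  diminishing adaptation 1/(t+20)^0.6) — the four base parameters are the
  analysed output, so their chains get the most mixing effort — and one
  9-dimensional update per effect family;
- a joint *translation* move per effect family that shifts the group effect
  means and every person's effects by the same vector — this decorrelates
  the group means from the person random effects, which otherwise mix very
  slowly (the standard funnel);
- the same translation move for the error non-decision time (group mean
  plus all person values): with ~3% errors a person's τ⁻ is pinned to the
  group mean, and without the joint move both stall;
- conjugate Gibbs for Gaussian-prior group means and for the group effect
  means; scalar adaptive Metropolis on log-spreads and non-conjugate means.

Starting values come from an EZ-style moment inversion per person (accuracy
and correct-RT mean/variance), with τ capped at 0.9 × the person's minimum
RT so the initial likelihood is finite; trials with RT ≤ τ contribute −∞
during sampling. Chain geometry defaults to 4 chains × 6000 iterations with
1000 burn-in; seeds derive from one master seed via `SeedSequence`, so runs
are bit-reproducible. Draws are stored for the four person-level base
parameters and all group-level parameters; person-level effect deviations
are sampled but not retained (they are nuisance for the stability
analyses).

Persons with fewer than 20 retained trials are excluded from a fit with a
warning. A person with zero error trials is legal — their τ⁻ is informed by
the hierarchy alone.

## Convergence gate and posterior predictive checks

Rank-normalized split-R̂ and bulk ESS (computed by arviz; zero-variance
chains are defined as R̂ = 1 and ESS = 0) gate each person × time-point
vector: if any of ν, a, τ⁺, τ⁻ has R̂ > 1.01 or ESS < 400, all four are
dropped for that person and time point. The exclusion fraction is logged.
Posterior predictive checks resimulate each person's observed condition mix
for 500 random joint posterior draws and compare RT quartiles
(linear-interpolation quantiles, correct and error separately) and error
rates; persons with ≤ 10 observed errors are omitted from the error-RT
comparison because their empirical quantiles are too unstable.

## Stability analyses

**Rank-order.** Bayesian correlation of person medians with a uniform prior
on ρ: the posterior is computed by quadrature of the reduced likelihood
p(r | ρ, n) ∝ (1 − ρ²)^((n−1)/2) (1 − ρr)^(−(n−3/2)) on an 8001-point grid,
and BF₁₀ is the Savage–Dickey ratio 0.5 / posterior density at ρ = 0.
Pairwise-complete cases per time pair; cells with n < 3 are missing; n < 30
is flagged small-sample. Subgroup filters reproduce the per-group tables.

**Mean-level.** 95% HDIs (shortest sorted window; ties broken leftmost) of
the group-level posterior draws per wave, pairwise overlap indicators and
posterior mean differences.

**Growth curves.** The four waves' medians are multivariate normal with
mean μ_I + μ_S·λ and covariance ΛΦΛ' + diag(ε), λ = (0, 1, λ₃, λ₄) with
λ₃, λ₄ free. Estimation is conjugate Gibbs with latent (I, S) augmentation;
persons with partial waves contribute their observed margins
(full-information treatment; listwise deletion is a switch). Variance
priors are heavy-tailed inverse-gammas (shape 1, scale = pooled
variance/100) and, for the free-covariance pass, an inverse-Wishart with
df 3 — deliberately weak because the slope variance is only weakly
identified at n ≈ 300 and stronger scales were observed to dominate it.
Three chains × 16000 iterations (4000 burn-in): Gibbs draws are more
autocorrelated than gradient-based samplers, and the longer default keeps
worst-case split-R̂ at or below the 1.01 flag threshold. Two-pass fixing:
σ_IS is fixed to 0 when its 95% CI includes 0; then σ²_S is fixed when its
posterior median falls below 3% of the intercept-variance median (the
scale-relative operationalization of "estimated to be zero" — it cleanly
separates the drift configuration, ratio ≈ 0.08–0.13, from the
boundary/non-decision configurations, ≈ 0.004–0.01). With the covariance
free, the likelihood at n = 300 has a near-flat ridge trading σ²_S against
σ_IS and the first residual variance; whether the covariance rule triggers
for a drift-like configuration is therefore seed-dependent, and the package
reports whatever the rule decides. Fit indices: per posterior draw the ML
discrepancy N·F_ML of the implied moments against the complete-case sample
moments gives χ²(θ); the effective number of parameters pD (mean posterior
discrepancy minus plug-in discrepancy) is subtracted before computing
GammaHat = p/(p + 2(χ² − pD − df)/N) and CFI against the independence
baseline; posterior means are reported, clipped to [0, 1].

**Profiles.** Medians are z-standardized per parameter *within each time
point* across persons (this removes mean-level change, so q measures
relative standing; pooled standardization is exposed as an option). q is
the Pearson correlation of the two 3-element z-profiles of one person at
two waves; zero-variance profiles yield a missing q, which is counted.

**Dropout.** Two-sample JZS Bayes factor with a zero-centered Cauchy(√2/2)
prior on the standardized effect, computed by quadrature over the
g-mixture; persons missing (or non-converged) at any later wave are
compared with completers on wave-1 medians.

## Problem sizes

Defaults reproduce the full study geometry (369 persons × 600 trials × 4
waves × 4 chains × 6000 iterations). The test suite and the acceptance
script use scaled-down versions chosen so each stage still exercises its
full code path: parameter recovery with 12 persons × 300 trials and
2 chains × 2000 iterations (recovery correlations are driven by trials per
person, so the bound r ≥ 0.90 is unaffected); growth recovery at n = 300,
the size at which the published generating values were estimated; the
longitudinal signature with the full default cohort but 150 trials per
person and 2 chains × 1400 iterations, since group-mean HDIs are dominated
by the number of persons, not trials. The convergence-gate thresholds scale
with chain length in the tiny smoke configurations (a 400-ESS gate is
meaningless with 1200 retained draws) and stay at R̂ ≤ 1.01, ESS ≥ 400 for
default-geometry runs.

## Known limitations

- The sampler is random-walk based; posterior tails mix more slowly than a
  gradient sampler would, which the chain-length defaults compensate.
- Group-level condition effects are reported, but person-level effect
  deviations are not retained in the draws object.
- The growth model's free-covariance pass is weakly identified at n ≈ 300
  (see above); interpret σ_IS and σ²_S jointly, not separately.
- The q-correlation of a 3-element profile is extremely coarse; its
  across-person dispersion is large by construction.
- The generator's condition-effect magnitudes are conventions, not
  estimates; analyses that depend on them (posterior predictive checks of
  block differences) test machinery, not substantive effect sizes.
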