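# Methods

This note documents the models, the numerical machinery and the design
choices behind `confrl`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task model

The environment is a two-cue instrumental learning task. On each trial one
of two abstract cues (A, B) appears and the agent bets a high stake
(risky, ±1.0) or a low stake (safe, ±0.1). One cue is currently positive:
following it, the outcome sign is favourable with probability `p_good`
(default 0.8); for the negative cue the probabilities are reversed. The
positive role alternates between blocks (default 4 blocks of 60 trials →
exactly 3 unannounced reversals, 240 trials). Outcome *optimality* (Op) is
1 when the outcome was favourable (winning the high stake or losing only
the low one), else 0; an *optimal response* is risky on the positive cue
and safe on the negative cue.

Choices within the simulator and response omissions are idealized: every
trial receives a response (no response-window timing is modeled), and cue
order is shuffled within blocks with balanced counts per cue (a
configuration switch `balanced_cues=False` gives fully random cue draws,
since balancing in the real task cannot be verified). Each session runs on
one seeded NumPy generator; the seed is stored on the `Session`.

## Model space

Three factors define 27 models:

1. **RL variant** — reinforcer r is the signed money amount (`money`), its
   sign (`valence`), or its sign with coupled updating (`coupled`): the
   presented cue moves toward r and the other cue toward −r with the same
   rate, exploiting the task's anti-symmetry. With symmetric initialization
   (both values 0) coupled updating maintains Q_A = −Q_B exactly.
2. **Confidence signal** — none (plain RL), `abspe` (target
   `1 − |PE| / PE_max`, with PE_max = 2 the largest attainable unsigned
   prediction error given values and reinforcers bounded in [−1, 1]; the
   normalisation keeps C a dimensionless [0, 1] level across variants), or
   `optimality` (target Op ∈ {0, 1}). Op is coded {1, 0} rather than
   {1, −1} so that C remains a probability-like belief bounded in [0, 1]
   under the delta rule.
3. **Modulation** — confidence modulates α, β, or both, with one shared κ
   or separate κα/κβ.

Free parameters: α0, β0 for plain RL; plus C0 (initial confidence), γ
(confidence learning rate) and κ (or κα, κβ) for the 24 hierarchical
models. Values start at 0 for both cues and are *not* reset at reversals
(reversals are unannounced); C starts at the fitted C0 once per session.

### Modulation form

The modulation must satisfy: equal learning rates for confirmatory and
contradictory outcomes at C = 0 (αm = α0, βm = β0); αm → 1 for
confirmatory and → 0 for contradictory outcomes as confidence-weight
grows; βm decreasing in C. Two forms satisfying these limits are
implemented behind one operation (`modulate_parameters`, `form=` flag):

- **exponential** (default): w = 1 − exp(−κC)
- **linear**: w = clip(κC, 0, 1)

with αm = α0 + w(1 − α0) (confirmatory), αm = α0(1 − w) (contradictory),
βm = max(β0(1 − w), 10⁻³). The exponential form is the default because it
is smooth in the parameters everywhere. The linear clamp introduces kinks
at κC = 1 that MAP fits repeatedly land on, and there the curvature-based
evidence approximation degenerates (finite-difference second derivatives
scale as 1/h² across a kink); with the smooth form the same limits hold
asymptotically and the evidence is stable. The compiled likelihood kernels
implement both forms.

An outcome is *confirmatory* when its valence matches the sign of the
presented cue's current value; Q = 0 is classified as confirmatory for
positive outcomes — an arbitrary but fixed tie rule for a measure-zero
event. Within a trial, βm is computed from the pre-outcome confidence (it
governs the choice), αm from the same pre-outcome confidence once the
outcome's category is known; confidence is updated after learning.

## Inversion

Parameters are fit in an unconstrained space: logit for α0, γ, C0; log for
β0 and κ. Priors are independent Gaussians there with mean 0 and variance
3 — weakly informative, symmetric around α0 = C0 = γ = 0.5, β0 = κ = 1 on
the native scale, in the spirit of common variational-Laplace toolbox
defaults without copying any.

MAP estimation maximizes log-likelihood + log-prior with multi-start
L-BFGS-B (numerical 3-point gradients, ftol 10⁻⁹, gtol 10⁻⁶). Starts are
the prior mean plus the best of a screened pool of prior draws (pool size
12 × n_restarts); the leading optima are then polished with Nelder-Mead.
The polish matters: the likelihood is only piecewise smooth (the
confirmatory/contradictory classification flips discretely as a cue value
crosses zero), quasi-Newton steps stall on the piece boundaries, and the
surface for long sessions is multi-modal — a low-α0 decoy basin attracts
generic starts. Eight restarts give reliable recovery on 2,400-trial
sessions; two suffice for 240-trial sessions in model-comparison use.
Transformed parameters are clipped to ±30 inside the objective so extreme
probes cannot leave the valid native ranges.

Log model evidence uses the Laplace formula at the MAP,
`log p(y|m) ≈ log-joint + (d/2)·log 2π − ½·log det H`. For session fits H
is the **empirical information matrix**: the outer product of per-trial
choice-likelihood scores (central differences, step 10⁻³) plus the prior
precision. This needs first derivatives only and is positive definite by
construction, which the piecewise-smooth likelihood requires — full
second-difference Hessians at these optima produce spurious eigenvalues of
order 1/h². Per-trial score norms are winsorized at max(20, 10 × the 95th
percentile): a finite difference that straddles a discontinuity yields a
single spurious O(jump/step) score, while genuine one-trial Bernoulli
scores are orders of magnitude smaller. A full finite-difference Hessian
(step 10⁻⁴, eigenvalue-clipped to positive definiteness when needed)
remains available via `hessian_method="fd"` and in the generic
`laplace_log_evidence`, which is exact for conjugate-Gaussian problems; if
the curvature is unusable the fit falls back to a BIC penalty and flags
it. The Laplace-at-MAP scheme stands in for a full variational free-energy
computation; for smooth, well-peaked posteriors the difference is
second-order.

## Group-level selection

Random-effects BMS treats each subject's model identity as drawn from a
population distribution with Dirichlet prior (symmetric, 1 count per model).
The variational fixed point alternates subject-wise posterior model
assignments (softmax of log evidence + expected log frequency) with
Dirichlet count updates until the concentration changes by less than 10⁻⁶.
Exceedance probabilities are Monte-Carlo estimates (default 10⁶ Dirichlet
draws, sampled as gamma variates in chunks); the K = 2 case has an analytic
Beta-tail form used as a test oracle. Family inference aggregates evidence
within a family as the log *mean* member evidence (uniform prior mass split
across members, so duplicating a model does not inflate its family) and
runs the same machinery over families. Protected exceedance probabilities
are not computed.

## Model-free statistics

Optimal responses are collapsed across cues and averaged within six bins
of 10 consecutive trials per 60-trial block (partial final bins are
dropped with a warning). The three-way repeated-measures ANOVA
(bin × block × condition, subjects random) uses the standard
within-subject decomposition via `statsmodels.AnovaRM` — each effect
tested against its own subject-interaction error term, no sphericity
correction. The last-bin drug contrast is a paired t between conditions
with the final bin collapsed (averaged) over blocks — consistent with a
drug effect that shows no block interaction — reported both as t and as
F = t²; each condition's last-bin mean is additionally tested against the
probability-matching benchmark 100·p_good with a one-sample t.

## Synthetic cohorts

A cohort draws per-subject parameters from Gaussians in transformed space,
shares them across the two conditions of a crossover (unless
`crossover=False`), multiplies κ by (1 − `ketamine_effect`) in the
ketamine condition (default effect 0.5), and simulates one session per
subject × condition. Ground truth is returned alongside the sessions;
`recovery_report` scores fits for per-parameter bias, RMSE and
truth-estimate correlation and runs the paired κ contrast.

Default population values (transformed means α0: 0.4, β0: 1.0, C0: −1.4,
γ: −0.4, κ: 1.2; all SDs 0.3) are a calibration, not estimates: they
produce noisy, exploratory behavior early in blocks and strong exploitation
late (placebo last-bin optimal responding in the low 90s percent, reduced
toward the matching level when κ is halved), a regime in which the
generating model is identifiable from single 240-trial sessions. Regimes
with weaker confidence grip (last bin closer to 85%) blur the behavioral
signatures that separate the modulation targets, and group-level selection
then cannot single out the generating model from 21 × 240-trial cohorts;
identifiability was given precedence when fixing defaults.

What the generator does *not* emulate: response omissions and timing,
motor/key-press counterbalancing, payout bookkeeping, session-order or
practice effects, any drug effect other than the κ reduction, and any
misspecification of the learner itself (real subjects need not belong to
the model space). Passing recovery tests therefore demonstrate internal
consistency of the pipeline under its own assumptions, not validity for
real data.

## Problem sizes used by the checks

The end-to-end checks run at sizes chosen for a single CPU: parameter
recovery uses 50 replicates of one 2,400-trial agent (40 blocks); model
recovery one 21-subject cohort of 240-trial sessions fit by all 27 models
at 2 restarts; the drug-effect power check three 12-subject cohorts; the
type-I calibration 200 null cohorts of 8 subjects with single-start fits
(the paired-t rejection rate depends on the null being exchangeable across
conditions, not on per-fit polish). The Monte-Carlo error of exceedance
probabilities at the default 10⁶ draws is below 10⁻³.

## Known limitations

- The evidence approximation is local (Laplace at the MAP with an
  outer-product curvature); models whose posteriors are strongly
  multi-modal or ridge-like within a session are scored by the dominant
  mode only.
- κ is weakly identified when sessions are short and confidence saturates
  (w → 1 early): C0 in particular recovers poorly from single sessions.
- The ANOVA requires a complete balanced design by construction; missing
  cells must be handled upstream.
- The trial-loop kernels are compiled with numba; the first call in a
  fresh environment pays a one-time compilation cost.
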