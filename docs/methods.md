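# Methods

This note documents the scientific and numerical choices behind `piddm`: the
task, the model, the estimation machinery, and the statistics, together with
the defaults and units used throughout.

## The recent-probes task and proactive interference

Each trial of the recent-probes task presents a *target set* of four lowercase
consonants, then after a delay a single *probe* letter; the participant judges
whether the probe is in the current target set. Probes come in three kinds:

- **positive** — in the current target set (50% of trials);
- **recent negative** — not in the current set, but present in the
  immediately preceding trial's set (25%);
- **non-recent negative** — absent from the current set and from the two
  preceding sets (25%).

Recent negatives feel familiar even though the correct answer is "no"; the
slowing and extra errors they cause relative to non-recent negatives is the
behavioral signature of **proactive interference (PI)**. A session is three
blocks of 160 trials (480 trials; 240/120/120 by condition). The generator
(`piddm.task.generate_session`) draws sequences that satisfy the recency
constraints exactly; `validate_sequence` re-audits any sequence independently
of how it was produced. The first two trials of a session cannot be recent
negatives (no look-back exists) and are restricted to the other conditions.

Because the original behavioral data are not publicly available, cohorts are
*synthesized*: participant-level parameters are drawn around the published
group means for young (n = 25) and older (n = 38) adults, with
between-subject SDs reconstructed as SE·√n from the printed standard errors,
and driven through the trial simulator.

## The diffusion decision model

A decision is modeled as a Wiener process with drift `v` between absorbing
boundaries at 0 and `a`, starting at `z`, plus a nondecision time `ter`
(seconds). Across trials the drift is Normal(v, η), the start
Uniform(z ± sz/2) and the nondecision time Uniform(ter ± st/2). The diffusion
constant is fixed at `s = 0.1` (the conventional scaling), so `v`, `a`, `z`,
`sz` and η are in those evidence units and all times are in seconds.

Six nested variants are compared, differing in which parameters may vary over
the three probe conditions:

| model | per-condition | starting point | free parameters |
|---|---|---|---|
| 1 | v, η | z = a/2 | 10 |
| 2 | v, η, a, sz | z = a/2 | 14 |
| 3 | v, η, a, sz, ter, st | z = a/2 | 18 |
| 4 | v, η | z estimated, shared | 11 |
| 5 | v, η, a, sz | z estimated, shared | 15 |
| 6 | v, η, a, sz, ter, st | z estimated, shared | 19 |

Unbiased models use *accuracy coding* (upper boundary = correct response).
The biased models use *stimulus coding* (upper boundary = "positive"
response; negative-probe trials drift at −v in that frame), since a start
bias toward one response is only meaningful in the stimulus frame.

## Likelihood evaluation

The first-passage-time density of the Wiener process is evaluated with the
classical pair of series expansions (one converging quickly at small
normalized times, one at large), switching adaptively to whichever needs
fewer terms for a truncation error below 1e−10.

Gaussian drift variability is integrated **analytically** (the Normal mixture
of exponentials has a closed form), so only the two uniform variabilities
need numerical quadrature: `sz` and `st` are integrated with fixed-order
Gauss–Legendre rules, 11 nodes each by default. Against an adaptive
quadrature oracle the 11-node rule is exact to near machine precision at
these parameter scales; 5- and 7-node rules carry total log-likelihood errors
of roughly 5e−3 and 2e−4 on a 480-trial dataset, which motivates the
coarse-to-fine scheme below. Per-trial densities are floored at 1e−10 inside
the log-likelihood so a single outlying trial cannot drive the objective to
−∞. Trials with RT < 0.200 s or > 7.000 s are excluded before fitting.

## Maximum-likelihood fitting

Each participant × model fit is a Nelder–Mead simplex search over an
unconstrained reparameterization (log scales for `a` and `ter`; scaled
logistic maps keeping η ≤ 0.5, the starting-point range strictly inside the
boundaries, and st ≤ 2·ter), so no proposal can violate the parameter
invariants. Starting values come from EZ-style closed-form moment equations
(accuracy and correct-RT mean/variance per condition), with accuracy clamped
to 1 − 1/(2n) for perfect cells; additional restarts jitter this start.

Each restart runs **coarse-to-fine**: an exploratory simplex search using
5-node quadrature, then up to three polishing rounds at 7 nodes from fresh,
progressively smaller initial simplexes (steps 0.03 / 0.01 / 0.005 in the
unconstrained space), stopping when the simplex converges (log-likelihood
tolerance 1e−6) or successive rounds improve by less than 1e−4 — far below
the ~0.5 log-likelihood change that one standard error in any parameter
produces. The reported log-likelihood and BIC are then evaluated at the full
11-node resolution. The iteration cap is 400·dim per coarse stage and
200·dim per polishing round; the simple 200·dim single-stage budget proved
insufficient for reliable convergence in the 14–19-dimensional variants,
which is why the staged scheme (with a larger coarse budget) is used.

Model selection uses BIC = −2·lnL + k·ln n per participant (n = trials used,
k = free parameters); exact ties break toward fewer parameters. The cohort
ranking counts winners per model.

## Monte-Carlo simulator

The simulator draws the trial-level variabilities explicitly and runs
Euler–Maruyama with step dt = 1e−4 s until absorption (cap 10 s; unabsorbed
trials are redrawn, with a warning above a 0.1% redraw rate). It is the
data-generating engine for synthetic cohorts and the ground-truth oracle in
the density tests: at these parameter scales the discretization error is far
below Monte-Carlo resolution at the sample sizes used.

## Group statistics

Behavior is summarized per participant × condition as mean correct RT and
error rate. The inferential layer mirrors the study design:

- mixed-design ANOVA (condition within, age group between) on error rates,
  mean correct RTs, and fitted drift rates, with classical uncorrected
  degrees of freedom (Greenhouse–Geisser ε reported alongside);
- planned PI contrasts: the recent-minus-non-recent difference tested against
  zero (one-sample t) and between groups (pooled two-sample t, reported also
  as F = t² with 1 numerator df);
- pooled-variance independent t-tests (df = n₁ + n₂ − 2; 61 at the study's
  25/38 split) on boundary separation and nondecision time.

The ANOVA implementation is validated against an independent sums-of-squares
oracle to 1e−8 in the test suite.

## Quantile-probability summaries

Model fit is displayed as quantile-probability panels: response proportion on
the x-axis against the 0.1/0.3/0.5/0.7/0.9 RT quantiles, observed (crosses)
vs predicted (circles), per condition and group. Empirical quantiles use the
type-7 linear-interpolation convention; predicted quantiles invert the
defective CDF per response. Cells with fewer than 5 RTs, or predicted
response probability below 1e−3, are flagged unreliable and drawn as gaps
rather than fabricated values. Predictions are computed per participant and
then averaged.

## Test and acceptance harness sizes

The acceptance suite keeps the expensive fixtures small enough for a
CPU-minutes budget while preserving each check's logic: parameter recovery
uses 6 + 6 participants at the exact group means (zero between-subject SD,
one 480-trial session each); the null PI×Age check uses ten replicate 2 + 2
cohorts generated with identical PI-in-drift in both groups; model recovery
uses three Model-1 participants fitted by all six variants. Full-scale runs
(25 + 38 participants, all models, five restarts) go through
`piddm.run_pipeline` and take hours, not minutes.

## Limitations

- The original human dataset is unavailable, so published F statistics,
  Bayes factors, and behavioral means are targets of *qualitative*
  reproduction only; quantitative acceptance rests on design exactness,
  parameter recovery against the printed estimates, and property checks.
- η, sz and st are weakly identified at 480 trials per participant; they are
  bounded (η ≤ 0.5) and recovered only loosely, as expected.
- The Bayesian ANOVA variant (default-prior Bayes factors) is out of scope;
  BIC-based selection is the implemented criterion.
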