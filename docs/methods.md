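# Methods

## Depletion functional response

The core observation model treats each single-prey trial as a binomial
draw: every one of the `N0` prey is consumed independently with
probability `p(N0) = Ne(a, h, T, N0) / N0`, where `Ne` is the root of the
random predator equation `Ne = N0 (1 - exp(a (Ne h - T)))`. This
likelihood respects the non-replacement design (consumption bounded by
`N0`, proportional mortality declining with density under handling
limitation) and is the standard choice for depletion experiments.

The implicit equation is solved in closed form through the principal
branch of the Lambert W function, evaluated as the Wright omega function
`omega(y) = W(e^y)` on `y = log(a h N0) - a(T - h N0)` so that large
`a h N0` cannot overflow the exponential. Edge cases use their analytic
limits: `a = 0` or `N0 = 0` gives zero consumption; `h = 0` gives pure
exponential depletion `N0 (1 - e^{-aT})`. A pure-Python bisection solver
on the implicit equation (tolerance 1e-12) is kept alongside as an
independent cross-check; a naive fixed-point iteration of the equation is
not usable as an oracle because the map's derivative at the root,
`a h (N0 - Ne)`, exceeds 1 for typical study-scale parameters and the
iteration diverges.

**Units.** Time is measured in experimental periods: `T = 1` is one
trial (the 6-h feeding window) and `h` is the fraction of a trial spent
per prey item, so `1/h` is prey per trial and the attack rate is per unit
prey density per trial. Absolute FRR values depend on this convention;
FRR *ratios* (and hence BR and RBR) do not.

**Estimation.** The binomial log-likelihood is maximised over
`(log a, log h)`, which enforces positivity without constraints. The
likelihood depends on density only through `N0`, so per-density
sufficient statistics (total offered, total eaten) make each objective
evaluation O(number of density levels). The default fit uses a
moment-style warm start (overall proportion eaten for `a`, the
high-density plateau for `h`) plus a 3x2 grid of dispersed starts,
Nelder-Mead on each, and a BFGS polish of the best point (objective
tolerance 1e-8). Success probabilities are clamped to
`[1e-9, 1 - 1e-9]`. Standard errors come from the inverse numerical
Hessian on the log scale, delta-method transformed; p-values are Wald
z-tests of the natural-scale estimates. All-zero consumption is reported
as a boundary error (`a -> 0`) rather than a fit.

**Bootstrap.** Non-parametric, stratified by density level so every
resample preserves the experimental design; each resample is refit from
the full-data optimum (single warm start — the optimum of a resample of
the same design is reliably in its basin). Percentile intervals are used
for `a`, `h`, FRR and per-density predictions: simple, deterministic
given a seed, and adequate at these sample sizes. Failed refits are
dropped and counted; more than 50% failures aborts with diagnostics.
Defaults: 2000 resamples, 95% intervals.

**Type classification.** A binomial GLM (logit link) of proportion
consumed on density (statsmodels). The sequencing fits the quadratic
model first and falls back to the linear model when the quadratic term is
not significant at 0.05; a significantly negative linear term then
indicates type II, while a significantly positive linear plus
significantly negative quadratic term indicates type III. Everything
else is reported as inconclusive — type I is never inferred from
curvature alone. On simulated type II data the quadratic term reaches
significance in roughly a fifth of experiments (depletion makes
proportional mortality genuinely convex in density), in which case the
sequenced protocol reports "inconclusive"; the linear-model term itself
is significantly negative in >95% of experiments, so power statements
about type II detection are made on the linear term.

## Trial simulator

Event-driven pure-death process with instantaneous kill rate
`a N / (1 + a h N)` on the current prey count; waiting times are
exponential and the trial stops at `T` or when the arena is empty. The
deterministic integral of this rate over a trial is exactly the random
predator equation, so the fitter is correctly specified on simulated
data. The stochastic mean sits slightly below the deterministic root
(the rate is concave in `N`, so demographic noise slows mean depletion);
at study-scale parameters the gap is within Monte-Carlo error of ~1 SE at
10,000 replicates. The two-prey variant uses competing event rates
`a_j N_j / (1 + Σ_k a_k h_k N_k)` with a shared handling denominator.

Default design mirrors the study: densities {2, 4, 7, 10, 15} with 5
replicates per predator-prey group; availability ratios
{2:18, 5:15, 10:10, 15:5, 18:2} (total 20) with 3 replicates; one
predator-free control per treatment, which by construction records zero
deaths. Default generating parameters are the study-scale (a, h)
estimates for the three copepod predators on the two mosquito prey.
Batch operations spawn per-trial seeds from the master seed via
`numpy.random.SeedSequence`, so datasets are reproducible from one
integer.

What the simulator does *not* emulate: predator individual variation
(each trial draws from the same kinetics), arena heterogeneity,
settling/acclimation effects, partial consumption, and any behavioural
switching mechanism — preference in the two-prey simulator is purely the
attack-rate ratio. Passing recovery tests therefore show the estimators
work when the depletion model is true, not that real arenas satisfy it.

## Preference

Manly's non-replacement index per trial, with analytic limits for
complete depletion: if exactly one prey type is wiped out the index is
pinned at that type's extreme (1 for the invader, 0 for the native); if
both are wiped out, kills are replaced by `n0 - 0.5` for both types
(half-count continuity correction). Zero-consumption trials are excluded
and logged. Per-availability summaries are the arithmetic mean ± SE of
per-trial raw indices (SE 0 by convention for a single trial); the
overall mean preference is the *unweighted* mean of per-availability
means, so each offered ratio contributes equally. The extreme-value
transformation uses the number of valid trials per predator as `n`.

At arena-scale counts the trial-level index is a biased estimator: with
few individuals of the rare type, the index has probability mass at
exactly 0 (no kills of that type) or 1 (type wiped out), which drags
per-availability means towards whichever type dominates the arena. This
is an estimator property, not prey switching; simulations with fixed
kinetics at 10x counts show flat preference across availabilities at
`a_i/(a_i + a_n)`. Reported preference tables at small counts should be
read with this in mind.

Inference against neutrality uses a percentile bootstrap of the mean
transformed index per predator (resampling trials with replacement;
default 2000 resamples): a predator is flagged as preferring the invader
when the whole CI clears 0.5. Fewer than two valid trials yields an
inconclusive result rather than an error.

## Biotic resistance

`BR = (FRR_i / FRR_n) x FE x mean_alpha` per predator, with the raw
(untransformed) overall mean preference and a literature fecundity proxy
FE (clutch weight per female body weight per day) supplied as
configuration — the package does not compute fecundity. Pairwise
`RBR = BR1 / BR2` over lexicographically ordered predator pairs.

**Rounding convention.** All computation is at full precision and report
tables are rounded to 3 decimals at write-out. The one exception is
pairwise RBR: published summary tables quote BR at fixed precision and
form RBR as the ratio of the quoted scores, and at three predators this
visibly changes one entry (0.364289/0.146669 = 2.484 at full precision
vs 0.364/0.147 = 2.476 as quoted). `compute_br` therefore defaults to
ratios of 3-dp-rounded BR scores (`report_decimals=None` restores full
precision). Antisymmetry `RBR(p,q) RBR(q,p) = 1` holds either way, and
rescaling all fecundities cancels exactly in full-precision RBR (and to
rounding error otherwise).

Triplot output is one record per predator — relative FRR, FE, mean
preference, BR and rank (BR descending, label-order tie-break) — plus an
optional matplotlib scatter (relative FRR vs FE, marker size by
preference, colour by BR).

## Pipeline

Control validation precedes analysis: any death in a predator-free
control breaks the attribution of deaths to predation and blocks the run
(overridable). Stage errors abort before any file is written, so output
directories are never left partially populated. All stochastic stages
(bootstraps) derive their seeds from the single configured master seed;
identical config and input files produce byte-identical outputs. The
run log records package version, seeds, bootstrap settings and
validation outcomes.

## Problem sizes in validation

Recovery and coverage statements use 100 simulated experiments under the
five-density design (25 trials each) with 500 bootstrap resamples per
experiment, chosen to estimate rates to a few percent; solver checks use
1,000 random parameter draws; selectivity neutrality uses 10,000
simulated two-prey trials. Under these conditions the median fitted
attack rate sits a little below truth (about 15-20% at a = 2.5) — a
known small-sample behaviour of depletion-model MLEs under this design —
while median handling time is within a few percent, bootstrap interval
coverage is near but slightly under nominal, and the type II linear
signature is detected in >95% of experiments.

## Known limitations

- The binomial observation model ignores overdispersion between
  replicates (predator individual variation); intervals can undercover
  on real data.
- Parameter uncertainty is not propagated into BR/RBR, which are point
  scores; FE enters as a fixed constant with no error.
- The Manly index small-count bias above affects any arena-scale design
  with extreme availability ratios.
- Absolute attack rates and FRRs are tied to the trial-period time unit;
  only ratios are unit-free.
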