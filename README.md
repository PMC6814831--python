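# bioticres

Quantifying **biotic resistance** — the capacity of resident natural
enemies to suppress an invading prey species — from laboratory predation
trials. The package targets quantitative ecologists and invasion
biologists working with prey-depletion experiments (a predator feeding in
a closed arena without prey replacement), such as cyclopoid copepods
preying on invasive *Aedes albopictus* and native *Culex pipiens* mosquito
larvae.

## The models

**Functional response.** Per-capita consumption over a trial of duration
*T* starting from *N₀* prey follows Rogers' random predator equation,
which accounts for depletion of prey during the trial:

    Nₑ = N₀ (1 − exp(a (Nₑ h − T)))

with attack rate *a* and handling time *h*. The implicit equation is
solved explicitly with the Lambert W function,

    Nₑ = N₀ − W(a h N₀ e^{−a(T − h N₀)}) / (a h),

and (*a*, *h*) are estimated by maximum likelihood under a per-trial
binomial observation model, with density-stratified non-parametric
bootstrap (default n = 2000) for 95% confidence intervals. Response type
(II vs III) is classified from a logistic regression of the proportion
consumed against density. Two derived per-capita impact summaries:
maximum feeding rate 1/*h* and the **functional response ratio**
FRR = *a*/*h*.

**Prey preference.** Two-prey trials are summarised with Manly's
selectivity index adjusted for non-replacement,

    αᵢ = ln((nᵢ₀ − rᵢ)/nᵢ₀) / Σⱼ ln((nⱼ₀ − rⱼ)/nⱼ₀),

where 0.5 is neutral and values above 0.5 indicate preference for the
invader; indices are pulled off the {0, 1} boundary with
αₜ = (αᵢ(n−1) + 0.5)/n before inference.

**Biotic resistance.** Per-capita skew, population response and
selectivity multiply into a single score per predator,

    BR = (FRRᵢ / FRRₙ) × FE × ᾱᵢ,

where FE is a literature fecundity proxy (clutch weight per female body
weight per day) standing in for the numerical response, and predators are
compared pairwise through RBR = BR₁/BR₂ (1 = equivalent, >1 = predator 1
resists more strongly).

An event-driven trial simulator (instantaneous kill rate
*aN*/(1 + *ahN*), whose deterministic limit is exactly Rogers' equation,
plus a competing-risks two-prey variant) generates synthetic studies with
known ground truth for power analysis and estimator validation.

## Worked example

```python
from bioticres import RogersModel, generate_study_dataset

fr, sw, truth = generate_study_dataset(seed=7)   # synthetic copepod study
grp = fr[(fr.predator == "M. viridis") & (fr.prey == "A. albopictus")
         & (fr.is_control == 0)]
res = RogersModel.from_dataframe(grp).fit()
print(res.summary())
```

```
Random predator equation (prey depletion, binomial MLE)
  trials: 25   duration T: 1.0
  log-likelihood: -37.8467   converged: True
  attack rate a    :     2.2936  (SE 0.8340, p 0.00596)
  handling time h  :     0.1343  (SE 0.0310, p 1.503e-05)
  max feeding rate :     7.4465  (1/h)
  FRR (a/h)        :    17.0792
```

The simulated group was generated with a = 2.549, h = 0.122: both
estimates sit within one standard error of truth. Bootstrap intervals
come from `res.bootstrap(n_boot=2000, seed=7)` — here the attack-rate 95%
CI is (1.216, 6.177) and the handling-time CI (0.077, 0.200); per-density
prediction bands are in `.band_frame()`. `attack rate` is the search
efficiency at low prey density (per unit density per trial period);
`handling time` is the fraction of the trial spent per prey item, so its
reciprocal 7.45 prey/period is the feeding ceiling, and the FRR of 17.1
combines both into one per-capita impact number.

The same workflow from the shell:

```sh
bioticres simulate --seed 7 --out-dir study/
bioticres run study/fr_trials.csv study/switch_trials.csv \
    --seed 7 --out-dir reports/
```

which writes per-group fits (`fits.csv`), bootstrap bands, per-availability
preference tables, BR/RBR comparisons (`resistance.csv`) and
triplot-ready coordinates. A metrics-only mode
(`bioticres resistance --params ... --preference ...`) computes 1/h, FRR,
BR and RBR directly from parameter tables without raw trials.

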