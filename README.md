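# cofeed

Bayesian analysis of group-level **cofeeding tolerance** — the willingness
of group-living animals to forage in close proximity around a valued
resource — from scan samples taken during experimental feeding sessions.
The package was built for longitudinal group-cofeeding assays in
chimpanzees (several groups followed over several years, each group-year
contributing repeated ~2-minute sessions at a depleting food patch), but
the models apply to any design of that shape.

It is aimed at behavioral ecologists and comparative psychologists who run
group tolerance assays and want estimates that correct for within-session
resource depletion, plus the downstream analyses those estimates feed:
demographic correlates, variance decomposition, counterfactual prediction,
and a dyadic network model.

## The model

During a session, the count of individuals inside the food zone at scan
*j* is modeled as

    k_j ~ Binomial(n_at_risk, θ[g, y] · r_j)
    r_1 = 1,  r_{j+1} = r_j · exp(−κ · k_j / n_at_risk)

where **θ[g, y]** is the *maximal (initial) cofeeding tolerance* of group
*g* in year *y* — the zone-occupancy probability before any food has been
consumed — and κ is the per-capita depletion rate (constant-resource
"juice pipe" sessions fix r ≡ 1). On the logit scale,

    logit θ[g, y] = α + u_g + X[g, y]·β(_g) + v_{g, y}

with group effects u_g ~ N(0, σ_g), group-year effects v ~ N(0, σ_gy), and
optional standardized demographic covariates (fraction of infants < 3,
fraction of females 5–12, group size, fraction with co-resident maternal
kin) whose coefficients are either shared across groups ("between-group
effects") or group-specific random vectors ("within-group effects").
A symmetric social relations model handles identity-resolved scans:
individual effects for food-zone presence and multi-membership dyad
effects for coresidence. Details in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a study with known truth and fit the tolerance model:

```python
import numpy as np
from cofeed import (CofeedingToleranceModel, SimConfig, SamplerSettings,
                    ToleranceModelSpec, simulate_study)

cfg = SimConfig(seed=11)                # 4 groups x 8 years, 6 sessions each
dem, cov, sessions, truth = simulate_study(cfg)

spec = ToleranceModelSpec(sampler=SamplerSettings(warmup=1200, steps=800, seed=2))
res = CofeedingToleranceModel(sessions, spec=spec).fit()

print(res.summary().head(3).round(3))
print("kappa:", res.kappa.mean().round(3), " truth:", cfg.kappa)
```

```
  group  year  median  lower  upper  level
0    g1  2011   0.596  0.557  0.634    0.9
1    g1  2012   0.537  0.499  0.576    0.9
2    g1  2013   0.507  0.468  0.550    0.9
```

```
kappa: 1.043  truth: 1.0
```

Each row is one group-year: the posterior median of maximal cofeeding
tolerance with its central 90% credible interval (here the model recovers
the simulated depletion rate κ = 1 within a few percent). From the same
results object, `res.decompose()` contrasts inter-group vs intra-group
variation, and a covariate fit (`effects="within"` or `"between"`)
supports `res.effect_summary()` and `res.counterfactual("all")`, which
reports how much of the between-group spread in θ disappears when
demographic composition is pinned at the grand mean.

The same pipeline runs from the shell:

```sh
cofeed simulate --seed 1 --out study/
cofeed fit --sessions study/sessions.csv --out fit/ --seed 1
cofeed run --seed 1 --out run/        # full pipeline + Markdown report
```

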