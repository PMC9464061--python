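# idiseg

Residential income segregation from census-tract household counts: the
income dissimilarity index (IDI), its finite-sample bias, the choice of the
low-income cut-off, and city-level association models — as one tested,
reproducible pipeline.

## The problem

How unevenly are low-income households spread over a city's census tracts?
The standard answer is the Duncan–Duncan dissimilarity index between a
minority group (households at or below a minimum-wage cut-off) and a
reference group, over the `J` tracts of a city:

```
D = 1/2 · Σⱼ | nⱼ¹/n¹ − nⱼ⁰/n⁰ |
```

`D` is the fraction of the minority that would have to move for both groups
to share the same tract distribution. Treating the counts as a product of
two independent multinomials with tract-allocation probabilities `pⱼ¹`,
`pⱼ⁰` makes `D` the plug-in estimator of the population quantity
`D_pop = ½ Σⱼ |pⱼ¹ − pⱼ⁰|` — and exposes its well-known upward bias when
tracts are small or the minority share is low: pure chance produces positive
unevenness. Three questions follow, each answered by a module here:

1. **Is the index biased enough to matter?** `idiseg.bias` quantifies it with
   Efron's parametric bootstrap from the fitted multinomial model
   (`bias ≈ mean(D*) − D`, corrected `D − bias`), plus a random-allocation
   null that measures chance unevenness directly.
2. **Which cut-off defines "low-income"?** `idiseg.cutoff` scans candidate
   cut-offs (½, 1, 2, 3 minimum wages), pools the national minority share,
   and selects the smallest cut-off whose share is large enough to be stable
   but still a minority (default band [0.20, 0.50)).
3. **How does segregation relate to inequality?** `idiseg.associations`
   builds the city panel (Gini, poverty rate, GDP per capita, unemployment,
   a Social Environment Index) and fits three OLS models of z-scored IDI on
   z-scored covariates, with Breusch–Pagan, White and Durbin–Watson
   diagnostics.

Because real tract-level income tables are access-restricted,
`idiseg.synthetic` generates IBGE-like cities — near-equal tract sizes,
log-normal household income binned at {½, 1, 2, 3} minimum wages, and an
exactly calibrated `D_pop` — so every stage is testable against known ground
truth.

## Worked example

```python
import numpy as np
from idiseg import (CityBlueprint, generate_city, city_dissimilarity,
                    bootstrap_bias, select_cutoff)

bp = CityBlueprint("salvador-like", region="ne", n_tracts=50,
                   households_per_tract=300, target_Dpop=0.34, seed=7)
table, incomes, true_dpop = generate_city(bp)

res = city_dissimilarity(table, cutoff=2.0)
est = bootstrap_bias(table, cutoff=2.0, B=1000, seed=7)
print(f"true D_pop        {true_dpop:.3f}")
print(f"plug-in D         {res.D:.3f}  (minority share {res.minority_share:.3f})")
print(f"bootstrap bias    {est.bias_hat:.4f}  ({est.bias_pct:.2f}% of D)")
print(f"corrected D       {est.D_corrected:.3f}  (bootstrap SE {est.se_boot:.4f})")
```

prints

```
true D_pop        0.340
plug-in D         0.345  (minority share 0.336)
bootstrap bias    0.0001  (0.02% of D)
corrected D       0.345  (bootstrap SE 0.0080)
```

A city of 50 tracts × ~300 households with true segregation 0.34 yields a
plug-in index within sampling error of the truth and a bootstrap bias two
orders of magnitude below it — tract sizes in this regime are large enough
that the index is essentially unbiased. The cut-off rule applied to the
published national pooled shares of the four candidate groups picks two
minimum wages:

```python
select_cutoff({0.5: 0.017, 1.0: 0.131, 2.0: 0.338, 3.0: 0.52})  # -> 2.0
```

The ½- and 1-MW groups are too small to give a stable index, and the 3-MW
group is no longer a minority.

## Command line

```bash
idiseg simulate --n-cities 20 --seed 1 --out data/
idiseg cutoff-scan --tracts data/tracts.csv --b 500 --out scan.csv
idiseg run --config config.yaml --seed 1      # full pipeline
```

`idiseg run` executes scan → selection → per-city index + bias → panel →
models 1–3 (on raw and bias-corrected IDI, side by side) → quartile summary,
ranking and correlation matrix, writing text tables stamped with the config
hash; the same config and seed reproduce every file byte for byte.

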