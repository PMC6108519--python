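# mealnets

Networks of food intake at the meal level and at the habitual (daily
average) level, estimated from 24-hour dietary recall data with
semiparametric Gaussian copula graphical models (SGCGMs).

## The problem

24-hour dietary recalls record, per participant and day, the gram amount of
each food consumed at each of 11 eating occasions. Nutritional
epidemiologists usually analyse the *habitual* diet — each participant's
average daily intake — but averaging hides *which foods are actually eaten
together at a meal*. `mealnets` estimates conditional-dependence networks
separately for the four main meals (breakfast, lunch, afternoon snack,
dinner) and for habitual intake, and quantifies how much of the meal-level
structure survives averaging.

Dietary gram amounts are heavily zero-inflated and right-skewed, so Gaussian
assumptions fail. The SGCGM sidesteps this through ranks: with Spearman's
ρ̂ (or Kendall's τ̂) the latent Gaussian correlation is estimated by the
nonparanormal *skeptic* sine maps

    Ŝ_jk = 2 sin(π ρ̂_jk / 6)        (Spearman)
    Ŝ_jk = sin(π τ̂_jk / 2)          (Kendall, tau-b)

A sparse precision matrix Ω̂ then maximises the ℓ₁-penalised likelihood

    log det Ω − tr(Ŝ Ω) − λ Σ_{i≠j} |ω_ij|

with λ chosen by tenfold cross-validation (held-out Gaussian log-likelihood,
ties within one standard error resolved toward the sparser penalty). Network
edges are the partial correlations −ω̂_ij /√(ω̂_ii ω̂_jj); |pcor| ≥ 0.30
counts as strong, and connected components of ≥ 3 food groups count as
networks. Overlapping *link communities* (clusters of edges, cut at maximum
partition density) and community-count centrality make the networks
interpretable, and meal-vs-habitual comparison matches edges
direction-specifically (same food pair, same sign).

The cohort data the method targets are not public, so the package ships a
first-class synthetic generator: recall-level amounts are drawn from a
latent Gaussian copula with a known sparse partial-correlation structure
per meal, zero-inflated lognormal margins calibrated to published per-meal
intake means/SDs, and a participant effect that correlates a person's
recall days.

## A worked example

```python
from mealnets import build_meal_table, estimate_network, simulate_cohort

dataset = simulate_cohort(seed=1, n_participants=300)
table = build_meal_table(dataset, "breakfast")
est = estimate_network(table.matrix(), tuple(table.data.columns),
                       method="spearman", k=10, seed=1)
for e in sorted(est.network.edges, key=lambda e: -abs(e.pcor))[:6]:
    print(f"{e.u} -- {e.v}: {e.pcor:+.2f}")
```

prints (seed 1):

```
Bread -- Butter & animal fat: +0.30
Cheese -- Bread: +0.30
Processed meat -- Margarine: +0.26
Bread -- Margarine: +0.25
Bread -- Processed meat: +0.25
Tea -- Coffee: -0.19
```

Each number is the partial correlation between two food groups at
breakfast given all other groups: bread is eaten with its spreads and
toppings, while tea and coffee substitute for each other (negative). The
`examples/` directory has one short script per capability (simulation,
network estimation, community detection, meal-vs-habitual comparison), and
the `mealnets` command line exposes the same stages
(`simulate`, `tables`, `network`, `communities`, `compare`, `run-all`).

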