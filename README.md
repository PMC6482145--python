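# reefbudget

Census-based carbonate budgets for coral reef-flat surfaces.

Coral reefs persist only while they deposit calcium carbonate faster than
biological and physical erosion removes it. The **carbonate budget** of a
reef is the net balance, in G = kg CaCO₃ m⁻² yr⁻¹, between gross carbonate
production by corals and calcifying algae and its removal by bioeroders
(parrotfish, endolithic borers, urchins). Reef-flat budgets matter because
the upper reef surface is the main wave-dissipating structure protecting
reef islands and the main sediment factory supplying them, yet most budget
surveys target the fore-reef slope.

`reefbudget` implements the census-based (ReefBudget-style) budget for
point-intercept transect surveys: 10 m survey lines with 100 benthic
observations each at 10 cm spacing, chain-method rugosity, and urchin belt
transects, organised along radial transects crossed with eco-geomorphic
zones. It is aimed at reef geomorphologists and ecologists who want the
full pipeline — parsing and validating survey CSVs, the budget arithmetic,
hierarchical aggregation with dispersion, and the live-coral-cover
threshold for budget positivity — as tested, reusable code, plus a
synthetic survey generator with recorded ground truth for method checks.

## The model

For each 10 m survey line with rugosity coefficient `R` (mean of three
chain ratios, `R ≥ 1`), gross production sums over producer groups `i`
(coral taxon × morphology, plus crustose coralline algae):

```
G_gross = Σ_i  R · (X_i / 100) · (C_i · 10)
```

where `X_i` is percent cover from the census and `C_i` the calcification
rate in g cm⁻² yr⁻¹ (the factor 10 = 10 000 cm² m⁻² / 1000 g kg⁻¹ converts
to kg m⁻² yr⁻¹). Bioerosion has three components, with `f_avail` the
fraction of points on available substrate (live coral, dead coral, reef
framework, rubble):

```
G_borer      = R · f_avail · (macro + micro)          # defaults 0.052 + 0.053
G_parrotfish = rate · f_avail                          # default 3.81 G, planar
G_echinoid   = mean over belts of Σ_genus ((a · X^1.6624) · e · 365/60)/1000
G_net        = G_gross − (G_borer + G_parrotfish + G_echinoid)
```

with `X` the mean urchin test size (mm) and `e` the density (ind. m⁻²).
Line budgets aggregate upward (mean ± sample SD) to (transect, zone)
groups, transects, and the reef, where the reef mean averages transect
means. The cover threshold is the x-intercept of an OLS fit of net G on
percent live coral cover, with a 95% interval from Fieller inversion of
the confidence band.

## Worked example

```python
from reefbudget import RateTable, ReefBudgetModel
from reefbudget.synthetic import default_mahutigala_scenario, generate

dataset = generate(default_mahutigala_scenario(), seed=1)
model = ReefBudgetModel(dataset.lines, dataset.belts, RateTable.default())
results = model.fit()
print(results.summary())
```

```
Reef-flat carbonate budget (census-based)
=========================================================
survey lines: 63   productive lines: 54   transects: 7   belts: 22

Reef scope (mean of transect means, +/- SD over transects):
  live coral cover      21.4 +/- 2.3 %
  rugosity R            2.59 +/- 0.06
  gross production       7.6 +/- 0.7 G
  total bioerosion       2.6 +/- 0.2 G   (parrotfish 93.3%, borers 6.7%, echinoids 0.0%)
  net production         5.1 +/- 0.6 G

Production by morphology: massive 52.5%, branching 37.2%, encrusting 5.3%, digitate 2.4%, tabular 1.5%, free_living 1.2%

Live-cover threshold for net G > 0: 2.6% (95% CI -1.3-5.4)  [slope 0.269 G/%, R^2 0.73, n 54]

G = kg CaCO3 m-2 yr-1
```

Reading the output: the synthetic reef deposits 7.6 kg CaCO₃ m⁻² yr⁻¹
gross, loses 2.6 to bioerosion (dominated by parrotfish grazing), and so
accretes 5.1 net — a strongly positive budget driven by the ~21% live
cover of mostly massive corals. The threshold line says net production
would cross zero if live cover fell to ~2.6% under these rates. Field
analyses should inject their own calcification table
(`RateTable.from_csv("rates.csv")`); the shipped defaults are labelled
placeholders. `results.frame("zone")`, `.frame("transect")` and
`.to_budget_csv(path)` expose the full hierarchy;
`results.cover_threshold(scope="zone")` refits at zone scope.

The same pipeline runs from the shell:

```sh
reefbudget simulate --seed 1 --out-dir survey/
reefbudget compute --observations survey/observations.csv \
    --rugosity survey/rugosity.csv --belts survey/belts.csv \
    --rates survey/rates.csv --out-dir out/
reefbudget threshold --budget out/budget.csv --out fit.json
```

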