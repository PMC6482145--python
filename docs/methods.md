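# Methods

## The budget model

The package implements the census-based carbonate budget for reef-flat
point-intercept surveys. The unit of computation is the 10 m survey line:
100 benthic observations at 10 cm spacing plus three 1 m chain-rugosity
sections. All budget quantities are computed per line first and only then
averaged; covers are never pooled across lines before entering the
production equation, because rugosity multiplies cover at line level and
the two covary.

**Gross production.** Each producer group — live coral keyed by
(taxon, morphology), plus crustose coralline algae (CCA) as a secondary
producer — contributes `R · (Xi/100) · (Ci · 10)` in G = kg CaCO₃ m⁻² yr⁻¹.
`R` is the arithmetic mean of the three chain ratios (dimensionless, ≥ 1),
`Xi` the group's percent cover on the line, `Ci` its calcification rate in
g cm⁻² yr⁻¹. The conversion factor is exactly 10 (= 10 000 cm² m⁻² / 1000
g kg⁻¹); a unit test pins the equivalence of the two ways of writing it.
Turf algae and non-calcifying macroalgae produce nothing; an optional
`halimeda_ci` assigns calcifying *Halimeda* a rate if desired (off by
default, since the census-rate budget here covers corals and CCA).

**Bioerosion.** Three components, each per line:

- *Endolithic borers*: `R · f_avail · (macro + micro)` with defaults
  0.052 and 0.053 G applied summed. `f_avail` is the fraction of census
  points on available substrate — live coral, dead coral, reef framework
  and rubble. Boring acts on the true (rugose) surface, hence the R
  multiplier. The two constants are independently configurable.
- *Parrotfish*: a published belt-survey rate (default 3.81 G) applied to
  planar available substrate, **without** the rugosity multiplier: rates
  of this kind are normalised per planar reef area by construction. A
  `parrotfish_uses_rugosity` flag enables R-scaling for sensitivity
  analysis; this is a genuinely open methodological choice and the flag
  makes it explicit.
- *Echinoids*: per belt transect, each genus contributes
  `((a · X^1.6624) · e · 365/60)/1000` with `X` its count-weighted mean
  test size (mm) and `e` its density in individuals m⁻² (count / belt
  area — the only reading consistent with a result in kg m⁻² yr⁻¹; a
  fixed-density test confirms the rate is invariant to belt area). Belt
  rates are averaged per transect and broadcast to that transect's lines;
  transects without belt surveys receive the reef-wide belt mean. The
  365/60 factor is carried verbatim from the published formulation; its
  unit chain is not documented there and we do not reinterpret it.

Coefficients default to a = 0.0029 (Diadema) and a = 8×10⁻⁵
(Phyllocanthus), b = 1.6624 for both. The Phyllocanthus coefficient
circulates in print as 8×10⁵, which would let a single 90 mm urchin erode
~10⁴ kg of carbonate per square metre per year — about 10⁸ times the
Diadema rate and physically absurd; we take the lost-exponent-sign reading
8×10⁻⁵ as the default and keep the literal printed value selectable via
`RateTable.verbatim_phyllocanthus()` for exact-formula reproduction.

**Net budget and aggregation.** Net G = gross − (borer + parrotfish +
echinoid), per line. Aggregation is unweighted arithmetic mean ± sample
(n−1) SD at (transect, zone), transect and reef scope; the reef mean
averages transect means (the radial-transect design's natural estimator),
with pooled-line averaging available (`reef_scope="pooled_lines"`) — the
two differ slightly whenever transects carry unequal line counts, which
is also why total-bioerosion summaries can differ in the first decimal
between the two paths. Sand-moat (zone 1) lines contain no producers and
are excluded from all aggregates (a warning reports the exclusion; an
`include_sand_moat` flag overrides). Aggregated means enforce the exact
accounting identities — net mean = gross mean − erosion mean, erosion
mean = sum of component means — by computing the derived means from the
component means rather than re-averaging, so the identities hold to the
last bit rather than up to float-summation order.

**Cover threshold.** The live-coral-cover threshold for budget positivity
is the x-intercept `−b₀/b₁` of an OLS fit of net G on percent live cover
(line-scope points by default; zone-scope via an option — which scope
such regressions "should" use is not settled, so both are exposed). The
95% interval inverts the confidence band for the mean response (Fieller):
the roots of `(b₀ + b₁x)² = t² · Var(b̂₀ + b̂₁x)`. A threshold is reported
only when the slope is positive and significant at α = 0.05; a flat or
negative fit returns the regression with a diagnostic instead. Zero
residual variance (noiseless input) is handled as a degenerate case: the
interval collapses to the point estimate, and a scale-relative slope
floor (10⁻⁹ of the data's own slope scale) prevents float round-off on a
flat response from masquerading as a significant slope.

## Rate tables

`RateTable` keys calcification on (taxon, morphology) with a
morphology-level fallback for unidentified genera (`strict=True` turns
the fallback into an error). The shipped defaults are **placeholder**
morphology-level magnitudes in the range reported for Indo-Pacific
reef-flat communities (massive 1.0, branching 2.1, tabular 2.0, digitate
1.5, encrusting/free-living 0.8, CCA 0.4 g cm⁻² yr⁻¹); they produce
budgets of realistic magnitude but are not a transcription of any field
study's rate table, and every quantitative test in the suite injects an
explicit table instead of relying on them.

## The synthetic survey generator

The generator emulates the survey design the analysis assumes, with a
recorded ground truth: per zone, census categories are i.i.d. multinomial
draws from `category_probs`; live-coral points get (taxon, morphology)
from `live_coral_mix`; the three rugosity sections are normal(mean, sd)
truncated at 1 (closed-form expectation exposed as
`expected_rugosity`); belt urchin counts are Poisson(density × area) with
genus from a mix and test sizes normal around the genus mean, clipped to
the class range (21–40 mm Diadema, 81–100 mm Phyllocanthus). An optional
`patchiness` parameter adds first-order Markov persistence of category
along the tape (default off — a point census carries no autocorrelation
information to calibrate it); persistence inflates per-line cover
variance but preserves the marginal composition, and a test checks both.

The default scenario is a small lagoonal reef platform surveyed shortly
after a mass bleaching event: five eco-geomorphic zones — barren sandy
moat (zone 1), patch reef (2), inner reef flat (3), outer reef flat
(4, 5) — crossed by seven radial transects (SW…SE) with three replicate
lines per surveyed zone. Zone compositions use midpoints of the reported
per-zone cover ranges (e.g. live coral 25% in the patch zone, 17.5% inner
flat, 20% outer flat; dead framework 30–40% on the flats), a shared
post-bleaching live-coral mix (massive 66.3%, branching 13.0%, Heliopora
12.6%, minor morphologies 8.1%), zone rugosity means 1.1–2.7 (sd 0.35,
truncated at 1), and urchin density 0.1 m⁻² in productive zones. The
survey totalled 63 lines, i.e. 21 surveyed (transect, zone) pairs; the
per-transect zone layout is not recoverable from the published text, so
the default assigns three zones per transect (zone 2 everywhere, since
the patch-reef ring surrounds the moat, plus one inner and/or outer zone)
summing to exactly 63. Belts run on four transects (SW, NW, NE, SE), two
replicates per productive zone, 30 m² normalising area per belt.
`transect_rugosity_mean` can override rugosity per transect, e.g. to
reproduce a reported 1.9–2.9 across-transect range.

What the generator does **not** emulate: spatial autocorrelation beyond
the optional Markov toggle, within-zone gradients, observer error,
transect-specific community differences (the live-coral mix is shared),
and any temporal dynamics (single-time-point censuses only). Passing
recovery tests on this generator therefore demonstrates that the pipeline
arithmetic and aggregation are correct under the design's sampling
assumptions — not that the defaults reproduce any particular field reef's
numbers, which would require the undeposited raw censuses.

## Verification strategy

- **Printed-arithmetic checks**: the budget equations evaluated at simple
  reference points (R = 2, Xi = 50%, Ci = 1 → 10 G; full substrate at
  R = 1 → 0.105 G borer, 3.81 G parrotfish; Diadema at 30 mm and
  1 m⁻² → 5.036×10⁻³ G, frozen from an independent numeric evaluation).
- **Oracle equivalence**: a brute-force recomputation in plain Python
  (tests/oracle_helpers.py), sharing no code with the pipeline, walks
  every observation and belt record; line-scope results must agree to
  1 part in 10¹² on 100 random synthetic reefs, and aggregate means/SDs
  against hand-rolled mean/SD.
- **Closed-form recovery**: over 500 generated lines from one zone
  profile, mean live cover and mean gross G must land within 3 Monte
  Carlo standard errors of `100·p_live` and
  `E[R] · (Σ p_i·Ci + p_cca·Ci_cca) · 10`. Problem sizes throughout the
  suite (100 reefs, 500–10 000 lines, 200 regression seeds) were chosen
  so each check resolves its expected effect with comfortable margin
  while the whole suite stays quick.
- **Threshold recovery and coverage**: noiseless points on
  `net = 0.25·cover − 2.5` must return exactly 10.0% with a degenerate
  interval; across 200 seeded noisy simulations, the 95% CIs for slope,
  intercept and Fieller x-intercept must each cover the truth in ≥ 90%
  of runs.
- **Properties** (hypothesis, seeded): category covers sum to exactly
  100; rugosity is permutation-invariant; gross production is linear in
  R and each cover and invariant to observation order; total erosion is
  monotone in substrate availability and every rate constant; zero rate
  constants make net equal gross; CSV round trips are lossless; the
  generator is byte-identical under a fixed seed.

## Known limitations

- Calcification defaults are placeholders (above); results with them are
  illustrative only.
- Echinoid erosion is not additionally scaled by each line's `f_avail`
  or rugosity: belts census the actual substrate, so their density
  already reflects availability. Lines inherit a transect-level rate,
  so within-transect echinoid variation is not represented (it is ~0.1%
  of bioerosion under realistic densities).
- The parrotfish component treats the imported rate as spatially uniform
  per unit available substrate; real grazing pressure varies with fish
  assemblage and feeding preference, which a census of benthos cannot
  resolve.
- Under the default scenario the budget is positive at every surveyed
  line, so the fitted cover threshold lies below the observed cover range
  and is an extrapolation; its value is sensitive to the scenario's
  erosion-to-production ratio and should only be read off data that
  actually straddle net G = 0.
- The Fieller interval assumes the OLS error model; with few points or a
  weak slope it can be unbounded on one side, in which case `ci95` is
  `None` and the caller should fall back to the bootstrap or collect
  more lines.
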