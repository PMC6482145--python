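"""Gross carbonate production from census covers, rugosity and Ci rates.

For one survey line, each producer group i (a (taxon, morphology) pair for
corals, plus crustose coralline algae) contributes

    G_i = R * (X_i / 100) * (C_i * 10)        [kg CaCO3 m^-2 yr^-1]

where R is the line's rugosity coefficient, X_i its percent cover on the
line and C_i the calcification rate in g cm^-2 yr^-1.  The factor 10 is
the exact unit conversion (C_i * 10_000 cm^2 m^-2) / (1000 g kg^-1): a
square metre of flat substrate fully covered by a producer depositing
1 g cm^-2 yr^-1 adds 10 kg m^-2 yr^-1.  Gross production is the sum over
producers; R is the line-level coefficient applied uniformly to every
producer on that line, and production is always computed per line before
any averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .rates import RateTable
from .survey import SurveyError, SurveyLine, percent_cover, rugosity_coefficient

__all__ = ["CI_UNIT_FACTOR", "ProductionTerm", "gross_production", "production_by_morphology"]

#: (10_000 cm^2 per m^2) / (1000 g per kg) — converts g cm^-2 yr^-1 to
#: kg m^-2 yr^-1 under percent cover.
CI_UNIT_FACTOR = 10_000 / 1000
assert CI_UNIT_FACTOR == 10.0  # exact equivalence of the two printed forms

#: Taxon label under which crustose coralline algae enter the rate table.
CCA_TAXON = "CCA"
HALIMEDA_TAXON = "Halimeda"


@dataclass(frozen=True)
class ProductionTerm:
    """One producer group's contribution to a line's gross production."""

    taxon: str | None
    morphology: str
    xi_pct: float
    ci_g_cm2_yr: float
    contribution_G: float

    def __post_init__(self) -> None:
        if self.contribution_G < 0:
            raise SurveyError("production contribution cannot be negative")


def gross_production(
    line: SurveyLine, rates: RateTable
) -> tuple[float, list[ProductionTerm]]:
    """Gross carbonate production G of one survey line, with its terms.

    Producers are live coral (per taxon x morphology) and CCA; optionally
    Halimeda if the rate table assigns it a Ci.  Non-producer categories
    contribute zero.  Raises if a coral (taxon, morphology) cannot be
    resolved in the rate table (strict mode disables the morphology-level
    fallback).
    """
    R = rugosity_coefficient(line)
    covers = percent_cover(line, key="taxon_morphology")

    terms: list[ProductionTerm] = []

    # live coral terms
    coral_keys = sorted(
        (
            (tax, morph)
            for (tax, morph), _ in covers.items()
            if morph != "none"
        ),
        key=lambda k: (k[0] or "", k[1]),
    )
    for tax, morph in coral_keys:
        xi = covers[(tax, morph)]
        ci = rates.lookup_ci(tax, morph)
        terms.append(
            ProductionTerm(tax, morph, xi, ci, R * (xi / 100.0) * (ci * CI_UNIT_FACTOR))
        )

    # crustose coralline algae: secondary producer with its own Ci
    cover_by_cat = percent_cover(line, key="category")
    cca_pct = cover_by_cat.get("cca", 0.0)
    if cca_pct > 0 and rates.cca_ci > 0:
        terms.append(
            ProductionTerm(
                CCA_TAXON,
                "encrusting",
                cca_pct,
                rates.cca_ci,
                R * (cca_pct / 100.0) * (rates.cca_ci * CI_UNIT_FACTOR),
            )
        )

    # optional calcifying macroalgae (off unless a rate is configured)
    if rates.halimeda_ci is not None:
        hal_pct = sum(
            1.0
            for o in line.observations
            if o.category == "macroalgae" and o.taxon == HALIMEDA_TAXON
        )
        if hal_pct > 0:
            terms.append(
                ProductionTerm(
                    HALIMEDA_TAXON,
                    "none",
                    hal_pct,
                    rates.halimeda_ci,
                    R * (hal_pct / 100.0) * (rates.halimeda_ci * CI_UNIT_FACTOR),
                )
            )

    gross = sum(t.contribution_G for t in terms)
    return gross, terms


def production_by_morphology(
    lines: Sequence[SurveyLine] | Iterable[SurveyLine], rates: RateTable
) -> dict[str, float]:
    """Share of total gross production contributed by each growth morphology.

    Shares sum to 1 over morphologies with nonzero production; a dataset
    with zero total production yields an empty mapping.
    """
    lines = list(lines)
    if not lines:
        raise SurveyError("production_by_morphology requires at least one line")
    totals: dict[str, float] = {}
    for line in lines:
        _, terms = gross_production(line, rates)
        for t in terms:
            if t.contribution_G > 0:
                totals[t.morphology] = totals.get(t.morphology, 0.0) + t.contribution_G
    grand = sum(totals.values())
    if grand <= 0:
        return {}
    return {m: v / grand for m, v in totals.items()}
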