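"""The three bioerosion components and their summation.

Borers (endolithic micro- and macro-boring organisms):

    borer_G = R * f_avail * (macro_rate + micro_rate)

with f_avail the fraction of census points on available substrate (live
coral, dead coral, reef framework, rubble) and R the rugosity coefficient
— boring acts on the true (rugose) substrate surface.

Parrotfish grazing applies a published belt-survey rate (default 3.81 G)
to the planar available substrate, without the rugosity multiplier: the
published rate is already normalised per planar reef area.  A flag enables
R-scaling for sensitivity analysis.

Echinoids follow the per-genus test-size power law

    rate_G = ((a * X^b) * e * 365 / 60) / 1000

with X the mean test size (mm), e the urchin density (individuals m^-2,
count / belt area) and the 365/60 factor carried verbatim from the
published formulation.  Belt-level genus rates are summed, then averaged
over belts; per transect where belts exist, with the reef-wide belt mean
broadcast to transects that carried no belt survey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rates import RateTable
from .survey import (
    EchinoidBelt,
    SurveyError,
    SurveyLine,
    available_substrate_fraction,
    rugosity_coefficient,
)

__all__ = [
    "ErosionBreakdown",
    "borer_erosion",
    "parrotfish_erosion",
    "echinoid_belt_rate",
    "echinoid_erosion",
    "echinoid_rates_by_transect",
    "total_bioerosion",
]

ECHINOID_ANNUALISATION = 365.0 / 60.0  # verbatim factor of the published power law
G_PER_GRAM = 1.0 / 1000.0


@dataclass(frozen=True)
class ErosionBreakdown:
    """Per-line erosion components, all in G = kg CaCO3 m^-2 yr^-1."""

    borer_G: float
    parrotfish_G: float
    echinoid_G: float

    @property
    def total_G(self) -> float:
        return self.borer_G + self.parrotfish_G + self.echinoid_G

    @property
    def shares_pct(self) -> dict[str, float]:
        """Percent share of each component; empty when total is zero."""
        total = self.total_G
        if total <= 0:
            return {}
        return {
            "borer": 100.0 * self.borer_G / total,
            "parrotfish": 100.0 * self.parrotfish_G / total,
            "echinoid": 100.0 * self.echinoid_G / total,
        }


def borer_erosion(line: SurveyLine, rates: RateTable) -> float:
    """Endolithic (micro + macro) borer erosion of one line, in G."""
    R = rugosity_coefficient(line)
    f_avail = available_substrate_fraction(line)
    return R * f_avail * (rates.macro_borer_rate + rates.micro_borer_rate)


def parrotfish_erosion(
    line: SurveyLine, rates: RateTable, use_rugosity: bool = False
) -> float:
    """Parrotfish erosion of one line: published rate x available substrate."""
    f_avail = available_substrate_fraction(line)
    scale = rugosity_coefficient(line) if use_rugosity else 1.0
    return rates.parrotfish_rate * f_avail * scale


def echinoid_belt_rate(belt: EchinoidBelt, rates: RateTable) -> float:
    """Echinoid erosion rate of one belt, in G.

    Within the belt, each genus contributes ((a * X^b) * e * 365/60)/1000
    with X its count-weighted mean test size and e its density
    (individuals m^-2); genus contributions are summed.
    """
    if not belt.area_m2 > 0:
        raise SurveyError(f"belt {belt.belt_id!r} has zero area")
    per_genus: dict[str, tuple[float, int]] = {}
    for genus, size, count in belt.records:
        if count == 0:
            continue
        sz_sum, n = per_genus.get(genus, (0.0, 0))
        per_genus[genus] = (sz_sum + size * count, n + count)
    rate = 0.0
    for genus, (sz_sum, n) in per_genus.items():
        if genus not in rates.echinoid_coeffs:
            raise SurveyError(f"no echinoid coefficients for genus {genus!r}")
        a, b = rates.echinoid_coeffs[genus]
        mean_size = sz_sum / n
        density = n / belt.area_m2
        rate += (a * mean_size**b) * density * ECHINOID_ANNUALISATION * G_PER_GRAM
    return rate


def echinoid_erosion(belts: Sequence[EchinoidBelt], rates: RateTable) -> float:
    """Mean echinoid erosion over a collection of belts, in G.

    The collection must be non-empty (belts with zero urchins are valid and
    contribute zero).
    """
    belts = list(belts)
    if not belts:
        raise SurveyError("echinoid_erosion requires at least one belt")
    return float(np.mean([echinoid_belt_rate(b, rates) for b in belts]))


def echinoid_rates_by_transect(
    belts: Iterable[EchinoidBelt],
    rates: RateTable,
    transects: Sequence[str],
) -> dict[str, float]:
    """Echinoid rate to apply on each transect's lines.

    Transects with belt surveys use the mean of their own belts; the rest
    receive the reef-wide mean over all belts (0 if no belts at all).
    """
    belts = list(belts)
    by_transect: dict[str, list[float]] = {}
    for b in belts:
        by_transect.setdefault(b.transect_id, []).append(echinoid_belt_rate(b, rates))
    reef_mean = (
        float(np.mean([r for rs in by_transect.values() for r in rs])) if belts else 0.0
    )
    return {
        t: float(np.mean(by_transect[t])) if t in by_transect else reef_mean
        for t in transects
    }


def total_bioerosion(
    line: SurveyLine,
    belts: Sequence[EchinoidBelt] | Mapping[str, float] | float | None,
    rates: RateTable,
    parrotfish_uses_rugosity: bool = False,
) -> ErosionBreakdown:
    """All three erosion components for one line.

    ``belts`` may be the belt collection (the line's transect rate is
    resolved from it), a precomputed transect -> rate mapping, a scalar
    echinoid rate, or ``None`` (no urchin census: component 0).
    """
    if belts is None:
        echinoid = 0.0
    elif isinstance(belts, (int, float)):
        echinoid = float(belts)
    elif isinstance(belts, Mapping):
        echinoid = float(belts.get(line.transect_id, 0.0))
    else:
        belt_list = list(belts)
        if belt_list:
            echinoid = echinoid_rates_by_transect(
                belt_list, rates, transects=[line.transect_id]
            )[line.transect_id]
        else:
            echinoid = 0.0
    return ErosionBreakdown(
        borer_G=borer_erosion(line, rates),
        parrotfish_G=parrotfish_erosion(line, rates, use_rugosity=parrotfish_uses_rugosity),
        echinoid_G=echinoid,
    )
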