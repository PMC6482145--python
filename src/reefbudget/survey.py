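"""Domain model for census-based reef-flat carbonate-budget surveys.

The field protocol is a point-intercept transect (PIT) census: along each
10 m survey line the benthic component lying directly beneath the tape is
recorded at every 10 cm increment, giving exactly 100 observations per
line.  Structural complexity is measured with the chain method on three
randomly placed 1 m sections per line; each section's value is chain
(surface) length divided by 1 m linear length, so every section is >= 1,
and the line's rugosity coefficient R is the arithmetic mean of the three.

Echinoid (urchin) abundance is censused separately on 30 m x 2 m belt
transects, recording genus and test (skeletal) diameter.

These types validate their own invariants at construction time so that the
downstream budget arithmetic can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CATEGORIES",
    "MORPHOLOGIES",
    "TRANSECTS",
    "URCHIN_GENERA",
    "AVAILABLE_SUBSTRATE",
    "CARBONATE_PRODUCERS",
    "CATEGORY_SETS",
    "POINTS_PER_LINE",
    "POSITION_STEP_CM",
    "SurveyError",
    "BenthicObservation",
    "SurveyLine",
    "EchinoidBelt",
    "percent_cover",
    "rugosity_coefficient",
    "available_substrate_fraction",
]

#: Benthic categories recordable beneath a census point.  ``dead_coral``
#: (recently dead colonies, structure intact), ``reef_framework`` (older
#: consolidated dead structure) and ``rubble`` are kept distinct because all
#: three are substrate available to bioeroders, while only some analyses
#: care about the distinction.
CATEGORIES = (
    "live_coral",
    "dead_coral",
    "reef_framework",
    "rubble",
    "sand",
    "cca",
    "turf_algae",
    "macroalgae",
    "other",
)

#: Coral growth morphologies; ``none`` is reserved for non-coral points.
MORPHOLOGIES = (
    "massive",
    "branching",
    "tabular",
    "digitate",
    "encrusting",
    "free_living",
    "none",
)

#: The seven shore-perpendicular radial transects of the survey design.
TRANSECTS = ("SW", "W", "NW", "N", "NE", "E", "SE")

URCHIN_GENERA = ("Diadema", "Phyllocanthus")

#: Substrate open to biological erosion (grazing and endolithic boring).
AVAILABLE_SUBSTRATE = frozenset({"live_coral", "dead_coral", "reef_framework", "rubble"})

#: Primary (coral) and secondary (crustose coralline algae) producers.
CARBONATE_PRODUCERS = frozenset({"live_coral", "cca"})

CATEGORY_SETS: Mapping[str, frozenset[str]] = {
    "available_substrate": AVAILABLE_SUBSTRATE,
    "carbonate_producer": CARBONATE_PRODUCERS,
    "inert": frozenset(CATEGORIES) - AVAILABLE_SUBSTRATE - CARBONATE_PRODUCERS,
}

POINTS_PER_LINE = 100
POSITION_STEP_CM = 10

#: The zone label of the inner sandy moat, which holds no carbonate
#: producers and is excluded from ecological aggregates.
SAND_MOAT_ZONE = 1


class SurveyError(ValueError):
    """Raised when survey data violate the census protocol."""


@dataclass(frozen=True)
class BenthicObservation:
    """One point-intercept record: what lies beneath the tape at one 10 cm mark.

    Parameters
    ----------
    line_id : str
        Identifier of the 10 m survey line the point belongs to.
    position_cm : int
        Position along the tape, in {10, 20, ..., 1000}.
    category : str
        Benthic category, one of :data:`CATEGORIES`.
    morphology : str
        Coral growth morphology; must be ``"none"`` unless the point is
        live coral, and live coral must carry a real morphology.
    taxon : str or None
        Optional genus label (e.g. ``"Porites"``, ``"Heliopora"``,
        ``"unidentified"``).
    """

    line_id: str
    position_cm: int
    category: str
    morphology: str = "none"
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SurveyError(
                f"unknown category {self.category!r}; allowed values: "
                f"{', '.join(CATEGORIES)}"
            )
        if self.morphology not in MORPHOLOGIES:
            raise SurveyError(
                f"unknown morphology {self.morphology!r}; allowed values: "
                f"{', '.join(MORPHOLOGIES)}"
            )
        p = self.position_cm
        if not (POSITION_STEP_CM <= p <= POINTS_PER_LINE * POSITION_STEP_CM) or (
            p % POSITION_STEP_CM != 0
        ):
            raise SurveyError(
                f"position_cm must be a multiple of {POSITION_STEP_CM} in "
                f"[{POSITION_STEP_CM}, {POINTS_PER_LINE * POSITION_STEP_CM}], "
                f"got {p} (line {self.line_id!r})"
            )
        if (self.category == "live_coral") != (self.morphology != "none"):
            raise SurveyError(
                f"morphology must be set iff category is live_coral; got "
                f"category={self.category!r}, morphology={self.morphology!r} "
                f"(line {self.line_id!r}, position {p} cm)"
            )


@dataclass(frozen=True)
class SurveyLine:
    """A complete 10 m survey line: 100 observations plus rugosity sections.

    The line is the atomic unit of the carbonate budget: gross production
    and erosion are computed per line and only then averaged upward.

    ``rugosity_sections`` may be ``None`` while observations and chain data
    are read from separate files; :func:`rugosity_coefficient` then raises
    until the three chain ratios are attached.
    """

    line_id: str
    transect_id: str
    zone_id: int
    observations: tuple[BenthicObservation, ...]
    rugosity_sections: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.transect_id not in TRANSECTS:
            raise SurveyError(
                f"unknown transect {self.transect_id!r}; allowed: {', '.join(TRANSECTS)}"
            )
        if not 1 <= int(self.zone_id) <= 5:
            raise SurveyError(f"zone_id must be in 1..5, got {self.zone_id!r}")
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) != POINTS_PER_LINE:
            raise SurveyError(
                f"line {self.line_id!r} has {len(obs)} observations; a complete "
                f"line has exactly {POINTS_PER_LINE}"
            )
        positions = [o.position_cm for o in obs]
        if len(set(positions)) != len(positions):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise SurveyError(
                f"duplicate position(s) {dupes} within line {self.line_id!r}"
            )
        for o in obs:
            if o.line_id != self.line_id:
                raise SurveyError(
                    f"observation at {o.position_cm} cm carries line_id "
                    f"{o.line_id!r}, expected {self.line_id!r}"
                )
        if self.rugosity_sections is not None:
            sections = tuple(float(s) for s in self.rugosity_sections)
            object.__setattr__(self, "rugosity_sections", sections)
            if len(sections) != 3:
                raise SurveyError(
                    f"line {self.line_id!r} has {len(sections)} rugosity "
                    f"sections; the chain protocol uses exactly 3"
                )
            if any(s < 1.0 for s in sections):
                raise SurveyError(
                    f"rugosity sections must be >= 1 (surface length cannot be "
                    f"shorter than linear length); got {sections} on line "
                    f"{self.line_id!r}"
                )
        if self.zone_id == SAND_MOAT_ZONE:
            n_prod = sum(1 for o in obs if o.category in CARBONATE_PRODUCERS)
            if n_prod:
                warnings.warn(
                    f"sand-moat (zone {SAND_MOAT_ZONE}) line {self.line_id!r} "
                    f"records {n_prod} carbonate-producer point(s); the moat "
                    f"holds no primary or major secondary producers",
                    UserWarning,
                    stacklevel=2,
                )

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for o in self.observations:
            counts[o.category] = counts.get(o.category, 0) + 1
        return counts


@dataclass(frozen=True)
class EchinoidBelt:
    """One 30 m x 2 m urchin belt transect.

    ``records`` holds ``(genus, test_size_mm, count)`` triples; emitting one
    record per observed individual (count = 1) is valid.  ``area_m2``
    defaults to 30 per replicate belt, matching the census design's
    per-belt normalising area.
    """

    belt_id: str
    transect_id: str
    zone_id: int
    records: tuple[tuple[str, float, int], ...] = ()
    area_m2: float = 30.0

    def __post_init__(self) -> None:
        if self.transect_id not in TRANSECTS:
            raise SurveyError(
                f"unknown transect {self.transect_id!r}; allowed: {', '.join(TRANSECTS)}"
            )
        if not self.area_m2 > 0:
            raise SurveyError(f"belt {self.belt_id!r}: area_m2 must be > 0")
        recs = tuple((str(g), float(x), int(c)) for g, x, c in self.records)
        object.__setattr__(self, "records", recs)
        for genus, size, count in recs:
            if genus not in URCHIN_GENERA:
                raise SurveyError(
                    f"unknown urchin genus {genus!r}; allowed: {', '.join(URCHIN_GENERA)}"
                )
            if not 1.0 <= size <= 200.0:
                raise SurveyError(
                    f"test size {size} mm out of range 1-200 mm (belt {self.belt_id!r})"
                )
            if count < 0:
                raise SurveyError(f"negative count in belt {self.belt_id!r}")

    def total_count(self) -> int:
        return sum(c for _, _, c in self.records)


def percent_cover(
    line: SurveyLine,
    key: str = "category",
    within: str | None = None,
) -> dict:
    """Percent cover of a survey line grouped by ``key``.

    Parameters
    ----------
    line : SurveyLine
        A complete line (the type guarantees 100 observations).
    key : {"category", "morphology", "taxon", "taxon_morphology"}
        Grouping variable.  ``"taxon_morphology"`` keys the result by
        ``(taxon, morphology)`` pairs — the census covers Xi that feed the
        gross-production equation.
    within : str, optional
        Restrict to points of this category (e.g. ``"live_coral"``) and
        renormalise so the restricted percentages sum to 100 — the
        proportion-of-live-coral composition view.  ``None`` (default)
        reports percent of all 100 points, which sums to exactly 100 when
        grouped by category.

    Returns
    -------
    dict
        Mapping group -> percent.  Groups absent from the line are omitted,
        except that ``within=None, key="category"`` reports 0.0 for every
        recognised category so that compositional tables align.
    """
    if key not in ("category", "morphology", "taxon", "taxon_morphology"):
        raise SurveyError(f"unknown grouping key {key!r}")
    obs: Iterable[BenthicObservation] = line.observations
    if within is not None:
        obs = [o for o in obs if o.category == within]
        denom = len(obs)
        if denom == 0:
            return {}
    else:
        denom = POINTS_PER_LINE

    counts: dict = {}
    for o in obs:
        if key == "category":
            k = o.category
        elif key == "morphology":
            k = o.morphology
        elif key == "taxon":
            k = o.taxon
        else:
            k = (o.taxon, o.morphology)
        counts[k] = counts.get(k, 0) + 1

    out = {k: 100.0 * c / denom for k, c in counts.items()}
    if within is None and key == "category":
        for c in CATEGORIES:
            out.setdefault(c, 0.0)
    return out


def rugosity_coefficient(line: SurveyLine) -> float:
    """Rugosity coefficient R: arithmetic mean of the three chain ratios.

    R is dimensionless and >= 1; R = 1 is a perfectly flat substrate.
    """
    sections = line.rugosity_sections
    if sections is None or len(sections) < 3:
        n = 0 if sections is None else len(sections)
        raise SurveyError(
            f"line {line.line_id!r} has {n} rugosity sections; 3 are required"
        )
    if any(s < 1.0 for s in sections):
        raise SurveyError(f"rugosity sections must be >= 1, got {sections}")
    return float(np.mean(sections))


def available_substrate_fraction(line: SurveyLine) -> float:
    """Fraction of census points on substrate available to bioeroders.

    Available substrate comprises live coral, dead coral, reef framework
    and rubble.
    """
    n = sum(1 for o in line.observations if o.category in AVAILABLE_SUBSTRATE)
    return n / POINTS_PER_LINE
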