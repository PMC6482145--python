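"""Shared fixtures and builders for the budget test suite."""

from __future__ import annotations

import pytest

from reefbudget import BenthicObservation, RateTable, SurveyLine


def build_line(
    spec,
    *,
    line_id="L1",
    transect="N",
    zone=3,
    rugosity=(2.0, 2.0, 2.0),
):
    """Build a complete 100-point survey line from a compact spec.

    ``spec`` is a list of (count, category[, morphology[, taxon]]) tuples;
    counts must sum to 100.  Points are laid down in order from 10 cm.
    """
    obs = []
    pos = 10
    for entry in spec:
        count, category = entry[0], entry[1]
        morphology = entry[2] if len(entry) > 2 else "none"
        taxon = entry[3] if len(entry) > 3 else None
        for _ in range(count):
            obs.append(
                BenthicObservation(
                    line_id=line_id,
                    position_cm=pos,
                    category=category,
                    morphology=morphology,
                    taxon=taxon,
                )
            )
            pos += 10
    assert pos == 1010, "spec counts must sum to 100"
    return SurveyLine(
        line_id=line_id,
        transect_id=transect,
        zone_id=zone,
        observations=tuple(obs),
        rugosity_sections=rugosity,
    )


# frozen dataclass, safe to share between tests and hypothesis examples
SIMPLE_RATES = RateTable(
    calcification={
        ("Porites", "massive"): 1.0,
        ("Acropora", "branching"): 2.0,
        ("Heliopora", "branching"): 1.5,
    },
    morphology_defaults={
        "massive": 1.0,
        "branching": 2.0,
        "tabular": 2.5,
        "digitate": 1.5,
        "encrusting": 0.8,
        "free_living": 0.8,
    },
    cca_ci=0.5,
)


@pytest.fixture
def simple_rates():
    """An explicit, injected rate table (no placeholder lookups needed)."""
    return SIMPLE_RATES
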