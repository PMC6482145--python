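"""Borer, parrotfish and echinoid erosion terms and their summation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_line
from reefbudget import (
    EchinoidBelt,
    RateTable,
    SurveyError,
    borer_erosion,
    echinoid_erosion,
    parrotfish_erosion,
    total_bioerosion,
)
from reefbudget.erosion import ErosionBreakdown, echinoid_belt_rate, echinoid_rates_by_transect

# independent numeric evaluation of the Diadema power law at X=30 mm,
# e=1 m^-2, a=0.0029, b=1.6624: ((0.0029*30**1.6624)*1*365/60)/1000
DIADEMA_30MM_UNIT_DENSITY_G = 0.00503623498757771

ALL_AVAILABLE = [(100, "dead_coral")]
ALL_SAND = [(100, "sand")]


class TestBorers:
    def test_zero_on_bare_sand(self):
        assert borer_erosion(build_line(ALL_SAND), RateTable()) == 0.0

    def test_printed_constants_on_full_substrate(self):
        # R=1, f_avail=1: 1 * 1 * (0.052 + 0.053) = 0.105 G
        line = build_line(ALL_AVAILABLE, rugosity=(1.0, 1.0, 1.0))
        assert borer_erosion(line, RateTable()) == pytest.approx(0.105)

    def test_bilinear_in_rugosity_and_substrate(self):
        half = build_line(
            [(50, "dead_coral"), (50, "sand")], rugosity=(2.0, 2.0, 2.0)
        )
        full = build_line(ALL_AVAILABLE, rugosity=(1.0, 1.0, 1.0))
        rates = RateTable()
        assert borer_erosion(half, rates) == pytest.approx(borer_erosion(full, rates))


class TestParrotfish:
    def test_full_substrate_yields_published_rate(self):
        line = build_line(ALL_AVAILABLE, rugosity=(2.5, 2.5, 2.5))
        assert parrotfish_erosion(line, RateTable()) == pytest.approx(3.81)

    def test_scales_with_available_fraction(self):
        line = build_line([(50, "rubble"), (50, "sand")])
        assert parrotfish_erosion(line, RateTable()) == pytest.approx(1.905)
        assert parrotfish_erosion(build_line(ALL_SAND), RateTable()) == 0.0

    def test_optional_rugosity_scaling(self):
        line = build_line(ALL_AVAILABLE, rugosity=(2.0, 2.0, 2.0))
        rates = RateTable()
        assert parrotfish_erosion(line, rates, use_rugosity=True) == pytest.approx(
            2 * parrotfish_erosion(line, rates)
        )


class TestEchinoids:
    def test_zero_urchins_zero_rate(self):
        belt = EchinoidBelt("B1", "SW", 2, records=())
        assert echinoid_erosion([belt], RateTable()) == 0.0

    def test_diadema_power_law_value(self):
        # one genus at unit density: 30 urchins on 30 m^2
        belt = EchinoidBelt("B1", "SW", 2, records=(("Diadema", 30.0, 30),))
        assert echinoid_belt_rate(belt, RateTable()) == pytest.approx(
            DIADEMA_30MM_UNIT_DENSITY_G, rel=1e-12
        )

    def test_linear_in_density(self):
        b1 = EchinoidBelt("B1", "SW", 2, records=(("Diadema", 30.0, 3),))
        b2 = EchinoidBelt("B2", "SW", 2, records=(("Diadema", 30.0, 6),))
        rates = RateTable()
        assert echinoid_belt_rate(b2, rates) == pytest.approx(
            2 * echinoid_belt_rate(b1, rates), rel=1e-12
        )

    def test_density_is_per_square_metre_not_per_belt(self):
        # same density, different area -> same rate
        rates = RateTable()
        b30 = EchinoidBelt("B1", "SW", 2, records=(("Diadema", 30.0, 3),), area_m2=30)
        b60 = EchinoidBelt("B2", "SW", 2, records=(("Diadema", 30.0, 6),), area_m2=60)
        assert echinoid_belt_rate(b30, rates) == pytest.approx(
            echinoid_belt_rate(b60, rates), rel=1e-12
        )

    def test_zero_area_rejected(self):
        with pytest.raises(SurveyError):
            EchinoidBelt("B1", "SW", 2, records=(), area_m2=0.0)

    def test_empty_belt_collection_rejected(self):
        with pytest.raises(SurveyError):
            echinoid_erosion([], RateTable())

    def test_verbatim_phyllocanthus_mode_is_selectable(self):
        belt = EchinoidBelt("B1", "SW", 2, records=(("Phyllocanthus", 90.0, 3),))
        default = echinoid_belt_rate(belt, RateTable())
        verbatim = echinoid_belt_rate(belt, RateTable().verbatim_phyllocanthus())
        assert verbatim == pytest.approx(default * 1e10, rel=1e-9)

    def test_unsurveyed_transect_gets_reef_wide_mean(self):
        rates = RateTable()
        belts = [
            EchinoidBelt("B1", "SW", 2, records=(("Diadema", 30.0, 3),)),
            EchinoidBelt("B2", "NW", 2, records=(("Diadema", 30.0, 9),)),
        ]
        by_t = echinoid_rates_by_transect(belts, rates, ["SW", "NW", "N"])
        assert by_t["SW"] == pytest.approx(echinoid_belt_rate(belts[0], rates))
        assert by_t["N"] == pytest.approx((by_t["SW"] + by_t["NW"]) / 2)


class TestBreakdown:
    def test_components_sum_exactly_and_shares(self):
        br = ErosionBreakdown(borer_G=0.2, parrotfish_G=3.0, echinoid_G=0.003)
        assert br.total_G == 0.2 + 3.0 + 0.003
        shares = br.shares_pct
        assert shares["parrotfish"] == pytest.approx(100 * 3.0 / 3.203)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_zero_components_have_empty_shares(self):
        assert ErosionBreakdown(0.0, 0.0, 0.0).shares_pct == {}

    def test_total_bioerosion_composes_the_three_terms(self):
        line = build_line(
            [(40, "dead_coral"), (20, "live_coral", "massive", "Porites"), (40, "sand")],
            rugosity=(2.0, 2.0, 2.0),
        )
        belts = [EchinoidBelt("B1", "N", 3, records=(("Diadema", 30.0, 3),))]
        rates = RateTable()
        br = total_bioerosion(line, belts, rates)
        assert br.borer_G == pytest.approx(borer_erosion(line, rates))
        assert br.parrotfish_G == pytest.approx(parrotfish_erosion(line, rates))
        assert br.echinoid_G == pytest.approx(echinoid_belt_rate(belts[0], rates))
        assert br.total_G == br.borer_G + br.parrotfish_G + br.echinoid_G


@settings(deadline=None, max_examples=30)
@given(
    n_avail=st.integers(min_value=0, max_value=100),
    extra_avail=st.integers(min_value=0, max_value=100),
    macro=st.floats(min_value=0, max_value=0.2, allow_nan=False),
    parrot=st.floats(min_value=0, max_value=6, allow_nan=False),
    bump=st.floats(min_value=0, max_value=2, allow_nan=False),
)
def test_total_erosion_monotone_in_substrate_and_rates(
    n_avail, extra_avail, macro, parrot, bump
):
    n_hi = min(100, n_avail + extra_avail)

    def make(n):
        spec = ([(n, "dead_coral")] if n else []) + (
            [(100 - n, "sand")] if n < 100 else []
        )
        return build_line(spec, rugosity=(2.0, 2.0, 2.0))

    lo_rates = RateTable(macro_borer_rate=macro, parrotfish_rate=parrot)
    hi_rates = RateTable(
        macro_borer_rate=macro + bump, parrotfish_rate=parrot + bump
    )
    lo = total_bioerosion(make(n_avail), None, lo_rates).total_G
    hi_substrate = total_bioerosion(make(n_hi), None, lo_rates).total_G
    hi_rate = total_bioerosion(make(n_avail), None, hi_rates).total_G
    assert hi_substrate >= lo - 1e-12
    assert hi_rate >= lo - 1e-12
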