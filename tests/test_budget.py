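"""Net budget assembly, aggregation and the cover-threshold regression."""

import math

import numpy as np
import pytest

from conftest import build_line
from reefbudget import (
    BudgetConfig,
    BudgetResult,
    RateTable,
    SurveyError,
    aggregate,
    cover_threshold,
    line_budgets,
    net_budget,
)

NAN = float("nan")


def make_line_result(
    gross=0.0,
    borer=0.0,
    parrotfish=0.0,
    echinoid=0.0,
    cover=0.0,
    rugosity=1.0,
    line_id="L1",
    transect="N",
    zone=3,
):
    total = borer + parrotfish + echinoid
    return BudgetResult(
        scope="line",
        line_id=line_id,
        transect_id=transect,
        zone_id=zone,
        n_lines=1,
        live_cover_pct=(cover, NAN),
        rugosity=(rugosity, NAN),
        gross_G=(gross, NAN),
        borer_G=(borer, NAN),
        parrotfish_G=(parrotfish, NAN),
        echinoid_G=(echinoid, NAN),
        total_erosion_G=(total, NAN),
        net_G=(gross - total, NAN),
    )


class TestNetBudget:
    def test_net_is_gross_minus_erosion_exactly(self, simple_rates):
        line = build_line(
            [
                (20, "live_coral", "massive", "Porites"),
                (40, "dead_coral"),
                (40, "sand"),
            ],
            rugosity=(2.5, 2.5, 2.5),
        )
        r = net_budget(line, None, simple_rates)
        assert r.net_G[0] == r.gross_G[0] - r.total_erosion_G[0]
        assert r.total_erosion_G[0] == (
            r.borer_G[0] + r.parrotfish_G[0] + r.echinoid_G[0]
        )

    def test_subtraction_matches_reported_style_numbers(self):
        # a budget with gross 5.9 and erosion 3.4 nets 2.5
        r = make_line_result(gross=5.9, parrotfish=3.4)
        assert r.net_G[0] == pytest.approx(2.5)

    def test_all_sand_line_has_zero_budget(self, simple_rates):
        r = net_budget(build_line([(100, "sand")]), None, simple_rates)
        assert r.gross_G[0] == 0.0
        assert r.total_erosion_G[0] == 0.0
        assert r.net_G[0] == 0.0

    def test_negative_net_is_permitted(self):
        # dead framework with a sliver of low-Ci coral: erosion > gross
        rates = RateTable(
            calcification={("Porites", "massive"): 0.5},
            morphology_defaults={"massive": 0.5},
        )
        line = build_line(
            [(2, "live_coral", "massive", "Porites"), (98, "dead_coral")],
            rugosity=(1.5, 1.5, 1.5),
        )
        r = net_budget(line, None, rates)
        assert r.net_G[0] < 0

    def test_zero_rate_constants_make_net_equal_gross(self, simple_rates):
        from dataclasses import replace

        rates = replace(
            simple_rates,
            macro_borer_rate=0.0,
            micro_borer_rate=0.0,
            parrotfish_rate=0.0,
        )
        line = build_line(
            [(30, "live_coral", "massive", "Porites"), (70, "dead_coral")]
        )
        r = net_budget(line, None, rates)
        assert r.net_G[0] == r.gross_G[0]


class TestAggregation:
    def test_identical_lines_have_zero_sd(self):
        lines = [
            make_line_result(gross=4.0, parrotfish=1.0, line_id=f"L{i}")
            for i in range(3)
        ]
        (zone,) = aggregate(lines, "zone")
        assert zone.net_G == (3.0, 0.0)
        assert zone.n_lines == 3

    def test_sample_sd_of_three_known_nets(self):
        lines = [
            make_line_result(gross=g, line_id=f"L{i}")
            for i, g in enumerate((1.0, 2.0, 6.0))
        ]
        (zone,) = aggregate(lines, "zone")
        assert zone.net_G[0] == pytest.approx(3.0)
        assert zone.net_G[1] == pytest.approx(math.sqrt(7.0))  # sample (n-1) SD

    def test_reef_scope_averages_transect_means(self):
        lines = [
            make_line_result(gross=2.0, transect="N", line_id="a"),
            make_line_result(gross=2.0, transect="N", line_id="b"),
            make_line_result(gross=4.0, transect="SE", line_id="c"),
        ]
        (reef,) = aggregate(lines, "reef")
        # transect means (2, 4) -> reef mean 3, not the pooled-line 8/3
        assert reef.net_G[0] == pytest.approx(3.0)
        (pooled,) = aggregate(lines, "reef", BudgetConfig(reef_scope="pooled_lines"))
        assert pooled.net_G[0] == pytest.approx(8.0 / 3.0)

    def test_sand_moat_lines_are_excluded_with_warning(self):
        lines = [
            make_line_result(gross=1.0, zone=1, line_id="moat"),
            make_line_result(gross=5.0, zone=3, line_id="flat"),
        ]
        with pytest.warns(UserWarning, match="sand-moat"):
            (reef,) = aggregate(lines, "reef")
        assert reef.net_G[0] == pytest.approx(5.0)
        assert reef.n_lines == 1

    def test_empty_aggregation_warns_and_returns_nothing(self):
        only_moat = [make_line_result(zone=1)]
        with pytest.warns(UserWarning):
            assert aggregate(only_moat, "transect") == []

    def test_exact_mean_accounting_at_every_scope(self, simple_rates):
        from reefbudget.synthetic import default_mahutigala_scenario, generate

        ds = generate(default_mahutigala_scenario(), seed=3)
        lr = line_budgets(ds.lines, ds.belts, simple_rates)
        for level in ("zone", "transect", "reef"):
            for r in aggregate(lr, level):
                assert r.net_G[0] == r.gross_G[0] - r.total_erosion_G[0]
                assert r.total_erosion_G[0] == (
                    r.borer_G[0] + r.parrotfish_G[0] + r.echinoid_G[0]
                )


class TestCoverThreshold:
    def test_noiseless_line_recovers_exact_intercept(self):
        covers = np.array([2.0, 8.0, 15.0, 22.0, 30.0])
        pts = [(c, 0.25 * c - 2.5) for c in covers]
        fit = cover_threshold(pts)
        assert fit.slope == pytest.approx(0.25, abs=1e-10)
        assert fit.intercept == pytest.approx(-2.5, abs=1e-9)
        assert fit.x_intercept_pct == pytest.approx(10.0, abs=1e-8)

    def test_degenerate_cover_variance_errors(self):
        with pytest.raises(SurveyError, match="degenerate"):
            cover_threshold([(10.0, 1.0), (10.0, 2.0), (10.0, 3.0)])

    def test_flat_response_reports_no_threshold(self):
        pts = [(5.0, 1.0), (10.0, 1.0), (20.0, 1.0), (30.0, 1.0)]
        fit = cover_threshold(pts)
        assert fit.x_intercept_pct is None
        assert fit.diagnostic is not None

    def test_too_few_points_rejected(self):
        with pytest.raises(SurveyError):
            cover_threshold([(1.0, 1.0), (2.0, 2.0)])

    def test_fieller_interval_brackets_the_estimate(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(4, 35, size=40)
        y = 0.25 * x - 2.5 + rng.normal(0, 0.8, size=40)
        fit = cover_threshold(list(zip(x, y)))
        assert fit.ci95 is not None
        lo, hi = fit.ci95
        assert lo < fit.x_intercept_pct < hi
        # the band inversion should be wider than a naive delta interval of
        # zero width and contained within the data's cover span, loosely
        assert hi - lo < 30


def test_bootstrap_interval_agrees_with_fieller_roughly():
    rng = np.random.default_rng(5)
    x = rng.uniform(4, 35, size=60)
    y = 0.25 * x - 2.5 + rng.normal(0, 0.8, size=60)
    pts = list(zip(x, y))
    fit = cover_threshold(pts)
    from reefbudget import cover_threshold_bootstrap

    lo, hi = cover_threshold_bootstrap(pts, seed=1)
    assert lo < fit.x_intercept_pct < hi
    # both intervals target the same quantity; centres should be close
    assert (lo + hi) / 2 == pytest.approx(fit.x_intercept_pct, abs=1.0)


def test_bootstrap_rejects_flat_response():
    pts = [(5.0, 1.0), (10.0, 1.0), (20.0, 1.0), (30.0, 1.0), (35.0, 1.0)]
    from reefbudget import cover_threshold_bootstrap

    with pytest.raises(SurveyError, match="bootstrap"):
        cover_threshold_bootstrap(pts, seed=0)
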