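"""Model/Results facade over the carbonate-budget pipeline.

``ReefBudgetModel`` is built from survey data (in memory or from the CSV
schemas) together with a rate table; ``fit()`` runs the full census-based
budget — gross production, the three erosion components, net G — at line
scope and aggregates it to zone, transect and reef scope, returning a
``ReefBudgetResults`` that carries the estimates with their dispersion,
the morphology composition of production, the cover-threshold regression,
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import io as rbio
from .budget import (
    BudgetConfig,
    BudgetResult,
    ThresholdFit,
    aggregate,
    cover_threshold,
    line_budgets,
)
from .production import production_by_morphology
from .rates import RateTable
from .survey import SAND_MOAT_ZONE, EchinoidBelt, SurveyError, SurveyLine

__all__ = ["ReefBudgetModel", "ReefBudgetResults"]


def _results_frame(results: Sequence[BudgetResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "scope": r.scope,
            "line_id": r.line_id,
            "transect_id": r.transect_id,
            "zone_id": r.zone_id,
            "n_lines": r.n_lines,
        }
        for m in (
            "live_cover_pct",
            "rugosity",
            "gross_G",
            "borer_G",
            "parrotfish_G",
            "echinoid_G",
            "total_erosion_G",
            "net_G",
        ):
            mean, sd = r.metric(m)
            row[f"{m}_mean"] = mean
            row[f"{m}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


class ReefBudgetModel:
    """Census-based reef-flat carbonate budget model.

    Parameters
    ----------
    lines : sequence of SurveyLine
        Complete survey lines with rugosity sections attached.
    belts : sequence of EchinoidBelt, optional
        Urchin belt transects; echinoid erosion is 0 without them.
    rates : RateTable, optional
        Calcification and erosion constants (defaults to the placeholder
        table — inject an explicit table for real analyses).
    config : BudgetConfig, optional
        Aggregation and sensitivity switches.
    """

    def __init__(
        self,
        lines: Sequence[SurveyLine],
        belts: Sequence[EchinoidBelt] | None = None,
        rates: RateTable | None = None,
        config: BudgetConfig | None = None,
    ) -> None:
        self.lines = list(lines)
        if not self.lines:
            raise SurveyError("ReefBudgetModel requires at least one survey line")
        self.belts = list(belts) if belts else []
        self.rates = rates or RateTable.default()
        self.config = config or BudgetConfig()

    @classmethod
    def from_csv(
        cls,
        observations,
        rugosity,
        belts=None,
        rates=None,
        erosion_config=None,
        config: BudgetConfig | None = None,
    ) -> "ReefBudgetModel":
        """Build a model from the CSV file schemas.

        ``rates`` may be a rates.csv path or a RateTable; ``erosion_config``
        an optional YAML key-value file overriding the erosion constants.
        """
        lines = rbio.load_survey(observations, rugosity)
        belt_objs = rbio.read_belts(belts) if belts is not None else []
        if rates is None:
            table = RateTable.default()
        elif isinstance(rates, RateTable):
            table = rates
        else:
            table = RateTable.from_csv(rates)
        if erosion_config is not None:
            table = rbio.apply_erosion_config(table, rbio.read_erosion_config(erosion_config))
        return cls(lines, belt_objs, table, config)

    def fit(self) -> "ReefBudgetResults":
        """Run the budget at every scope and return the results object."""
        lr = line_budgets(self.lines, self.belts, self.rates, self.config)
        productive = [
            line
            for line in self.lines
            if self.config.include_sand_moat or line.zone_id != SAND_MOAT_ZONE
        ]
        return ReefBudgetResults(
            model=self,
            line_results=lr,
            zone_results=aggregate(lr, "zone", self.config),
            transect_results=aggregate(lr, "transect", self.config),
            reef_result=aggregate(lr, "reef", self.config)[0],
            morphology_shares=production_by_morphology(productive, self.rates)
            if productive
            else {},
        )


@dataclass
class ReefBudgetResults:
    """Fitted budget: per-scope results, composition, threshold, summary."""

    model: ReefBudgetModel
    line_results: list[BudgetResult]
    zone_results: list[BudgetResult]
    transect_results: list[BudgetResult]
    reef_result: BudgetResult
    morphology_shares: dict[str, float] = field(default_factory=dict)

    def frame(self, scope: str = "all") -> pd.DataFrame:
        """Results as a tidy DataFrame (scope: line/zone/transect/reef/all)."""
        by_scope = {
            "line": self.line_results,
            "zone": self.zone_results,
            "transect": self.transect_results,
            "reef": [self.reef_result],
        }
        if scope == "all":
            results = [r for rs in by_scope.values() for r in rs]
        elif scope in by_scope:
            results = by_scope[scope]
        else:
            raise SurveyError(f"unknown scope {scope!r}")
        return _results_frame(results)

    def to_budget_csv(self, path, include_lines: bool = True) -> None:
        """Write budget.csv (one row per result scope)."""
        scope = "all" if include_lines else "zone"
        if include_lines:
            df = self.frame("all")
        else:
            df = pd.concat(
                [self.frame("zone"), self.frame("transect"), self.frame("reef")],
                ignore_index=True,
            )
        cols = [c for c in rbio.BUDGET_COLUMNS if c in df.columns]
        df[cols].to_csv(path, index=False)

    def erosion_shares_pct(self) -> dict[str, float]:
        """Reef-scope percent share of each erosion component."""
        total = self.reef_result.total_erosion_G[0]
        if total <= 0:
            return {}
        return {
            "borer": 100.0 * self.reef_result.borer_G[0] / total,
            "parrotfish": 100.0 * self.reef_result.parrotfish_G[0] / total,
            "echinoid": 100.0 * self.reef_result.echinoid_G[0] / total,
        }

    def cover_threshold(self, scope: str = "line") -> ThresholdFit:
        """OLS cover-vs-net-G threshold fit at line (default) or zone scope."""
        if scope == "line":
            pts = [
                (r.live_cover_pct[0], r.net_G[0])
                for r in self.line_results
                if self.model.config.include_sand_moat or r.zone_id != SAND_MOAT_ZONE
            ]
        elif scope == "zone":
            pts = [(r.live_cover_pct[0], r.net_G[0]) for r in self.zone_results]
        else:
            raise SurveyError(f"unknown threshold scope {scope!r}")
        return cover_threshold(pts)

    def summary(self) -> str:
        """Plain-text summary of the reef-scope budget."""
        r = self.reef_result
        shares = self.erosion_shares_pct()
        lines = [
            "Reef-flat carbonate budget (census-based)",
            "=" * 57,
            f"survey lines: {len(self.line_results)}   "
            f"productive lines: {r.n_lines}   "
            f"transects: {len(self.transect_results)}   "
            f"belts: {len(self.model.belts)}",
            "",
            "Reef scope ("
            + (
                "mean of transect means, +/- SD over transects"
                if self.model.config.reef_scope == "transect_means"
                else "pooled lines, +/- SD over lines"
            )
            + "):",
            f"  live coral cover    {r.live_cover_pct[0]:6.1f} +/- {r.live_cover_pct[1]:.1f} %",
            f"  rugosity R          {r.rugosity[0]:6.2f} +/- {r.rugosity[1]:.2f}",
            f"  gross production    {r.gross_G[0]:6.1f} +/- {r.gross_G[1]:.1f} G",
            f"  total bioerosion    {r.total_erosion_G[0]:6.1f} +/- {r.total_erosion_G[1]:.1f} G"
            + (
                f"   (parrotfish {shares['parrotfish']:.1f}%, borers "
                f"{shares['borer']:.1f}%, echinoids {shares['echinoid']:.1f}%)"
                if shares
                else ""
            ),
            f"  net production      {r.net_G[0]:6.1f} +/- {r.net_G[1]:.1f} G",
        ]
        if self.morphology_shares:
            comp = ", ".join(
                f"{m} {100 * s:.1f}%"
                for m, s in sorted(
                    self.morphology_shares.items(), key=lambda kv: -kv[1]
                )
            )
            lines += ["", f"Production by morphology: {comp}"]
        try:
            thr = self.cover_threshold()
            if thr.x_intercept_pct is not None:
                ci = (
                    f" (95% CI {thr.ci95[0]:.1f}-{thr.ci95[1]:.1f})"
                    if thr.ci95
                    else ""
                )
                lines += [
                    "",
                    f"Live-cover threshold for net G > 0: "
                    f"{thr.x_intercept_pct:.1f}%{ci}  "
                    f"[slope {thr.slope:.3f} G/%, R^2 {thr.r_squared:.2f}, "
                    f"n {thr.n_points}]",
                ]
        except SurveyError:
            pass
        lines += ["", "G = kg CaCO3 m-2 yr-1"]
        return "\n".join(lines)
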