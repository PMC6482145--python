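"""Net budget assembly, hierarchical aggregation and the cover threshold.

Net carbonate production of a line is gross production minus total
bioerosion.  Line results aggregate upward with unweighted arithmetic
means and sample (n-1) standard deviations: lines -> (transect, zone)
groups -> transects -> the reef, where the reef-scope mean averages
transect means ("average of all radial transects"); pooled-line averaging
is available as an option.  Sand-moat (zone 1) lines are excluded from
productive-zone aggregates.

Mean accounting is exact at every scope: the aggregated net mean is
computed as gross mean minus total-erosion mean, and the total-erosion
mean as the sum of the component means, so the budget identity holds to
the last bit rather than up to float-summation order.

The live-coral-cover threshold for budget positivity is an ordinary
least-squares fit of net G on percent live cover; the zero-crossing
x-intercept is -intercept/slope, with a 95% interval obtained by
inverting the confidence band for the mean response (Fieller's method).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm

from .erosion import echinoid_rates_by_transect, total_bioerosion
from .production import gross_production
from .rates import RateTable
from .survey import (
    SAND_MOAT_ZONE,
    EchinoidBelt,
    SurveyError,
    SurveyLine,
    percent_cover,
    rugosity_coefficient,
)

__all__ = [
    "BudgetConfig",
    "BudgetResult",
    "ThresholdFit",
    "net_budget",
    "line_budgets",
    "aggregate",
    "cover_threshold",
    "cover_threshold_bootstrap",
]

_METRICS = (
    "live_cover_pct",
    "rugosity",
    "gross_G",
    "borer_G",
    "parrotfish_G",
    "echinoid_G",
    "total_erosion_G",
    "net_G",
)


@dataclass(frozen=True)
class BudgetConfig:
    """Switches for the genuinely open methodological choices.

    parrotfish_uses_rugosity
        Scale the parrotfish rate by R (default off: the published rate is
        per planar area).
    reef_scope
        "transect_means" (default) averages transect means at reef scope;
        "pooled_lines" averages all productive lines directly.
    include_sand_moat
        Keep zone-1 lines in aggregates (default off: the moat holds no
        producers and is excluded from ecological analyses).
    """

    parrotfish_uses_rugosity: bool = False
    reef_scope: str = "transect_means"
    include_sand_moat: bool = False

    def __post_init__(self) -> None:
        if self.reef_scope not in ("transect_means", "pooled_lines"):
            raise SurveyError(f"unknown reef_scope {self.reef_scope!r}")


@dataclass(frozen=True)
class BudgetResult:
    """Budget numbers (mean +/- sample SD) at one scope.

    scope is one of "line", "zone", "transect", "reef"; identifiers not
    applicable at a scope are None.  At line scope every sd is NaN and
    n_lines is 1.  All G metrics are kg CaCO3 m^-2 yr^-1.
    """

    scope: str
    line_id: str | None
    transect_id: str | None
    zone_id: int | None
    n_lines: int
    live_cover_pct: tuple[float, float]
    rugosity: tuple[float, float]
    gross_G: tuple[float, float]
    borer_G: tuple[float, float]
    parrotfish_G: tuple[float, float]
    echinoid_G: tuple[float, float]
    total_erosion_G: tuple[float, float]
    net_G: tuple[float, float]

    def metric(self, name: str) -> tuple[float, float]:
        if name not in _METRICS:
            raise KeyError(name)
        return getattr(self, name)


def net_budget(
    line: SurveyLine,
    belts: Sequence[EchinoidBelt] | dict[str, float] | float | None,
    rates: RateTable,
    config: BudgetConfig | None = None,
) -> BudgetResult:
    """Line-scope budget: gross production, erosion components, net G."""
    config = config or BudgetConfig()
    gross, _ = gross_production(line, rates)
    erosion = total_bioerosion(
        line, belts, rates, parrotfish_uses_rugosity=config.parrotfish_uses_rugosity
    )
    cover = percent_cover(line, key="category")["live_coral"]
    nan = float("nan")
    return BudgetResult(
        scope="line",
        line_id=line.line_id,
        transect_id=line.transect_id,
        zone_id=line.zone_id,
        n_lines=1,
        live_cover_pct=(cover, nan),
        rugosity=(rugosity_coefficient(line), nan),
        gross_G=(gross, nan),
        borer_G=(erosion.borer_G, nan),
        parrotfish_G=(erosion.parrotfish_G, nan),
        echinoid_G=(erosion.echinoid_G, nan),
        total_erosion_G=(erosion.total_G, nan),
        net_G=(gross - erosion.total_G, nan),
    )


def line_budgets(
    lines: Sequence[SurveyLine],
    belts: Sequence[EchinoidBelt] | None,
    rates: RateTable,
    config: BudgetConfig | None = None,
) -> list[BudgetResult]:
    """Line-scope budgets for a whole survey, resolving echinoid rates once."""
    config = config or BudgetConfig()
    transects = sorted({line.transect_id for line in lines})
    echinoid_by_transect = echinoid_rates_by_transect(belts or [], rates, transects)
    return [net_budget(line, echinoid_by_transect, rates, config) for line in lines]


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd


def _aggregate_group(
    members: Sequence[BudgetResult],
    scope: str,
    transect_id: str | None,
    zone_id: int | None,
) -> BudgetResult:
    stats = {m: _mean_sd([r.metric(m)[0] for r in members]) for m in _METRICS}
    # enforce exact mean accounting (see module docstring)
    total_mean = (
        stats["borer_G"][0] + stats["parrotfish_G"][0] + stats["echinoid_G"][0]
    )
    stats["total_erosion_G"] = (total_mean, stats["total_erosion_G"][1])
    stats["net_G"] = (stats["gross_G"][0] - total_mean, stats["net_G"][1])
    return BudgetResult(
        scope=scope,
        line_id=None,
        transect_id=transect_id,
        zone_id=zone_id,
        n_lines=sum(r.n_lines for r in members),
        **stats,
    )


def aggregate(
    results: Iterable[BudgetResult],
    level: str,
    config: BudgetConfig | None = None,
) -> list[BudgetResult]:
    """Aggregate line-scope results to zone, transect or reef scope.

    "zone" groups lines by (transect, zone) — the triplet of replicate
    lines; "transect" pools a transect's productive-zone lines; "reef"
    averages transect means (or pools lines, per config).  Empty groups
    are omitted with a warning.
    """
    config = config or BudgetConfig()
    results = [r for r in results if r.scope == "line"]
    if not config.include_sand_moat:
        dropped = [r for r in results if r.zone_id == SAND_MOAT_ZONE]
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} sand-moat (zone {SAND_MOAT_ZONE}) "
                f"line(s) from {level}-scope aggregation",
                UserWarning,
                stacklevel=2,
            )
        results = [r for r in results if r.zone_id != SAND_MOAT_ZONE]
    if not results:
        warnings.warn("no lines to aggregate", UserWarning, stacklevel=2)
        return []

    if level == "zone":
        keys = sorted({(r.transect_id, r.zone_id) for r in results})
        return [
            _aggregate_group(
                [r for r in results if (r.transect_id, r.zone_id) == key],
                "zone",
                key[0],
                key[1],
            )
            for key in keys
        ]
    if level == "transect":
        keys = sorted({r.transect_id for r in results})
        return [
            _aggregate_group(
                [r for r in results if r.transect_id == key], "transect", key, None
            )
            for key in keys
        ]
    if level == "reef":
        if config.reef_scope == "pooled_lines":
            return [_aggregate_group(results, "reef", None, None)]
        transect_results = aggregate(results, "transect", config)
        stats = {
            m: _mean_sd([t.metric(m)[0] for t in transect_results]) for m in _METRICS
        }
        total_mean = (
            stats["borer_G"][0] + stats["parrotfish_G"][0] + stats["echinoid_G"][0]
        )
        stats["total_erosion_G"] = (total_mean, stats["total_erosion_G"][1])
        stats["net_G"] = (stats["gross_G"][0] - total_mean, stats["net_G"][1])
        return [
            BudgetResult(
                scope="reef",
                line_id=None,
                transect_id=None,
                zone_id=None,
                n_lines=sum(t.n_lines for t in transect_results),
                **stats,
            )
        ]
    raise SurveyError(f"unknown aggregation level {level!r}")


@dataclass(frozen=True)
class ThresholdFit:
    """OLS fit of net G on live coral cover and its zero-crossing.

    x_intercept_pct is the live cover at which predicted net G crosses
    zero (None when the slope is not significantly positive, in which
    case ``diagnostic`` explains why); ci95 is the Fieller interval from
    inverting the 95% confidence band for the mean response.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    slope_pvalue: float
    r_squared: float
    n_points: int
    x_intercept_pct: float | None
    ci95: tuple[float, float] | None
    diagnostic: str | None = None

    def predict(self, cover_pct: float) -> float:
        return self.intercept + self.slope * cover_pct


def cover_threshold(
    points: Sequence[tuple[float, float]], alpha: float = 0.05
) -> ThresholdFit:
    """Live-coral-cover threshold for a positive budget, by OLS inversion.

    ``points`` are (live_cover_pct, net_G) pairs, typically line-scope.
    Requires >= 3 points with non-degenerate cover variance.  The
    threshold is reported only when the slope is positive and significant
    at ``alpha`` (two-sided); otherwise the fit is returned with a
    diagnostic and no threshold.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise SurveyError("cover_threshold requires >= 3 (cover, net_G) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise SurveyError("degenerate cover values: no variance in x")

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        # a noiseless line gives zero residual variance; that is a valid
        # degenerate input here, not a user error
        warnings.simplefilter("ignore")
        fit = sm.OLS(y, X).fit()
        b0, b1 = float(fit.params[0]), float(fit.params[1])
        cov = np.asarray(fit.cov_params())
        conf = np.asarray(fit.conf_int(alpha=alpha))
        pvalue = float(fit.pvalues[1])

    n = len(x)
    base = dict(
        slope=b1,
        intercept=b0,
        slope_se=float(np.sqrt(cov[1, 1])),
        intercept_se=float(np.sqrt(cov[0, 0])),
        slope_ci=(float(conf[1, 0]), float(conf[1, 1])),
        intercept_ci=(float(conf[0, 0]), float(conf[0, 1])),
        slope_pvalue=pvalue,
        r_squared=float(fit.rsquared) if not math.isnan(fit.rsquared) else 1.0,
        n_points=n,
    )

    ssr = float(fit.ssr)
    noiseless = ssr <= max(1e-12 * float(np.sum(y**2)), 1e-300)
    # in the noiseless case the slope must also clear float round-off on
    # the data's own scale, else a flat response would look "significant"
    slope_floor = 1e-9 * (float(np.max(np.abs(y))) + np.finfo(float).eps) / float(np.ptp(x))
    if noiseless:
        # p-values are meaningless at zero residual variance (se = 0)
        significant = b1 > slope_floor
    else:
        significant = b1 > 0 and pvalue < alpha
    if not significant:
        reason = (
            "slope is not positive" if b1 <= 0 else
            f"slope not significant at alpha={alpha} (p={pvalue:.3g})"
        )
        return ThresholdFit(
            **base, x_intercept_pct=None, ci95=None, diagnostic=reason
        )

    x0 = -b0 / b1
    if noiseless:
        return ThresholdFit(**base, x_intercept_pct=x0, ci95=(x0, x0))

    # Fieller: solve (b0 + b1*x)^2 = t^2 * (v00 + 2*x*v01 + x^2*v11)
    t = scipy.stats.t.ppf(1 - alpha / 2, n - 2)
    v00, v01, v11 = cov[0, 0], cov[0, 1], cov[1, 1]
    A = b1**2 - t**2 * v11
    B = b0 * b1 - t**2 * v01
    C = b0**2 - t**2 * v00
    ci: tuple[float, float] | None
    if A > 0 and B**2 - A * C >= 0:
        root = math.sqrt(B**2 - A * C)
        lo, hi = (-B - root) / A, (-B + root) / A
        ci = (min(lo, hi), max(lo, hi))
    else:
        # band never excludes zero on one side: interval unbounded
        ci = None
    return ThresholdFit(**base, x_intercept_pct=x0, ci95=ci)


def cover_threshold_bootstrap(
    points: Sequence[tuple[float, float]],
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap interval for the cover threshold.

    Case-resamples the (cover, net_G) points, refits OLS and collects the
    x-intercept; resamples with a non-positive slope or degenerate cover
    are discarded (they carry no crossing).  An alternative to the
    Fieller interval of :func:`cover_threshold` when the OLS error model
    is in doubt.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise SurveyError("bootstrap requires >= 3 points")
    rng = np.random.default_rng(seed)
    n = pts.shape[0]
    crossings = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        x, y = pts[idx, 0], pts[idx, 1]
        if np.ptp(x) == 0:
            continue
        b1, b0 = np.polyfit(x, y, 1)
        if b1 > 0:
            crossings.append(-b0 / b1)
    if len(crossings) < n_boot // 2:
        raise SurveyError(
            "bootstrap threshold undefined: slope not reliably positive"
        )
    lo, hi = np.quantile(crossings, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
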