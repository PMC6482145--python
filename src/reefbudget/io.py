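"""CSV readers and writers for survey inputs and budget outputs.

Schemas (UTF-8, header required):

- observations.csv: line_id,transect_id,zone_id,position_cm,category,morphology,taxon
- rugosity.csv:     line_id,section_index,chain_ratio
- rates.csv:        taxon,morphology,ci_g_cm2_yr,source
- belts.csv:        belt_id,transect_id,zone_id,area_m2,genus,test_size_mm,count
- erosion config:   YAML key-value file (macro_borer_rate, micro_borer_rate,
                    parrotfish_rate, echinoid_coeffs overrides)

Empty ``taxon`` cells round-trip as ``None``.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .rates import ECHINOID_SIZE_EXPONENT, RateTable
from .survey import (
    POINTS_PER_LINE,
    BenthicObservation,
    EchinoidBelt,
    SurveyError,
    SurveyLine,
)

OBSERVATION_COLUMNS = [
    "line_id",
    "transect_id",
    "zone_id",
    "position_cm",
    "category",
    "morphology",
    "taxon",
]

BUDGET_COLUMNS = [
    "scope",
    "line_id",
    "transect_id",
    "zone_id",
    "n_lines",
    "live_cover_pct_mean",
    "live_cover_pct_sd",
    "rugosity_mean",
    "rugosity_sd",
    "gross_G_mean",
    "gross_G_sd",
    "borer_G_mean",
    "parrotfish_G_mean",
    "echinoid_G_mean",
    "total_erosion_G_mean",
    "total_erosion_G_sd",
    "net_G_mean",
    "net_G_sd",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyError(f"{what} is missing column(s): {missing}")


def read_observations(path) -> list[SurveyLine]:
    """Read a point-intercept observations CSV into complete survey lines.

    Lines are returned without rugosity sections (see :func:`read_rugosity`
    / :func:`attach_rugosity`).  Incomplete lines (fewer or more than 100
    points) raise, naming the line and its count; malformed rows raise
    naming the file row.
    """
    df = pd.read_csv(path, dtype={"taxon": "string"})
    _require_columns(df, OBSERVATION_COLUMNS[:-1], "observations CSV")
    if "taxon" not in df.columns:
        df["taxon"] = pd.NA

    lines: list[SurveyLine] = []
    # preserve file order of first appearance per line
    for line_id, grp in df.groupby("line_id", sort=False):
        obs = []
        for idx, row in grp.iterrows():
            rowno = idx + 2  # header + 1-based
            try:
                taxon = row["taxon"]
                taxon = None if pd.isna(taxon) else str(taxon)
                obs.append(
                    BenthicObservation(
                        line_id=str(row["line_id"]),
                        position_cm=int(row["position_cm"]),
                        category=str(row["category"]),
                        morphology=str(row["morphology"]),
                        taxon=taxon,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise SurveyError(f"observations CSV row {rowno}: {exc}") from exc
        if len(obs) != POINTS_PER_LINE:
            raise SurveyError(
                f"line {line_id!r} has {len(obs)} observations; a complete line "
                f"has exactly {POINTS_PER_LINE}"
            )
        transects = grp["transect_id"].unique()
        zones = grp["zone_id"].unique()
        if len(transects) != 1 or len(zones) != 1:
            raise SurveyError(
                f"line {line_id!r} spans multiple transect/zone labels: "
                f"{list(transects)} / {list(zones)}"
            )
        obs.sort(key=lambda o: o.position_cm)
        lines.append(
            SurveyLine(
                line_id=str(line_id),
                transect_id=str(transects[0]),
                zone_id=int(zones[0]),
                observations=tuple(obs),
            )
        )
    return lines


def write_observations(lines: Iterable[SurveyLine], path) -> None:
    rows = [
        {
            "line_id": line.line_id,
            "transect_id": line.transect_id,
            "zone_id": line.zone_id,
            "position_cm": o.position_cm,
            "category": o.category,
            "morphology": o.morphology,
            "taxon": "" if o.taxon is None else o.taxon,
        }
        for line in lines
        for o in line.observations
    ]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def read_rugosity(path) -> dict[str, tuple[float, ...]]:
    """Read per-line chain ratios; returns line_id -> ordered section ratios."""
    df = pd.read_csv(path)
    _require_columns(df, ["line_id", "section_index", "chain_ratio"], "rugosity CSV")
    out: dict[str, tuple[float, ...]] = {}
    for line_id, grp in df.groupby("line_id", sort=False):
        grp = grp.sort_values("section_index")
        out[str(line_id)] = tuple(float(v) for v in grp["chain_ratio"])
    return out


def write_rugosity(lines: Iterable[SurveyLine], path) -> None:
    rows = []
    for line in lines:
        if line.rugosity_sections is None:
            raise SurveyError(f"line {line.line_id!r} has no rugosity sections")
        for i, ratio in enumerate(line.rugosity_sections, start=1):
            rows.append(
                {"line_id": line.line_id, "section_index": i, "chain_ratio": ratio}
            )
    pd.DataFrame(rows, columns=["line_id", "section_index", "chain_ratio"]).to_csv(
        path, index=False
    )


def attach_rugosity(
    lines: Iterable[SurveyLine], sections: dict[str, tuple[float, ...]]
) -> list[SurveyLine]:
    """Return lines with their chain sections attached (validated)."""
    out = []
    for line in lines:
        if line.line_id not in sections:
            raise SurveyError(f"no rugosity sections for line {line.line_id!r}")
        out.append(replace(line, rugosity_sections=sections[line.line_id]))
    return out


def load_survey(observations_path, rugosity_path) -> list[SurveyLine]:
    """Read observations + rugosity CSVs into fully specified survey lines."""
    return attach_rugosity(read_observations(observations_path), read_rugosity(rugosity_path))


def read_belts(path) -> list[EchinoidBelt]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["belt_id", "transect_id", "zone_id", "area_m2", "genus", "test_size_mm", "count"],
        "belts CSV",
    )
    belts: list[EchinoidBelt] = []
    for belt_id, grp in df.groupby("belt_id", sort=False):
        records = [
            (str(r["genus"]), float(r["test_size_mm"]), int(r["count"]))
            for _, r in grp.iterrows()
            if not (pd.isna(r["genus"]) or str(r["genus"]) == "")
        ]
        first = grp.iloc[0]
        belts.append(
            EchinoidBelt(
                belt_id=str(belt_id),
                transect_id=str(first["transect_id"]),
                zone_id=int(first["zone_id"]),
                area_m2=float(first["area_m2"]),
                records=tuple(records),
            )
        )
    return belts


def write_belts(belts: Iterable[EchinoidBelt], path) -> None:
    rows = []
    for belt in belts:
        base = {
            "belt_id": belt.belt_id,
            "transect_id": belt.transect_id,
            "zone_id": belt.zone_id,
            "area_m2": belt.area_m2,
        }
        if belt.records:
            for genus, size, count in belt.records:
                rows.append({**base, "genus": genus, "test_size_mm": size, "count": count})
        else:
            # keep empty belts on file: a censused belt with zero urchins
            # is data, not absence of data
            rows.append({**base, "genus": "", "test_size_mm": "", "count": ""})
    pd.DataFrame(
        rows,
        columns=["belt_id", "transect_id", "zone_id", "area_m2", "genus", "test_size_mm", "count"],
    ).to_csv(path, index=False)


def write_rates(rates: RateTable, path) -> None:
    rows = [
        {"taxon": t, "morphology": m, "ci_g_cm2_yr": ci, "source": ""}
        for (t, m), ci in sorted(rates.calcification.items())
    ] + [
        {"taxon": "*", "morphology": m, "ci_g_cm2_yr": ci, "source": "morphology default"}
        for m, ci in sorted(rates.morphology_defaults.items())
    ]
    pd.DataFrame(rows, columns=["taxon", "morphology", "ci_g_cm2_yr", "source"]).to_csv(
        path, index=False
    )


def read_erosion_config(path) -> dict:
    """Read the erosion constants key-value (YAML) file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SurveyError("erosion config must be a key-value mapping")
    return cfg


def apply_erosion_config(rates: RateTable, cfg: dict) -> RateTable:
    """Overlay erosion constants from a config mapping onto a rate table."""
    kwargs = {}
    for key in ("macro_borer_rate", "micro_borer_rate", "parrotfish_rate", "cca_ci", "halimeda_ci"):
        if key in cfg:
            kwargs[key] = cfg[key]
    coeffs = dict(rates.echinoid_coeffs)
    for genus, spec in (cfg.get("echinoid_coeffs") or {}).items():
        if isinstance(spec, dict):
            a = float(spec.get("a"))
            b = float(spec.get("b", ECHINOID_SIZE_EXPONENT))
        else:
            a, b = (float(spec[0]), float(spec[1])) if len(spec) > 1 else (
                float(spec[0]),
                ECHINOID_SIZE_EXPONENT,
            )
        coeffs[genus] = (a, b)
    return replace(rates, echinoid_coeffs=coeffs, **kwargs)
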