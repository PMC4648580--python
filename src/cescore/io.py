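"""Country-table readers, report writers, and the end-to-end pipeline.

One strict CSV dialect (UTF-8, comma-separated, dot decimal) with clear
errors; blank cells are missing values, unknown columns pass through.
Reports are deterministic — identical inputs give byte-identical output —
and carry a hash of the model/threshold configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model_config import (
    CountryProfile,
    ModelDefinition,
    _model_to_dict,
    default_model,
    load_model,
)
from .scoring_engine import (
    LOW_MODERATE_CAVEAT,
    ComponentScore,
    SeverityResult,
    TierAssignment,
    ValueScore,
    rank_countries,
    score_country,
)
from .threshold_derivation import TierThresholds, load_thresholds

__all__ = [
    "FormatError",
    "RunConfig",
    "read_countries",
    "write_countries",
    "write_report",
    "read_report_json",
    "run_pipeline",
    "config_hash",
]

logger = logging.getLogger("cescore")

_EXPOSURE_COLUMNS = ("population", "affected", "uprooted")


class FormatError(ValueError):
    """An input file does not match the expected tabular format."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for one scoring run."""

    countries_path: str | Path
    thresholds_path: str | Path
    model_path: str | Path | None = None
    combiner: str | None = None
    missing_policy: str = "exclude"
    output_path: str | Path | None = None
    output_format: str = "csv"

    def __post_init__(self) -> None:
        if self.output_format not in ("csv", "json"):
            raise FormatError(f"unsupported output format {self.output_format!r}")


def read_countries(
    path: str | Path, model: ModelDefinition | None = None
) -> list[CountryProfile]:
    """Read one country per row from a strict CSV.

    Numeric columns are the model's vulnerability indicators plus
    population/affected/uprooted; blank cells become missing values and
    unknown columns are preserved as pass-through metadata.
    """
    model = model or default_model()
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    if "country" not in df.columns:
        raise FormatError(
            f"{path}: mandatory 'country' column not found "
            f"(columns: {list(df.columns)})"
        )
    numeric_cols = [i.name for i in model.vulnerability_indicators] + list(
        _EXPOSURE_COLUMNS
    )
    extra_cols = [c for c in df.columns if c != "country" and c not in numeric_cols]
    profiles: list[CountryProfile] = []
    for row_idx, row in df.iterrows():
        values: dict[str, float] = {}
        counts: dict[str, float | None] = {c: None for c in _EXPOSURE_COLUMNS}
        for col in numeric_cols:
            if col not in df.columns:
                continue
            cell = row[col]
            if cell is None or (isinstance(cell, float) and pd.isna(cell)):
                continue
            cell = str(cell).strip()
            if cell == "":
                continue
            try:
                num = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, "
                    f"row {row_idx + 2} (country {row['country']!r})"
                ) from None
            if col in counts:
                counts[col] = num
            else:
                values[col] = num
        profiles.append(
            CountryProfile(
                country=str(row["country"]),
                values=values,
                population=counts["population"],
                affected=counts["affected"],
                uprooted=counts["uprooted"],
                extras={
                    c: str(row[c])
                    for c in extra_cols
                    if not pd.isna(row[c]) and str(row[c]).strip() != ""
                },
            )
        )
    return profiles


def write_countries(profiles: Iterable[CountryProfile], path: str | Path) -> None:
    """Write profiles in the same CSV dialect `read_countries` consumes."""
    profiles = list(profiles)
    value_cols: list[str] = []
    for p in profiles:
        for k in p.values:
            if k not in value_cols:
                value_cols.append(k)
    rows = []
    for p in profiles:
        row: dict[str, object] = {"country": p.country}
        for c in value_cols:
            row[c] = p.values.get(c, "")
        for c in _EXPOSURE_COLUMNS:
            v = getattr(p, c)
            row[c] = "" if v is None else v
        row.update(p.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def config_hash(
    model: ModelDefinition, thresholds: Mapping[str, TierThresholds]
) -> str:
    """Short provenance hash of the model and threshold configuration."""
    payload = {
        "model": _model_to_dict(model),
        "thresholds": {
            k: {**dataclasses.asdict(t), "polarity": t.polarity.value}
            for k, t in sorted(thresholds.items())
        },
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:12]


# --- report writing ------------------------------------------------------


def _component_to_dict(c: ComponentScore) -> dict:
    return {
        "category": c.category.value,
        "score": c.score,
        "n_missing": c.n_missing,
        "value_scores": [
            {
                "name": vs.name,
                "raw": vs.raw,
                "tier_label": vs.tier.label if vs.tier else None,
                "tier_value": vs.tier.value if vs.tier else None,
                "flag": vs.flag,
            }
            for vs in c.value_scores
        ],
    }


def _component_from_dict(d: dict) -> ComponentScore:
    from .model_config import Category

    return ComponentScore(
        category=Category(d["category"]),
        score=d["score"],
        n_missing=d["n_missing"],
        value_scores=tuple(
            ValueScore(
                name=vs["name"],
                raw=vs["raw"],
                tier=(
                    TierAssignment(vs["tier_label"], vs["tier_value"])
                    if vs["tier_label"] is not None
                    else None
                ),
                flag=vs["flag"],
            )
            for vs in d["value_scores"]
        ),
    )


def result_to_dict(r: SeverityResult) -> dict:
    return {
        "country": r.country,
        "vulnerability": _component_to_dict(r.vulnerability),
        "exposure": _component_to_dict(r.exposure),
        "severity": r.severity,
        "complete": r.complete,
        "flags": list(r.flags),
    }


def result_from_dict(d: dict) -> SeverityResult:
    return SeverityResult(
        country=d["country"],
        vulnerability=_component_from_dict(d["vulnerability"]),
        exposure=_component_from_dict(d["exposure"]),
        severity=d["severity"],
        complete=d["complete"],
        flags=tuple(d["flags"]),
    )


def _report_frame(results: list[SeverityResult]) -> pd.DataFrame:
    columns = ["country"]
    if results:
        for c in (results[0].vulnerability, results[0].exposure):
            for vs in c.value_scores:
                columns += [vs.name, f"{vs.name}_tier"]
    else:
        columns += ["severity"]
    columns += [
        "vulnerability_score",
        "exposure_score",
        "severity",
        "complete",
        "flags",
    ]
    rows = []
    for r in results:
        row: dict[str, object] = {"country": r.country}
        for c in (r.vulnerability, r.exposure):
            for vs in c.value_scores:
                row[vs.name] = "" if vs.raw is None else vs.raw
                row[f"{vs.name}_tier"] = vs.tier.label if vs.tier else ""
        row["vulnerability_score"] = r.vulnerability.score
        row["exposure_score"] = r.exposure.score
        row["severity"] = "" if r.severity is None else r.severity
        row["complete"] = r.complete
        row["flags"] = "; ".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(dict.fromkeys(columns)))


def write_report(
    results: list[SeverityResult],
    path: str | Path,
    format: str = "csv",
    provenance: str | None = None,
) -> None:
    """Write a ranked report; the JSON variant round-trips exactly.

    CSV columns: country, each scored value's raw number and tier, the
    two component scores, the combined severity, completeness, flags.
    """
    path = Path(path)
    if not results:
        logger.warning("writing empty report to %s", path)
    if format == "csv":
        _report_frame(results).to_csv(path, index=False)
    elif format == "json":
        payload = {
            "note": LOW_MODERATE_CAVEAT,
            "provenance": provenance,
            "results": [result_to_dict(r) for r in results],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise FormatError(f"unsupported report format {format!r}")


def read_report_json(path: str | Path) -> list[SeverityResult]:
    """Read back a JSON report into `SeverityResult` objects."""
    payload = json.loads(Path(path).read_text())
    return [result_from_dict(d) for d in payload["results"]]


def run_pipeline(config: RunConfig) -> list[SeverityResult]:
    """Read countries, score them, rank, and (optionally) write a report."""
    model = load_model(config.model_path) if config.model_path else default_model()
    thresholds = load_thresholds(config.thresholds_path)
    logger.info(
        "loaded model with %d indicators, %d threshold records",
        len(model.indicators),
        len(thresholds),
    )
    profiles = read_countries(config.countries_path, model)
    logger.info("read %d countries from %s", len(profiles), config.countries_path)
    results = [
        score_country(
            p,
            model,
            thresholds,
            combiner=config.combiner,
            missing_policy=config.missing_policy,
        )
        for p in profiles
    ]
    n_missing = sum(r.vulnerability.n_missing + r.exposure.n_missing for r in results)
    ranked = rank_countries(results) if results else []
    logger.info(
        "scored %d countries (%d missing values), config hash %s",
        len(ranked),
        n_missing,
        config_hash(model, thresholds),
    )
    if config.output_path is not None:
        write_report(
            ranked,
            config.output_path,
            format=config.output_format,
            provenance=config_hash(model, thresholds),
        )
    return ranked
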