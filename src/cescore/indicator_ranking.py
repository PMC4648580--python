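"""Three-criterion ranking and diversity-aware selection of indicators.

Each candidate indicator is scored 1–3 on three criteria — evidence
(literature and index support), timeliness (update frequency) and
availability (appeal documents and the World Bank database) — for a total
of 3–9 points.  Selection is greedy by total score but spreads picks
across thematic fields (economics, health, education, ...) before any
field receives a second indicator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model_config import InvalidInputError

__all__ = [
    "UpdateFrequency",
    "IndicatorEvidence",
    "RankResult",
    "Selection",
    "rank_evidence",
    "rank_timeliness",
    "rank_availability",
    "total_rank",
    "select_indicators",
    "read_evidence_csv",
    "write_ranked_csv",
]


class UpdateFrequency(str, enum.Enum):
    CONTEXT_DRIVEN_OR_SUBANNUAL = "context_driven_or_subannual"
    ANNUAL = "annual"
    LESS_THAN_ANNUAL = "less_than_annual"


@dataclass(frozen=True)
class IndicatorEvidence:
    """Evidence collected for one candidate indicator."""

    name: str
    n_articles: int
    n_indexes: int
    update_frequency: UpdateFrequency
    in_over_third_of_caps: bool
    in_worldbank: bool
    field: str = ""

    def __post_init__(self) -> None:
        if self.n_articles < 0 or self.n_indexes < 0:
            raise InvalidInputError(
                f"article/index counts must be non-negative for {self.name!r}"
            )
        object.__setattr__(
            self, "update_frequency", UpdateFrequency(self.update_frequency)
        )


@dataclass(frozen=True)
class RankResult:
    """Per-criterion points and their 3–9 total for one indicator."""

    name: str
    evidence_points: int
    timeliness_points: int
    availability_points: int
    total: int
    field: str = ""

    def __post_init__(self) -> None:
        expected = (
            self.evidence_points + self.timeliness_points + self.availability_points
        )
        if self.total != expected:
            raise InvalidInputError(
                f"total {self.total} != sum of sub-scores {expected}"
            )
        if not 3 <= self.total <= 9:
            raise InvalidInputError(f"total must lie in [3, 9], got {self.total}")


@dataclass(frozen=True)
class Selection:
    """Result of diversity-aware selection; ``warning`` flags short supply."""

    selected: tuple[RankResult, ...]
    warning: bool = False


def rank_evidence(ev: IndicatorEvidence) -> int:
    """Evidence points: both thresholds must be met at each level.

    3 points for at least three supporting articles *and* use in at least
    three indexes; 2 for at least two of each; otherwise 1.
    """
    if ev.n_articles >= 3 and ev.n_indexes >= 3:
        return 3
    if ev.n_articles >= 2 and ev.n_indexes >= 2:
        return 2
    return 1


def rank_timeliness(ev: IndicatorEvidence) -> int:
    """Timeliness points: 3 if context-driven or sub-annual updates,
    2 if annual, 1 if less frequent."""
    return {
        UpdateFrequency.CONTEXT_DRIVEN_OR_SUBANNUAL: 3,
        UpdateFrequency.ANNUAL: 2,
        UpdateFrequency.LESS_THAN_ANNUAL: 1,
    }[ev.update_frequency]


def rank_availability(ev: IndicatorEvidence) -> int:
    """Availability points: one source (frequent appeal use, World Bank
    database) is worth a point above the baseline of 1."""
    return 1 + int(ev.in_over_third_of_caps) + int(ev.in_worldbank)


def total_rank(ev: IndicatorEvidence) -> RankResult:
    """Rank one indicator on all three criteria; total is their sum (3–9)."""
    e = rank_evidence(ev)
    t = rank_timeliness(ev)
    a = rank_availability(ev)
    return RankResult(
        name=ev.name,
        evidence_points=e,
        timeliness_points=t,
        availability_points=a,
        total=e + t + a,
        field=ev.field,
    )


def _sort_key(r: RankResult) -> tuple:
    return (-r.total, -r.evidence_points, r.name)


def select_indicators(ranked: list[RankResult], k: int) -> Selection:
    """Pick ``k`` indicators by descending total, spreading across fields.

    A field may contribute a second indicator only once every field with
    an unselected candidate has contributed at least one.  Ties break by
    evidence points (desc), then name (asc).
    """
    if not ranked:
        raise InvalidInputError("ranked candidate list must be non-empty")
    if len(ranked) < k:
        return Selection(selected=tuple(sorted(ranked, key=_sort_key)), warning=True)

    remaining = sorted(ranked, key=_sort_key)
    counts: dict[str, int] = {}
    chosen: list[RankResult] = []
    while len(chosen) < k and remaining:
        empty_fields = {
            r.field for r in remaining if counts.get(r.field, 0) == 0
        }
        pick = None
        for r in remaining:
            if counts.get(r.field, 0) == 0:
                pick = r
                break
            # second pick for this field allowed only if no other field
            # with unselected candidates is still empty
            if not (empty_fields - {r.field}):
                pick = r
                break
        if pick is None:  # pragma: no cover - loop always finds a candidate
            break
        chosen.append(pick)
        remaining.remove(pick)
        counts[pick.field] = counts.get(pick.field, 0) + 1
    return Selection(selected=tuple(chosen), warning=False)


# --- CSV interfaces ------------------------------------------------------

_EVIDENCE_COLUMNS = [
    "name",
    "field",
    "n_articles",
    "n_indexes",
    "update_frequency",
    "in_over_third_of_caps",
    "in_worldbank",
]

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def candidate_fixture_path() -> Path:
    """Path to the packaged candidate-indicator table.

    The table is a synthetic reconstruction: 25 plausible candidate
    names with thematic field tags, evidence columns left blank for the
    user to fill from their own literature and appeal-document searches.
    """
    return Path(__file__).parent / "data" / "candidate_indicators_synthetic.csv"


def read_evidence_csv(path: str | Path) -> list[IndicatorEvidence]:
    """Read candidate-indicator evidence, one row per candidate.

    Expected columns: name, field, n_articles, n_indexes,
    update_frequency, in_over_third_of_caps, in_worldbank.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(
            f"evidence table missing columns: {sorted(missing)}"
        )
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                IndicatorEvidence(
                    name=row["name"],
                    field=row["field"],
                    n_articles=int(row["n_articles"]),
                    n_indexes=int(row["n_indexes"]),
                    update_frequency=UpdateFrequency(row["update_frequency"]),
                    in_over_third_of_caps=_BOOL_MAP[
                        row["in_over_third_of_caps"].strip().lower()
                    ],
                    in_worldbank=_BOOL_MAP[row["in_worldbank"].strip().lower()],
                )
            )
        except (KeyError, ValueError) as exc:
            raise InvalidInputError(
                f"bad evidence row for {row.get('name', '?')!r}: {exc}"
            ) from exc
    return out


def write_ranked_csv(ranked: list[RankResult], path: str | Path) -> None:
    """Write ranked results sorted by total (desc), evidence (desc), name."""
    rows = sorted(ranked, key=_sort_key)
    df = pd.DataFrame(
        {
            "name": [r.name for r in rows],
            "field": [r.field for r in rows],
            "evidence_points": [r.evidence_points for r in rows],
            "timeliness_points": [r.timeliness_points for r in rows],
            "availability_points": [r.availability_points for r in rows],
            "total": [r.total for r in rows],
        }
    )
    df.to_csv(path, index=False)
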