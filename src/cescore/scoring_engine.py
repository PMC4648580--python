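"""Tier scoring, component aggregation, composite severity, and ranking.

Each of a country's eight scored values (four vulnerability, four
exposure) falls into one of three bands — Low-Moderate (1), High (2),
Critical (3) — relative to its reference cut points.  The band values sum
to a vulnerability score and an exposure score (each 4–12 when complete),
which combine into a single severity figure, by sum (default, 8–24) or by
product (16–144).  Note that Low-Moderate does not indicate an acceptable
situation, only that a country scored less poorly than those scoring High
or Critical.

Missing values are flagged and excluded by default; the ``critical``
missing-data policy scores them as worst-case instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model_config import (
    Category,
    CountryProfile,
    InvalidInputError,
    ModelDefinition,
    Polarity,
    ValueKind,
    exposure_proportion,
)
from .threshold_derivation import TierThresholds

__all__ = [
    "TierAssignment",
    "ValueScore",
    "ComponentScore",
    "SeverityResult",
    "score_value",
    "score_component",
    "compute_severity",
    "score_country",
    "rank_countries",
    "LOW_MODERATE_CAVEAT",
]

LOW_MODERATE_CAVEAT = (
    "Scoring Low-Moderate does not indicate an acceptable situation, only "
    "that the country scored less poorly than those scoring High or Critical."
)

_TIER_LABELS = ("Low-Moderate", "High", "Critical")
_TIER_VALUES = {"Low-Moderate": 1, "High": 2, "Critical": 3}


@dataclass(frozen=True)
class TierAssignment:
    """A tier label with its numeric severity value."""

    label: str
    value: int


@dataclass(frozen=True)
class ValueScore:
    """One scored value: the raw number and the tier it received."""

    name: str
    raw: float | None
    tier: TierAssignment | None
    flag: str | None = None

    @property
    def missing(self) -> bool:
        return self.raw is None


@dataclass(frozen=True)
class ComponentScore:
    """Per-category score: sum of tier values over the scored values."""

    category: Category
    value_scores: tuple[ValueScore, ...]
    score: int
    n_missing: int

    @property
    def fully_missing(self) -> bool:
        return all(vs.tier is None for vs in self.value_scores)


@dataclass(frozen=True)
class SeverityResult:
    """A country's component scores and combined severity."""

    country: str
    vulnerability: ComponentScore
    exposure: ComponentScore
    severity: float | None
    complete: bool
    flags: tuple[str, ...] = ()


def score_value(
    value: float,
    thresholds: TierThresholds,
    tier_labels: tuple[str, ...] = _TIER_LABELS,
    tier_values: Mapping[str, int] = _TIER_VALUES,
) -> TierAssignment:
    """Assign a value to a tier relative to its cut points.

    For higher_is_worse indicators, values up to the lower cut are
    Low-Moderate, values above the upper cut Critical.  For
    higher_is_better indicators the order mirrors.  A value exactly on a
    cut point takes the *less severe* adjacent tier.
    """
    if value is None or not math.isfinite(value):
        raise InvalidInputError(f"cannot score non-finite value {value!r}")
    low, high, critical = tier_labels
    if thresholds.polarity is Polarity.HIGHER_IS_WORSE:
        if value <= thresholds.lower_cut:
            label = low
        elif value <= thresholds.upper_cut:
            label = high
        else:
            label = critical
    else:
        if value >= thresholds.upper_cut:
            label = low
        elif value >= thresholds.lower_cut:
            label = high
        else:
            label = critical
    return TierAssignment(label=label, value=tier_values[label])


def _raw_value(profile: CountryProfile, sv) -> tuple[float | None, str | None]:
    """Extract a scored value's raw number; second element is a flag."""
    if sv.category is Category.VULNERABILITY:
        v = profile.values.get(sv.name)
        return (v, None) if v is not None else (None, f"{sv.name}: value missing")
    count = getattr(profile, sv.source, None)
    if count is None:
        return None, f"{sv.name}: {sv.source} count missing"
    if sv.kind is ValueKind.RAW:
        return count, None
    if profile.population is None or profile.population <= 0:
        return None, f"{sv.name}: population missing or non-positive"
    return exposure_proportion(count, profile.population), None


def score_component(
    profile: CountryProfile,
    category: Category | str,
    model: ModelDefinition,
    thresholds: Mapping[str, TierThresholds],
    missing_policy: str = "exclude",
) -> ComponentScore:
    """Score every available value of one category and sum the tiers.

    ``missing_policy='exclude'`` drops unavailable values from the score
    (flagged); ``'critical'`` scores them as the worst tier instead, a
    conservative worst-case treatment.  Either way ``n_missing`` counts
    them and the result carries a flag per missing value.
    """
    if missing_policy not in ("exclude", "critical"):
        raise InvalidInputError(f"unknown missing policy {missing_policy!r}")
    category = Category(category)
    labels = tuple(model.tier_labels)
    values = dict(model.tier_values)
    out: list[ValueScore] = []
    score = 0
    n_missing = 0
    for sv in model.scored_values(category):
        if sv.name not in thresholds:
            raise InvalidInputError(
                f"no thresholds supplied for scored value {sv.name!r}"
            )
        raw, flag = _raw_value(profile, sv)
        if raw is None:
            n_missing += 1
            tier = None
            if missing_policy == "critical":
                critical_label = labels[-1]
                tier = TierAssignment(critical_label, values[critical_label])
                score += tier.value
                flag = (flag or "") + " (scored as Critical by policy)"
            out.append(ValueScore(name=sv.name, raw=None, tier=tier, flag=flag))
            continue
        tier = score_value(raw, thresholds[sv.name], labels, values)
        score += tier.value
        out.append(ValueScore(name=sv.name, raw=float(raw), tier=tier))
    return ComponentScore(
        category=category,
        value_scores=tuple(out),
        score=score,
        n_missing=n_missing,
    )


def compute_severity(
    country: str,
    vulnerability: ComponentScore,
    exposure: ComponentScore,
    combiner: str = "sum",
) -> SeverityResult:
    """Combine the two component scores into one severity figure.

    The combiner is ``sum`` by default; ``product`` is available since
    the underlying severity logic is multiplicative.  Both component
    scores are always reported alongside, so the choice stays
    transparent.  If either component is fully missing the result is
    incomplete and severity is unset.
    """
    if combiner not in ("sum", "product"):
        raise InvalidInputError(f"unknown combiner {combiner!r}")
    flags = [vs.flag for c in (vulnerability, exposure) for vs in c.value_scores if vs.flag]
    if vulnerability.fully_missing or exposure.fully_missing:
        return SeverityResult(
            country=country,
            vulnerability=vulnerability,
            exposure=exposure,
            severity=None,
            complete=False,
            flags=tuple(flags + ["severity unset: a component is fully missing"]),
        )
    severity = (
        vulnerability.score + exposure.score
        if combiner == "sum"
        else vulnerability.score * exposure.score
    )
    complete = vulnerability.n_missing + exposure.n_missing == 0
    return SeverityResult(
        country=country,
        vulnerability=vulnerability,
        exposure=exposure,
        severity=float(severity),
        complete=complete,
        flags=tuple(flags),
    )


def score_country(
    profile: CountryProfile,
    model: ModelDefinition,
    thresholds: Mapping[str, TierThresholds],
    combiner: str | None = None,
    missing_policy: str = "exclude",
) -> SeverityResult:
    """Convenience wrapper: score both components and combine them."""
    v = score_component(
        profile, Category.VULNERABILITY, model, thresholds, missing_policy
    )
    e = score_component(
        profile, Category.EXPOSURE, model, thresholds, missing_policy
    )
    return compute_severity(
        profile.country, v, e, combiner or model.combiner
    )


def rank_countries(results: Iterable[SeverityResult]) -> list[SeverityResult]:
    """Order results by descending severity.

    Ties break by exposure score (desc), vulnerability score (desc),
    then country name (asc).  Results without a severity figure sort
    last, carrying their flags.
    """
    results = list(results)
    if not results:
        raise InvalidInputError("cannot rank an empty result list")

    def key(r: SeverityResult):
        has = r.severity is not None
        return (
            0 if has else 1,
            -(r.severity if has else 0.0),
            -r.exposure.score,
            -r.vulnerability.score,
            r.country,
        )

    return sorted(results, key=key)
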