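"""Derivation of three-tier cut points from reference distributions.

The two cut points per scored value are the tertiles (33.33rd and 66.67th
linear-interpolation percentiles) of a reference distribution —
vulnerability indicators against ~50 low-development (HDI < 0.5)
countries, exposure values against consolidated-appeal-scale emergencies.
Tertiles give the three bands approximately equal occupancy on
reference-like data; hand-set cut points can be loaded from JSON/YAML
instead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .model_config import (
    Category,
    CountryProfile,
    InvalidInputError,
    ModelDefinition,
    Polarity,
    ValueKind,
    exposure_proportion,
)

__all__ = [
    "TierThresholds",
    "InsufficientDataError",
    "DegenerateDistributionError",
    "percentile",
    "derive_cutoffs",
    "derive_all",
    "save_thresholds",
    "load_thresholds",
]

LOWER_Q = 1.0 / 3.0
UPPER_Q = 2.0 / 3.0


class InsufficientDataError(ValueError):
    """Too few reference observations to place cut points."""


class DegenerateDistributionError(ValueError):
    """All reference observations identical; tiers cannot be separated."""


@dataclass(frozen=True)
class TierThresholds:
    """Two cut points splitting an indicator's range into three bands."""

    indicator: str
    lower_cut: float
    upper_cut: float
    polarity: Polarity
    method: str = "tertile"
    reference_n: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        if self.lower_cut > self.upper_cut:
            raise InvalidInputError(
                f"lower_cut > upper_cut for {self.indicator!r}"
            )
        if self.reference_n < 3:
            raise InsufficientDataError(
                f"thresholds for {self.indicator!r} need >= 3 reference "
                f"observations, got {self.reference_n}"
            )


def percentile(values: Sequence[float], q: float) -> float:
    """Linear-interpolation percentile with inclusive endpoints.

    ``q`` is a fraction in [0, 1]; q=0 is the minimum, q=1 the maximum,
    intermediate quantiles interpolate linearly between order statistics.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot take a percentile of an empty list")
    if not 0.0 <= q <= 1.0:
        raise InvalidInputError(f"q must lie in [0, 1], got {q}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("percentile requires finite values")
    return float(np.quantile(arr, q, method="linear"))


def derive_cutoffs(
    reference_values: Sequence[float],
    polarity: Polarity | str,
    indicator: str = "",
    method: str = "tertile",
) -> TierThresholds:
    """Place tertile cut points on a reference distribution.

    Raises
    ------
    InsufficientDataError
        Fewer than three reference observations.
    DegenerateDistributionError
        All observations identical — no tiers can be distinguished.
    """
    vals = [float(v) for v in reference_values]
    if len(vals) < 3:
        raise InsufficientDataError(
            f"need >= 3 reference values for {indicator!r}, got {len(vals)}"
        )
    if len(set(vals)) == 1:
        raise DegenerateDistributionError(
            f"all reference values identical for {indicator!r}"
        )
    return TierThresholds(
        indicator=indicator,
        lower_cut=percentile(vals, LOWER_Q),
        upper_cut=percentile(vals, UPPER_Q),
        polarity=Polarity(polarity),
        method=method,
        reference_n=len(vals),
    )


def _extract(profile: CountryProfile, sv) -> float | None:
    """Raw scored value for one profile, or None when unavailable."""
    if sv.category is Category.VULNERABILITY:
        return profile.values.get(sv.name)
    count = getattr(profile, sv.source, None)
    if sv.kind is ValueKind.RAW:
        return count
    if count is None or profile.population is None or profile.population <= 0:
        return None
    return exposure_proportion(count, profile.population)


def derive_all(
    model: ModelDefinition,
    reference: Iterable[CountryProfile],
    exposure_reference: Iterable[CountryProfile] | None = None,
) -> dict[str, TierThresholds]:
    """Derive thresholds for every scored value of the model.

    Vulnerability thresholds come from ``reference``; exposure thresholds
    come from ``exposure_reference`` when given (mirroring the model's two
    data sources: a low-HDI country set and an appeal-scale emergency
    set), otherwise from ``reference`` as well.  Profiles missing a value
    are excluded from that value's derivation, never imputed.
    """
    reference = list(reference)
    expo_ref = list(exposure_reference) if exposure_reference is not None else reference
    out: dict[str, TierThresholds] = {}
    for sv in model.all_scored_values():
        pool = reference if sv.category is Category.VULNERABILITY else expo_ref
        vals = [v for p in pool if (v := _extract(p, sv)) is not None]
        if len(vals) < 3:
            raise InsufficientDataError(
                f"indicator {sv.name!r}: only {len(vals)} reference "
                f"observations (need >= 3)"
            )
        out[sv.name] = derive_cutoffs(vals, sv.polarity, indicator=sv.name)
    return out


# --- serialization -------------------------------------------------------


def save_thresholds(
    thresholds: Mapping[str, TierThresholds], path: str | Path
) -> None:
    """Write thresholds to JSON (or YAML if the suffix is .yaml/.yml)."""
    path = Path(path)
    data = {
        name: {**dataclasses.asdict(t), "polarity": t.polarity.value}
        for name, t in thresholds.items()
    }
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def load_thresholds(path: str | Path) -> dict[str, TierThresholds]:
    """Read thresholds from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return {name: TierThresholds(**d) for name, d in data.items()}
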