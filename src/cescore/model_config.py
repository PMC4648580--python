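"""Domain types and the default severity model.

The model follows the Utstein-template logic: disaster severity is a
function of a population's preexisting *vulnerability* and its *exposure*
to the emergency.  The default model carries four vulnerability indicators
(GNI per capita PPP, under-five mortality, adult literacy, child
underweight prevalence) and two exposure indicators (persons affected,
persons uprooted), each exposure indicator scored both as an absolute
count and as a proportion of the population — six indicators, eight
scored values, four per category.

Tier values 1/2/3 for Low-Moderate/High/Critical are the minimal monotone
encoding of the three severity bands and are configurable, as are
indicator polarities.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Category",
    "Polarity",
    "ValueKind",
    "IndicatorDefinition",
    "ScoredValue",
    "ModelDefinition",
    "CountryProfile",
    "InvalidInputError",
    "ConfigError",
    "default_model",
    "exposure_proportion",
    "load_model",
    "save_model",
    "TIER_LABELS",
    "TIER_VALUES",
]


class InvalidInputError(ValueError):
    """A value violates an operation's preconditions."""


class ConfigError(ValueError):
    """A model or generator configuration is inconsistent."""


class Category(str, enum.Enum):
    VULNERABILITY = "vulnerability"
    EXPOSURE = "exposure"


class Polarity(str, enum.Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    HIGHER_IS_BETTER = "higher_is_better"


class ValueKind(str, enum.Enum):
    """How a scored value is obtained from a profile."""

    RAW = "raw"
    PROPORTION = "proportion"


TIER_LABELS: tuple[str, ...] = ("Low-Moderate", "High", "Critical")
TIER_VALUES: dict[str, int] = {"Low-Moderate": 1, "High": 2, "Critical": 3}


@dataclass(frozen=True)
class IndicatorDefinition:
    """One candidate or selected indicator.

    ``polarity`` states which direction is *worse for the population*:
    mortality rises with severity (higher_is_worse) while income and
    literacy fall with it (higher_is_better).
    """

    name: str
    label: str
    category: Category
    units: str
    polarity: Polarity
    field: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "polarity", Polarity(self.polarity))


@dataclass(frozen=True)
class ScoredValue:
    """A single value that receives a tier when a country is scored.

    Vulnerability indicators map one-to-one onto scored values; each
    exposure indicator expands into an absolute count and a proportion of
    the total population.
    """

    name: str
    label: str
    category: Category
    polarity: Polarity
    kind: ValueKind
    source: str  # indicator name this value derives from


@dataclass(frozen=True)
class ModelDefinition:
    """The complete scoring model: indicators, tiers, and combiner."""

    vulnerability_indicators: tuple[IndicatorDefinition, ...]
    exposure_indicators: tuple[IndicatorDefinition, ...]
    tier_labels: tuple[str, ...] = TIER_LABELS
    tier_values: Mapping[str, int] = field(
        default_factory=lambda: dict(TIER_VALUES)
    )
    combiner: str = "sum"

    def __post_init__(self) -> None:
        if self.combiner not in ("sum", "product"):
            raise ConfigError(f"unknown combiner: {self.combiner!r}")
        if len(self.tier_labels) != 3:
            raise ConfigError("exactly three tier labels are required")
        values = [self.tier_values[lab] for lab in self.tier_labels]
        if not all(a < b for a, b in zip(values, values[1:])):
            raise ConfigError(
                "tier values must be strictly increasing with severity"
            )
        names = [ind.name for ind in self.indicators]
        if len(set(names)) != len(names):
            raise ConfigError("indicator names must be unique")

    @property
    def indicators(self) -> tuple[IndicatorDefinition, ...]:
        return self.vulnerability_indicators + self.exposure_indicators

    def scored_values(self, category: Category | str) -> tuple[ScoredValue, ...]:
        """The scored values of one category (four each in the default model)."""
        category = Category(category)
        if category is Category.VULNERABILITY:
            return tuple(
                ScoredValue(
                    name=ind.name,
                    label=ind.label,
                    category=category,
                    polarity=ind.polarity,
                    kind=ValueKind.RAW,
                    source=ind.name,
                )
                for ind in self.vulnerability_indicators
            )
        out: list[ScoredValue] = []
        for ind in self.exposure_indicators:
            out.append(
                ScoredValue(
                    name=ind.name,
                    label=f"{ind.label} (absolute)",
                    category=category,
                    polarity=ind.polarity,
                    kind=ValueKind.RAW,
                    source=ind.name,
                )
            )
            out.append(
                ScoredValue(
                    name=f"{ind.name}_prop",
                    label=f"{ind.label} (proportion of population)",
                    category=category,
                    polarity=ind.polarity,
                    kind=ValueKind.PROPORTION,
                    source=ind.name,
                )
            )
        return tuple(out)

    def all_scored_values(self) -> tuple[ScoredValue, ...]:
        return self.scored_values(Category.VULNERABILITY) + self.scored_values(
            Category.EXPOSURE
        )


@dataclass
class CountryProfile:
    """One country's raw data: indicator values plus exposure counts.

    ``values`` maps vulnerability-indicator names to numbers; a missing
    key means the value is unavailable.  ``population``, ``affected`` and
    ``uprooted`` back the exposure scored values.  ``extras`` carries
    pass-through columns from input files.
    """

    country: str
    values: dict[str, float] = field(default_factory=dict)
    population: float | None = None
    affected: float | None = None
    uprooted: float | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("population", "affected", "uprooted"):
            v = getattr(self, attr)
            if v is None:
                continue
            if v < 0:
                raise InvalidInputError(f"{attr} must be non-negative, got {v}")
        if self.population is not None:
            for attr in ("affected", "uprooted"):
                v = getattr(self, attr)
                if v is not None and v > self.population:
                    raise InvalidInputError(
                        f"{attr} ({v}) exceeds population ({self.population}) "
                        f"for {self.country}"
                    )


def exposure_proportion(count: float, population: float) -> float:
    """Fraction of the population represented by an exposure count.

    Raises
    ------
    InvalidInputError
        If ``population <= 0`` or ``count`` lies outside [0, population].
    """
    if population is None or population <= 0:
        raise InvalidInputError(f"population must be positive, got {population}")
    if count is None or count < 0 or count > population:
        raise InvalidInputError(
            f"count must lie in [0, population], got count={count}, "
            f"population={population}"
        )
    return count / population


def default_model() -> ModelDefinition:
    """The default severity model.

    Four vulnerability indicators and two exposure indicators; the
    exposure indicators are each scored as an absolute count and as a
    proportion of population, giving four scored values per category.
    """
    vuln = (
        IndicatorDefinition(
            name="gni_per_capita",
            label="GNI per capita, PPP",
            category=Category.VULNERABILITY,
            units="current international $",
            polarity=Polarity.HIGHER_IS_BETTER,
            field="economics",
        ),
        IndicatorDefinition(
            name="u5mr",
            label="Under-five mortality rate",
            category=Category.VULNERABILITY,
            units="per 1,000 live births",
            polarity=Polarity.HIGHER_IS_WORSE,
            field="health",
        ),
        IndicatorDefinition(
            name="adult_literacy",
            label="Adult literacy rate",
            category=Category.VULNERABILITY,
            units="% of people ages 15 and above",
            polarity=Polarity.HIGHER_IS_BETTER,
            field="education",
        ),
        IndicatorDefinition(
            name="underweight",
            label="Underweight prevalence",
            category=Category.VULNERABILITY,
            units="% of population under 5 years",
            polarity=Polarity.HIGHER_IS_WORSE,
            field="nutrition",
        ),
    )
    expo = (
        IndicatorDefinition(
            name="affected",
            label="Persons affected",
            category=Category.EXPOSURE,
            units="persons",
            polarity=Polarity.HIGHER_IS_WORSE,
            field="displacement",
        ),
        IndicatorDefinition(
            name="uprooted",
            label="Persons uprooted",
            category=Category.EXPOSURE,
            units="persons",
            polarity=Polarity.HIGHER_IS_WORSE,
            field="displacement",
        ),
    )
    return ModelDefinition(vulnerability_indicators=vuln, exposure_indicators=expo)


def default_model_path() -> Path:
    """Path to the packaged copy of the default model config."""
    return Path(__file__).parent / "data" / "default_model.yaml"


# --- serialization -------------------------------------------------------


def _model_to_dict(model: ModelDefinition) -> dict:
    def ind(d: IndicatorDefinition) -> dict:
        out = dataclasses.asdict(d)
        out["category"] = d.category.value
        out["polarity"] = d.polarity.value
        return out

    return {
        "vulnerability_indicators": [ind(i) for i in model.vulnerability_indicators],
        "exposure_indicators": [ind(i) for i in model.exposure_indicators],
        "tier_labels": list(model.tier_labels),
        "tier_values": dict(model.tier_values),
        "combiner": model.combiner,
    }


def _model_from_dict(data: dict) -> ModelDefinition:
    try:
        return ModelDefinition(
            vulnerability_indicators=tuple(
                IndicatorDefinition(**d) for d in data["vulnerability_indicators"]
            ),
            exposure_indicators=tuple(
                IndicatorDefinition(**d) for d in data["exposure_indicators"]
            ),
            tier_labels=tuple(data.get("tier_labels", TIER_LABELS)),
            tier_values=dict(data.get("tier_values", TIER_VALUES)),
            combiner=data.get("combiner", "sum"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid model definition: {exc}") from exc


def save_model(model: ModelDefinition, path: str | Path) -> None:
    """Write a model definition to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = _model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_model(path: str | Path) -> ModelDefinition:
    """Read a model definition from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _model_from_dict(data)
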