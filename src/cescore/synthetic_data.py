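"""Synthetic reference-country and emergency-exposure generators.

Produces country profiles with the statistical structure the scoring
model assumes: a reference set resembling ~50 low-development (HDI < 0.5)
countries for vulnerability thresholds, and an appeal-scale emergency set
(default 15, the number of consolidated appeals in the model's exposure
reference year) for exposure thresholds.  All values are drawn from
truncated parametric families — log-normal for GNI per capita, truncated
normal for mortality, literacy and underweight — and are fully
reproducible from a seed.

The default parameters are plausible synthetic values for low-HDI
countries, not observed data; every parameter sits in `GeneratorConfig`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .model_config import ConfigError, CountryProfile

__all__ = [
    "TruncatedDistribution",
    "GeneratorConfig",
    "generate_reference_countries",
    "generate_ce_exposure",
    "generate_scored_countries",
    "inject_missingness",
]


@dataclass(frozen=True)
class TruncatedDistribution:
    """A parametric family truncated to plausible bounds.

    ``family='lognormal'`` uses ``loc`` as the median and ``scale`` as the
    log-space sigma; ``family='normal'`` uses ``loc`` as the mean and
    ``scale`` as the standard deviation.  Sampling is by inverse-CDF on
    the truncated distribution, so bounds reshape the density rather than
    piling mass at the clip points.
    """

    family: str
    loc: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ConfigError(f"unknown distribution family {self.family!r}")
        if self.scale <= 0:
            raise ConfigError("scale parameter must be positive")
        if not self.lower < self.upper:
            raise ConfigError("bounds must satisfy lower < upper")

    def _frozen(self):
        if self.family == "lognormal":
            return stats.lognorm(s=self.scale, scale=self.loc)
        return stats.norm(loc=self.loc, scale=self.scale)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        dist = self._frozen()
        flo, fhi = dist.cdf(self.lower), dist.cdf(self.upper)
        u = rng.uniform(flo, fhi, size=n)
        return dist.ppf(u)

    def quantile(self, q: float) -> float:
        """True quantile of the truncated distribution."""
        dist = self._frozen()
        flo, fhi = dist.cdf(self.lower), dist.cdf(self.upper)
        return float(dist.ppf(flo + q * (fhi - flo)))

    def mean(self) -> float:
        """True mean of the truncated distribution."""
        return float(
            self._frozen().expect(lb=self.lower, ub=self.upper, conditional=True)
        )

    def sd(self) -> float:
        """True standard deviation of the truncated distribution."""
        dist = self._frozen()
        m = self.mean()
        m2 = dist.expect(
            lambda x: x * x, lb=self.lower, ub=self.upper, conditional=True
        )
        return float(np.sqrt(m2 - m * m))


def _default_indicators() -> dict[str, TruncatedDistribution]:
    return {
        "gni_per_capita": TruncatedDistribution(
            "lognormal", loc=1400.0, scale=0.55, lower=300.0, upper=6000.0
        ),
        "u5mr": TruncatedDistribution(
            "normal", loc=95.0, scale=35.0, lower=25.0, upper=250.0
        ),
        "adult_literacy": TruncatedDistribution(
            "normal", loc=55.0, scale=17.0, lower=15.0, upper=95.0
        ),
        "underweight": TruncatedDistribution(
            "normal", loc=22.0, scale=8.0, lower=3.0, upper=45.0
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generators.

    ``n_countries`` sizes the low-HDI vulnerability reference (default
    50); ``n_ce_countries`` sizes the emergency exposure set (default
    15).  Populations are log-uniform over ``population_range``; the
    affected count is a uniform fraction of the population and the
    uprooted count a uniform sub-fraction of the affected, which
    guarantees uprooted <= affected <= population by construction.
    """

    n_countries: int = 50
    n_ce_countries: int = 15
    seed: int = 0
    indicators: dict[str, TruncatedDistribution] = field(
        default_factory=_default_indicators
    )
    population_range: tuple[float, float] = (1.0e6, 8.0e7)
    affected_fraction_range: tuple[float, float] = (0.02, 0.6)
    uprooted_fraction_range: tuple[float, float] = (0.1, 0.8)

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ConfigError("n_countries must be >= 3")
        if self.n_ce_countries < 3:
            raise ConfigError("n_ce_countries must be >= 3")
        lo, hi = self.population_range
        if not 0 < lo <= hi:
            raise ConfigError("population_range must be positive and ordered")
        for name in ("affected_fraction_range", "uprooted_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"{name} must be ordered within [0, 1]")


def _draw_values(
    config: GeneratorConfig, rng: np.random.Generator, n: int
) -> list[dict[str, float]]:
    columns = {
        name: dist.sample(rng, n) for name, dist in sorted(config.indicators.items())
    }
    return [{name: float(col[i]) for name, col in columns.items()} for i in range(n)]


def _draw_exposure(
    config: GeneratorConfig, rng: np.random.Generator, n: int
) -> list[tuple[float, float, float]]:
    lo, hi = config.population_range
    population = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    af_lo, af_hi = config.affected_fraction_range
    up_lo, up_hi = config.uprooted_fraction_range
    affected = np.floor(population * rng.uniform(af_lo, af_hi, size=n))
    uprooted = np.floor(affected * rng.uniform(up_lo, up_hi, size=n))
    population = np.floor(population)
    return [
        (float(population[i]), float(affected[i]), float(uprooted[i]))
        for i in range(n)
    ]


def generate_reference_countries(config: GeneratorConfig) -> list[CountryProfile]:
    """Vulnerability reference set: ``n_countries`` low-HDI-like profiles.

    Each profile carries all configured indicator values (no exposure
    counts); identical configs produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    values = _draw_values(config, rng, config.n_countries)
    return [
        CountryProfile(country=f"REF{i + 1:03d}", values=values[i])
        for i in range(config.n_countries)
    ]


def generate_ce_exposure(config: GeneratorConfig) -> list[CountryProfile]:
    """Exposure reference set: ``n_ce_countries`` appeal-scale emergencies.

    Profiles carry population, affected and uprooted counts satisfying
    0 <= uprooted <= affected <= population.
    """
    # separate stream so exposure draws do not shift when indicator
    # families change
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    expo = _draw_exposure(config, rng, config.n_ce_countries)
    return [
        CountryProfile(
            country=f"CE{i + 1:03d}",
            population=pop,
            affected=aff,
            uprooted=upr,
        )
        for i, (pop, aff, upr) in enumerate(expo)
    ]


def generate_scored_countries(config: GeneratorConfig) -> list[CountryProfile]:
    """Full profiles (vulnerability values plus exposure counts) for
    end-to-end scoring, sized ``n_ce_countries``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_ce_countries
    values = _draw_values(config, rng, n)
    expo = _draw_exposure(config, rng, n)
    return [
        CountryProfile(
            country=f"CTY{i + 1:03d}",
            values=values[i],
            population=expo[i][0],
            affected=expo[i][1],
            uprooted=expo[i][2],
        )
        for i in range(n)
    ]


def inject_missingness(
    profiles: Iterable[CountryProfile], rate: float, seed: int
) -> list[CountryProfile]:
    """Remove each indicator value independently with probability ``rate``.

    Returns new profiles; the inputs are not mutated.  Exposure counts
    are left intact — missing counts are better exercised by omitting
    columns in input files.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"missingness rate must lie in [0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    out: list[CountryProfile] = []
    for p in profiles:
        q = copy.deepcopy(p)
        if rate > 0:
            q.values = {
                k: v
                for k, v in sorted(q.values.items())
                if rng.random() >= rate
            }
        out.append(q)
    return out
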