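"""Run configuration: every model parameter plus the seed, in one place.

A :class:`SimulationConfig` is the single source of truth for a run. It can be
built in Python or loaded from a YAML/TOML file; unknown keys are rejected so a
typo in a config file fails loudly instead of silently running the defaults.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "FragmentDistribution",
    "SimulationConfig",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class FragmentDistribution:
    """Right-skewed distribution of fragment masses detached at breakage.

    Three kinds are supported:

    ``"lognormal_mixture"`` (default)
        With probability ``1 - p_large`` a small flake is drawn from
        LogNormal(log(small_median), small_sigma); with probability ``p_large``
        a large chunk from LogNormal(log(large_median), large_sigma). Defaults
        give a mixture mean of roughly 20 g: most breaks shed grams, rare ones
        shed a tenth of a kilogram or more.

    ``"empirical"``
        Masses resampled uniformly from a user-supplied table (e.g. a CSV of
        field-measured fragments, column ``mass_g``).

    ``"constant"``
        Every fragment has mass ``value`` — useful for deterministic tests.
    """

    kind: str = "lognormal_mixture"
    p_large: float = 0.1
    small_median: float = 6.0
    small_sigma: float = 0.8
    large_median: float = 100.0
    large_sigma: float = 0.7
    value: float = 50.0
    table: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal_mixture", "empirical", "constant"):
            raise ConfigurationError(f"unknown fragment distribution kind {self.kind!r}")
        if self.kind == "lognormal_mixture":
            if not 0.0 <= self.p_large <= 1.0:
                raise ConfigurationError("p_large must lie in [0, 1]")
            if self.small_median <= 0 or self.large_median <= 0:
                raise ConfigurationError("fragment medians must be positive")
            if self.small_sigma < 0 or self.large_sigma < 0:
                raise ConfigurationError("fragment sigmas must be non-negative")
        if self.kind == "constant" and self.value <= 0:
            raise ConfigurationError("constant fragment mass must be positive")
        if self.kind == "empirical":
            if not self.table:
                raise ConfigurationError("empirical fragment distribution needs a table")
            if any(m <= 0 for m in self.table):
                raise ConfigurationError("empirical fragment masses must be positive")

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one fragment mass in grams."""
        if self.kind == "constant":
            return float(self.value)
        if self.kind == "empirical":
            assert self.table is not None
            return float(self.table[rng.integers(len(self.table))])
        if rng.random() < self.p_large:
            return float(rng.lognormal(math.log(self.large_median), self.large_sigma))
        return float(rng.lognormal(math.log(self.small_median), self.small_sigma))

    @property
    def mean(self) -> float:
        """Analytic mean of the distribution (grams)."""
        if self.kind == "constant":
            return float(self.value)
        if self.kind == "empirical":
            assert self.table is not None
            return float(np.mean(self.table))
        small = self.small_median * math.exp(self.small_sigma**2 / 2)
        large = self.large_median * math.exp(self.large_sigma**2 / 2)
        return (1 - self.p_large) * small + self.p_large * large

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind}
        if self.kind == "lognormal_mixture":
            d.update(
                p_large=self.p_large,
                small_median=self.small_median,
                small_sigma=self.small_sigma,
                large_median=self.large_median,
                large_sigma=self.large_sigma,
            )
        elif self.kind == "constant":
            d["value"] = self.value
        else:
            d["table"] = list(self.table or ())
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FragmentDistribution":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown fragment_distribution keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "table" in kwargs and kwargs["table"] is not None:
            kwargs["table"] = tuple(float(m) for m in kwargs["table"])
        return cls(**kwargs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FragmentDistribution":
        """Build an empirical distribution from a CSV with a ``mass_g`` column."""
        import pandas as pd

        df = pd.read_csv(path)
        if "mass_g" not in df.columns:
            raise ConfigurationError(f"{path}: expected a 'mass_g' column")
        return cls(kind="empirical", table=tuple(float(m) for m in df["mass_g"]))


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulation run.

    Distances are Chebyshev (chessboard) cells, masses are grams, time is in
    discrete steps where one step is roughly one nut-cracking episode.
    """

    width: int = 250
    height: int = 250
    n_primates: int = 100
    n_trees: int = 1000
    n_sources: int = 100
    dynamic_trees: bool = True
    n_steps: int = 75_000
    tree_lifespan: int = 10_000
    regrow_radius: int = 10
    search_radius: int = 2
    interaction_radius: int = 1
    usable_threshold: float = 2000.0
    baseline_break_prob: float = 0.25
    fragility_levels: tuple[int, ...] = (0, 25, 50, 75)
    initial_mass_mean: float = 6000.0
    initial_mass_sd: float = 2000.0
    fragment_distribution: FragmentDistribution = field(default_factory=FragmentDistribution)
    seed: int = 0
    torus: bool = False
    record_every: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragility_levels", tuple(int(f) for f in self.fragility_levels))
        for name in ("width", "height", "n_primates", "n_trees", "n_sources", "tree_lifespan"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_steps < 0:
            raise ConfigurationError("n_steps must be non-negative")
        if not 0.0 <= self.baseline_break_prob <= 1.0:
            raise ConfigurationError("baseline_break_prob must lie in [0, 1]")
        if not self.fragility_levels:
            raise ConfigurationError("fragility_levels must be non-empty")
        for f in self.fragility_levels:
            if self.baseline_break_prob + f / 100.0 < 0:
                raise ConfigurationError(f"fragility level {f} gives a negative break probability")
        if self.usable_threshold <= 0:
            raise ConfigurationError("usable_threshold must be positive")
        if self.search_radius < 1:
            raise ConfigurationError("search_radius must be at least 1")
        if self.interaction_radius < 1:
            raise ConfigurationError("interaction_radius must be at least 1")
        if self.regrow_radius < 1:
            raise ConfigurationError("regrow_radius must be at least 1")
        if self.n_trees + self.n_sources > self.width * self.height:
            raise ConfigurationError(
                "n_trees + n_sources exceeds the number of grid cells; "
                "unique-cell placement is impossible"
            )
        if self.initial_mass_sd < 0:
            raise ConfigurationError("initial_mass_sd must be non-negative")
        if self.initial_mass_sd == 0 and self.initial_mass_mean < self.usable_threshold:
            raise ConfigurationError(
                "initial_mass_sd is 0 but initial_mass_mean is below usable_threshold: "
                "no usable tool can ever be drawn"
            )
        if self.torus:
            # wrapped coverage windows must not self-overlap
            reach = 2 * (self.search_radius + self.interaction_radius) + 1
            if self.width < reach or self.height < reach:
                raise ConfigurationError("grid too small for wrapped neighbourhoods under torus")
        if self.record_every is not None and self.record_every < 1:
            raise ConfigurationError("record_every must be at least 1")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")

    @property
    def location_radius(self) -> int:
        """Radius defining a tool-use location: a live tree counts as one when a
        source or usable tool lies within this many cells (search + interaction,
        i.e. 3 under the defaults — the farthest a material can be from a tree
        and still be moved to it in one bout)."""
        return self.search_radius + self.interaction_radius

    @property
    def effective_record_every(self) -> int:
        """Recording interval for the tool-use-location time series: every step
        for runs up to 10,000 steps, every 50 steps beyond that, unless
        ``record_every`` overrides."""
        if self.record_every is not None:
            return self.record_every
        return 1 if self.n_steps <= 10_000 else 50

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["fragility_levels"] = list(self.fragility_levels)
        d["fragment_distribution"] = self.fragment_distribution.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(d)
        fd = kwargs.get("fragment_distribution")
        if isinstance(fd, str):
            kwargs["fragment_distribution"] = FragmentDistribution.from_csv(fd)
        elif isinstance(fd, dict):
            kwargs["fragment_distribution"] = FragmentDistribution.from_dict(fd)
        if "fragility_levels" in kwargs:
            kwargs["fragility_levels"] = tuple(kwargs["fragility_levels"])
        return cls(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML (``.yaml``/``.yml``) or
    TOML (``.toml``) file. Unknown keys raise :class:`ConfigurationError`."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping of configuration keys")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as YAML (round-trips through :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
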