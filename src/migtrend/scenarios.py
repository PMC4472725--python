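"""Experiment design grid and per-year daily-survival (stopover) schedules.

A migration-count simulation scenario is one cell of a factorial design:
a true population trend, a 20-year schedule of daily survival probability
``phi`` (the probability that an individual on stopover stays through to the
next day, so mean stopover length is ``1/(1-phi)`` days), and optional
analysis treatment arms (an annual ``phi`` covariate in the trend model,
and/or subsampling of count days).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PhiSchedule",
    "ScenarioSpec",
    "make_phi_schedule",
    "build_design_grid",
    "core_grid",
    "treatment_grid",
    "load_design_config",
]

PHI_PATTERNS = ("constant", "random", "cyclic", "linear")

#: The three true trends studied, as % change per year (−20%, 0, +20% in 20 years).
TREND_GRID_PCT = (-1.2, 0.0, 0.96)
#: Constant daily-survival levels studied.
CONSTANT_PHI_LEVELS = (0.0, 0.2, 0.5, 0.7)
#: (lo, hi) ranges for the time-varying daily-survival schedules.
PHI_RANGES = ((0.4, 0.5), (0.35, 0.55), (0.3, 0.6), (0.25, 0.65), (0.2, 0.7))


@dataclass(frozen=True)
class PhiSchedule:
    """Per-year daily survival probabilities ``phi_i`` for one scenario.

    ``pattern`` is one of ``constant``, ``random``, ``cyclic`` or ``linear``;
    ``values`` always has length ``nyears`` and every entry lies in
    ``[lo, hi] ⊂ [0, 1)``.
    """

    pattern: str
    lo: float
    hi: float
    values: tuple[float, ...]
    cycle_period: int | None = None
    seed: int | None = None

    @property
    def nyears(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def label(self) -> str:
        if self.pattern == "constant":
            return f"constant[{self.lo:g}]"
        return f"{self.pattern}[{self.lo:g}-{self.hi:g}]"


def make_phi_schedule(
    pattern: str,
    lo: float,
    hi: float,
    nyears: int = 20,
    cycle_period: int = 5,
    seed: int | None = None,
    cycle_phase: float = 0.0,
) -> PhiSchedule:
    """Build a per-year daily-survival schedule.

    Parameters
    ----------
    pattern
        ``constant`` (all years equal ``lo``, which must equal ``hi``),
        ``linear`` (arithmetic progression from ``lo`` in year 1 to ``hi``
        in the final year), ``cyclic`` (sinusoid between ``lo`` and ``hi``
        with the given period in years), or ``random`` (iid Uniform(lo, hi)
        draws).
    cycle_phase
        Phase offset (radians) of the cyclic sinusoid; the default 0 starts
        the cycle at its midpoint, which for a 5-year period over 20 years
        ends the series at a lower survival than it began.
    seed
        Required for ``random`` schedules; identical seeds give identical
        schedules.
    """
    if not (0.0 <= lo <= hi < 1.0):
        raise ValueError(f"invalid probability range: need 0 <= lo <= hi < 1, got ({lo}, {hi})")
    if nyears < 2:
        raise ValueError("nyears must be >= 2")

    if pattern == "constant":
        if lo != hi:
            raise ValueError("constant pattern requires lo == hi")
        values = np.full(nyears, lo)
    elif pattern == "linear":
        values = np.linspace(lo, hi, nyears)
    elif pattern == "cyclic":
        if cycle_period < 2:
            raise ValueError("cycle_period must be >= 2 for cyclic schedules")
        years = np.arange(nyears)
        s = np.sin(2.0 * np.pi * years / cycle_period + cycle_phase)
        if s.max() > s.min():
            # rescale the sampled sinusoid so the series spans [lo, hi] exactly
            # (integer-year sampling of an odd period never hits both extremes)
            values = lo + (hi - lo) * (s - s.min()) / (s.max() - s.min())
        else:
            values = np.full(nyears, 0.5 * (lo + hi))
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        values = rng.uniform(lo, hi, size=nyears)
    else:
        raise ValueError(f"unknown phi pattern: {pattern!r}")

    values = np.clip(values, lo, hi)  # guard fp round-off at the bounds
    return PhiSchedule(
        pattern=pattern,
        lo=lo,
        hi=hi,
        values=tuple(float(v) for v in values),
        cycle_period=cycle_period if pattern == "cyclic" else None,
        seed=seed if pattern == "random" else None,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation experiment.

    ``trend_pct`` is the true constant rate of population change in
    %·year⁻¹; ``trend_beta = trend_pct / 100`` is the per-year proportional
    rate used by the simulator. ``covariate_arm`` and ``subsample_arm``
    describe how the trend model is applied to datasets from this scenario,
    not how the data are generated.
    """

    trend_pct: float
    phi: PhiSchedule
    n_replicates: int = 100
    nyears: int = 20
    detection_p: float = 0.30
    covariate_arm: bool = False
    subsample_arm: str = "none"  # none | every3 | every5

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.nyears < 2:
            raise ValueError("nyears must be >= 2")
        if self.phi.nyears != self.nyears:
            raise ValueError("phi schedule length must equal nyears")
        if self.subsample_arm not in ("none", "every3", "every5"):
            raise ValueError(f"unknown subsample arm: {self.subsample_arm!r}")
        if not (0.0 < self.detection_p <= 1.0):
            raise ValueError("detection_p must be in (0, 1]")

    @property
    def trend_beta(self) -> float:
        return self.trend_pct / 100.0

    @property
    def subsample_k(self) -> int:
        return {"none": 1, "every3": 3, "every5": 5}[self.subsample_arm]

    def scenario_id(self) -> str:
        arm = ""
        if self.covariate_arm:
            arm += "+cov"
        if self.subsample_arm != "none":
            arm += f"+{self.subsample_arm}"
        return f"trend{self.trend_pct:+g}_{self.phi.label()}{arm}"

    def stable_hash(self) -> int:
        """Deterministic 32-bit hash used to derive per-scenario RNG streams."""
        key = f"{self.trend_pct:+.6f}|{self.phi.pattern}|{self.phi.lo:.6f}|{self.phi.hi:.6f}"
        return zlib.crc32(key.encode())


def _as_ranges(ranges: Iterable[Sequence[float]]) -> list[tuple[float, float]]:
    return [(float(lo), float(hi)) for lo, hi in ranges]


def core_grid(
    trends_pct: Sequence[float] = TREND_GRID_PCT,
    constant_levels: Sequence[float] = CONSTANT_PHI_LEVELS,
    phi_ranges: Iterable[Sequence[float]] = PHI_RANGES,
    patterns: Sequence[str] = ("random", "cyclic", "linear"),
    n_replicates: int = 100,
    nyears: int = 20,
    random_seed: int = 0,
) -> list[ScenarioSpec]:
    """The main factorial: {trends} × ({constant phi levels} ∪ {patterns × ranges}).

    At the study's levels this is 3 × (4 + 3×5) = 57 scenarios.
    """
    if not trends_pct:
        raise ValueError("empty trend list")
    scenarios: list[ScenarioSpec] = []
    for trend in trends_pct:
        for level in constant_levels:
            phi = make_phi_schedule("constant", level, level, nyears)
            scenarios.append(
                ScenarioSpec(trend_pct=trend, phi=phi, n_replicates=n_replicates, nyears=nyears)
            )
        for pattern in patterns:
            for lo, hi in _as_ranges(phi_ranges):
                phi = make_phi_schedule(
                    pattern, lo, hi, nyears,
                    seed=random_seed + zlib.crc32(f"{pattern}|{lo}|{hi}|{trend}".encode()) % 2**20,
                )
                scenarios.append(
                    ScenarioSpec(trend_pct=trend, phi=phi, n_replicates=n_replicates, nyears=nyears)
                )
    return scenarios


def treatment_grid(
    phi_ranges: Iterable[Sequence[float]] = PHI_RANGES,
    trend_pct: float = -1.2,
    covariate_levels: Sequence[bool] = (False, True),
    subsample_levels: Sequence[str] = ("none", "every3", "every5"),
    n_replicates: int = 100,
    nyears: int = 20,
) -> list[ScenarioSpec]:
    """The treatment-arm factorial on declining-trend, linearly increasing phi
    datasets: {ranges} × {covariate off/on} × {no subset, every 3rd, every 5th day}
    (5 × 2 × 3 = 30 cells at the study's levels).
    """
    scenarios = []
    for lo, hi in _as_ranges(phi_ranges):
        phi = make_phi_schedule("linear", lo, hi, nyears)
        for cov in covariate_levels:
            for sub in subsample_levels:
                scenarios.append(
                    ScenarioSpec(
                        trend_pct=trend_pct,
                        phi=phi,
                        n_replicates=n_replicates,
                        nyears=nyears,
                        covariate_arm=bool(cov),
                        subsample_arm=sub,
                    )
                )
    return scenarios


def build_design_grid(config: dict) -> list[ScenarioSpec]:
    """Enumerate the full scenario crossing described by a configuration dict.

    Recognised keys (all optional, defaulting to the study's design):
    ``trends_pct``, ``constant_levels``, ``phi_ranges``, ``patterns``,
    ``n_replicates``, ``nyears``, ``random_seed``, and ``treatment_arms``
    (bool or dict of ``treatment_grid`` overrides). An explicitly empty
    factor list raises ``ValueError``.
    """
    if "trends_pct" in config and not list(config["trends_pct"]):
        raise ValueError("empty factor list: trends_pct")
    grid = core_grid(
        trends_pct=config.get("trends_pct", TREND_GRID_PCT),
        constant_levels=config.get("constant_levels", CONSTANT_PHI_LEVELS),
        phi_ranges=config.get("phi_ranges", PHI_RANGES),
        patterns=config.get("patterns", ("random", "cyclic", "linear")),
        n_replicates=config.get("n_replicates", 100),
        nyears=config.get("nyears", 20),
        random_seed=config.get("random_seed", 0),
    )
    arms = config.get("treatment_arms", False)
    if arms:
        overrides = arms if isinstance(arms, dict) else {}
        grid += treatment_grid(
            phi_ranges=overrides.get("phi_ranges", config.get("phi_ranges", PHI_RANGES)),
            trend_pct=overrides.get("trend_pct", -1.2),
            n_replicates=overrides.get("n_replicates", config.get("n_replicates", 100)),
            nyears=config.get("nyears", 20),
        )
    if not grid:
        raise ValueError("configuration produces an empty scenario grid")
    return grid


def load_design_config(path: str | Path) -> dict:
    """Read a design configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)
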