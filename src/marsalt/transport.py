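"""Hop counting and end-member travel distances.

One rotation collision in a tumbling experiment is taken to correspond
to one saltation hop, so a tumbling duration maps to a hop count through
the drum rotation rate (default 1 rotation per second: 1 minute = 60
hops, 1 day = 86,400 hops).

Two transport end-members bracket how far a grain travels in n hops of
length L:

* prevailing wind — hops add collinearly; net distance n*L (a maximum);
* isotropic — each hop points in a uniformly random direction on the
  surface plane; the RMS net displacement of that fixed-step 2-D walk is
  sqrt(n)*L (a minimum-transport end-member).

:func:`simulate_walk` validates both closed forms by direct Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidParameterError
from .physics import ParticleClass, PlanetaryEnvironment, WindRegime, hop_length
from .survival import SurvivalCurve, surviving_fraction

__all__ = [
    "TumblingProtocol",
    "TransportScenario",
    "TransportResult",
    "WalkSummary",
    "hops_from_duration",
    "linear_distance",
    "random_walk_distance",
    "simulate_walk",
    "transport_result",
]

WalkMode = Literal["prevailing_wind", "isotropic"]


@dataclass(frozen=True)
class TumblingProtocol:
    """A tumbling run: drum rotation rate (rotations/s) and duration (s)."""

    rotation_rate: float = 1.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rotation_rate > 0.0 and math.isfinite(self.rotation_rate)):
            raise InvalidParameterError(
                f"rotation_rate must be > 0, got {self.rotation_rate!r}"
            )
        if not (self.duration >= 0.0 and math.isfinite(self.duration)):
            raise InvalidParameterError(
                f"duration must be >= 0, got {self.duration!r}"
            )


@dataclass(frozen=True)
class TransportScenario:
    """Inputs for one travel-distance evaluation."""

    environment: PlanetaryEnvironment
    wind: WindRegime
    particle: ParticleClass
    n_hops: int
    mode: WalkMode = "prevailing_wind"

    def __post_init__(self) -> None:
        if self.n_hops < 0:
            raise InvalidParameterError(f"n_hops must be >= 0, got {self.n_hops!r}")
        if self.mode not in ("prevailing_wind", "isotropic"):
            raise InvalidParameterError(f"unknown transport mode {self.mode!r}")


@dataclass(frozen=True)
class TransportResult:
    """Hop length plus both end-member distances (all metres) and the
    surviving spore fraction at the scenario's tumbling time."""

    hop_length: float
    linear_distance: float
    random_walk_distance: float
    surviving_fraction: float


@dataclass(frozen=True)
class WalkSummary:
    """Monte Carlo net-displacement summary over a walker ensemble."""

    mode: WalkMode
    n_hops: int
    hop_length: float
    n_walkers: int
    mean: float
    rms: float
    max: float
    std_error_rms: float


def hops_from_duration(protocol: TumblingProtocol) -> int:
    """Hop count = rotation_rate * duration, rounded half away from zero
    to the nearest integer."""
    raw = protocol.rotation_rate * protocol.duration
    return int(math.floor(raw + 0.5))


def linear_distance(n_hops: int, hop_length: float) -> float:
    """Maximum (prevailing-wind) travel distance n*L in metres."""
    _check_distance_args(n_hops, hop_length)
    return n_hops * hop_length


def random_walk_distance(n_hops: int, hop_length: float) -> float:
    """Minimum-end-member travel distance sqrt(n)*L in metres: the RMS
    net displacement of an isotropic fixed-step walk."""
    _check_distance_args(n_hops, hop_length)
    return math.sqrt(n_hops) * hop_length


def _check_distance_args(n_hops: int, hop_length: float) -> None:
    if n_hops < 0:
        raise InvalidParameterError(f"n_hops must be >= 0, got {n_hops!r}")
    if hop_length < 0.0 or not math.isfinite(hop_length):
        raise InvalidParameterError(f"hop_length must be >= 0, got {hop_length!r}")


def simulate_walk(
    n_hops: int,
    hop_length: float,
    mode: WalkMode = "isotropic",
    n_walkers: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
) -> WalkSummary:
    """Monte Carlo ensemble of fixed-step surface walks.

    In ``prevailing_wind`` mode every hop is collinear, so each walker's
    net displacement is exactly n*L.  In ``isotropic`` mode each hop
    direction is drawn uniformly on [0, 2*pi); the ensemble RMS
    displacement estimates sqrt(n)*L.  ``std_error_rms`` is the standard
    error of the RMS estimate, propagated from the sample variance of
    the squared displacements.
    """
    _check_distance_args(n_hops, hop_length)
    if n_walkers < 1:
        raise InvalidParameterError(f"n_walkers must be >= 1, got {n_walkers!r}")

    if mode == "prevailing_wind":
        r = np.full(n_walkers, n_hops * hop_length, dtype=float)
    elif mode == "isotropic":
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_walkers, n_hops))
        x = hop_length * np.cos(theta).sum(axis=1)
        y = hop_length * np.sin(theta).sum(axis=1)
        r = np.hypot(x, y)
    else:
        raise InvalidParameterError(f"unknown walk mode {mode!r}")

    r2 = r * r
    mean_r2 = float(r2.mean())
    rms = math.sqrt(mean_r2)
    # SE of the RMS via the delta method: var(rms) ~ var(r^2) / (4 n rms^2)
    if n_walkers > 1 and rms > 0.0:
        se = math.sqrt(float(r2.var(ddof=1)) / n_walkers) / (2.0 * rms)
    else:
        se = 0.0
    return WalkSummary(
        mode=mode,
        n_hops=n_hops,
        hop_length=hop_length,
        n_walkers=n_walkers,
        mean=float(r.mean()),
        rms=rms,
        max=float(r.max()),
        std_error_rms=se,
    )


def transport_result(
    scenario: TransportScenario,
    curve: SurvivalCurve,
    rotation_rate: float = 1.0,
) -> TransportResult:
    """Evaluate both end-member distances and the surviving fraction for
    a scenario.

    The survival curve is a function of tumbling time; the hop count is
    converted back to time through ``rotation_rate`` (hops per second).
    """
    L = hop_length(scenario.environment, scenario.wind, scenario.particle)
    time_s = scenario.n_hops / rotation_rate
    return TransportResult(
        hop_length=L,
        linear_distance=linear_distance(scenario.n_hops, L),
        random_walk_distance=random_walk_distance(scenario.n_hops, L),
        surviving_fraction=float(surviving_fraction(curve, time_s)),
    )
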