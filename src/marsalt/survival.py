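"""Spore-survival curves under abrasive tumbling.

Tumbling spore-coated grains (a lab proxy for saltation on Mars)
inactivates *Bacillus subtilis* endospores, fastest at the start: about
half the spores die within the first minute, yet ~0.5% are still viable
after a full day.  This module represents that surviving fraction S(t)
in two ways:

* an **interpolant** curve: piecewise-linear in (log t, log S) through a
  set of anchor points, exact at every anchor.  The default anchors are
  the three digitized tumbling-experiment values
  (60 s, 0.50), (3600 s, 0.03), (86400 s, 0.005);
* a **Weibull** curve S(t) = exp(-(t/lambda)**k).  A shape k < 1 gives
  sub-exponential inactivation: each successive halving of the surviving
  population takes longer than the last, which is exactly the observed
  behaviour (1 minute for the first 50%, days for a later 50%).

:func:`fit_weibull` estimates (k, lambda) by least squares on the
linearisation log(-log S) = k*log t - k*log lambda.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FitError, InvalidParameterError, OutOfRangeError

__all__ = [
    "SurvivalAnchor",
    "SurvivalCurve",
    "default_anchors",
    "surviving_fraction",
    "fit_weibull",
    "weibull_curve",
    "interpolant_curve",
    "read_anchors_csv",
    "write_anchors_csv",
]


@dataclass(frozen=True)
class SurvivalAnchor:
    """One digitized point of a survival curve: time in seconds,
    surviving fraction in (0, 1]."""

    time: float
    surviving_fraction: float

    def __post_init__(self) -> None:
        if not (self.time > 0.0 and math.isfinite(self.time)):
            raise InvalidParameterError(f"anchor time must be > 0, got {self.time!r}")
        if not (0.0 < self.surviving_fraction <= 1.0):
            raise InvalidParameterError(
                "anchor surviving_fraction must lie in (0, 1], "
                f"got {self.surviving_fraction!r}"
            )


@dataclass(frozen=True)
class SurvivalCurve:
    """A survival model S(t).

    ``model_kind`` selects the evaluation rule:

    interpolant
        piecewise-linear interpolation in (log t, log S) through
        ``anchors``; evaluation outside the anchor time range raises
        :class:`~marsalt.errors.OutOfRangeError` unless
        ``allow_extrapolation`` is set, in which case the terminal
        segments are extended.
    weibull
        S(t) = exp(-(t / weibull_scale) ** weibull_shape); ``anchors``
        may be empty.
    """

    anchors: tuple[SurvivalAnchor, ...] = ()
    model_kind: Literal["interpolant", "weibull"] = "interpolant"
    weibull_shape: float | None = None
    weibull_scale: float | None = None
    allow_extrapolation: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.model_kind == "interpolant":
            if len(self.anchors) < 2:
                raise InvalidParameterError(
                    "an interpolant survival curve needs at least two anchors"
                )
            times = [a.time for a in self.anchors]
            fracs = [a.surviving_fraction for a in self.anchors]
            if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
                raise InvalidParameterError("anchor times must be strictly increasing")
            if any(f1 < f2 for f1, f2 in zip(fracs, fracs[1:])):
                raise InvalidParameterError(
                    "anchor fractions must be non-increasing in time"
                )
        elif self.model_kind == "weibull":
            if self.weibull_shape is None or self.weibull_scale is None:
                raise InvalidParameterError(
                    "a weibull survival curve needs weibull_shape and weibull_scale"
                )
            if not (self.weibull_shape > 0.0 and self.weibull_scale > 0.0):
                raise InvalidParameterError(
                    "weibull shape and scale must be strictly positive"
                )
        else:  # pragma: no cover - guarded by Literal typing
            raise InvalidParameterError(f"unknown model_kind {self.model_kind!r}")

    # convenience evaluation
    def __call__(self, time):
        return surviving_fraction(self, time)


def default_anchors() -> list[SurvivalAnchor]:
    """The three digitized tumbling anchors: 50% survival at 1 minute,
    3% at 1 hour, 0.5% at 1 day."""
    return [
        SurvivalAnchor(60.0, 0.50),
        SurvivalAnchor(3600.0, 0.03),
        SurvivalAnchor(86400.0, 0.005),
    ]


def interpolant_curve(
    anchors: Sequence[SurvivalAnchor] | None = None,
    *,
    allow_extrapolation: bool = False,
) -> SurvivalCurve:
    """Build a log-log interpolant curve (default anchors if none given)."""
    if anchors is None:
        anchors = default_anchors()
    return SurvivalCurve(
        anchors=tuple(anchors),
        model_kind="interpolant",
        allow_extrapolation=allow_extrapolation,
    )


def weibull_curve(shape: float, scale: float) -> SurvivalCurve:
    """Build a Weibull survival curve S(t) = exp(-(t/scale)**shape)."""
    return SurvivalCurve(
        anchors=(), model_kind="weibull", weibull_shape=shape, weibull_scale=scale
    )


def surviving_fraction(curve: SurvivalCurve, time) -> float | np.ndarray:
    """Evaluate S(t) for scalar or array ``time`` (seconds, > 0)."""
    t = np.asarray(time, dtype=float)
    if np.any(t <= 0.0) or not np.all(np.isfinite(t)):
        raise InvalidParameterError("evaluation time must be strictly positive")
    if curve.model_kind == "weibull":
        out = np.exp(-((t / curve.weibull_scale) ** curve.weibull_shape))
        return float(out) if np.isscalar(time) or t.ndim == 0 else out

    times = np.array([a.time for a in curve.anchors])
    if not curve.allow_extrapolation and (
        np.any(t < times[0]) or np.any(t > times[-1])
    ):
        raise OutOfRangeError(
            f"time outside anchor range [{times[0]}, {times[-1]}] s; "
            "enable extrapolation explicitly to evaluate there"
        )
    log_t = np.log(times)
    log_s = np.log([a.surviving_fraction for a in curve.anchors])
    # np.interp clamps outside the range; extend the terminal segments
    # instead so extrapolation follows the local power law.
    slopes = np.diff(log_s) / np.diff(log_t)
    x = np.log(t)
    out = np.interp(x, log_t, log_s)
    out = np.where(x < log_t[0], log_s[0] + slopes[0] * (x - log_t[0]), out)
    out = np.where(x > log_t[-1], log_s[-1] + slopes[-1] * (x - log_t[-1]), out)
    out = np.exp(out)
    return float(out) if np.isscalar(time) or t.ndim == 0 else out


def fit_weibull(
    data: Iterable[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Fit (k, lambda) of S(t) = exp(-(t/lambda)**k) by (optionally
    weighted) least squares on log(-log S) vs log t.

    ``data`` is an iterable of (time_s, surviving_fraction) pairs with
    times strictly positive and fractions strictly inside (0, 1) — a
    fraction of exactly 1 or 0 has no finite log(-log S).  Returns the
    shape ``k`` (the regression slope) and the scale ``lambda`` in
    seconds.  Raises :class:`~marsalt.errors.FitError` on fewer than two
    usable points or degenerate (all-equal) times.
    """
    pts = [(float(t), float(s)) for t, s in data]
    if any(not (t > 0.0 and math.isfinite(t)) for t, _ in pts):
        raise FitError("fit times must be strictly positive and finite")
    if any(not (0.0 < s < 1.0) for _, s in pts):
        raise FitError("fit fractions must lie strictly inside (0, 1)")
    if len(pts) < 2:
        raise FitError(f"need at least two points to fit, got {len(pts)}")
    log_t = np.log([t for t, _ in pts])
    if np.ptp(log_t) == 0.0:
        raise FitError("fit times are degenerate (all equal)")
    y = np.log(-np.log([s for _, s in pts]))
    w = None if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    slope, intercept = np.polyfit(log_t, y, 1, w=w)
    k = float(slope)
    if k <= 0.0:
        raise FitError(f"fitted shape k={k:.4g} is non-positive; data are not decaying")
    lam = float(math.exp(-intercept / k))
    return k, lam


def read_anchors_csv(path: str | Path) -> list[SurvivalAnchor]:
    """Read anchors from a two-column CSV with columns time_s, fraction."""
    df = pd.read_csv(path)
    missing = {"time_s", "fraction"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"anchor CSV missing columns: {sorted(missing)}")
    return [
        SurvivalAnchor(float(row.time_s), float(row.fraction))
        for row in df.itertuples()
    ]


def write_anchors_csv(anchors: Sequence[SurvivalAnchor], path: str | Path) -> None:
    """Write anchors to a two-column CSV (time_s, fraction)."""
    pd.DataFrame(
        {
            "time_s": [a.time for a in anchors],
            "fraction": [a.surviving_fraction for a in anchors],
        }
    ).to_csv(path, index=False)
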