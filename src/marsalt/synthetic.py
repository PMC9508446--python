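"""Synthetic tumbling-experiment generator.

Emulates the structure of a spore-tumbling survival assay: spores coated
on grains are tumbled, aliquots are plated at a series of time points,
and colony-forming units (CFU) are counted, alongside an untumbled
control series plated at the same times.  The generator draws counts
from a Poisson distribution with mean ``initial_cfu * S_true(t)``
(``initial_cfu`` for the control), the standard counting-noise model for
plate assays; an expected-value mode with no noise supports exact
pipeline tests.

The output is a tidy table with one row per (time, replicate, group),
ready for :func:`marsalt.survival.fit_weibull` via
:func:`empirical_fractions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .survival import (
    SurvivalCurve,
    default_anchors,
    fit_weibull,
    surviving_fraction,
    weibull_curve,
)

__all__ = [
    "SyntheticExperimentConfig",
    "default_true_curve",
    "generate_tumbling_series",
    "empirical_fractions",
    "fit_from_counts",
]


def default_true_curve() -> SurvivalCurve:
    """Synthetic ground-truth Weibull fitted to the three digitized
    anchors (k ~ 0.285, lambda ~ 134 s); used only as simulation truth,
    never presented as experimental data."""
    k, lam = fit_weibull(
        [(a.time, a.surviving_fraction) for a in default_anchors()]
    )
    return weibull_curve(k, lam)


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Configuration of one synthetic tumbling experiment.

    Parameters
    ----------
    true_curve : SurvivalCurve
        Ground-truth survival model (Weibull mode).
    initial_cfu : int
        Expected CFU count of an untumbled plating, >= 1.
    sampling_times : tuple of float
        Plating times in seconds, strictly positive and increasing.
    replicates : int
        Platings per time point and group, >= 1.
    seed : int
        Seed for the Poisson draws.
    noise : {"poisson", "none"}
        "none" emits expected values (rounded to integer counts).
    """

    true_curve: SurvivalCurve = field(default_factory=default_true_curve)
    initial_cfu: int = 200
    sampling_times: tuple[float, ...] = tuple(np.geomspace(10.0, 1000.0, 20))
    replicates: int = 3
    seed: int = 0
    noise: Literal["poisson", "none"] = "poisson"

    def __post_init__(self) -> None:
        if self.initial_cfu < 1:
            raise InvalidParameterError(
                f"initial_cfu must be >= 1, got {self.initial_cfu!r}"
            )
        if self.replicates < 1:
            raise InvalidParameterError(
                f"replicates must be >= 1, got {self.replicates!r}"
            )
        times = self.sampling_times
        if len(times) == 0:
            raise InvalidParameterError("sampling_times must be non-empty")
        if any(not (t > 0.0 and math.isfinite(t)) for t in times):
            raise InvalidParameterError("sampling_times must be strictly positive")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise InvalidParameterError("sampling_times must be strictly increasing")
        if self.noise not in ("poisson", "none"):
            raise InvalidParameterError(f"unknown noise model {self.noise!r}")


def generate_tumbling_series(config: SyntheticExperimentConfig) -> pd.DataFrame:
    """Generate a synthetic CFU table.

    Returns a tidy DataFrame with columns ``time_s``, ``replicate``
    (1-based), ``group`` ("tumbled" or "control") and ``cfu``.  The
    tumbled series has expected count ``initial_cfu * S_true(t)``; the
    control series (no tumbling, S = 1) has expected count
    ``initial_cfu`` at every time.  Identical configs (including seed)
    produce identical tables.
    """
    times = np.asarray(config.sampling_times, dtype=float)
    s_true = np.asarray(surviving_fraction(config.true_curve, times), dtype=float)
    mean_tumbled = config.initial_cfu * s_true
    mean_control = np.full_like(mean_tumbled, float(config.initial_cfu))

    rng = np.random.default_rng(config.seed)
    rows = []
    for group, means in (("tumbled", mean_tumbled), ("control", mean_control)):
        for rep in range(1, config.replicates + 1):
            if config.noise == "poisson":
                counts = rng.poisson(means)
            else:
                counts = np.rint(means).astype(int)
            for t, c in zip(times, counts):
                rows.append((t, rep, group, int(c)))
    return pd.DataFrame(rows, columns=["time_s", "replicate", "group", "cfu"])


def empirical_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a generated CFU table to one empirical surviving fraction
    per time point.

    The fraction at each time is the replicate-summed tumbled count
    divided by the replicate-summed control count at the same time,
    which cancels plating-efficiency offsets the way a paired control
    is meant to.  Returns a DataFrame with columns ``time_s`` and
    ``fraction``.
    """
    required = {"time_s", "replicate", "group", "cfu"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"CFU table missing columns: {sorted(missing)}")
    totals = table.groupby(["time_s", "group"])["cfu"].sum().unstack("group")
    if "control" not in totals or "tumbled" not in totals:
        raise InvalidParameterError("CFU table must contain both groups")
    frac = (totals["tumbled"] / totals["control"]).rename("fraction")
    return frac.reset_index()


def fit_from_counts(table: pd.DataFrame) -> tuple[float, float]:
    """Fit Weibull (k, lambda) from a generated CFU table.

    Empirical fractions are computed per time point; points whose
    fraction falls outside (0, 1) (extinct platings, or noise pushing
    the tumbled count above the control) carry no log(-log S)
    information and are dropped.  The remaining points enter
    :func:`marsalt.survival.fit_weibull` with inverse-variance weights
    from the delta method, var(log(-log S)) ~ (1 - S) / (N S (log S)^2)
    with N the summed control count — binomial counting error pushed
    through the double log, which otherwise lets the noisiest early
    points (S near 1) dominate the fit.
    """
    frac = empirical_fractions(table)
    controls = table[table["group"] == "control"].groupby("time_s")["cfu"].sum()
    n_ref = controls.reindex(frac["time_s"]).to_numpy(dtype=float)
    s = frac["fraction"].to_numpy(dtype=float)
    keep = (s > 0.0) & (s < 1.0) & (n_ref > 0)
    s, t, n_ref = s[keep], frac["time_s"].to_numpy(dtype=float)[keep], n_ref[keep]
    var = (1.0 - s) / (n_ref * s * np.log(s) ** 2)
    weights = 1.0 / np.maximum(var, 1e-300)
    return fit_weibull(list(zip(t, s)), weights=weights)
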