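"""Reduction of NADH-coupled assay traces to wild-type-relative activities.

The cleavage assays couple the aldolase reaction to NADH-consuming
auxiliary enzymes and monitor the absorbance decrease at 340 nm. The
reduction chain is

    trace -> initial rate (dA340/min) -> specific activity (min^-1, via
    Beer-Lambert) -> activity relative to the wild-type enzyme (wt = 1),

which is the quantity the specificity models are trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

NADH_EPSILON_340 = 6220.0  # M^-1 cm^-1, molar absorptivity of NADH at 340 nm

SUBSTRATES = ("DRP", "DR", "ACET", "FORM_ACET")
ROUNDS = (1, 2, 3)


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A 340 nm time course with the assay metadata needed for reduction."""

    time_s: np.ndarray
    a340: np.ndarray
    enzyme_conc_uM: float
    path_cm: float
    substrate: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("time and absorbance must be 1-D arrays of equal length")
        if len(t) < 5:
            raise ValueError("a trace needs at least 5 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance values must be finite")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "a340", a)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class ActivityRecord:
    """One variant x substrate measurement relative to wild type (wt = 1)."""

    variant: str
    substrate: str
    relative_activity: float
    round: int = 1
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"substrate must be one of {SUBSTRATES}, got {self.substrate!r}")
        if self.relative_activity < 0:
            raise ValueError("relative activity cannot be negative")
        if self.round not in ROUNDS:
            raise ValueError(f"mutagenesis round must be one of {ROUNDS}")


def initial_rate(
    trace: AbsorbanceTrace,
    window_fraction: float = 0.1,
    mode: str = "fraction",
    r2_min: float = 0.99,
) -> float:
    """Initial decline rate of a trace, in absorbance units per minute.

    ``mode="fraction"`` fits a least-squares line to the first
    ``window_fraction`` of the points (at least 3); ``mode="linear_prefix"``
    instead uses the longest prefix whose linear fit keeps R^2 >= r2_min.
    The slope is sign-flipped so a declining trace gives a positive rate; a
    rising trace yields 0 with a warning.
    """
    n = len(trace)
    if mode == "fraction":
        if not 0 < window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")
        k = max(3, int(np.ceil(window_fraction * n)))
    elif mode == "linear_prefix":
        k = _best_linear_prefix(trace.time_s, trace.a340, r2_min)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if k < 3:
        raise ValueError("initial-rate window must contain at least 3 points")
    t, a = trace.time_s[:k], trace.a340[:k]
    slope_per_s = np.polyfit(t, a, 1)[0]
    rate = -slope_per_s * 60.0
    if rate < 0:
        # tolerate numerically-zero slopes from flat traces
        if rate > -1e-12 * max(1.0, float(np.max(np.abs(a)))):
            return 0.0
        warnings.warn("absorbance rises over the initial window; rate set to 0", stacklevel=2)
        return 0.0
    return float(rate)


def _best_linear_prefix(t: np.ndarray, a: np.ndarray, r2_min: float) -> int:
    best = 3
    for k in range(3, len(t) + 1):
        coeffs = np.polyfit(t[:k], a[:k], 1)
        resid = a[:k] - np.polyval(coeffs, t[:k])
        ss_tot = float(np.sum((a[:k] - a[:k].mean()) ** 2))
        if ss_tot == 0.0:
            best = k
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        if r2 >= r2_min:
            best = k
        else:
            break
    return best


def specific_activity(
    rate_per_min: float,
    epsilon: float = NADH_EPSILON_340,
    path_cm: float | None = None,
    enzyme_conc_uM: float | None = None,
    stoichiometry: float = 1.0,
) -> float:
    """Turnovers per minute per enzyme from an absorbance decline rate.

    Beer-Lambert converts dA/min to M/min of NADH consumed; dividing by
    the NADH-per-substrate-event stoichiometry and the enzyme
    concentration yields min^-1 per enzyme. The optical path length is
    instrument-dependent and therefore a required argument.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be nonnegative")
    if path_cm is None or enzyme_conc_uM is None:
        raise ValueError("path_cm and enzyme_conc_uM are required")
    for name, value in (("epsilon", epsilon), ("path_cm", path_cm),
                        ("enzyme_conc_uM", enzyme_conc_uM), ("stoichiometry", stoichiometry)):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    molar_per_min = rate_per_min / (epsilon * path_cm)
    umolar_per_min = molar_per_min * 1e6
    return umolar_per_min / stoichiometry / enzyme_conc_uM


def reduce_trace(
    trace: AbsorbanceTrace,
    window_fraction: float = 0.1,
    epsilon: float = NADH_EPSILON_340,
    stoichiometry: float = 1.0,
    mode: str = "fraction",
) -> float:
    """Trace straight to specific activity (min^-1), using its metadata."""
    rate = initial_rate(trace, window_fraction=window_fraction, mode=mode)
    return specific_activity(rate, epsilon=epsilon, path_cm=trace.path_cm,
                             enzyme_conc_uM=trace.enzyme_conc_uM,
                             stoichiometry=stoichiometry)


def relative_to_wt(activities: Mapping[str, float], wt_key: str = "WT") -> dict[str, float]:
    """Divide every specific activity by the wild type's (wild type -> exactly 1)."""
    if wt_key not in activities:
        raise ValueError(f"wild-type entry {wt_key!r} missing from activities")
    wt = activities[wt_key]
    if wt <= 0:
        raise ValueError("wild-type activity must be positive to normalize against")
    return {k: v / wt for k, v in activities.items()}
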