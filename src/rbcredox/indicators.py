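"""Indicators of redox imbalance computed from one perturbation run.

Three quantities summarise a subject's response to the oxidative dose:

- *initial GSH/GSSG* — the redox ratio at the pre-perturbation steady
  state;
- *amount of change* — the fractional dip of the ratio,
  (ratio_ss - ratio_min) / ratio_ss;
- *recovery time* — the first time after the minimum at which the ratio
  regains a threshold fraction theta of its initial value (the ratio
  approaches its steady state asymptotically, so exact return is never
  attained; theta defaults to 0.99 and is reported with every value).

A subject whose ratio stays below the threshold for the whole
observation window is assigned the ``NOT_RECOVERED`` sentinel
(``math.inf``), which downstream statistics may cap at the window length
or drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import SteadyState, Trajectory

__all__ = [
    "NOT_RECOVERED",
    "IndicatorSet",
    "initial_ratio",
    "amount_of_change",
    "recovery_time",
    "compute_indicators",
    "is_recovered",
]

#: Sentinel for a subject that never regains the threshold within the window.
NOT_RECOVERED = math.inf


def is_recovered(value: float) -> bool:
    return math.isfinite(value)


@dataclass(frozen=True)
class IndicatorSet:
    """Redox-imbalance indicators for one subject."""

    initial_ratio: float
    min_ratio: float
    amount_of_change: float
    recovery_time: float  # seconds, or NOT_RECOVERED
    theta: float

    def __post_init__(self) -> None:
        if not (0 <= self.amount_of_change <= 1):
            raise ValueError("amount of change must lie in [0, 1]")
        if self.min_ratio > self.initial_ratio * (1 + 1e-12):
            raise ValueError("minimum ratio cannot exceed the initial ratio")
        if self.recovery_time < 0:
            raise ValueError("recovery time must be non-negative")


def initial_ratio(ss: SteadyState) -> float:
    """GSH/GSSG at the pre-perturbation steady state."""
    gssg = ss.state["GSSG"]
    if gssg == 0:
        raise ZeroDivisionError("GSSG is zero at steady state; the redox ratio is undefined")
    return ss.state["GSH"] / gssg


def amount_of_change(initial: float, minimum: float) -> float:
    """Fractional dip (initial - minimum) / initial of the redox ratio."""
    if initial <= 0:
        raise ValueError("initial ratio must be positive")
    if minimum < 0:
        raise ValueError("minimum ratio cannot be negative")
    if minimum > initial * (1 + 1e-12):
        raise ValueError(
            f"minimum ratio {minimum:g} exceeds initial {initial:g}: the ratio rose, not a dip")
    return max(0.0, (initial - minimum) / initial)


def _refined_minimum(t: np.ndarray, r: np.ndarray) -> tuple[int, float, float]:
    """Discrete argmin with parabolic refinement of the minimum value.

    Returns ``(index, t_min, r_min)``.  The refinement fits a parabola
    through the minimum sample and its neighbours; it is skipped at the
    grid edges or when the three points are not convex.
    """
    i = int(np.argmin(r))
    if 0 < i < len(r) - 1:
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            delta = 0.5 * (y0 - y2) / denom
            if -1.0 < delta < 1.0:
                t_min = t[i] + delta * (t[min(i + 1, len(t) - 1)] - t[i])
                r_min = y1 - 0.25 * (y0 - y2) * delta
                return i, float(t_min), float(min(r_min, y1))
    return i, float(t[i]), float(r[i])


def recovery_time(
    traj: Trajectory,
    theta: float = 0.99,
    window: float = 1800.0,
    baseline: float | None = None,
) -> float:
    """First time after the ratio minimum at which ratio >= theta * baseline.

    ``baseline`` defaults to the trajectory's first sample (for a bolus
    run the ratio at t = 0 is the unperturbed steady-state ratio; for a
    synthetic trace pass the asymptote explicitly).  The crossing is
    located by linear interpolation between recorded samples.  Returns
    0.0 when the ratio never drops below the threshold and
    ``NOT_RECOVERED`` when it never regains it within the window.
    """
    if not (0 < theta < 1):
        raise ValueError("theta must lie in (0, 1)")
    if traj.t[-1] < window * (1 - 1e-9):
        raise ValueError(
            f"trajectory ends at {traj.t[-1]:g} s, shorter than the window {window:g} s")
    mask = traj.t <= window * (1 + 1e-9)
    t = traj.t[mask]
    r = traj.ratio[mask]
    if baseline is None:
        baseline = float(r[0])
    threshold = theta * baseline

    i_min = int(np.argmin(r))
    if r[i_min] >= threshold:
        return 0.0
    below = r < threshold
    for j in range(i_min + 1, len(t)):
        if not below[j]:
            # linear interpolation between samples j-1 and j
            r0, r1 = r[j - 1], r[j]
            if r1 == r0:
                return float(t[j])
            frac = (threshold - r0) / (r1 - r0)
            return float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return NOT_RECOVERED


def compute_indicators(
    ss: SteadyState,
    traj: Trajectory,
    theta: float = 0.99,
    window: float = 1800.0,
) -> IndicatorSet:
    """All three indicators for one perturbation run."""
    r0 = initial_ratio(ss)
    _, _, r_min = _refined_minimum(traj.t, traj.ratio)
    r_min = min(r_min, r0)
    return IndicatorSet(
        initial_ratio=r0,
        min_ratio=r_min,
        amount_of_change=amount_of_change(r0, r_min),
        recovery_time=recovery_time(traj, theta=theta, window=window, baseline=r0),
        theta=theta,
    )
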