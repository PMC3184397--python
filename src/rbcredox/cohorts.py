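"""Subject generation: reference patients, virtual patients, synthetic traces.

The reference set holds the published kinetic parameters of ten
G6PD-deficient patients plus a healthy control.  Virtual patients are
parameter vectors drawn independently and uniformly from the published
realistic ranges (each spanning the minimum to maximum of the reference
set); 500 virtual patients per trial run is the study's convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import PatientKinetics
from .protocol import Trajectory

__all__ = [
    "REFERENCE_PATIENTS",
    "SamplingRanges",
    "DEFAULT_RANGES",
    "SyntheticTrajectorySpec",
    "load_reference_patients",
    "sample_virtual_patients",
    "synth_ratio_trajectory",
    "cohort_to_frame",
    "frame_to_cohort",
]

# (vmax, km_g6p, km_nadp, ki_nadph, ki_atp, ki_23bpg) per subject
_REFERENCE_ROWS = [
    ("Patient 1", 1.1, 152.0, 3.8, 0.62, 180.0, 520.0),
    ("Patient 2", 36.7, 140.0, 115.0, 33.6, 4687.0, 8515.0),
    ("Patient 3", 0.8, 7.0, 4.1, 8.9, 952.0, 1071.0),
    ("Patient 4", 0.8, 43.0, 155.0, 56.0, 11000.0, 35000.0),
    ("Patient 5", 37.1, 57.0, 30.5, 3.7, 5016.0, 5507.0),
    ("Patient 6", 14.5, 66.0, 3.5, 1.1, 212.0, 532.0),
    ("Patient 7", 8.9, 80.0, 3.6, 1.0, 125.0, 586.0),
    ("Patient 8", 0.8, 68.0, 1.4, 0.9, 500.0, 2000.0),
    ("Patient 9", 0.6, 40.0, 4.8, 6.9, 314.0, 3784.0),
    ("Patient 10", 18.9, 79.0, 3.0, 4.1, 407.0, 2200.0),
    ("Control", 64.0, 67.0, 3.7, 3.1, 749.0, 2289.0),
]

REFERENCE_PATIENTS: tuple[PatientKinetics, ...] = tuple(
    PatientKinetics(vmax=v, km_g6p=kg, km_nadp=kn, ki_nadph=kih, ki_atp=kia,
                    ki_23bpg=kib, label=label)
    for label, v, kg, kn, kih, kia, kib in _REFERENCE_ROWS
)


def load_reference_patients() -> list[PatientKinetics]:
    """The ten published G6PD-deficient patients plus the healthy control."""
    return list(REFERENCE_PATIENTS)


@dataclass(frozen=True)
class SamplingRanges:
    """Closed sampling intervals for each kinetic parameter (uM except vmax)."""

    vmax: tuple[float, float] = (1.0, 64.0)
    km_g6p: tuple[float, float] = (7.0, 152.0)
    km_nadp: tuple[float, float] = (3.0, 155.0)
    ki_nadph: tuple[float, float] = (1.0, 56.0)
    ki_atp: tuple[float, float] = (125.0, 11000.0)
    ki_23bpg: tuple[float, float] = (520.0, 35000.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid interval for {name!r}: [{lo}, {hi}]")

    def items(self):
        return [(f, getattr(self, f)) for f in
                ("vmax", "km_g6p", "km_nadp", "ki_nadph", "ki_atp", "ki_23bpg")]


DEFAULT_RANGES = SamplingRanges()


def sample_virtual_patients(
    n: int,
    ranges: SamplingRanges | None = None,
    seed: int | np.random.Generator | None = None,
    log_uniform: bool = False,
    label_prefix: str = "VP",
) -> list[PatientKinetics]:
    """Draw ``n`` virtual patients, each parameter independent and uniform
    on its interval (``log_uniform=True`` draws uniformly in log space,
    an option for the wide inhibition-constant ranges).

    A fixed integer ``seed`` makes the draw reproducible; a Generator may
    be passed directly to continue an existing stream.
    """
    if n < 0:
        raise ValueError(f"cohort size must be non-negative, got {n}")
    ranges = ranges or DEFAULT_RANGES
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fields = ranges.items()
    draws = {}
    for name, (lo, hi) in fields:
        if log_uniform:
            draws[name] = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
        else:
            draws[name] = rng.uniform(lo, hi, size=n)
        # guard against any floating artefact outside the closed interval
        draws[name] = np.clip(draws[name], lo, hi)
    width = max(4, len(str(n)))
    return [
        PatientKinetics(
            vmax=float(draws["vmax"][i]),
            km_g6p=float(draws["km_g6p"][i]),
            km_nadp=float(draws["km_nadp"][i]),
            ki_nadph=float(draws["ki_nadph"][i]),
            ki_atp=float(draws["ki_atp"][i]),
            ki_23bpg=float(draws["ki_23bpg"][i]),
            label=f"{label_prefix}{i + 1:0{width}d}",
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Exponential-recovery ratio trace r(t) = r0 (1 - a exp(-t/tau)).

    ``r0`` is the asymptotic (pre-perturbation) ratio, ``dip`` the
    fractional dip a in (0, 1], ``tau`` the recovery time constant (s).
    """

    r0: float = 700.0
    dip: float = 0.2
    tau: float = 60.0
    step: float = 1.0
    window: float = 1800.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (0 <= self.dip <= 1):
            raise ValueError("dip fraction must lie in [0, 1]")
        if self.tau <= 0 or self.step <= 0 or self.window <= 0:
            raise ValueError("tau, step and window must be positive")

    def crossing_time(self, theta: float) -> float:
        """Closed-form time at which r(t) reaches theta*r0 (requires dip > 1-theta)."""
        return self.tau * math.log(self.dip / (1.0 - theta))


def synth_ratio_trajectory(spec: SyntheticTrajectorySpec) -> Trajectory:
    """Sample the analytic recovery trace on its time grid (ratio channel only)."""
    t = np.arange(0.0, spec.window + 0.5 * spec.step, spec.step)
    ratio = spec.r0 * (1.0 - spec.dip * np.exp(-t / spec.tau))
    return Trajectory(t=t, species={}, fluxes={}, ratio=ratio)


def cohort_to_frame(patients: list[PatientKinetics]) -> pd.DataFrame:
    """One row per patient: label plus the six kinetic parameters."""
    return pd.DataFrame([p.as_dict() for p in patients])[
        ["label", "vmax", "km_g6p", "km_nadp", "ki_nadph", "ki_atp", "ki_23bpg"]
    ]


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientKinetics]:
    return [
        PatientKinetics(
            vmax=row.vmax, km_g6p=row.km_g6p, km_nadp=row.km_nadp,
            ki_nadph=row.ki_nadph, ki_atp=row.ki_atp, ki_23bpg=row.ki_23bpg,
            label=str(row.label),
        )
        for row in frame.itertuples(index=False)
    ]
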