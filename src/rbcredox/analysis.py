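"""Cohort-level analyses: indicator tables, correlations, parameter grids.

The unit of analysis is the cohort table — one row per subject holding
the six G6PD kinetic parameters joined with the three redox-imbalance
indicators from the perturbation protocol.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import compute_indicators
from .network import NetworkModel, PatientKinetics, build_default_model
from .protocol import ProtocolConfig, find_steady_state, run_perturbation

__all__ = [
    "CohortError",
    "GridSpec",
    "evaluate_subject",
    "evaluate_cohort",
    "indicator_correlations",
    "vmax_km_grid",
    "grid_to_long_frame",
    "trend_summary",
]

INDICATOR_COLUMNS = ["initial_ratio", "min_ratio", "amount_of_change", "recovery_time"]
PARAM_COLUMNS = ["vmax", "km_g6p", "km_nadp", "ki_nadph", "ki_atp", "ki_23bpg"]


class CohortError(RuntimeError):
    """Raised when every subject in a cohort failed to evaluate."""


def evaluate_subject(
    kin: PatientKinetics,
    model: NetworkModel | None = None,
    cfg: ProtocolConfig | None = None,
):
    """Full protocol for one subject: steady state, perturbation, indicators."""
    model = model or build_default_model()
    cfg = cfg or ProtocolConfig()
    ss = find_steady_state(model, kin, cfg)
    traj = run_perturbation(model, kin, ss, cfg)
    ind = compute_indicators(ss, traj, theta=cfg.theta, window=cfg.window)
    return ss, traj, ind


def evaluate_cohort(
    patients: list[PatientKinetics],
    model: NetworkModel | None = None,
    cfg: ProtocolConfig | None = None,
    provenance: str = "real",
    run_index: int = 0,
) -> pd.DataFrame:
    """Indicator table for a cohort; per-subject failures are recorded
    in the ``error`` column rather than aborting the whole cohort.
    """
    if not patients:
        raise ValueError("cohort must be non-empty")
    model = model or build_default_model()
    cfg = cfg or ProtocolConfig()
    rows = []
    n_failed = 0
    for kin in patients:
        row: dict = {"label": kin.label, **{c: getattr(kin, c) for c in PARAM_COLUMNS}}
        try:
            _, _, ind = evaluate_subject(kin, model, cfg)
            row.update(
                initial_ratio=ind.initial_ratio,
                min_ratio=ind.min_ratio,
                amount_of_change=ind.amount_of_change,
                recovery_time=ind.recovery_time,
                theta=ind.theta,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - failures are data here
            n_failed += 1
            row.update(
                initial_ratio=np.nan, min_ratio=np.nan,
                amount_of_change=np.nan, recovery_time=np.nan,
                theta=cfg.theta, error=str(exc),
            )
        rows.append(row)
    if n_failed == len(patients):
        raise CohortError(f"all {n_failed} subjects failed to evaluate")
    table = pd.DataFrame(rows)
    table["provenance"] = provenance
    table["run"] = run_index
    return table


def _usable(table: pd.DataFrame, policy: str, window: float) -> pd.DataFrame:
    ok = table[table["error"] == ""] if "error" in table.columns else table
    ok = ok.dropna(subset=["initial_ratio", "amount_of_change", "recovery_time"])
    if policy == "window_cap":
        ok = ok.assign(recovery_time=np.minimum(ok["recovery_time"], window))
    elif policy == "drop":
        ok = ok[np.isfinite(ok["recovery_time"])]
    else:
        raise ValueError(f"unknown NOT_RECOVERED policy {policy!r}")
    return ok


def indicator_correlations(
    table: pd.DataFrame,
    not_recovered_policy: str = "window_cap",
    window: float = 1800.0,
) -> pd.DataFrame:
    """Pairwise Pearson coefficients among the three indicators.

    Rows with the NOT_RECOVERED sentinel are capped at the window length
    (``"window_cap"``) or removed (``"drop"``) before the computation.
    The result carries the used-row count in ``.attrs["n_used"]``; a
    zero-variance column yields NaN for its pairs.
    """
    cols = ["initial_ratio", "recovery_time", "amount_of_change"]
    ok = _usable(table, not_recovered_policy, window)
    if len(ok) < 3:
        raise ValueError(f"need at least 3 usable rows, got {len(ok)}")
    out = pd.DataFrame(np.eye(3), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        x = ok[a].to_numpy(float)
        y = ok[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        out.loc[a, b] = out.loc[b, a] = r
    out.attrs["n_used"] = len(ok)
    out.attrs["policy"] = not_recovered_policy
    return out


@dataclass(frozen=True)
class GridSpec:
    """Vmax x KmG6P evaluation grid with the other four parameters fixed.

    The fixed values default to the healthy control's constants.  A zero
    on either axis is evaluated at ``floor`` instead (a vanishing Vmax or
    Michaelis constant makes the G6PD rate law degenerate); the
    substitution is recorded in the returned surfaces' metadata.
    """

    vmax_values: tuple[float, ...] = tuple(float(v) for v in range(0, 65, 1))
    km_values: tuple[float, ...] = tuple(float(k) for k in range(0, 201, 2))
    km_nadp: float = 3.7
    ki_nadph: float = 3.1
    ki_atp: float = 749.0
    ki_23bpg: float = 2289.0
    floor: float = 0.01

    def __post_init__(self) -> None:
        if not self.vmax_values or not self.km_values:
            raise ValueError("grid axes must be non-empty")
        for name in ("km_nadp", "ki_nadph", "ki_atp", "ki_23bpg", "floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def coarse(cls, vmax_step: int = 8, km_step: int = 25, **fixed) -> "GridSpec":
        return cls(
            vmax_values=tuple(float(v) for v in range(0, 65, vmax_step)),
            km_values=tuple(float(k) for k in range(0, 201, km_step)),
            **fixed,
        )


def vmax_km_grid(
    grid: GridSpec,
    model: NetworkModel | None = None,
    cfg: ProtocolConfig | None = None,
) -> dict:
    """Indicator surfaces over the (Vmax, KmG6P) grid.

    Returns a dict with the two axes and one 2-D array per indicator
    (``initial_ratio``, ``recovery_time``, ``amount_of_change``), shaped
    ``(len(vmax_values), len(km_values))``.  Cells with the NOT_RECOVERED
    sentinel hold ``inf`` in the recovery surface; per-cell failures hold
    NaN and are listed under ``"failures"``.
    """
    model = model or build_default_model()
    cfg = cfg or ProtocolConfig()
    nv, nk = len(grid.vmax_values), len(grid.km_values)
    surfaces = {name: np.full((nv, nk), np.nan) for name in
                ("initial_ratio", "recovery_time", "amount_of_change")}
    failures = []
    substituted = []
    for i, vmax in enumerate(grid.vmax_values):
        for j, km in enumerate(grid.km_values):
            v_eff = vmax if vmax > 0 else grid.floor
            k_eff = km if km > 0 else grid.floor
            if v_eff != vmax or k_eff != km:
                substituted.append((vmax, km))
            kin = PatientKinetics(
                vmax=v_eff, km_g6p=k_eff, km_nadp=grid.km_nadp,
                ki_nadph=grid.ki_nadph, ki_atp=grid.ki_atp,
                ki_23bpg=grid.ki_23bpg, label=f"grid_v{vmax:g}_k{km:g}",
            )
            try:
                _, _, ind = evaluate_subject(kin, model, cfg)
            except Exception as exc:  # noqa: BLE001
                failures.append((vmax, km, str(exc)))
                continue
            surfaces["initial_ratio"][i, j] = ind.initial_ratio
            surfaces["recovery_time"][i, j] = ind.recovery_time
            surfaces["amount_of_change"][i, j] = ind.amount_of_change
    return {
        "vmax_values": np.asarray(grid.vmax_values),
        "km_values": np.asarray(grid.km_values),
        **surfaces,
        "failures": failures,
        "substituted_cells": substituted,
        "fixed": {"km_nadp": grid.km_nadp, "ki_nadph": grid.ki_nadph,
                  "ki_atp": grid.ki_atp, "ki_23bpg": grid.ki_23bpg},
    }


def grid_to_long_frame(surfaces: dict) -> pd.DataFrame:
    """Long-format (vmax, km_g6p, indicator, value) view of the surfaces."""
    rows = []
    for name in ("initial_ratio", "recovery_time", "amount_of_change"):
        Z = surfaces[name]
        for i, v in enumerate(surfaces["vmax_values"]):
            for j, k in enumerate(surfaces["km_values"]):
                rows.append((float(v), float(k), name, float(Z[i, j])))
    return pd.DataFrame(rows, columns=["vmax", "km_g6p", "indicator", "value"])


def trend_summary(
    table: pd.DataFrame,
    vmax_cut: float,
    km_cut: float,
    window: float = 1800.0,
) -> pd.DataFrame:
    """Stratified indicator dispersion over the 2x2 (Vmax, KmG6P) split.

    Each stratum reports its size, the quartiles and interquartile range
    of every indicator, and the count of subjects whose recovery exceeded
    the observation window.  Empty strata appear with count 0.
    """
    ok = table[table["error"] == ""] if "error" in table.columns else table
    rows = []
    strata = {
        "low_vmax/low_km": (ok["vmax"] < vmax_cut) & (ok["km_g6p"] < km_cut),
        "low_vmax/high_km": (ok["vmax"] < vmax_cut) & (ok["km_g6p"] >= km_cut),
        "high_vmax/low_km": (ok["vmax"] >= vmax_cut) & (ok["km_g6p"] < km_cut),
        "high_vmax/high_km": (ok["vmax"] >= vmax_cut) & (ok["km_g6p"] >= km_cut),
    }
    for name, mask in strata.items():
        sub = ok[mask]
        row: dict = {"stratum": name, "n": len(sub)}
        row["n_abnormal_recovery"] = int((sub["recovery_time"] > window).sum()) if len(sub) else 0
        for col in INDICATOR_COLUMNS:
            if len(sub):
                capped = np.minimum(sub[col], window) if col == "recovery_time" else sub[col]
                q1, q2, q3 = np.nanpercentile(capped, [25, 50, 75])
            else:
                q1 = q2 = q3 = np.nan
            row[f"{col}_q1"] = q1
            row[f"{col}_median"] = q2
            row[f"{col}_q3"] = q3
            row[f"{col}_iqr"] = q3 - q1
        rows.append(row)
    return pd.DataFrame(rows)
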