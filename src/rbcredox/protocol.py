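"""The oxidative-perturbation experiment.

A run has three stages: (1) relax the network to its pre-perturbation
steady state, (2) add the H2O2 dose at t = 0 (by default a bolus raising
the intracellular concentration; clamping the extracellular concentration
is available as an alternative), (3) integrate over the observation
window recording concentrations, reaction fluxes and the derived
GSH/GSSG and NADPH/NADP ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import NetworkModel, PatientKinetics, conserved_totals

__all__ = [
    "ProtocolConfig",
    "SteadyState",
    "Trajectory",
    "SteadyStateError",
    "find_steady_state",
    "run_perturbation",
    "enzyme_activity_series",
]


class SteadyStateError(RuntimeError):
    """Steady-state search failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class ProtocolConfig:
    """Perturbation-experiment settings.

    ``dose`` is the H2O2 perturbation in uM (default 100 uM = 0.1 mM),
    ``window`` the observation length in seconds (default 1800 s, about
    30 min), ``theta`` the recovery threshold as a fraction of the initial
    GSH/GSSG.  ``dose_mode`` selects how the dose is applied:
    ``"bolus_internal"`` raises the intracellular H2O2 instantaneously at
    t = 0; ``"clamp_external"`` holds the extracellular concentration at
    the dose for the whole window.
    """

    dose: float = 100.0
    window: float = 1800.0
    dose_mode: str = "bolus_internal"
    record_step: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    theta: float = 0.99
    ss_horizon: float = 1e6
    ss_residual_tol: float = 1e-9
    max_negative: float = 1e-6  # uM; a dip below -max_negative is an integration failure

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.window <= 0 or self.record_step <= 0:
            raise ValueError("window and record step must be positive")
        if self.dose_mode not in ("bolus_internal", "clamp_external"):
            raise ValueError(f"unknown dose mode {self.dose_mode!r}")
        if not (0 < self.theta < 1):
            raise ValueError("recovery threshold theta must lie in (0, 1)")


@dataclass
class SteadyState:
    """Pre-perturbation steady state of one subject."""

    state: dict[str, float]
    residual: float
    ratio_gsh_gssg: float

    @property
    def ratio_nadph_nadp(self) -> float:
        return self.state["NADPH"] / self.state["NADP"]


@dataclass
class Trajectory:
    """Recorded time courses from one perturbation run.

    ``t`` is the time grid in seconds with t = 0 at the perturbation;
    ``species`` and ``fluxes`` map names to arrays on that grid; ``ratio``
    is the derived GSH/GSSG series (for synthetic ratio-only traces the
    concentration and flux maps are empty).
    """

    t: np.ndarray
    species: dict[str, np.ndarray]
    fluxes: dict[str, np.ndarray]
    ratio: np.ndarray
    nadph_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory time grid must be strictly increasing")
        if len(self.ratio) != len(self.t):
            raise ValueError("ratio series length must match the time grid")

    def to_wide_frame(self) -> pd.DataFrame:
        data = {"time": self.t}
        data.update(self.species)
        data.update({f"flux_{k}": v for k, v in self.fluxes.items()})
        data["ratio_gsh_gssg"] = self.ratio
        if self.nadph_ratio is not None:
            data["ratio_nadph_nadp"] = self.nadph_ratio
        return pd.DataFrame(data)

    def to_tidy_frame(self) -> pd.DataFrame:
        wide = self.to_wide_frame()
        return wide.melt(id_vars="time", var_name="variable", value_name="value")


def _moiety_rows(model: NetworkModel, dynamic_names: list[str]) -> list[tuple[int, dict[str, float], float]]:
    """For the Newton polish: one row per moiety to replace in the residual.

    Replacing one ODE row per conserved moiety by the corresponding linear
    constraint removes the stoichiometric rank deficiency; the replaced
    row is the member species with the largest index (deterministic).
    """
    rows = []
    init = model.initial_state()
    for combo in model.moieties.values():
        members = [dynamic_names.index(sp) for sp in combo if sp in dynamic_names]
        if not members:
            continue
        target = sum(c * init[sp] for sp, c in combo.items() if sp in dynamic_names)
        rows.append((max(members), dict(combo), target))
    return rows


def find_steady_state(
    model: NetworkModel,
    kin: PatientKinetics,
    cfg: ProtocolConfig | None = None,
) -> SteadyState:
    """Relax the network to steady state for one subject.

    Long-horizon stiff integration from the model's initial state,
    followed by a Newton polish of the right-hand side with the conserved
    moieties pinned to their initial values.  Raises
    :class:`SteadyStateError` if the final residual exceeds the tolerance.
    """
    cfg = cfg or ProtocolConfig()
    rhs, rates_fn, y0, dyn_names = model.compile(kin)

    sol = solve_ivp(rhs, (0.0, cfg.ss_horizon), y0, method="BDF",
                    rtol=cfg.rtol, atol=cfg.atol, dense_output=False)
    if not sol.success:
        raise SteadyStateError(f"steady-state relaxation failed: {sol.message}")
    y_rel = sol.y[:, -1]

    mrows = _moiety_rows(model, dyn_names)

    def polish_fn(y):
        f = rhs(0.0, y)
        for row, combo, target in mrows:
            f[row] = sum(c * y[dyn_names.index(sp)] for sp, c in combo.items()
                         if sp in dyn_names) - target
        return f

    res = root(polish_fn, y_rel, method="hybr", tol=1e-13)
    y_ss = res.x if res.success else y_rel
    residual = float(np.abs(rhs(0.0, y_ss)).max())
    if residual > cfg.ss_residual_tol:
        # fall back to the relaxed point if the polish wandered
        residual_rel = float(np.abs(rhs(0.0, y_rel)).max())
        if residual_rel < residual:
            y_ss, residual = y_rel, residual_rel
    if residual > cfg.ss_residual_tol:
        raise SteadyStateError(
            f"no steady state within tolerance for {kin.label!r} "
            f"(residual {residual:.3e} uM/s)", residual=residual)
    if np.any(y_ss < -cfg.max_negative):
        raise SteadyStateError(f"negative steady-state concentration for {kin.label!r}")

    state = model.initial_state()
    state.update({name: max(float(v), 0.0) for name, v in zip(dyn_names, y_ss)})

    totals0 = conserved_totals(model.initial_state(), model)
    totals = conserved_totals(state, model)
    for name, t0 in totals0.items():
        if t0 > 0 and abs(totals[name] - t0) / t0 > 1e-6:
            raise SteadyStateError(
                f"conserved moiety {name!r} drifted during steady-state search")

    if state["GSSG"] <= 0:
        raise SteadyStateError(f"GSSG vanished at steady state for {kin.label!r}")
    return SteadyState(state=state, residual=residual,
                       ratio_gsh_gssg=state["GSH"] / state["GSSG"])


def _perturbed_model(model: NetworkModel, ss_state: Mapping[str, float],
                     cfg: ProtocolConfig) -> NetworkModel:
    """Model whose initial state is the dosed steady state."""
    from .network import SpeciesDef  # local import to avoid cycle noise

    new_initial = dict(ss_state)
    if cfg.dose_mode == "bolus_internal":
        new_initial["H2O2_in"] = new_initial["H2O2_in"] + cfg.dose
    else:  # clamp_external
        new_initial["H2O2_ext"] = cfg.dose
    species = [SpeciesDef(s.name, new_initial[s.name], s.clamped) for s in model.species]
    return NetworkModel(species, model.reactions, model.moieties)


def run_perturbation(
    model: NetworkModel,
    kin: PatientKinetics,
    ss: SteadyState,
    cfg: ProtocolConfig | None = None,
) -> Trajectory:
    """Apply the H2O2 dose at t = 0 and record the response.

    Returns the concentration, flux and ratio series on the recording
    grid covering [0, window].
    """
    cfg = cfg or ProtocolConfig()
    pmodel = _perturbed_model(model, ss.state, cfg)
    rhs, rates_fn, y0, dyn_names = pmodel.compile(kin)

    t_eval = np.arange(0.0, cfg.window + 0.5 * cfg.record_step, cfg.record_step)
    if t_eval[-1] < cfg.window:
        t_eval = np.append(t_eval, cfg.window)
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), y0, method="BDF",
                    rtol=cfg.rtol, atol=cfg.atol, t_eval=t_eval)
    if not sol.success:
        raise SteadyStateError(
            f"perturbation integration failed for {kin.label!r} at t={sol.t[-1]:g}: {sol.message}")

    Y = sol.y
    if Y.min() < -cfg.max_negative:
        i, j = np.unravel_index(np.argmin(Y), Y.shape)
        raise SteadyStateError(
            f"negative concentration {Y[i, j]:.3e} uM for species {dyn_names[i]!r} "
            f"at t={sol.t[j]:g} s for {kin.label!r}")
    Y = np.clip(Y, 0.0, None)  # reporting only; true negatives raised above

    species = {name: Y[i] for i, name in enumerate(dyn_names)}
    fluxes = {r.name: np.empty(len(sol.t)) for r in pmodel.reactions}
    for j in range(len(sol.t)):
        v = rates_fn(Y[:, j])
        for i, r in enumerate(pmodel.reactions):
            fluxes[r.name][j] = v[i]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = species["GSH"] / species["GSSG"]
        nadph_ratio = species["NADPH"] / species["NADP"]
    return Trajectory(t=sol.t, species=species, fluxes=fluxes,
                      ratio=ratio, nadph_ratio=nadph_ratio)


def enzyme_activity_series(
    traj: Trajectory,
    enzymes: tuple[str, ...] = ("G6PD", "CAT", "GSHpx", "SOD", "GR"),
) -> dict[str, np.ndarray]:
    """Flux-through-reaction time courses for the named enzymes."""
    out = {}
    for name in enzymes:
        if name not in traj.fluxes:
            raise KeyError(
                f"unknown enzyme {name!r}; available: {sorted(traj.fluxes)}")
        out[name] = traj.fluxes[name]
    return out
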