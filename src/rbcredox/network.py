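"""Reaction network of the erythrocyte antioxidant system.

The model is a reduced kinetic description of hydrogen-peroxide
detoxification in the red blood cell, centred on the glutathione redox
couple (GSH/GSSG) and its NADPH supply through the oxidative pentose
phosphate pathway.  Dynamic species are intracellular H2O2, superoxide,
GSH, GSSG, NADPH, NADP, G6P and 6-phosphogluconolactone (GL6P);
extracellular H2O2, ATP, 2,3-bisphosphoglycerate and glucose are clamped.

Reactions
---------
- passive H2O2 permeation across the membrane (linear in the gradient),
- superoxide generation (linear in the clamped glucose pool, i.e. a
  constant basal flux while the cell is metabolically active),
- superoxide dismutase (SOD), first order in O2-, 2 O2- -> H2O2,
- catalase (CAT), first order in H2O2, 2 H2O2 -> H2O + O2,
- glutathione peroxidase (GSHpx), bi-substrate Michaelis-Menten,
  H2O2 + 2 GSH -> GSSG,
- glutathione reductase (GR), bi-substrate Michaelis-Menten,
  GSSG + NADPH -> 2 GSH + NADP,
- glucose-6-phosphate dehydrogenase (G6PD) with the full
  substrate/product/effector rate law (see :func:`g6pd_rate`),
- a lumped second oxidative-PPP step (GL6P + NADP -> NADPH + downstream),
- a lumped glycolytic G6P supply (linear in clamped glucose) and drain
  (first order in G6P),
- a saturable basal NADPH sink (NADPH -> NADP).

Two moieties are conserved by construction: total glutathione
GSH + 2*GSSG and total nicotinamide NADP + NADPH.

Concentrations are in uM and time in seconds throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "PatientKinetics",
    "RateParameters",
    "SpeciesDef",
    "Reaction",
    "NetworkModel",
    "ConfigurationError",
    "IntegrationError",
    "g6pd_rate",
    "antioxidant_rates",
    "ode_rhs",
    "conserved_totals",
    "build_default_model",
    "load_model",
    "save_model",
    "DEFAULT_RATE_PARAMETERS",
]


class ConfigurationError(ValueError):
    """Raised for an inconsistent model definition."""


class IntegrationError(RuntimeError):
    """Raised when a rate or derivative evaluates to NaN/Inf."""


# ---------------------------------------------------------------------------
# patient kinetics and the G6PD rate law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientKinetics:
    """The six G6PD kinetic parameters identifying one subject.

    ``vmax`` is the maximal velocity (model velocity units, uM/s);
    the Michaelis constants ``km_g6p``/``km_nadp`` and the inhibition
    constants ``ki_nadph``/``ki_atp``/``ki_23bpg`` are in uM.
    """

    vmax: float
    km_g6p: float
    km_nadp: float
    ki_nadph: float
    ki_atp: float
    ki_23bpg: float
    label: str = "subject"

    def __post_init__(self) -> None:
        for name in ("vmax", "km_g6p", "km_nadp", "ki_nadph", "ki_atp", "ki_23bpg"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"kinetic parameter {name!r} must be strictly positive, got {value!r}")
        if not self.label:
            raise ValueError("patient label must be non-empty")

    def as_dict(self) -> dict[str, float | str]:
        return asdict(self)

    def with_(self, **kwargs) -> "PatientKinetics":
        return replace(self, **kwargs)


def g6pd_rate(state: Mapping[str, float], kin: PatientKinetics) -> float:
    """Velocity of the G6PD reaction, G6P + NADP -> GL6P + NADPH.

    The rate law is an ordered bi-substrate form with competitive product
    inhibition by NADPH and allosteric inhibition by ATP and 2,3-BPG::

        v = Vmax [NADP][G6P] / ( KmNADP KmG6P (
                1 + ([NADP]/KmNADP)(1 + [G6P]/KmG6P)
                  + [NADPH]/KiNADPH + [ATP]/KiATP + [2,3BPG]/Ki2,3BPG ) )

    The velocity is zero iff either substrate is absent, strictly below
    ``Vmax`` everywhere, non-decreasing in each substrate and
    non-increasing in each inhibitor.
    """
    g6p = state["G6P"]
    nadp = state["NADP"]
    nadph = state["NADPH"]
    atp = state["ATP"]
    bpg = state["BPG23"]
    denom = kin.km_nadp * kin.km_g6p * (
        1.0
        + (nadp / kin.km_nadp) * (1.0 + g6p / kin.km_g6p)
        + nadph / kin.ki_nadph
        + atp / kin.ki_atp
        + bpg / kin.ki_23bpg
    )
    return kin.vmax * nadp * g6p / denom


# ---------------------------------------------------------------------------
# non-G6PD rate parameters (defaults calibrated; see docs/methods.md)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateParameters:
    """Kinetic constants of the non-G6PD reactions.

    Units: first-order constants 1/s, Michaelis constants uM, maximal
    velocities uM/s.  ``k_o2_gen`` and ``k_g6p_supply`` are per uM of the
    clamped glucose pool, so the corresponding fluxes are constant while
    glucose is clamped and vanish in a glucose-free state.
    """

    k_h2o2_diff: float = 0.01          # membrane H2O2 permeation, 1/s
    k_o2_gen: float = 2.64e-05         # superoxide generation per uM glucose, 1/s
    k_sod: float = 50.0                # SOD, first order in O2-, 1/s
    k_cat: float = 0.1125              # catalase, first order in H2O2, 1/s
    vmax_gshpx: float = 0.25875        # GSHpx maximal velocity, uM/s
    km_gshpx_h2o2: float = 0.02        # GSHpx Km for H2O2, uM
    km_gshpx_gsh: float = 1400.0       # GSHpx Km for GSH, uM
    vmax_gr: float = 5.606058513582682 # glutathione reductase Vmax, uM/s (calibrated)
    km_gr_gssg: float = 200.0          # GR Km for GSSG, uM
    km_gr_nadph: float = 60.0          # GR Km for NADPH, uM
    k_ppp2: float = 0.5                # lumped GL6P oxidation, 1/s
    km_ppp2_nadp: float = 0.5          # NADP half-saturation of the lumped step, uM
    k_g6p_supply: float = 1.1e-04      # G6P supply per uM glucose, 1/s
    k_g6p_drain: float = 0.01          # glycolytic G6P drain, 1/s
    vmax_nadph_drain: float = 0.24     # basal NADPH sink Vmax, uM/s
    km_nadph_drain: float = 1.0        # NADPH sink half-saturation, uM

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"rate parameter {name!r} must be strictly positive, got {value!r}")


DEFAULT_RATE_PARAMETERS = RateParameters()


# ---------------------------------------------------------------------------
# rate-law registry
# ---------------------------------------------------------------------------

RateLaw = Callable[[Mapping[str, float], Mapping[str, float], "PatientKinetics | None"], float]


def _law_linear_diffusion(state, p, kin=None):
    return p["k"] * (state[p["external"]] - state[p["internal"]])


def _law_first_order(state, p, kin=None):
    return p["k"] * state[p["species"]]


def _law_mm_bisubstrate(state, p, kin=None):
    a = state[p["a"]]
    b = state[p["b"]]
    return p["vmax"] * (a / (p["km_a"] + a)) * (b / (p["km_b"] + b))


def _law_mm_single(state, p, kin=None):
    a = state[p["species"]]
    return p["vmax"] * a / (p["km"] + a)


def _law_first_order_mm_cofactor(state, p, kin=None):
    # first order in the driving species, saturable in the cofactor
    a = state[p["species"]]
    b = state[p["cofactor"]]
    return p["k"] * a * b / (p["km_cofactor"] + b)


def _law_g6pd(state, p, kin=None):
    if kin is None:
        raise ConfigurationError("the g6pd rate law requires patient kinetics")
    return g6pd_rate(state, kin)


RATE_LAWS: dict[str, RateLaw] = {
    "linear_diffusion": _law_linear_diffusion,
    "first_order": _law_first_order,
    "mm_bisubstrate": _law_mm_bisubstrate,
    "mm_single": _law_mm_single,
    "first_order_mm_cofactor": _law_first_order_mm_cofactor,
    "g6pd": _law_g6pd,
}


# ---------------------------------------------------------------------------
# network model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    initial: float
    clamped: bool = False


@dataclass(frozen=True)
class Reaction:
    name: str
    rate_law: str
    stoichiometry: Mapping[str, float]
    parameters: Mapping[str, float | str] = field(default_factory=dict)


@dataclass
class NetworkModel:
    """Species, reactions and conserved moieties of a kinetic network."""

    species: Sequence[SpeciesDef]
    reactions: Sequence[Reaction]
    moieties: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def dynamic_names(self) -> list[str]:
        return [s.name for s in self.species if not s.clamped]

    @property
    def clamped_names(self) -> list[str]:
        return [s.name for s in self.species if s.clamped]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def initial_state(self) -> dict[str, float]:
        return {s.name: s.initial for s in self.species}

    def stoichiometry_matrix(self) -> np.ndarray:
        """Full stoichiometry matrix, one row per species (clamped rows zero)."""
        S = np.zeros((len(self.species), len(self.reactions)))
        clamped = {s.name for s in self.species if s.clamped}
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.stoichiometry.items():
                if name not in clamped:
                    S[self.index(name), j] = coeff
        return S

    def validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names")
        for rxn in self.reactions:
            if rxn.rate_law not in RATE_LAWS:
                raise ConfigurationError(f"reaction {rxn.name!r}: unknown rate law {rxn.rate_law!r}")
            for sp in rxn.stoichiometry:
                if sp not in names:
                    raise ConfigurationError(f"reaction {rxn.name!r} references unknown species {sp!r}")
            for key, value in rxn.parameters.items():
                if isinstance(value, str) and value not in names and key not in ("note",):
                    raise ConfigurationError(
                        f"reaction {rxn.name!r}: parameter {key!r} references unknown species {value!r}"
                    )
        for moiety, combo in self.moieties.items():
            for sp in combo:
                if sp not in names:
                    raise ConfigurationError(f"moiety {moiety!r} references unknown species {sp!r}")
        # moieties must lie in the left null space of the (dynamic) stoichiometry
        S = self.stoichiometry_matrix()
        for moiety, combo in self.moieties.items():
            w = np.zeros(len(names))
            for sp, coeff in combo.items():
                w[self.index(sp)] = coeff
            residual = np.abs(w @ S).max() if S.size else 0.0
            if residual > 1e-10:
                raise ConfigurationError(
                    f"moiety {moiety!r} is not conserved by the stoichiometry (residual {residual:g})"
                )

    # -- evaluation ---------------------------------------------------------

    def reaction_rates(
        self, state: Mapping[str, float], kin: PatientKinetics | None = None
    ) -> dict[str, float]:
        """Evaluate every reaction velocity at ``state`` (uM/s)."""
        rates = {}
        for rxn in self.reactions:
            v = RATE_LAWS[rxn.rate_law](state, rxn.parameters, kin)
            if not math.isfinite(v):
                raise IntegrationError(f"non-finite rate in reaction {rxn.name!r}")
            rates[rxn.name] = v
        return rates

    def compile(self, kin: PatientKinetics | None = None):
        """Build fast closures for ODE integration over the dynamic species.

        Returns ``(rhs, rates_fn, y0, dynamic_names)`` where ``rhs(t, y)``
        evaluates the time derivative of the dynamic concentrations and
        ``rates_fn(y)`` the vector of reaction velocities, both taking the
        dynamic state vector (clamped species folded in as constants).
        """
        names = self.species_names
        n_all = len(names)
        dyn_idx = [i for i, s in enumerate(self.species) if not s.clamped]
        full0 = np.array([s.initial for s in self.species])
        S_dyn = self.stoichiometry_matrix()[dyn_idx, :]
        laws = [RATE_LAWS[r.rate_law] for r in self.reactions]
        params = [r.parameters for r in self.reactions]
        rxn_names = [r.name for r in self.reactions]

        view = {name: full0[i] for i, name in enumerate(names)}

        def rates_fn(y: np.ndarray) -> np.ndarray:
            for k, i in enumerate(dyn_idx):
                view[names[i]] = y[k]
            v = np.empty(len(laws))
            for j, law in enumerate(laws):
                v[j] = law(view, params[j], kin)
            return v

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            v = rates_fn(y)
            if not np.all(np.isfinite(v)):
                bad = rxn_names[int(np.argmax(~np.isfinite(v)))]
                raise IntegrationError(f"non-finite rate in reaction {bad!r} at t={t:g}")
            return S_dyn @ v

        y0 = full0[dyn_idx]
        return rhs, rates_fn, y0, [names[i] for i in dyn_idx]


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def antioxidant_rates(
    state: Mapping[str, float], params: RateParameters | None = None
) -> dict[str, float]:
    """Named velocities of the non-G6PD reactions at ``state``.

    Returns a mapping with keys ``h2o2_influx``, ``o2minus_generation``,
    ``SOD``, ``CAT``, ``GSHpx``, ``GR``, ``ppp_second_step``,
    ``g6p_supply``, ``g6p_drain`` and ``nadph_drain``.  All are
    non-negative except ``h2o2_influx``, which is negative when the
    internal H2O2 concentration exceeds the external one (efflux).
    """
    model = build_default_model(params)
    # evaluate without the G6PD reaction, which needs patient kinetics
    out = {}
    for rxn in model.reactions:
        if rxn.rate_law == "g6pd":
            continue
        out[rxn.name] = RATE_LAWS[rxn.rate_law](state, rxn.parameters, None)
    return out


def ode_rhs(
    t: float,
    state: Mapping[str, float],
    model: NetworkModel,
    kin: PatientKinetics,
) -> dict[str, float]:
    """Time derivative of every species at ``state`` (uM/s).

    Clamped species have derivative exactly zero; the dynamic derivatives
    equal the stoichiometry matrix applied to the reaction-rate vector.
    """
    rates = model.reaction_rates(state, kin)
    deriv = {name: 0.0 for name in model.species_names}
    clamped = set(model.clamped_names)
    for rxn in model.reactions:
        v = rates[rxn.name]
        for sp, coeff in rxn.stoichiometry.items():
            if sp not in clamped:
                deriv[sp] += coeff * v
    return deriv


def conserved_totals(state: Mapping[str, float], model: NetworkModel) -> dict[str, float]:
    """Value of each conserved moiety (uM) at ``state``."""
    totals = {}
    for moiety, combo in model.moieties.items():
        try:
            totals[moiety] = sum(coeff * state[sp] for sp, coeff in combo.items())
        except KeyError as exc:
            raise ConfigurationError(f"moiety {moiety!r} references unknown species {exc}") from exc
    return totals


# ---------------------------------------------------------------------------
# default model
# ---------------------------------------------------------------------------

#: Default initial concentrations (uM).  GSH/GSSG and NADPH/NADP start near
#: the healthy steady state; the clamped effector levels are conventional
#: physiological values for the human erythrocyte.
DEFAULT_INITIAL = {
    "H2O2_in": 0.02,
    "O2minus": 0.0016,
    "GSH": 3200.0,
    "GSSG": 4.5,
    "NADPH": 60.0,
    "NADP": 2.0,
    "G6P": 40.0,
    "GL6P": 0.3,
    "H2O2_ext": 0.0,
    "ATP": 1600.0,
    "BPG23": 5000.0,
    "GLC": 5000.0,
}

_CLAMPED = ("H2O2_ext", "ATP", "BPG23", "GLC")

_default_model_cache: dict[tuple, NetworkModel] = {}


def build_default_model(
    params: RateParameters | None = None,
    initial: Mapping[str, float] | None = None,
) -> NetworkModel:
    """Construct the reduced antioxidant network with the given constants."""
    p = params or DEFAULT_RATE_PARAMETERS
    init = dict(DEFAULT_INITIAL)
    if initial:
        init.update(initial)
    key = (p, tuple(sorted(init.items())))
    cached = _default_model_cache.get(key)
    if cached is not None:
        return cached

    species = [SpeciesDef(name, init[name], clamped=name in _CLAMPED) for name in DEFAULT_INITIAL]
    reactions = [
        Reaction("h2o2_influx", "linear_diffusion", {"H2O2_in": 1},
                 {"k": p.k_h2o2_diff, "external": "H2O2_ext", "internal": "H2O2_in"}),
        Reaction("o2minus_generation", "first_order", {"O2minus": 1},
                 {"k": p.k_o2_gen, "species": "GLC"}),
        Reaction("SOD", "first_order", {"O2minus": -2, "H2O2_in": 1},
                 {"k": p.k_sod, "species": "O2minus"}),
        Reaction("CAT", "first_order", {"H2O2_in": -2},
                 {"k": p.k_cat, "species": "H2O2_in"}),
        Reaction("GSHpx", "mm_bisubstrate", {"H2O2_in": -1, "GSH": -2, "GSSG": 1},
                 {"vmax": p.vmax_gshpx, "a": "H2O2_in", "km_a": p.km_gshpx_h2o2,
                  "b": "GSH", "km_b": p.km_gshpx_gsh}),
        Reaction("GR", "mm_bisubstrate", {"GSSG": -1, "NADPH": -1, "GSH": 2, "NADP": 1},
                 {"vmax": p.vmax_gr, "a": "GSSG", "km_a": p.km_gr_gssg,
                  "b": "NADPH", "km_b": p.km_gr_nadph}),
        Reaction("G6PD", "g6pd", {"G6P": -1, "NADP": -1, "GL6P": 1, "NADPH": 1}, {}),
        Reaction("ppp_second_step", "first_order_mm_cofactor",
                 {"GL6P": -1, "NADP": -1, "NADPH": 1},
                 {"k": p.k_ppp2, "species": "GL6P", "cofactor": "NADP",
                  "km_cofactor": p.km_ppp2_nadp}),
        Reaction("g6p_supply", "first_order", {"G6P": 1},
                 {"k": p.k_g6p_supply, "species": "GLC"}),
        Reaction("g6p_drain", "first_order", {"G6P": -1},
                 {"k": p.k_g6p_drain, "species": "G6P"}),
        Reaction("nadph_drain", "mm_single", {"NADPH": -1, "NADP": 1},
                 {"vmax": p.vmax_nadph_drain, "km": p.km_nadph_drain, "species": "NADPH"}),
    ]
    moieties = {
        "glutathione": {"GSH": 1.0, "GSSG": 2.0},
        "nicotinamide": {"NADP": 1.0, "NADPH": 1.0},
    }
    model = NetworkModel(species, reactions, moieties)
    _default_model_cache[key] = model
    return model


# ---------------------------------------------------------------------------
# declarative model definition file (JSON)
# ---------------------------------------------------------------------------


def save_model(model: NetworkModel, path) -> None:
    """Write a model definition file (JSON; documented in docs/methods.md)."""
    doc = {
        "species": [
            {"name": s.name, "initial": s.initial, "clamped": s.clamped} for s in model.species
        ],
        "reactions": [
            {
                "name": r.name,
                "rate_law": r.rate_law,
                "stoichiometry": dict(r.stoichiometry),
                "parameters": dict(r.parameters),
            }
            for r in model.reactions
        ],
        "moieties": {k: dict(v) for k, v in model.moieties.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_model(path) -> NetworkModel:
    """Read a model definition file written by :func:`save_model`."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        species = [SpeciesDef(s["name"], float(s["initial"]), bool(s.get("clamped", False)))
                   for s in doc["species"]]
        reactions = [
            Reaction(r["name"], r["rate_law"], r["stoichiometry"], r.get("parameters", {}))
            for r in doc["reactions"]
        ]
        moieties = doc.get("moieties", {})
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed model definition file {path}: {exc}") from exc
    return NetworkModel(species, reactions, moieties)
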