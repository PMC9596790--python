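"""Cell-level building blocks: myocyte and fibroblast membrane models,
gap-junction coupling, Rush-Larsen gating updates and population scaling.

The myocyte is a human atrial model of the Nygren/Koivumaki family with
AF-remodelled conductances and a small-conductance Ca2+-activated K+ current
(I_KCa); the fibroblast is the MacCannell/Maleckar four-current active
fibroblast.  Baseline parameter sets and settled resting states are shipped
as versioned JSON files under ``atriasim/data``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields, replace
from functools import lru_cache
from importlib import resources

import numpy as np

from . import _constants as C
from ._constants import MYO_PARAM_NAMES, FIB_PARAM_NAMES, MYO_STATE_NAMES, \
    FIB_STATE_NAMES
from ._kernel import build_rate_tables, myocyte_node_step, \
    fibroblast_node_step


def _load_data(name):
    with resources.files("atriasim.data").joinpath(name).open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MyocyteParameters:
    """Maximal conductances / fluxes of the atrial myocyte (nS, pA, pF, mM)."""
    p_na: float
    g_cal: float
    g_t: float
    g_kur: float
    g_ks: float
    g_kr: float
    g_k1: float
    g_sk: float
    i_nak_max: float
    k_naca: float
    i_cap_max: float
    g_nab: float
    g_cab: float
    k_o: float
    na_o: float
    ca_o: float
    cm: float
    i_up_max: float
    phi_na_en: float

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MYO_PARAM_NAMES],
                        dtype=np.float64)

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite myocyte parameter {f.name}")
        if self.cm <= 0:
            raise ValueError("membrane capacitance must be positive")


@dataclass(frozen=True)
class FibroblastParameters:
    """Maximal conductances of the active fibroblast (nS, pA, pF, mM)."""
    g_kv: float
    g_k1: float
    i_nak_max: float
    g_nab: float
    k_o: float
    na_o: float
    cm: float
    na_i: float
    k_i: float

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FIB_PARAM_NAMES],
                        dtype=np.float64)


@dataclass(frozen=True)
class CellParameters:
    """Full parameter bundle for one simulated condition.

    ``g_gap_na`` and ``g_gap_k`` are the species-resolved components of the
    myocyte-fibroblast gap conductance (nS); their sum is the total G_gap
    (0.5 nS by default).  ``diffusion`` is the monodomain diffusion
    coefficient D (cm^2/ms) and is part of the profile-scaled parameter set.
    """
    myocyte: MyocyteParameters
    fibroblast: FibroblastParameters
    g_gap_na: float = 0.25
    g_gap_k: float = 0.25
    diffusion: float = 0.0012

    def __post_init__(self):
        if self.g_gap_na < 0 or self.g_gap_k < 0:
            raise ValueError("gap conductances must be non-negative")
        if self.diffusion < 0:
            raise ValueError("diffusion coefficient must be non-negative")

    @property
    def g_gap(self) -> float:
        return self.g_gap_na + self.g_gap_k


@lru_cache(maxsize=1)
def baseline_parameters() -> CellParameters:
    """The shipped AF-remodelled baseline parameter set."""
    myo = _load_data("myocyte_baseline.json")
    fib = _load_data("fibroblast_baseline.json")
    extra = myo.pop("_meta", None)
    fib.pop("_meta", None)
    diffusion = (extra or {}).get("diffusion", 0.0012)
    return CellParameters(
        myocyte=MyocyteParameters(**myo),
        fibroblast=FibroblastParameters(**fib),
        diffusion=diffusion,
    )


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------

_GATING_SLICE = slice(C.I_M, C.I_PA + 1)


@dataclass
class MyocyteState:
    """State vector wrapper for the atrial myocyte (26 variables)."""
    vector: np.ndarray

    @property
    def vm(self) -> float:
        return float(self.vector[C.I_V])

    @property
    def gating(self) -> np.ndarray:
        return self.vector[_GATING_SLICE]

    @property
    def na_i(self) -> float:
        return float(self.vector[C.I_NAI])

    @property
    def k_i(self) -> float:
        return float(self.vector[C.I_KI])

    @property
    def ca_i(self) -> float:
        return float(self.vector[C.I_CAI])

    def as_dict(self) -> dict:
        return dict(zip(MYO_STATE_NAMES, self.vector.tolist()))

    def copy(self) -> "MyocyteState":
        return MyocyteState(self.vector.copy())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            bad = [n for n, v in self.as_dict().items()
                   if not math.isfinite(v)]
            raise SimulationFailure(f"non-finite state variables: {bad}")
        g = self.gating
        if np.any(g < -1e-9) or np.any(g > 1 + 1e-9):
            raise ValueError("gating variable outside [0, 1]")
        if not -120.0 <= self.vm <= 80.0:
            raise ValueError(f"membrane potential {self.vm:.2f} mV "
                             "outside the physiological window")
        conc = self.vector[[C.I_NAI, C.I_KI, C.I_CAI, C.I_CAD, C.I_CAUP,
                            C.I_CAREL]]
        if np.any(conc <= 0):
            raise ValueError("non-positive ionic concentration")

    @classmethod
    def rest(cls) -> "MyocyteState":
        data = _load_data("initial_states.json")["myocyte"]
        return cls(np.array([data[n] for n in MYO_STATE_NAMES]))


@dataclass
class FibroblastState:
    """State vector wrapper for the active fibroblast (3 variables)."""
    vector: np.ndarray

    @property
    def vm(self) -> float:
        return float(self.vector[C.IF_V])

    @property
    def gating(self) -> np.ndarray:
        return self.vector[C.IF_R:C.IF_S + 1]

    def as_dict(self) -> dict:
        return dict(zip(FIB_STATE_NAMES, self.vector.tolist()))

    def copy(self) -> "FibroblastState":
        return FibroblastState(self.vector.copy())

    @classmethod
    def rest(cls) -> "FibroblastState":
        data = _load_data("initial_states.json")["fibroblast"]
        return cls(np.array([data[n] for n in FIB_STATE_NAMES]))


class SimulationFailure(RuntimeError):
    """Raised when the integrator produces non-finite state."""


# ---------------------------------------------------------------------------
# Gap junction current
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapCurrents:
    """Species-resolved gap-junction currents (pA).

    Positive values flow outward from the myocyte into the fibroblast.
    """
    i_na: float
    i_k: float

    @property
    def total(self) -> float:
        return self.i_na + self.i_k


def gap_current(vm_myocyte: float, vm_fibroblast: float,
                params: CellParameters) -> GapCurrents:
    """Ohmic, species-resolved gap-junction current for a myocyte-fibroblast
    pair driven by their membrane-potential difference."""
    if not (math.isfinite(vm_myocyte) and math.isfinite(vm_fibroblast)):
        raise ValueError("non-finite membrane potential")
    dv = vm_myocyte - vm_fibroblast
    return GapCurrents(i_na=params.g_gap_na * dv, i_k=params.g_gap_k * dv)


# ---------------------------------------------------------------------------
# Rush-Larsen update
# ---------------------------------------------------------------------------

def rush_larsen_update(w, alpha, beta, h):
    """Exponential (Rush-Larsen) update of a gating variable.

    For dw/dt = alpha*(1-w) - beta*w the update is
    w' = exp(a h) (w + b/a) - b/a with a = -(alpha+beta), b = alpha, which is
    exact when the rates are constant over the step.  The degenerate case
    alpha = beta = 0 is the identity.
    """
    w = np.asarray(w, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha < 0) or np.any(beta < 0):
        raise ValueError("rate constants must be non-negative")
    if h <= 0:
        raise ValueError("step size must be positive")
    a = alpha + beta
    with np.errstate(divide="ignore", invalid="ignore"):
        winf = np.where(a > 0, alpha / np.where(a > 0, a, 1.0), w)
    out = winf + (w - winf) * np.exp(-a * h)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Single-step integration wrappers
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _tables(dt_ms: float):
    tab, v0, dv = build_rate_tables(dt_ms)
    return tab, v0, 1.0 / dv


def step_myocyte(state: MyocyteState, params: CellParameters, dt: float,
                 i_stim: float = 0.0, i_gap_na: float = 0.0,
                 i_gap_k: float = 0.0,
                 diffusion_term: float = 0.0) -> MyocyteState:
    """Advance the myocyte one step of ``dt`` ms.

    ``i_stim`` and ``diffusion_term`` are in pA/pF (mV/ms); the gap currents
    are in pA with the outward-from-myocyte sign convention.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate()
    tab, v0, idv = _tables(dt)
    S = state.vector.copy().reshape(1, -1)
    myocyte_node_step(S, 0, float(state.vector[C.I_V]),
                      params.myocyte.to_vector(), tab, v0, idv, dt,
                      i_stim + diffusion_term, i_gap_na, i_gap_k)
    new = MyocyteState(S[0])
    if not np.all(np.isfinite(new.vector)):
        bad = [n for n, v in new.as_dict().items() if not math.isfinite(v)]
        raise SimulationFailure(f"myocyte state non-finite after step: {bad}")
    return new


def step_fibroblast(state: FibroblastState, params: CellParameters,
                    dt: float, i_gap_total: float = 0.0) -> FibroblastState:
    """Advance the fibroblast one step of ``dt`` ms.

    ``i_gap_total`` is the total gap current leaving the myocyte (pA); it
    enters the fibroblast with depolarizing sign.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    S = state.vector.copy().reshape(1, -1)
    fibroblast_node_step(S, 0, float(state.vector[C.IF_V]),
                         params.fibroblast.to_vector(), dt, i_gap_total)
    new = FibroblastState(S[0])
    if not np.all(np.isfinite(new.vector)):
        raise SimulationFailure("fibroblast state non-finite after step")
    return new


# ---------------------------------------------------------------------------
# Population profile scaling
# ---------------------------------------------------------------------------

#: the nine population-varied parameters, in canonical CSV column order
PROFILE_PARAMETERS = ("gNa", "INaK", "gK1", "gCaL", "gKur", "IKCa",
                      "D", "Ko", "Nao")

SCALING_MIN = -50.0
SCALING_MAX = 100.0


@dataclass(frozen=True)
class ProfileScaling:
    """Percent modifiers of the nine population-varied parameters.

    Each entry is a percentage relative to baseline in [-50, +100]; the
    scaled value is ``base * (1 + pct/100)``.
    """
    gNa: float = 0.0
    INaK: float = 0.0
    gK1: float = 0.0
    gCaL: float = 0.0
    gKur: float = 0.0
    IKCa: float = 0.0
    D: float = 0.0
    Ko: float = 0.0
    Nao: float = 0.0
    profile_id: int = -1

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in PROFILE_PARAMETERS}

    def validate(self) -> None:
        for n, v in self.as_dict().items():
            if not SCALING_MIN <= v <= SCALING_MAX:
                raise ValueError(
                    f"scaling {n}={v}% outside [{SCALING_MIN}, {SCALING_MAX}]")

    @classmethod
    def from_dict(cls, d: dict, profile_id: int = -1) -> "ProfileScaling":
        unknown = set(d) - set(PROFILE_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown profile parameters: {sorted(unknown)}")
        return cls(profile_id=profile_id, **d)


# scaling name -> myocyte parameter attribute (D and the extracellular
# concentrations are handled explicitly)
_SCALE_TARGETS = {
    "gNa": "p_na",
    "INaK": "i_nak_max",
    "gK1": "g_k1",
    "gCaL": "g_cal",
    "gKur": "g_kur",
    "IKCa": "g_sk",
    "Ko": "k_o",
    "Nao": "na_o",
}


def apply_profile_scaling(base: CellParameters,
                          scaling: ProfileScaling | dict) -> CellParameters:
    """Multiply each of the nine varied parameters by (1 + pct/100).

    Only the myocyte model and the diffusion coefficient are touched;
    fibroblast parameters carry no population variability.
    """
    if isinstance(scaling, dict):
        scaling = ProfileScaling.from_dict(scaling)
    scaling.validate()
    changes = {}
    for name, attr in _SCALE_TARGETS.items():
        pct = getattr(scaling, name)
        if pct != 0.0:
            changes[attr] = getattr(base.myocyte, attr) * (1.0 + pct / 100.0)
    myo = replace(base.myocyte, **changes) if changes else base.myocyte
    d = base.diffusion * (1.0 + scaling.D / 100.0)
    return replace(base, myocyte=myo, diffusion=d)
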