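"""2D monodomain tissue solver with diffuse fibroblast replacement.

The sheet is a regular nx-by-ny grid (default 200x200 nodes, 0.01 cm
spacing, i.e. a 2 cm side plane) with no-flux boundaries.  A configured
fraction of nodes is replaced by non-excitable fibroblasts placed uniformly
at random; fibroblast nodes are excluded from the diffusion stencil and are
coupled to each von-Neumann myocyte neighbour through a species-resolved
ohmic gap-junction current.  Pacing follows an S1 train applied to the left
edge columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _constants as C
from ._kernel import build_rate_tables, integrate_tissue
from .cell_models import (CellParameters, FibroblastState, MyocyteState,
                          ProfileScaling, SimulationFailure,
                          apply_profile_scaling, baseline_parameters)
from .pharmacology import DrugSpec, apply_drug

__all__ = [
    "TissueGeometry", "StimulusProtocol", "NumericsConfig",
    "SimulationResult", "build_fibrosis_mask", "diffusion_term",
    "run_simulation", "simulate_single_myocyte", "simulate_single_fibroblast",
    "simulate_pair",
]

#: physical probe x positions as fractions of the plane side (the 2 cm plane
#: convention puts them at 0.5 mm and 19.5 mm)
PROBE_X_FRACTIONS = (0.025, 0.975)


def build_fibrosis_mask(nx: int, ny: int, fraction: float,
                        seed: int) -> np.ndarray:
    """Uniform random fibroblast mask with exactly round(fraction*nx*ny)
    True entries; deterministic in (nx, ny, fraction, seed)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fibrosis fraction must be in [0, 1)")
    n = nx * ny
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        rng = np.random.default_rng(seed)
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask.reshape(ny, nx)


@dataclass
class TissueGeometry:
    """Grid geometry, fibroblast mask and conduction-velocity probes.

    Probes are mapped from the physical convention (2.5% and 97.5% of the
    x extent, centred in y).  If a probe lands on a fibroblast the mask is
    re-drawn deterministically so probe nodes are always myocytes.
    """
    nx: int = 200
    ny: int = 200
    dx: float = 0.01                   # cm
    fibrosis_fraction: float = 0.0
    mask_seed: int = 0
    fibrosis_mask: Optional[np.ndarray] = None
    probe_left: Optional[tuple] = None   # (ix, iy)
    probe_right: Optional[tuple] = None

    def __post_init__(self):
        if self.nx < 2 or self.ny < 1:
            raise ValueError("grid must be at least 2x1 nodes")
        if self.probe_left is None:
            # 2.5% of the side = 0.5 mm = column 5 on the 200-node plane;
            # never inside the stimulated left edge column
            ix = max(1, int(round(PROBE_X_FRACTIONS[0] * self.nx)))
            self.probe_left = (ix, self.ny // 2)
        if self.probe_right is None:
            ix = min(self.nx - 1, int(round(PROBE_X_FRACTIONS[1] * self.nx)))
            self.probe_right = (ix, self.ny // 2)
        if self.fibrosis_mask is None:
            seed = self.mask_seed
            for _ in range(1000):
                mask = build_fibrosis_mask(self.nx, self.ny,
                                           self.fibrosis_fraction, seed)
                if not (mask[self.probe_left[1], self.probe_left[0]] or
                        mask[self.probe_right[1], self.probe_right[0]]):
                    break
                seed += 10007    # deterministic re-draw
            self.fibrosis_mask = mask
        self.fibrosis_mask = np.asarray(self.fibrosis_mask, dtype=bool)
        if self.fibrosis_mask.shape != (self.ny, self.nx):
            raise ValueError("fibrosis mask shape does not match the grid")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def probe_distance_cm(self) -> float:
        return (self.probe_right[0] - self.probe_left[0]) * self.dx

    def node_index(self, ix: int, iy: int) -> int:
        return iy * self.nx + ix


@dataclass(frozen=True)
class StimulusProtocol:
    """S1 pacing train applied to the left-edge myocyte columns.

    The study protocol is 4 pulses of 4000 pA/pF and 3 ms at 1 Hz delivered
    to the left-edge column.  The amplitude is applied literally as a
    per-capacitance current density on each stimulated myocyte; the edge
    column transiently overshoots during the pulse but the scheme remains
    stable and the launched wave is independent of the overdrive.
    """
    n_pulses: int = 4
    amplitude: float = 4000.0  # pA/pF per stimulated cell
    duration: float = 3.0     # ms
    period: float = 1000.0    # ms
    stim_cols: int = 1

    def __post_init__(self):
        if self.duration >= self.period:
            raise ValueError("stimulus duration must be below the period")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be non-negative")

    @classmethod
    def scaled(cls, nx: int, reference_nx: int = 200,
               **kw) -> "StimulusProtocol":
        """Protocol with the edge drive rescaled for a down-sized plane.

        The full-size pulse injects charge equivalent to raising the whole
        200-column domain by ~60 mV; on an nx-column domain the same
        per-cell amplitude would overdrive the entire sheet, so the
        amplitude is scaled by nx/200 to preserve the charge-per-area of
        the reference protocol.
        """
        kw.setdefault("amplitude", 4000.0 * nx / reference_nx)
        return cls(**kw)


@dataclass(frozen=True)
class NumericsConfig:
    """Time stepping and recording configuration.

    ``dt_us`` is the forward-Euler step in microseconds (10 us desk default;
    a convergence test against finer steps gates this choice).  The explicit
    stability bound dt <= dx^2/(4 D) is checked at start.
    """
    dt_us: float = 10.0
    record_stride: int = 100
    dvdt_threshold: float = 1.0    # mV/ms upstroke validation
    # upstroke validation requires an overshoot: on down-scaled planes the
    # rescaled edge stimulus can passively lift remote nodes to ~-20 mV,
    # while a genuine action potential overshoots far above 0 mV
    v_cross: float = 0.0           # mV

    @property
    def dt_ms(self) -> float:
        return self.dt_us * 1e-3

    @classmethod
    def for_diffusion(cls, max_diffusion: float, dx: float = 0.01,
                      base_dt_us: float = 10.0, safety: float = 0.9,
                      **kw) -> "NumericsConfig":
        """A config whose step also satisfies the stability bound for the
        largest diffusion coefficient in a profile set (profiles scale D up
        to +100%)."""
        limit_us = safety * dx * dx / (4.0 * max_diffusion) * 1e3
        return cls(dt_us=min(base_dt_us, limit_us), **kw)

    def check_stability(self, dx: float, diffusion: float) -> None:
        if diffusion > 0:
            limit = dx * dx / (4.0 * diffusion)
            if self.dt_ms > limit:
                raise ValueError(
                    f"dt = {self.dt_ms} ms violates the explicit stability "
                    f"bound {limit:.4f} ms for D = {diffusion} cm^2/ms")


@dataclass
class SimulationResult:
    """Output bundle of one tissue run."""
    time: np.ndarray                # recorded time base (ms)
    traces: np.ndarray              # (n_rec, n_probes) Vm at probe nodes
    probe_nodes: tuple              # flat node indices of recorded traces
    act_times: np.ndarray           # (n_beats, ny, nx) activation time (ms)
    rmp: np.ndarray                 # (n_beats, ny, nx) diastolic minimum (mV)
    v_peak: np.ndarray              # (n_beats, ny, nx) AP peak (mV)
    apd_end: np.ndarray             # (n_beats, ny, nx) APD90 end time (ms)
    depolarized: np.ndarray         # (n_beats, ny, nx) bool
    repolarized: np.ndarray         # (n_beats, ny, nx) bool
    geometry: TissueGeometry = None
    protocol: StimulusProtocol = None
    numerics: NumericsConfig = None
    params: CellParameters = None
    conducted: bool = False
    stimulus_log: list = field(default_factory=list)
    final_states: tuple = ()        # (myocyte S, fibroblast SF) node arrays

    @property
    def n_beats(self) -> int:
        return self.act_times.shape[0]

    def probe_activation(self, which: str, beat: int) -> float:
        """Activation time of the left/right CV probe on a given beat,
        relative to that beat's stimulus onset (ms)."""
        g = self.geometry
        ix, iy = g.probe_left if which == "left" else g.probe_right
        t = self.act_times[beat, iy, ix]
        return t - beat * self.protocol.period


def diffusion_term(vm_field: np.ndarray, geometry: TissueGeometry,
                   diffusion: float) -> np.ndarray:
    """Heterogeneous 5-point Laplacian D*lap(Vm) (mV/ms) with no-flux outer
    boundaries; faces adjoining fibroblast nodes carry no diffusive flux and
    the returned value at fibroblast nodes is zero."""
    vm = np.asarray(vm_field, dtype=float)
    if vm.shape != (geometry.ny, geometry.nx):
        raise ValueError("field shape does not match geometry")
    if not np.all(np.isfinite(vm)):
        raise ValueError("non-finite membrane potential field")
    myo = ~geometry.fibrosis_mask
    out = np.zeros_like(vm)
    for shift, axis in (((1), 0), (-1, 0), (1, 1), (-1, 1)):
        nb_v = np.roll(vm, shift, axis=axis)
        nb_m = np.roll(myo, shift, axis=axis)
        valid = nb_m.copy()
        # zero-flux at the outer edges: rolled-in wrap values are invalid
        if axis == 0:
            (valid[0, :] if shift == 1 else valid[-1, :])[:] = False
        else:
            (valid[:, 0] if shift == 1 else valid[:, -1])[:] = False
        out += np.where(valid & myo, nb_v - vm, 0.0)
    return out * (diffusion / geometry.dx ** 2)


def _initial_states(geometry: TissueGeometry):
    n = geometry.n_nodes
    myo0 = MyocyteState.rest().vector
    fib0 = FibroblastState.rest().vector
    S = np.tile(myo0, (n, 1))
    SF = np.tile(fib0, (n, 1))
    return S, SF


def run_simulation(geometry: TissueGeometry,
                   profile: Optional[ProfileScaling] = None,
                   drug: Optional[DrugSpec] = None,
                   protocol: Optional[StimulusProtocol] = None,
                   numerics: Optional[NumericsConfig] = None,
                   params: Optional[CellParameters] = None,
                   extra_probes: tuple = (),
                   duration_ms: Optional[float] = None) -> SimulationResult:
    """Run the S1 protocol on a tissue sheet and extract per-beat markers.

    ``params`` defaults to the shipped baseline; ``profile`` applies the
    population percent-scalings and ``drug`` the pore-block conductance
    factors (myocyte channels only).  Fully deterministic given the
    configuration and the geometry's mask seed.
    """
    from .biomarkers import classify_conduction

    protocol = protocol or StimulusProtocol()
    numerics = numerics or NumericsConfig()
    params = params or baseline_parameters()
    if profile is not None:
        params = apply_profile_scaling(params, profile)
    if drug is not None:
        params = apply_drug(params, drug)
    numerics.check_stability(geometry.dx, params.diffusion)

    dt = numerics.dt_ms
    total = duration_ms if duration_ms is not None \
        else protocol.n_pulses * protocol.period
    n_steps = int(round(total / dt))
    n_beats = max(1, min(protocol.n_pulses,
                         int(math.ceil(total / protocol.period))))

    S, SF = _initial_states(geometry)
    is_fib = geometry.fibrosis_mask.ravel().astype(np.uint8)
    tab, v0, dv = build_rate_tables(dt)

    g = geometry
    probe_nodes = [g.node_index(*g.probe_left), g.node_index(*g.probe_right)]
    probe_nodes += [g.node_index(*p) for p in extra_probes]
    probe_idx = np.asarray(probe_nodes, dtype=np.int64)

    n_rec = (n_steps + numerics.record_stride - 1) // numerics.record_stride
    traces = np.empty((n_rec, len(probe_nodes)))
    n = g.n_nodes
    act_t = np.full((n_beats, n), np.nan)
    rmp_b = np.full((n_beats, n), np.nan)
    vmax_b = np.full((n_beats, n), np.nan)
    apd_end = np.full((n_beats, n), np.nan)
    depol_b = np.zeros((n_beats, n), dtype=np.uint8)
    repol_b = np.zeros((n_beats, n), dtype=np.uint8)

    status, t_fail = integrate_tissue(
        S, SF, is_fib, g.nx, g.ny, g.dx, params.diffusion,
        params.myocyte.to_vector(), params.fibroblast.to_vector(),
        params.g_gap_na, params.g_gap_k, tab, v0, dv, dt, n_steps,
        protocol.amplitude, protocol.duration, protocol.period,
        protocol.n_pulses, protocol.stim_cols,
        probe_idx, numerics.record_stride, traces,
        act_t, rmp_b, vmax_b, apd_end, depol_b, repol_b,
        numerics.dvdt_threshold, numerics.v_cross)
    if status != 0:
        raise SimulationFailure(
            f"numerical blow-up: non-finite state at t = {t_fail:.3f} ms")

    shape = (n_beats, g.ny, g.nx)
    result = SimulationResult(
        time=np.arange(n_rec) * dt * numerics.record_stride,
        traces=traces,
        probe_nodes=tuple(probe_nodes),
        act_times=act_t.reshape(shape),
        rmp=rmp_b.reshape(shape),
        v_peak=vmax_b.reshape(shape),
        apd_end=apd_end.reshape(shape),
        depolarized=depol_b.reshape(shape).astype(bool),
        repolarized=repol_b.reshape(shape).astype(bool),
        geometry=g, protocol=protocol, numerics=numerics, params=params,
        final_states=(S, SF),
        stimulus_log=[{"pulse": k, "t_on": k * protocol.period,
                       "amplitude_pApF": protocol.amplitude,
                       "duration_ms": protocol.duration}
                      for k in range(protocol.n_pulses)],
    )
    result.conducted = classify_conduction(result)
    return result


# ---------------------------------------------------------------------------
# Convenience wrappers: single cells and coupled pairs as degenerate grids
# ---------------------------------------------------------------------------

def simulate_single_myocyte(params: Optional[CellParameters] = None,
                            protocol: Optional[StimulusProtocol] = None,
                            numerics: Optional[NumericsConfig] = None,
                            duration_ms: Optional[float] = None,
                            state0: Optional[MyocyteState] = None):
    """Paced (or quiescent, with ``n_pulses=0``) isolated myocyte.

    Returns (time ms, Vm trace mV, SimulationResult).
    """
    geom = TissueGeometry(nx=2, ny=1, fibrosis_fraction=0.0,
                          probe_left=(0, 0), probe_right=(1, 0))
    # an isolated cell has no diffusive sink: use a cellular-scale stimulus
    protocol = protocol or StimulusProtocol(stim_cols=2, amplitude=20.0)
    params = params or baseline_parameters()
    # an isolated cell: no diffusion between the two stimulated nodes matters
    res = run_simulation(geom, protocol=protocol, numerics=numerics,
                         params=params, duration_ms=duration_ms)
    return res.time, res.traces[:, 0], res


def simulate_single_fibroblast(params: Optional[CellParameters] = None,
                               duration_ms: float = 2000.0,
                               v0: Optional[float] = None,
                               numerics: Optional[NumericsConfig] = None):
    """Uncoupled fibroblast relaxation; returns (time, Vm trace)."""
    params = params or baseline_parameters()
    numerics = numerics or NumericsConfig()
    dt = numerics.dt_ms
    n_steps = int(round(duration_ms / dt))
    state = FibroblastState.rest()
    if v0 is not None:
        state.vector[C.IF_V] = v0
    SF = state.vector.reshape(1, -1).copy()
    fp = params.fibroblast.to_vector()
    stride = numerics.record_stride
    n_rec = (n_steps + stride - 1) // stride
    out = np.empty(n_rec)
    from ._kernel import fibroblast_node_step
    k = 0
    for step in range(n_steps):
        if step % stride == 0:
            out[k] = SF[0, C.IF_V]
            k += 1
        fibroblast_node_step(SF, 0, SF[0, C.IF_V], fp, dt, 0.0)
    return np.arange(n_rec) * dt * stride, out


def simulate_pair(params: Optional[CellParameters] = None,
                  duration_ms: float = 1000.0,
                  numerics: Optional[NumericsConfig] = None):
    """One myocyte coupled to one fibroblast through I_Gap, unpaced.

    Returns (time, Vm_myocyte, Vm_fibroblast).
    """
    params = params or baseline_parameters()
    mask = np.array([[False, True]])
    geom = TissueGeometry(nx=2, ny=1, fibrosis_mask=mask,
                          probe_left=(0, 0), probe_right=(1, 0))
    protocol = StimulusProtocol(n_pulses=0)
    res = run_simulation(geom, protocol=protocol, numerics=numerics,
                         params=params, duration_ms=duration_ms)
    return res.time, res.traces[:, 0], res.traces[:, 1]
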