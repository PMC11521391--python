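"""Single-neuron model and excitability characterization.

The cell is a single-compartment conductance-based model of a cortical
pyramidal neuron carrying fast sodium, delayed-rectifier potassium, leak,
and a slow non-inactivating M-type potassium current.  The M-current
conductance ``g_ks`` is the cholinergic modulation knob: muscarinic
blockade of the channel (high acetylcholine) corresponds to ``g_ks = 0``
and Type I excitability — a continuous current-frequency (I-F) curve with
arbitrarily low onset rate and an all-advance phase response curve (PRC);
an intact channel (``g_ks = 1.5`` mS/cm²) gives Type II excitability — a
nonzero minimum firing rate at threshold and a PRC with an early-phase
delay lobe.  Sodium activation is instantaneous (m = m_inf(V)), so the
state is (V, h, n, z).

Membrane equation (C_m = 1 µF/cm²)::

    dV/dt = -g_na * m_inf(V)^3 * h * (V - E_na)
            - g_kd * n^4 * (V - E_k)
            - g_ks * z * (V - E_k)
            - g_l * (V - E_l)
            + I_app - I_syn

with first-order gate kinetics dX/dt = (X_inf(V) - X) / tau_X(V) for
X in {h, n, z}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import _core
from .errors import CalibrationError, IntegrationError, PrcUndefinedError

__all__ = [
    "NeuronParameters", "NeuronState", "PhaseResponseCurve",
    "SingleNeuronResult", "steady_state_gates", "gate_time_constants",
    "membrane_derivative", "simulate_single_neuron", "steady_rate",
    "fi_curve", "calibrate_drive", "compute_prc",
]

#: The two M-current conductances of the standard modulation states.
GKS_TYPE_I = 0.0
GKS_TYPE_II = 1.5

DEFAULT_DT_MS = 0.05
RATE_RUN_MS = 2000.0
RATE_TRANSIENT_MS = 500.0


@dataclass(frozen=True)
class NeuronParameters:
    """Maximal conductances (mS/cm²) and reversal potentials (mV)."""

    g_na: float = 24.0
    g_kd: float = 3.0
    g_ks: float = GKS_TYPE_I
    g_l: float = 0.02
    e_na: float = 55.0
    e_k: float = -90.0
    e_l: float = -60.0

    def __post_init__(self):
        for name in ("g_na", "g_kd", "g_ks", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.g_ks not in (GKS_TYPE_I, GKS_TYPE_II):
            warnings.warn(
                f"g_ks={self.g_ks} is outside the two standard modulation "
                f"states ({GKS_TYPE_I} = Type I, {GKS_TYPE_II} = Type II)",
                stacklevel=2,
            )

    @classmethod
    def type_i(cls) -> "NeuronParameters":
        """Full M-current blockade (high ACh): Type I excitability."""
        return cls(g_ks=GKS_TYPE_I)

    @classmethod
    def type_ii(cls) -> "NeuronParameters":
        """Intact M-current (low ACh): Type II excitability."""
        return cls(g_ks=GKS_TYPE_II)

    @property
    def is_type_ii(self) -> bool:
        return self.g_ks > 0.0

    def with_gks(self, g_ks: float) -> "NeuronParameters":
        return replace(self, g_ks=g_ks)


@dataclass
class NeuronState:
    """Dynamic state: membrane voltage (mV) and gate variables in [0, 1]."""

    v: float
    h: float
    n: float
    z: float

    def __post_init__(self):
        if not np.isfinite(self.v):
            raise ValueError("voltage must be finite")
        for name in ("h", "n", "z"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {name}={x} outside [0, 1]")

    @classmethod
    def resting(cls, v: float = -65.0) -> "NeuronState":
        """Deterministic start point: gates at steady state for ``v``."""
        g = steady_state_gates(v)
        return cls(v=float(v), h=float(g.h), n=float(g.n), z=float(g.z))


class Gates(NamedTuple):
    m: float | np.ndarray
    h: float | np.ndarray
    n: float | np.ndarray
    z: float | np.ndarray


class TimeConstants(NamedTuple):
    h: float | np.ndarray
    n: float | np.ndarray
    z: float | np.ndarray


def steady_state_gates(v):
    """Steady-state activation/inactivation curves (m, h, n, z) at ``v``.

    m, n, z are sigmoidal increasing in V (midpoints -30, -30, -39 mV);
    h is decreasing (midpoint -53 mV).  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    m = 1.0 / (1.0 + np.exp(-(v + 30.0) / 9.5))
    h = 1.0 / (1.0 + np.exp((v + 53.0) / 7.0))
    n = 1.0 / (1.0 + np.exp(-(v + 30.0) / 10.0))
    z = 1.0 / (1.0 + np.exp(-(v + 39.0) / 5.0))
    return Gates(m[()], h[()], n[()], z[()])


def gate_time_constants(v):
    """Voltage-dependent time constants (ms) of the h, n, z gates.

    tau_z is voltage independent (75 ms) — the slow timescale responsible
    for spike-frequency adaptation through the M-current.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    tau_h = 0.37 + 2.78 / (1.0 + np.exp((v + 40.5) / 6.0))
    tau_n = 0.37 + 1.85 / (1.0 + np.exp((v + 27.0) / 15.0))
    tau_z = np.full_like(tau_h, _core.TAU_Z_MS)
    return TimeConstants(tau_h[()], tau_n[()], tau_z[()])


def membrane_derivative(state: NeuronState, params: NeuronParameters,
                        i_app: float = 0.0, i_syn: float = 0.0):
    """Right-hand side (dV/dt, dh/dt, dn/dt, dz/dt) at one state point.

    ``i_syn`` follows the synaptic-current sign convention: it is
    subtracted from the membrane equation, so a negative value (excitatory
    current at V < Esyn) depolarizes.
    """
    g = steady_state_gates(state.v)
    tau = gate_time_constants(state.v)
    dv = (-params.g_na * g.m ** 3 * state.h * (state.v - params.e_na)
          - params.g_kd * state.n ** 4 * (state.v - params.e_k)
          - params.g_ks * state.z * (state.v - params.e_k)
          - params.g_l * (state.v - params.e_l)
          + i_app - i_syn)
    dh = (g.h - state.h) / tau.h
    dn = (g.n - state.n) / tau.n
    dz = (g.z - state.z) / tau.z
    return float(dv), float(dh), float(dn), float(dz)


@dataclass
class SingleNeuronResult:
    """Voltage/gate traces and detected spikes of one isolated-cell run."""

    t: np.ndarray
    v: np.ndarray
    gates: np.ndarray      # rows h, n, z over time
    spike_times: np.ndarray
    dt: float
    duration: float


def _run_uncoupled(params_list: Sequence[NeuronParameters],
                   i_app: np.ndarray, duration: float, dt: float,
                   initial: np.ndarray, record: bool,
                   pulse=(0.0, 0.0, 0.0)):
    """Integrate decoupled cells; ``initial`` is (4, n) rows V,h,n,z."""
    n_cells = i_app.shape[0]
    V = initial[0].copy()
    h = initial[1].copy()
    n = initial[2].copy()
    z = initial[3].copy()
    gNa = np.array([p.g_na for p in params_list])
    gKd = np.array([p.g_kd for p in params_list])
    gKs = np.array([p.g_ks for p in params_list])
    gL = np.array([p.g_l for p in params_list])
    p0 = params_list[0]
    n_steps = int(round(duration / dt))
    max_spk = int(duration / _core.REFRACTORY_MS) + 2
    spike_times = np.zeros((n_cells, max_spk))
    spike_counts = np.zeros(n_cells, dtype=np.int64)
    indptr, targets = _core.empty_adjacency(n_cells)
    zeros = np.zeros(n_cells)
    traces = (np.zeros((4, n_cells, n_steps + 1))
              if record else np.zeros((4, 0, 0)))
    pulse_amp, pulse_t0, pulse_t1 = pulse
    bad_step, bad_cell = _core.integrate(
        V, h, n, z, gNa, gKd, gKs, gL, p0.e_na, p0.e_k, p0.e_l,
        np.asarray(i_app, dtype=float),
        indptr, targets, np.ones(n_cells, dtype=np.bool_),
        zeros, zeros,
        0.2, 3.0, 5.5, 0.0, -75.0,
        dt, n_steps, np.inf,
        float(pulse_amp), float(pulse_t0), float(pulse_t1),
        spike_times, spike_counts,
        record, traces)
    if bad_step >= 0:
        raise IntegrationError(bad_step, bad_cell, dt)
    spikes = [spike_times[j, :spike_counts[j]].copy()
              for j in range(n_cells)]
    return spikes, traces


def simulate_single_neuron(params: NeuronParameters, i_app: float,
                           duration: float = RATE_RUN_MS,
                           dt: float = DEFAULT_DT_MS,
                           initial: NeuronState | None = None,
                           pulse=(0.0, 0.0, 0.0)) -> SingleNeuronResult:
    """Fixed-step RK4 run of one isolated cell under constant drive.

    ``pulse`` = (amplitude µA/cm², start ms, end ms) adds a square current
    pulse on top of ``i_app`` (used by the PRC protocol).  Spikes are
    upward 0 mV crossings with a 2 ms lockout, reported at step
    resolution.
    """
    if dt <= 0 or duration <= dt:
        raise ValueError("require dt > 0 and duration > dt")
    if initial is None:
        initial = NeuronState.resting()
    init = np.array([[initial.v], [initial.h], [initial.n], [initial.z]])
    spikes, traces = _run_uncoupled(
        [params], np.array([float(i_app)]), duration, dt, init,
        record=True, pulse=pulse)
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    return SingleNeuronResult(t=t, v=traces[0, 0], gates=traces[1:, 0],
                              spike_times=spikes[0], dt=dt,
                              duration=duration)


def steady_rate(spike_times: np.ndarray,
                start: float = RATE_TRANSIENT_MS,
                end: float = RATE_RUN_MS) -> float:
    """Steady firing rate (Hz) from spikes in the post-transient window.

    Rate = (count - 1) / (last - first) over spikes in [start, end];
    fewer than two spikes count as silence (0 Hz).
    """
    s = np.asarray(spike_times, dtype=float)
    s = s[(s >= start) & (s <= end)]
    if s.size < 2:
        return 0.0
    return 1000.0 * (s.size - 1) / (s[-1] - s[0])


def _rates_for_currents(params: NeuronParameters, currents: np.ndarray,
                        duration: float, dt: float) -> np.ndarray:
    n = currents.shape[0]
    init_state = NeuronState.resting()
    init = np.array([
        np.full(n, init_state.v), np.full(n, init_state.h),
        np.full(n, init_state.n), np.full(n, init_state.z)])
    spikes, _ = _run_uncoupled([params] * n, currents, duration, dt, init,
                               record=False)
    transient = duration - (RATE_RUN_MS - RATE_TRANSIENT_MS)
    return np.array([steady_rate(s, transient, duration) for s in spikes])


def fi_curve(params: NeuronParameters, currents,
             duration: float = RATE_RUN_MS,
             dt: float = DEFAULT_DT_MS):
    """Steady firing rate at each drive current on an ascending grid.

    Returns (currents, rates_hz).  All grid points are integrated in one
    vectorized pass (the cells are uncoupled).
    """
    currents = np.asarray(currents, dtype=float)
    if currents.ndim != 1 or np.any(np.diff(currents) < 0):
        raise ValueError("current grid must be 1-D and sorted ascending")
    rates = _rates_for_currents(params, currents, duration, dt)
    return currents, rates


#: Bisection brackets (µA/cm²) for drive calibration, by excitability type.
CALIBRATION_BRACKET_TYPE_I = (0.0, 5.0)
CALIBRATION_BRACKET_TYPE_II = (0.0, 10.0)


def calibrate_drive(params: NeuronParameters, target_rate: float,
                    tolerance: float = 0.1,
                    bracket: tuple[float, float] | None = None,
                    max_iter: int = 60,
                    dt: float = DEFAULT_DT_MS) -> float:
    """Drive current at which the isolated cell fires at ``target_rate`` Hz.

    Deterministic bisection on the (monotone) steady I-F relation; raises
    :class:`CalibrationError` if the bracket does not straddle the target.
    """
    if bracket is None:
        bracket = (CALIBRATION_BRACKET_TYPE_II if params.is_type_ii
                   else CALIBRATION_BRACKET_TYPE_I)
    lo, hi = bracket

    def rate_at(i_app: float) -> float:
        return _rates_for_currents(params, np.array([i_app]),
                                   RATE_RUN_MS, dt)[0]

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_lo <= target_rate <= r_hi):
        raise CalibrationError(
            f"target {target_rate} Hz not bracketed by rates "
            f"[{r_lo:.2f}, {r_hi:.2f}] Hz on currents [{lo}, {hi}]")
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate_at(mid)
        if abs(r - target_rate) <= tolerance:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach {target_rate} +/- {tolerance} Hz "
        f"in {max_iter} iterations (last rate {r:.3f} Hz)")


@dataclass
class PhaseResponseCurve:
    """Normalized first-order PRC of a periodically firing cell.

    ``shifts[k]`` = (T0 - T_perturbed) / T0 for a square pulse delivered
    at phase ``phases[k]`` of the cycle: positive values are phase
    advances, negative values delays.
    """

    phases: np.ndarray
    shifts: np.ndarray
    pulse_amplitude: float
    pulse_duration: float
    period: float

    def __post_init__(self):
        if np.any(np.diff(self.phases) <= 0):
            raise ValueError("phases must be strictly increasing")
        if np.any(np.abs(self.shifts) >= 1):
            raise ValueError("|shifts| must be < 1")


def compute_prc(params: NeuronParameters, i_app: float,
                pulse_amplitude: float = 2.0,
                pulse_duration: float = 0.5,
                n_phases: int = 50,
                dt: float = 0.01) -> PhaseResponseCurve:
    """PRC by direct perturbation of a steadily firing cell.

    The unperturbed run determines the steady period T0 (mean of late
    interspike intervals); a square pulse is then delivered at
    ``n_phases`` evenly spaced phases of one late cycle, and the shift of
    the next spike is measured.  Raises :class:`PrcUndefinedError` when
    the baseline is not periodic (silent or drifting ISIs).
    """
    base = simulate_single_neuron(params, i_app, duration=1600.0, dt=dt)
    late = base.spike_times[base.spike_times > 800.0]
    if late.size < 6:
        raise PrcUndefinedError(
            f"baseline at i_app={i_app} produced {late.size} late spikes; "
            "PRC requires steady periodic firing")
    isis = np.diff(late)
    t0_period = float(np.mean(isis))
    if np.std(isis) > 0.02 * t0_period:
        raise PrcUndefinedError(
            f"baseline ISIs not steady (CV {np.std(isis)/t0_period:.3f})")
    t_ref = float(late[-3])

    phases = np.arange(n_phases, dtype=float) / n_phases
    shifts = np.empty(n_phases)
    duration = t_ref + 3.0 * t0_period
    for k, phi in enumerate(phases):
        p_start = t_ref + phi * t0_period
        run = simulate_single_neuron(
            params, i_app, duration=duration, dt=dt,
            pulse=(pulse_amplitude, p_start, p_start + pulse_duration))
        after = run.spike_times[run.spike_times > t_ref + 0.5 * dt]
        if after.size == 0:
            raise PrcUndefinedError(
                f"no spike after perturbation at phase {phi:.3f}")
        t_pert = after[0] - t_ref
        shifts[k] = (t0_period - t_pert) / t0_period
    return PhaseResponseCurve(
        phases=phases, shifts=shifts, pulse_amplitude=pulse_amplitude,
        pulse_duration=pulse_duration, period=t0_period)
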