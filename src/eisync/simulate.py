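"""Full-network integration with double-exponential conductance synapses.

Each synapse class contributes a current

    I_syn(t) = g_syn * (V_post - E_syn) * sum_i [ exp(-(t - s_i)/tau_d)
                                                - exp(-(t - s_i)/tau_r) ]

summed over all presynaptic spike times s_i.  The sum is never formed
explicitly: two exponential accumulators per postsynaptic cell and
incoming class (one per kernel branch) are decayed analytically each step
and incremented by 1 at every presynaptic spike, which is algebraically
identical to the spike-list sum.

Runs start from random initial conditions (V uniform in [-62, -22] mV,
h and n in [0.2, 0.8], z in [0.15, 0.25]) and spikes trigger no synaptic
current during the first 100 ms so initial transients decay before the
network couples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .errors import IntegrationError
from .network import NetworkModel
from .raster import SpikeRaster

__all__ = ["SimulationSettings", "SynapticDriveState", "synaptic_current",
           "run_simulation", "initial_state_arrays"]


@dataclass(frozen=True)
class SimulationSettings:
    """Integration protocol and synaptic kinetics."""

    duration: float = 1500.0      # ms
    dt: float = 0.05              # ms
    synapse_onset: float = 100.0  # ms of initial synaptic silence
    tau_r: float = 0.2            # rise time, all synapses (ms)
    tau_d_exc: float = 3.0        # excitatory decay (ms)
    tau_d_inh: float = 5.5        # inhibitory decay (ms)
    e_syn_exc: float = 0.0        # mV
    e_syn_inh: float = -75.0      # mV
    record_traces: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tau_r < min(self.tau_d_exc, self.tau_d_inh):
            raise ValueError("require 0 < tau_r < tau_d for both classes")
        if not 0 <= self.synapse_onset < self.duration:
            raise ValueError("synapse_onset must lie within the run")
        if self.dt <= 0 or self.duration <= self.dt:
            raise ValueError("require dt > 0 and duration > dt")


@dataclass
class SynapticDriveState:
    """Incremental double-exponential kernel state for one input class.

    ``decay_acc - rise_acc`` equals sum_i [exp(-(t-s_i)/tau_d)
    - exp(-(t-s_i)/tau_r)] over all spikes registered so far.
    """

    tau_r: float
    tau_d: float
    decay_acc: float = 0.0
    rise_acc: float = 0.0

    def advance(self, dt: float) -> None:
        """Decay both accumulators by ``dt`` ms."""
        self.decay_acc *= np.exp(-dt / self.tau_d)
        self.rise_acc *= np.exp(-dt / self.tau_r)

    def register_spike(self) -> None:
        """Presynaptic spike at the current time: add 1 to each branch."""
        self.decay_acc += 1.0
        self.rise_acc += 1.0

    @property
    def gate(self) -> float:
        return self.decay_acc - self.rise_acc

    @staticmethod
    def kernel_peak_time(tau_r: float, tau_d: float) -> float:
        """Analytic time-to-peak of the kernel after a single spike."""
        return tau_d * tau_r / (tau_d - tau_r) * np.log(tau_d / tau_r)


def synaptic_current(state: SynapticDriveState, v_post: float,
                     g_syn: float, e_syn: float) -> float:
    """Synaptic current (µA/cm²) seen by a cell at voltage ``v_post``.

    Positive for v_post > e_syn (outward / hyperpolarizing once
    subtracted in the membrane equation).
    """
    return g_syn * (v_post - e_syn) * state.gate


def initial_state_arrays(n_cells: int, rng: np.random.Generator):
    """Random initial conditions, stacked rows (V, h, n, z)."""
    v = rng.uniform(-62.0, -22.0, n_cells)
    h = rng.uniform(0.2, 0.8, n_cells)
    n = rng.uniform(0.2, 0.8, n_cells)
    z = rng.uniform(0.15, 0.25, n_cells)
    return np.stack([v, h, n, z])


def _config_hash(network: NetworkModel,
                 settings: SimulationSettings) -> str:
    h = hashlib.sha256()
    h.update(repr(network.config).encode())
    h.update(repr(sorted(network.g.items())).encode())
    h.update(repr(settings).encode())
    return h.hexdigest()[:16]


def run_simulation(network: NetworkModel, settings: SimulationSettings,
                   rng: np.random.Generator | None = None):
    """Integrate the network and return its spike raster.

    Returns ``raster`` or ``(raster, traces)`` when
    ``settings.record_traces`` is set, where ``traces`` is a
    (4, n_cells, n_steps + 1) state array (rows V, h, n, z).  Raises
    :class:`IntegrationError` naming the step and cell on numerical
    blow-up.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    n_exc, n_inh = network.n_exc, network.n_inh
    n_cells = network.n_cells

    init = initial_state_arrays(n_cells, rng)
    V, h, n, z = (init[i].copy() for i in range(4))

    pe, pi = network.config.exc_params, network.config.inh_params
    gNa = np.concatenate([np.full(n_exc, pe.g_na), np.full(n_inh, pi.g_na)])
    gKd = np.concatenate([np.full(n_exc, pe.g_kd), np.full(n_inh, pi.g_kd)])
    gKs = np.concatenate([np.full(n_exc, pe.g_ks), np.full(n_inh, pi.g_ks)])
    gL = np.concatenate([np.full(n_exc, pe.g_l), np.full(n_inh, pi.g_l)])
    if (pe.e_na, pe.e_k, pe.e_l) != (pi.e_na, pi.e_k, pi.e_l):
        raise ValueError("populations must share reversal potentials")

    indptr, targets = network.global_adjacency()
    is_exc = np.zeros(n_cells, dtype=np.bool_)
    is_exc[:n_exc] = True
    g = network.g
    g_in_exc = np.where(is_exc, g["EE"], g["EI"]).astype(float)
    g_in_inh = np.where(is_exc, g["IE"], g["II"]).astype(float)

    n_steps = int(round(settings.duration / settings.dt))
    max_spk = int(settings.duration / _core.REFRACTORY_MS) + 2
    spike_times = np.zeros((n_cells, max_spk))
    spike_counts = np.zeros(n_cells, dtype=np.int64)
    record = bool(settings.record_traces)
    traces = (np.zeros((4, n_cells, n_steps + 1)) if record
              else np.zeros((4, 0, 0)))

    bad_step, bad_cell = _core.integrate(
        V, h, n, z, gNa, gKd, gKs, gL, pe.e_na, pe.e_k, pe.e_l,
        network.iapp,
        indptr, targets, is_exc,
        g_in_exc, g_in_inh,
        settings.tau_r, settings.tau_d_exc, settings.tau_d_inh,
        settings.e_syn_exc, settings.e_syn_inh,
        settings.dt, n_steps, settings.synapse_onset,
        0.0, 0.0, 0.0,
        spike_times, spike_counts,
        record, traces)
    if bad_step >= 0:
        raise IntegrationError(bad_step, bad_cell, settings.dt)

    raster = SpikeRaster(
        spikes=[spike_times[j, :spike_counts[j]].copy()
                for j in range(n_cells)],
        is_exc=is_exc,
        duration=settings.duration,
        config_hash=_config_hash(network, settings),
    )
    if record:
        return raster, traces
    return raster
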