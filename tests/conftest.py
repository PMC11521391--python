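"""Shared fixtures: cell parameters, small networks, reference rasters."""

import numpy as np
import pytest

from eisync.network import NetworkConfig, build_network
from eisync.neuron import NeuronParameters
from eisync.raster import SpikeRaster


@pytest.fixture(scope="session")
def type_i():
    return NeuronParameters.type_i()


@pytest.fixture(scope="session")
def type_ii():
    return NeuronParameters.type_ii()


@pytest.fixture(scope="session")
def small_network():
    """A 100E/25I high-inter network (conductances on full-size scale x4)."""
    cfg = NetworkConfig(n_exc=100, n_inh=25, exc_type="I", inh_type="I",
                        g_inter=0.00175 * 8, g_ii=0.00025 * 8, seed=11)
    return build_network(cfg)


@pytest.fixture
def periodic_raster():
    """Ten identical 50 Hz trains over 1 s."""
    times = np.arange(20.0, 1000.0, 20.0)
    return SpikeRaster(spikes=[times.copy() for _ in range(10)],
                       is_exc=np.ones(10, dtype=bool),
                       duration=1000.0)


def brute_force_trace(all_spikes, grid):
    """Direct-definition Gaussian activity trace: full sum, no truncation."""
    s = np.asarray(all_spikes, dtype=float)
    if s.size == 0:
        return np.zeros_like(grid)
    return np.exp(-((grid[:, None] - s[None, :]) ** 2) / 1.6).sum(axis=1)


def brute_force_synchrony(spike_lists, window, grid_dt=0.1):
    """Direct evaluation of the variance-ratio synchrony measure."""
    start, end = window
    n = int(round((end - start) / grid_dt))
    grid = start + np.arange(n) * grid_dt
    traces = []
    for s in spike_lists:
        s = np.asarray(s, dtype=float)
        if not np.any((s >= start) & (s < end)):
            continue
        traces.append(brute_force_trace(s, grid))
    if not traces:
        return np.nan
    traces = np.array(traces)
    mean_trace = traces.mean(axis=0)
    var = lambda x: np.mean(x ** 2) - np.mean(x) ** 2
    denom = np.mean([var(tr) for tr in traces])
    return var(mean_trace) / denom
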