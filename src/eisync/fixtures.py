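"""Synthetic rasters with known ground truth for testing the measures.

These generators emulate the two ends of the dynamics the simulator can
produce — packet-structured population bursting with controllable jitter
and participation, and fully asynchronous Poisson firing — without any
membrane dynamics.  They share the :class:`~eisync.raster.SpikeRaster`
container, so the measures layer consumes fixtures and simulations
identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster

__all__ = ["FixtureSpec", "make_burst_raster", "make_async_raster"]

#: Minimum separation enforced between consecutive spikes of one cell (ms).
_MIN_ISI = 1e-6


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a packet-burst raster.

    Each cell joins each packet independently with probability
    ``participation`` and fires once per joined packet at the packet time
    plus N(0, jitter²) ms; independent Poisson background spikes at
    ``background_rate`` Hz are superimposed.
    """

    n_cells: int
    packet_times: tuple[float, ...]
    participation: float = 1.0
    jitter: float = 0.0
    background_rate: float = 0.0
    duration: float = 1000.0
    population: str = "E"

    def __post_init__(self):
        if not 0.0 <= self.participation <= 1.0:
            raise ValueError("participation must be in [0, 1]")
        if self.jitter < 0 or self.background_rate < 0:
            raise ValueError("jitter and background rate must be >= 0")
        if any(t < 0 or t > self.duration for t in self.packet_times):
            raise ValueError("packet times must lie within the duration")


def _finalize(times: np.ndarray, duration: float) -> np.ndarray:
    """Sort, clip into the run, and enforce strictly increasing times."""
    t = np.sort(times[(times >= 0.0) & (times <= duration)])
    if t.size > 1:
        # nudge exact ties apart rather than dropping spikes
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + _MIN_ISI
        t = t[t <= duration]
    return t


def make_burst_raster(spec: FixtureSpec, rng: np.random.Generator):
    """Generate a packet raster; returns (raster, ground_truth_times)."""
    packets = np.asarray(spec.packet_times, dtype=float)
    spikes = []
    for _ in range(spec.n_cells):
        joined = rng.random(packets.size) < spec.participation
        t = packets[joined]
        if spec.jitter > 0 and t.size:
            t = t + rng.normal(0.0, spec.jitter, t.size)
        if spec.background_rate > 0:
            n_bg = rng.poisson(spec.background_rate * spec.duration / 1000.0)
            t = np.concatenate([t, rng.uniform(0.0, spec.duration, n_bg)])
        spikes.append(_finalize(t, spec.duration))
    raster = SpikeRaster(spikes=spikes,
                         is_exc=np.full(spec.n_cells,
                                        spec.population == "E"),
                         duration=spec.duration,
                         config_hash="fixture")
    return raster, packets


def make_async_raster(n_cells: int, rate: float, duration: float,
                      rng: np.random.Generator,
                      population: str = "E") -> SpikeRaster:
    """Independent homogeneous Poisson trains (asynchronous firing)."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    spikes = []
    for _ in range(n_cells):
        n_spk = rng.poisson(rate * duration / 1000.0)
        spikes.append(_finalize(rng.uniform(0.0, duration, n_spk),
                                duration))
    return SpikeRaster(spikes=spikes,
                       is_exc=np.full(n_cells, population == "E"),
                       duration=duration,
                       config_hash="fixture")
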