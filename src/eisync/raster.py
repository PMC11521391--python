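"""Spike raster container shared by the simulator, fixtures, and measures."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Per-neuron spike times (ms) with population labels over one run.

    ``spikes[i]`` is a strictly increasing float array of cell i's spike
    times in [0, duration].  ``is_exc[i]`` labels the cell excitatory
    (True) or inhibitory (False).
    """

    spikes: list[np.ndarray]
    is_exc: np.ndarray
    duration: float
    config_hash: str = ""

    def __post_init__(self):
        self.is_exc = np.asarray(self.is_exc, dtype=bool)
        if len(self.spikes) != self.is_exc.shape[0]:
            raise ValueError("spikes and is_exc length mismatch")
        for i, s in enumerate(self.spikes):
            s = np.asarray(s, dtype=float)
            self.spikes[i] = s
            if s.size and (s[0] < 0 or s[-1] > self.duration):
                raise ValueError(f"cell {i}: spike outside [0, duration]")
            if np.any(np.diff(s) <= 0):
                raise ValueError(f"cell {i}: spike times not strictly "
                                 "increasing")

    @property
    def n_cells(self) -> int:
        return len(self.spikes)

    @property
    def n_exc(self) -> int:
        return int(self.is_exc.sum())

    @property
    def n_inh(self) -> int:
        return self.n_cells - self.n_exc

    def population_indices(self, population: str) -> np.ndarray:
        """Cell indices for population 'E', 'I', or 'all'."""
        if population == "E":
            return np.flatnonzero(self.is_exc)
        if population == "I":
            return np.flatnonzero(~self.is_exc)
        if population == "all":
            return np.arange(self.n_cells)
        raise ValueError(f"unknown population {population!r}")

    def population_spikes(self, population: str) -> list[np.ndarray]:
        return [self.spikes[i] for i in self.population_indices(population)]

    def shifted(self, offset: float) -> "SpikeRaster":
        """Copy with all spike times translated by ``offset`` ms."""
        return SpikeRaster(
            spikes=[s + offset for s in self.spikes],
            is_exc=self.is_exc.copy(),
            duration=self.duration + max(offset, 0.0),
            config_hash=self.config_hash,
        )

    @classmethod
    def from_lists(cls, exc: Sequence[Sequence[float]],
                   inh: Sequence[Sequence[float]] = (),
                   duration: float | None = None) -> "SpikeRaster":
        """Convenience constructor from python lists (E cells then I)."""
        spikes = [np.asarray(s, dtype=float) for s in exc]
        spikes += [np.asarray(s, dtype=float) for s in inh]
        if duration is None:
            duration = max((s[-1] for s in spikes if s.size), default=0.0)
        is_exc = np.array([True] * len(exc) + [False] * len(inh))
        return cls(spikes=spikes, is_exc=is_exc, duration=float(duration))
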