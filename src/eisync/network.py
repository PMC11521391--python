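"""E-I network construction: wiring, cell types, and heterogeneous drive.

The network has two populations (default 800 excitatory, 200 inhibitory)
wired by four directed synapse classes drawn as independent Bernoulli
edges: inter-population E->I and I->E at probability 0.5, and
intra-population E->E and I->I at probability 0.3 (self-synapses
excluded).  Each class carries one maximal conductance; inter-class
conductances are varied jointly (g_EI = g_IE = g_inter) and the E->E
conductance defaults to a quarter of the I->I value, compensating for the
4:1 excess of excitatory cells.

Drive heterogeneity: every excitatory cell receives a constant current
drawn uniformly from the interval that spans intrinsic firing rates of
45-55 Hz (endpoints calibrated by bisection for the configured cell
type).  Inhibitory cells are held just below firing threshold: currents
drawn from U(0.95*IA, 1.05*IA) with IA = -0.2 µA/cm² for Type I
interneurons (which would otherwise fire spontaneously) and +1.0 µA/cm²
for the less excitable Type II interneurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .neuron import NeuronParameters, calibrate_drive

__all__ = ["NetworkConfig", "NetworkModel", "build_connectivity",
           "assign_excitatory_drive", "assign_inhibitory_drive",
           "build_network", "SYNAPSE_CLASSES"]

#: Directed synapse classes as (presynaptic population, postsynaptic).
SYNAPSE_CLASSES = ("EE", "EI", "IE", "II")

#: Default average inhibitory drive (µA/cm²) by interneuron type.
INHIBITORY_DRIVE = {"I": -0.2, "II": 1.0}


def _params_for(cell_type: str) -> NeuronParameters:
    if cell_type == "I":
        return NeuronParameters.type_i()
    if cell_type == "II":
        return NeuronParameters.type_ii()
    raise ValueError(f"cell type must be 'I' or 'II', got {cell_type!r}")


@dataclass(frozen=True)
class NetworkConfig:
    """Full recipe for one network realization."""

    n_exc: int = 800
    n_inh: int = 200
    p_ei: float = 0.5        # E -> I connection probability
    p_ie: float = 0.5        # I -> E
    p_ee: float = 0.3        # E -> E
    p_ii: float = 0.3        # I -> I
    exc_type: str = "I"
    inh_type: str = "I"
    g_inter: float = 0.00175  # applied to both E->I and I->E, mS/cm²
    g_ii: float = 0.00025
    g_ee: float | None = None  # defaults to g_ii / 4
    exc_rate_band: tuple[float, float] = (45.0, 55.0)
    ia_inh: float | None = None  # defaults by inh_type
    seed: int = 0

    def __post_init__(self):
        if self.n_exc < 1 or self.n_inh < 1:
            raise ValueError("populations must have at least one cell")
        for name in ("p_ei", "p_ie", "p_ee", "p_ii"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("g_inter", "g_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.g_ee is not None and self.g_ee < 0:
            raise ValueError("g_ee must be nonnegative")
        _params_for(self.exc_type)
        _params_for(self.inh_type)

    @property
    def conductances(self) -> dict[str, float]:
        g_ee = self.g_ii / 4.0 if self.g_ee is None else self.g_ee
        return {"EE": g_ee, "EI": self.g_inter,
                "IE": self.g_inter, "II": self.g_ii}

    @property
    def inhibitory_drive_mean(self) -> float:
        if self.ia_inh is not None:
            return self.ia_inh
        return INHIBITORY_DRIVE[self.inh_type]

    @property
    def exc_params(self) -> NeuronParameters:
        return _params_for(self.exc_type)

    @property
    def inh_params(self) -> NeuronParameters:
        return _params_for(self.inh_type)


@dataclass
class NetworkModel:
    """A realized network: wiring, conductances, and per-cell drives.

    Edge arrays are (pre, post) index pairs with population-local
    indices.  Excitatory cells occupy global indices [0, n_exc) and
    inhibitory cells [n_exc, n_exc + n_inh).
    """

    config: NetworkConfig
    edges: dict[str, tuple[np.ndarray, np.ndarray]]
    g: dict[str, float]
    iapp_exc: np.ndarray
    iapp_inh: np.ndarray
    iapp_band: tuple[float, float]   # calibrated (min, max) exc current

    @property
    def n_exc(self) -> int:
        return self.config.n_exc

    @property
    def n_inh(self) -> int:
        return self.config.n_inh

    @property
    def n_cells(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def iapp(self) -> np.ndarray:
        return np.concatenate([self.iapp_exc, self.iapp_inh])

    def with_conductances(self, **g_updates: float) -> "NetworkModel":
        """Copy with some class conductances replaced (wiring shared)."""
        g = dict(self.g)
        for k, v in g_updates.items():
            key = k.upper()
            if key not in SYNAPSE_CLASSES:
                raise ValueError(f"unknown synapse class {k!r}")
            g[key] = float(v)
        return replace(self, g=g)

    def ablate_ie(self) -> "NetworkModel":
        """Remove inhibitory-to-excitatory signaling (g_IE = 0)."""
        return self.with_conductances(IE=0.0)

    def global_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, targets) over global cell indices, presyn-major."""
        n = self.n_cells
        pre_all, post_all = [], []
        for cls in SYNAPSE_CLASSES:
            pre, post = self.edges[cls]
            pre_g = pre if cls[0] == "E" else pre + self.n_exc
            post_g = post if cls[1] == "E" else post + self.n_exc
            pre_all.append(pre_g)
            post_all.append(post_g)
        pre_all = np.concatenate(pre_all)
        post_all = np.concatenate(post_all)
        order = np.argsort(pre_all, kind="stable")
        pre_all, post_all = pre_all[order], post_all[order]
        counts = np.bincount(pre_all, minlength=n)
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return indptr, post_all.astype(np.int64)


def build_connectivity(config: NetworkConfig,
                       rng: np.random.Generator) -> dict:
    """Draw the four Bernoulli wiring classes.

    Every potential directed edge is an independent coin flip at its
    class probability; within-population self-edges are excluded.
    Returns {class: (pre_indices, post_indices)} with local indices.
    """
    shapes = {"EE": (config.n_exc, config.n_exc, config.p_ee),
              "EI": (config.n_exc, config.n_inh, config.p_ei),
              "IE": (config.n_inh, config.n_exc, config.p_ie),
              "II": (config.n_inh, config.n_inh, config.p_ii)}
    edges = {}
    for cls in SYNAPSE_CLASSES:
        n_pre, n_post, p = shapes[cls]
        mask = rng.random((n_pre, n_post)) < p
        if cls[0] == cls[1]:
            np.fill_diagonal(mask, False)
        pre, post = np.nonzero(mask)
        edges[cls] = (pre.astype(np.int64), post.astype(np.int64))
    return edges


@lru_cache(maxsize=32)
def _calibrated_band(cell_type: str,
                     band: tuple[float, float]) -> tuple[float, float]:
    params = _params_for(cell_type)
    lo = calibrate_drive(params, band[0])
    if band[1] == band[0]:
        return lo, lo
    hi = calibrate_drive(params, band[1])
    return lo, hi


def assign_excitatory_drive(config: NetworkConfig,
                            rng: np.random.Generator):
    """Sample per-cell excitatory drive currents.

    The band endpoints are calibrated deterministically (bisection on the
    isolated-cell rate), then each cell draws i.i.d. uniform between
    them.  Returns (currents, (i_min, i_max)).
    """
    i_min, i_max = _calibrated_band(config.exc_type,
                                    tuple(config.exc_rate_band))
    if i_max < i_min:
        raise ValueError("rate band endpoints must be ascending")
    currents = rng.uniform(i_min, i_max, size=config.n_exc)
    return currents, (i_min, i_max)


def assign_inhibitory_drive(config: NetworkConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample interneuron drives from U(0.95*IA, 1.05*IA).

    Endpoints are ordered numerically, so a negative IA (Type I) gives
    the interval [1.05*IA, 0.95*IA].
    """
    ia = config.inhibitory_drive_mean
    lo, hi = sorted((0.95 * ia, 1.05 * ia))
    return rng.uniform(lo, hi, size=config.n_inh)


def build_network(config: NetworkConfig,
                  rng: np.random.Generator | None = None) -> NetworkModel:
    """Realize a full network from a config (seeded and reproducible)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    edges = build_connectivity(config, rng)
    iapp_exc, band = assign_excitatory_drive(config, rng)
    iapp_inh = assign_inhibitory_drive(config, rng)
    return NetworkModel(config=config, edges=edges,
                        g=config.conductances, iapp_exc=iapp_exc,
                        iapp_inh=iapp_inh, iapp_band=band)
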