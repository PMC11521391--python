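"""On-disk formats: rasters (HDF5, CSV), networks (HDF5), configs (YAML)."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .network import NetworkConfig, NetworkModel, SYNAPSE_CLASSES
from .raster import SpikeRaster

__all__ = ["save_raster_hdf5", "load_raster_hdf5", "save_raster_csv",
           "load_raster_csv", "save_network_hdf5", "load_network_hdf5",
           "load_config_yaml", "save_config_yaml"]


def save_raster_hdf5(raster: SpikeRaster, path) -> None:
    """Ragged spike lists as a flat array plus per-cell offsets."""
    flat = (np.concatenate(raster.spikes) if raster.n_cells
            else np.zeros(0))
    counts = np.array([s.size for s in raster.spikes], dtype=np.int64)
    offsets = np.zeros(raster.n_cells + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    with h5py.File(path, "w") as f:
        f.create_dataset("spike_times_ms", data=flat)
        f.create_dataset("offsets", data=offsets)
        f.create_dataset("is_exc", data=raster.is_exc.astype(np.int8))
        f.attrs["duration_ms"] = raster.duration
        f.attrs["config_hash"] = raster.config_hash


def load_raster_hdf5(path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        flat = f["spike_times_ms"][:]
        offsets = f["offsets"][:]
        is_exc = f["is_exc"][:].astype(bool)
        duration = float(f.attrs["duration_ms"])
        config_hash = str(f.attrs.get("config_hash", ""))
    spikes = [flat[offsets[i]:offsets[i + 1]].copy()
              for i in range(len(offsets) - 1)]
    return SpikeRaster(spikes=spikes, is_exc=is_exc, duration=duration,
                       config_hash=config_hash)


def save_raster_csv(raster: SpikeRaster, path,
                    drive_order: np.ndarray | None = None) -> None:
    """Two-column (neuron_index, spike_time_ms) plotting dialect.

    ``drive_order``, if given, maps cell index -> plotted index so that
    the most strongly driven excitatory cells get the lowest indices
    (the raster-plot convention used throughout the study).
    """
    with open(path, "w") as f:
        f.write("neuron_index,spike_time_ms\n")
        for i, s in enumerate(raster.spikes):
            row = int(drive_order[i]) if drive_order is not None else i
            for t in s:
                f.write(f"{row},{t:.6g}\n")


def load_raster_csv(path, n_cells: int | None = None,
                    n_exc: int | None = None,
                    duration: float | None = None) -> SpikeRaster:
    """Read the CSV dialect back (labels: first ``n_exc`` cells are E)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        idx = np.zeros(0, dtype=int)
        times = np.zeros(0)
    else:
        idx = data[:, 0].astype(int)
        times = data[:, 1]
    n = n_cells if n_cells is not None else (idx.max() + 1 if idx.size
                                             else 0)
    spikes = [np.sort(times[idx == i]) for i in range(n)]
    if duration is None:
        duration = float(times.max()) if times.size else 0.0
    is_exc = np.arange(n) < (n_exc if n_exc is not None else n)
    return SpikeRaster(spikes=spikes, is_exc=is_exc, duration=duration)


def drive_ordering(model: NetworkModel) -> np.ndarray:
    """Plot index per cell: excitatory cells by descending drive."""
    order = np.argsort(-model.iapp_exc, kind="stable")
    plot_idx = np.empty(model.n_cells, dtype=np.int64)
    plot_idx[order] = np.arange(model.n_exc)
    plot_idx[model.n_exc:] = np.arange(model.n_exc, model.n_cells)
    return plot_idx


def save_network_hdf5(model: NetworkModel, path) -> None:
    with h5py.File(path, "w") as f:
        for cls in SYNAPSE_CLASSES:
            pre, post = model.edges[cls]
            f.create_dataset(f"edges/{cls}",
                             data=np.stack([pre, post], axis=1))
            f.attrs[f"g_{cls}"] = model.g[cls]
        f.create_dataset("iapp_exc", data=model.iapp_exc)
        f.create_dataset("iapp_inh", data=model.iapp_inh)
        f.attrs["iapp_band"] = np.array(model.iapp_band)
        f.attrs["config_yaml"] = yaml.safe_dump(asdict(model.config))


def load_network_hdf5(path) -> NetworkModel:
    with h5py.File(path, "r") as f:
        cfg_dict = yaml.safe_load(str(f.attrs["config_yaml"]))
        cfg_dict["exc_rate_band"] = tuple(cfg_dict["exc_rate_band"])
        config = NetworkConfig(**cfg_dict)
        edges = {}
        g = {}
        for cls in SYNAPSE_CLASSES:
            pairs = f[f"edges/{cls}"][:]
            edges[cls] = (pairs[:, 0].astype(np.int64),
                          pairs[:, 1].astype(np.int64))
            g[cls] = float(f.attrs[f"g_{cls}"])
        iapp_exc = f["iapp_exc"][:]
        iapp_inh = f["iapp_inh"][:]
        band = tuple(f.attrs["iapp_band"])
    return NetworkModel(config=config, edges=edges, g=g,
                        iapp_exc=iapp_exc, iapp_inh=iapp_inh,
                        iapp_band=band)


def load_config_yaml(path) -> NetworkConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if "exc_rate_band" in data:
        data["exc_rate_band"] = tuple(data["exc_rate_band"])
    return NetworkConfig(**data)


def save_config_yaml(config: NetworkConfig, path) -> None:
    data = asdict(config)
    data["exc_rate_band"] = list(data["exc_rate_band"])
    with open(path, "w") as f:
        yaml.safe_dump(data, f)
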