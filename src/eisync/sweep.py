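"""Connectivity sweeps: inter- vs intra-conductance grids across cell types.

Each grid cell fixes g_EI = g_IE = ``inter`` and g_II = ``intra`` (with
g_EE = intra / 4), builds ``repetitions`` independent network
realizations, simulates each, and aggregates the measures over the final
second.  Burst statistics follow the majority rule: frequency and width
are averaged only over repetitions in which repetitive bursting was
detected, and reported only when detections exceed half the repetitions.
Each aggregate also records the detection count and a qualitative flag
('all', 'majority-partial', 'minority', 'none') mirroring how partially
reproducible bursting is marked on the published-style heatmaps.

Network sizes come from presets: ``full`` is 800E/200I at the quoted
conductances; ``scaled`` is 200E/50I with all four class conductances
multiplied by the size ratio (4) so the expected aggregate synaptic
input per cell is preserved (conductance values in grids are therefore
always quoted on the full-size scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EisyncError
from .measures import MeasureReport, measure_report
from .network import NetworkConfig, build_network
from .simulate import SimulationSettings, run_simulation

__all__ = ["SweepGrid", "CellAggregate", "SweepResult", "run_sweep",
           "run_ablation", "aggregate_repetitions", "export_heatmaps",
           "PRESETS", "ALL_TYPE_COMBOS", "cell_seeds"]

#: (n_exc, n_inh, conductance multiplier applied to quoted full-size values)
PRESETS = {"full": (800, 200, 1.0), "scaled": (200, 50, 4.0)}

ALL_TYPE_COMBOS = (("I", "I"), ("I", "II"), ("II", "I"), ("II", "II"))

_POPS = (("E", "exc"), ("I", "inh"))


@dataclass(frozen=True)
class SweepGrid:
    """Axes and protocol of one sweep."""

    inter_values: tuple[float, ...]
    intra_values: tuple[float, ...]   # I-I conductance; E-E is 1/4 of it
    combos: tuple[tuple[str, str], ...] = ALL_TYPE_COMBOS
    repetitions: int = 5
    base_seed: int = 0
    preset: str = "scaled"
    ablate_ie: bool = False
    duration: float = 1500.0
    dt: float = 0.05

    def __post_init__(self):
        if not self.inter_values or not self.intra_values:
            raise ValueError("grids must be nonempty")
        for vals in (self.inter_values, self.intra_values):
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("grid values must be ascending")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


def cell_seeds(grid: SweepGrid, combo_idx: int, i_inter: int,
               i_intra: int, rep: int) -> tuple[int, int]:
    """Deterministic (wiring seed, simulation seed) for one repetition.

    Derived from the base seed and the cell coordinates through a
    SeedSequence spawn key, so any single cell/repetition can be re-run
    in isolation.  The wiring seed ignores ``ablate_ie`` so an ablation
    sweep reuses the exact wiring of its intact counterpart.
    """
    ss = np.random.SeedSequence(
        entropy=grid.base_seed,
        spawn_key=(combo_idx, i_inter, i_intra, rep))
    wiring, sim = ss.generate_state(2)
    return int(wiring % (2 ** 31)), int(sim % (2 ** 31))


@dataclass
class CellAggregate:
    """Aggregated measures for one grid cell and type combination."""

    exc_type: str
    inh_type: str
    inter: float
    intra: float
    s_exc: float
    s_inh: float
    active_exc: float
    active_inh: float
    detect_exc: int
    detect_inh: int
    repetitions: int
    burst_freq_exc: float | None
    burst_freq_inh: float | None
    burst_width_exc: float | None
    burst_width_inh: float | None
    flag_exc: str
    flag_inh: str
    n_failed: int = 0


def _detection_flag(k: int, reps: int) -> str:
    if k == 0:
        return "none"
    if k == reps:
        return "all"
    if k > reps / 2:
        return "majority-partial"
    return "minority"


def aggregate_repetitions(reports: Sequence[MeasureReport],
                          repetitions: int | None = None) -> dict:
    """Apply the majority rule to per-repetition measure reports.

    Synchrony and active-cell counts average over all repetitions;
    burst frequency/width average only over detecting repetitions and
    are reported only when detections exceed half the repetitions.
    """
    if not reports:
        raise ValueError("need at least one report")
    if repetitions is None:
        repetitions = len(reports)
    out = {"repetitions": repetitions}
    for pop, tag in _POPS:
        s_vals = np.array([getattr(r, f"s_{tag}") for r in reports])
        out[f"s_{tag}"] = float(np.nanmean(s_vals)) if np.any(
            np.isfinite(s_vals)) else float("nan")
        out[f"active_{tag}"] = float(np.mean(
            [getattr(r, f"active_{tag}") for r in reports]))
        detecting = [r for r in reports if getattr(r, f"bursting_{tag}")]
        k = len(detecting)
        out[f"detect_{tag}"] = k
        out[f"flag_{tag}"] = _detection_flag(k, repetitions)
        if k > repetitions / 2:
            out[f"burst_freq_{tag}"] = float(np.mean(
                [getattr(r, f"burst_freq_{tag}") for r in detecting]))
            out[f"burst_width_{tag}"] = float(np.mean(
                [getattr(r, f"burst_width_{tag}") for r in detecting]))
        else:
            out[f"burst_freq_{tag}"] = None
            out[f"burst_width_{tag}"] = None
    return out


@dataclass
class SweepResult:
    """All cell aggregates of one sweep, indexable by coordinates."""

    grid: SweepGrid
    cells: dict[tuple[str, str, int, int], CellAggregate]

    def get(self, exc_type: str, inh_type: str, i_inter: int,
            i_intra: int) -> CellAggregate:
        return self.cells[(exc_type, inh_type, i_inter, i_intra)]

    def matrix(self, exc_type: str, inh_type: str,
               measure: str) -> np.ndarray:
        """(n_inter, n_intra) array of one measure; None -> NaN."""
        g = self.grid
        out = np.full((len(g.inter_values), len(g.intra_values)), np.nan)
        for i in range(len(g.inter_values)):
            for j in range(len(g.intra_values)):
                v = getattr(self.get(exc_type, inh_type, i, j), measure)
                if v is not None:
                    out[i, j] = v
        return out


def run_cell(grid: SweepGrid, combo_idx: int, i_inter: int,
             i_intra: int) -> CellAggregate:
    """Simulate and aggregate one grid cell (all repetitions)."""
    exc_type, inh_type = grid.combos[combo_idx]
    inter = grid.inter_values[i_inter]
    intra = grid.intra_values[i_intra]
    n_exc, n_inh, g_scale = PRESETS[grid.preset]

    reports, n_failed = [], 0
    for rep in range(grid.repetitions):
        wiring_seed, sim_seed = cell_seeds(grid, combo_idx, i_inter,
                                           i_intra, rep)
        cfg = NetworkConfig(
            n_exc=n_exc, n_inh=n_inh, exc_type=exc_type,
            inh_type=inh_type, g_inter=inter * g_scale,
            g_ii=intra * g_scale, seed=wiring_seed)
        try:
            net = build_network(cfg)
            if grid.ablate_ie:
                net = net.ablate_ie()
            settings = SimulationSettings(duration=grid.duration,
                                          dt=grid.dt, seed=sim_seed)
            raster = run_simulation(net, settings)
            reports.append(measure_report(raster))
        except EisyncError:
            n_failed += 1
    if not reports:
        raise EisyncError(
            f"all {grid.repetitions} repetitions failed for combo "
            f"{exc_type}/{inh_type} at inter={inter}, intra={intra}")
    agg = aggregate_repetitions(reports, grid.repetitions)
    return CellAggregate(exc_type=exc_type, inh_type=inh_type,
                         inter=inter, intra=intra, n_failed=n_failed,
                         **{k: v for k, v in agg.items()})


def run_sweep(grid: SweepGrid, progress: bool = False) -> SweepResult:
    """Run every (combo, inter, intra) cell of the grid."""
    cells = {}
    for c, (exc_type, inh_type) in enumerate(grid.combos):
        for i in range(len(grid.inter_values)):
            for j in range(len(grid.intra_values)):
                cells[(exc_type, inh_type, i, j)] = run_cell(grid, c, i, j)
                if progress:
                    a = cells[(exc_type, inh_type, i, j)]
                    print(f"[{exc_type}/{inh_type}] inter={a.inter:g} "
                          f"intra={a.intra:g}: S_exc={a.s_exc:.3f} "
                          f"detect={a.detect_exc}/{a.repetitions}")
    return SweepResult(grid=grid, cells=cells)


def run_ablation(grid: SweepGrid, progress: bool = False) -> SweepResult:
    """Run the sweep with I->E synapses removed after wiring.

    The wiring seeds are identical to the intact sweep's, so the forced
    g_IE = 0 is the only difference.
    """
    from dataclasses import replace
    return run_sweep(replace(grid, ablate_ie=True), progress=progress)


_HEATMAP_MEASURES = ("s_exc", "s_inh", "active_exc", "active_inh",
                     "burst_freq_exc", "burst_freq_inh",
                     "burst_width_exc", "burst_width_inh")


def export_heatmaps(result: SweepResult, out_dir, plots: bool = True):
    """Write one CSV matrix (and optionally a PNG) per measure and combo.

    CSV rows are inter values, columns intra values; undefined entries
    (no majority bursting) are empty cells.  Returns the written paths.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = result.grid
    written = []
    for exc_type, inh_type in grid.combos:
        combo_tag = f"E{exc_type}_I{inh_type}"
        for measure in _HEATMAP_MEASURES:
            mat = result.matrix(exc_type, inh_type, measure)
            df = pd.DataFrame(mat, index=list(grid.inter_values),
                              columns=list(grid.intra_values))
            df.index.name = "inter"
            path = out_dir / f"{combo_tag}_{measure}.csv"
            df.to_csv(path)
            written.append(path)
            if plots:
                written.append(_plot_heatmap(
                    result, exc_type, inh_type, measure, mat,
                    out_dir / f"{combo_tag}_{measure}.png"))
    manifest = {
        "grid": {**asdict(grid),
                 "combos": [list(c) for c in grid.combos]},
        "flags": {
            f"E{e}_I{i}": [[result.get(e, i, a, b).flag_exc
                            for b in range(len(grid.intra_values))]
                           for a in range(len(grid.inter_values))]
            for e, i in grid.combos},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)
    return written


def _plot_heatmap(result, exc_type, inh_type, measure, mat, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = result.grid
    fig, ax = plt.subplots(figsize=(5, 4))
    masked = np.ma.masked_invalid(mat)
    im = ax.imshow(masked, origin="lower", aspect="auto", cmap="viridis")
    tag = "exc" if measure.endswith("exc") else "inh"
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            flag = getattr(result.get(exc_type, inh_type, i, j),
                           f"flag_{tag}")
            if flag in ("majority-partial", "minority"):
                ax.add_patch(plt.Rectangle(
                    (j - 0.5, i - 0.5), 1, 1, fill=False,
                    edgecolor="black", linewidth=2.5))
    ax.set_xticks(range(mat.shape[1]),
                  [f"{v:g}" for v in grid.intra_values], rotation=45)
    ax.set_yticks(range(mat.shape[0]),
                  [f"{v:g}" for v in grid.inter_values])
    ax.set_xlabel("intra-connectivity g_II (mS/cm², full-size scale)")
    ax.set_ylabel("inter-connectivity g (mS/cm², full-size scale)")
    ax.set_title(f"{measure}  E:{exc_type} I:{inh_type}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
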