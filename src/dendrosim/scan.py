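"""Grid scan over branching/terminating rate space.

Produces mean-R95, SD-R95, CV and density surfaces over a (k_b, k_t) grid.
Cells with k_b >= k_t are excluded without simulation: there the dendrite
count grows without bound (or is null-recurrent on the diagonal) and the
field has no finite size.  Refinement cells with small Δk = k_t - k_b are
appended per k_b column to probe field radii beyond the coarse grid's
characteristic maximum sqrt(1/Δk_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import GrowthSchedule, simulate_neuron, spawn_rng
from .summaries import summarize_ensemble

__all__ = [
    "GridSpec",
    "GridScanResult",
    "default_k_values",
    "characteristic_radius",
    "scan",
]


def default_k_values() -> tuple[float, ...]:
    """49 rate values 0.01, 0.03, ..., 0.97 μm⁻¹ (spacing 0.02)."""
    return tuple(round(0.01 + 0.02 * i, 4) for i in range(49))


#: Δk offsets appended per k_b column to probe near-critical kinetics.
DEFAULT_REFINEMENTS = (0.01, 0.05, 0.025, 0.0125)


def characteristic_radius(delta_k: float) -> float:
    """sqrt(1/Δk): the field-radius scale set by the characteristic total
    dendrite length 1/Δk of a subcritical stage."""
    if delta_k <= 0:
        raise ValueError("delta_k must be positive")
    return math.sqrt(1.0 / delta_k)


@dataclass(frozen=True)
class GridSpec:
    k_values: tuple[float, ...] = field(default_factory=default_k_values)
    delta_k_refinements: tuple[float, ...] = DEFAULT_REFINEMENTS
    n_neurons_per_cell: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_values", tuple(self.k_values))
        object.__setattr__(self, "delta_k_refinements", tuple(self.delta_k_refinements))
        if self.n_neurons_per_cell < 2:
            raise ValueError("n_neurons_per_cell must be >= 2")
        if any(k <= 0 for k in self.k_values):
            raise ValueError("rate values must be positive")
        if any(d <= 0 for d in self.delta_k_refinements):
            raise ValueError("refinement Δk offsets must be positive")


@dataclass
class GridScanResult:
    records: pd.DataFrame  # k_b, k_t, mean_r95, sd_r95, cv, density, status, refined
    grid: GridSpec
    n0: int

    def matrix(self, stat: str) -> pd.DataFrame:
        """Wide matrix (rows = k_t, columns = k_b) of one coarse-grid statistic."""
        coarse = self.records[~self.records["refined"]]
        return coarse.pivot(index="k_t", columns="k_b", values=stat)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "grid_scan_long.csv", index=False)
        for stat in ("mean_r95", "sd_r95", "density"):
            self.matrix(stat).to_csv(out / f"grid_{stat}_matrix.csv")

    def plot_heatmaps(self, path) -> None:
        """Quick-look heat maps of the mean, SD and density surfaces."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(15, 4.2))
        for ax, stat in zip(axes, ("mean_r95", "sd_r95", "density")):
            m = self.matrix(stat)
            im = ax.pcolormesh(m.columns.values, m.index.values, m.values, shading="nearest")
            ax.set_xlabel("k_b (μm⁻¹)")
            ax.set_ylabel("k_t (μm⁻¹)")
            ax.set_title(stat)
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _cell_record(k_b: float, k_t: float, refined: bool) -> dict:
    return {"k_b": k_b, "k_t": k_t, "mean_r95": np.nan, "sd_r95": np.nan,
            "cv": np.nan, "density": np.nan, "status": "", "refined": refined}


def _simulate_cell(k_b: float, k_t: float, grid: GridSpec, n0: int,
                   spawn_key: tuple[int, ...], refined: bool) -> dict:
    rec = _cell_record(k_b, k_t, refined)
    schedule = GrowthSchedule.one_stage(k_b, k_t, n0=n0)
    # cell seed = (master_seed, *spawn_key, neuron index): stable across runs
    neurons = [
        simulate_neuron(schedule, seed=(grid.master_seed, *spawn_key, i),
                        rng=spawn_rng(grid.master_seed, *spawn_key, i),
                        record_events=False)
        for i in range(grid.n_neurons_per_cell)
    ]
    truncated = sum(nr.truncated for nr in neurons)
    if truncated:
        rec["status"] = "truncated"
    else:
        rec["status"] = "ok"
    usable = [nr for nr in neurons if not nr.truncated]
    if len(usable) >= 2:
        s = summarize_ensemble(neurons)
        rec.update(mean_r95=s.mean_r95, sd_r95=s.sd_r95, cv=s.cv_r95, density=s.density)
    return rec


def scan(grid: GridSpec, n0: int = 30) -> GridScanResult:
    """Run the full grid scan.

    Coarse cells take every (k_b, k_t) pair from ``grid.k_values``; cells
    with k_b >= k_t get status ``supercritical_excluded`` and are never
    simulated.  Refinement cells add k_t = k_b + Δk per column.  Cell seeds
    derive from the master seed and the cell's grid indices, so re-running
    with the same master seed reproduces every cell bitwise.
    """
    records = []
    for i, k_b in enumerate(grid.k_values):
        for j, k_t in enumerate(grid.k_values):
            if k_b >= k_t:
                rec = _cell_record(k_b, k_t, refined=False)
                rec["status"] = "supercritical_excluded"
                records.append(rec)
                continue
            records.append(_simulate_cell(k_b, k_t, grid, n0, (0, i, j), refined=False))
        for j, dk in enumerate(grid.delta_k_refinements):
            k_t = round(k_b + dk, 6)
            records.append(_simulate_cell(k_b, k_t, grid, n0, (1, i, j), refined=True))
    return GridScanResult(records=pd.DataFrame(records), grid=grid, n0=n0)
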