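"""Per-neuron and ensemble summary statistics.

R95 — the per-neuron field radius — is the 95th percentile (linear
interpolation between order statistics, numpy's default) of the radial
distances sqrt(r) of that neuron's termination points.  Ensembles are
summarised by the mean, sample SD (n-1 denominator), median and CV
(100·SD/mean) of the per-neuron R95 values; the dendritic density of a
neuron is its total dendrite length divided by the circular field area
π·R95².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import NeuronResult, radial_distance

__all__ = [
    "NeuronStats",
    "EnsembleSummary",
    "r95",
    "neuron_stats",
    "summarize_ensemble",
    "mean_segment_length",
    "density",
    "ensemble_table",
]


@dataclass(frozen=True)
class NeuronStats:
    r95: float                # field radius (μm)
    n_terminals: int
    total_length: float       # Σ n·Δr over the trajectory (μm)
    mean_segment: float       # mean per-tip birth-to-event distance (μm)


@dataclass(frozen=True)
class EnsembleSummary:
    n_neurons: int            # non-truncated neurons only
    mean_r95: float           # μm
    sd_r95: float             # μm, sample SD
    median_r95: float         # μm
    cv_r95: float             # percent, 100·sd/mean
    mean_segment: float       # μm, pooled over all segments
    density: float            # μm dendrite per μm² field
    n_truncated: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def r95(neuron: NeuronResult) -> float:
    """95th percentile of the radial distances of a neuron's terminals."""
    if neuron.truncated:
        raise ValueError("truncated neuron: field size undefined")
    if neuron.n_terminations == 0:
        raise ValueError("neuron has no termination events")
    return float(np.percentile(neuron.terminal_distances, 95))


def neuron_stats(neuron: NeuronResult) -> NeuronStats:
    return NeuronStats(
        r95=r95(neuron),
        n_terminals=neuron.n_terminations,
        total_length=neuron.total_length,
        mean_segment=float(np.mean(neuron.segment_lengths)),
    )


def _usable(neurons: Sequence[NeuronResult]) -> list[NeuronResult]:
    return [nr for nr in neurons if not nr.truncated]


def mean_segment_length(neurons: Sequence[NeuronResult]) -> float:
    """Arithmetic mean of per-tip segment lengths pooled across neurons.

    The analytic expectation is 1/(k_b + k_t): each tip's hazard per unit
    grown length is constant at k_b + k_t while it is alive.
    """
    segs = [nr.segment_lengths for nr in neurons if len(nr.segment_lengths)]
    if not segs:
        raise ValueError("no segments recorded")
    return float(np.mean(np.concatenate(segs)))


def density(neurons: Sequence[NeuronResult]) -> float:
    """Mean over neurons of total_length / (π R95²), μm/μm².

    Neurons with R95 = 0 carry no defined field area and are excluded with
    a warning.
    """
    usable = _usable(neurons)
    vals = []
    skipped = 0
    for nr in usable:
        radius = r95(nr)
        if radius <= 0:
            skipped += 1
            continue
        vals.append(nr.total_length / (np.pi * radius ** 2))
    if skipped:
        warnings.warn(f"excluded {skipped} neuron(s) with R95 = 0 from density")
    if not vals:
        raise ValueError("no neurons with positive field radius")
    return float(np.mean(vals))


def summarize_ensemble(neurons: Sequence[NeuronResult]) -> EnsembleSummary:
    usable = _usable(neurons)
    if not usable:
        raise ValueError("all neurons truncated: parameter set appears divergent")
    if len(usable) < 2:
        raise ValueError("need at least two non-truncated neurons")
    r = np.array([r95(nr) for nr in usable])
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    return EnsembleSummary(
        n_neurons=len(usable),
        mean_r95=mean,
        sd_r95=sd,
        median_r95=float(np.median(r)),
        cv_r95=100.0 * sd / mean if mean > 0 else float("nan"),
        mean_segment=mean_segment_length(usable),
        density=density(usable),
        n_truncated=len(neurons) - len(usable),
    )


def ensemble_table(neurons: Sequence[NeuronResult]) -> pd.DataFrame:
    """Per-neuron table: one row per simulated neuron (truncated included)."""
    rows = []
    for i, nr in enumerate(neurons):
        rows.append({
            "neuron_id": i,
            "seed": repr(nr.seed),
            "r95_um": r95(nr) if (not nr.truncated and nr.n_terminations) else np.nan,
            "n_terminals": nr.n_terminations,
            "total_length_um": nr.total_length,
            "mean_segment_um": float(np.mean(nr.segment_lengths)) if len(nr.segment_lengths) else np.nan,
            "truncated": nr.truncated,
        })
    return pd.DataFrame(rows)
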