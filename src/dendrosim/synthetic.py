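"""Synthetic dendritic-field-size measurement sets.

Generates per-genotype samples of field sizes in dfu (dendritic field
units: the rhombic area spanned by four neighbouring photoreceptor
terminals), emulating the structure of confocal measurement tables — a
label, a mean, an SD and a sample size per genotype — so that the
mean-comparison and dispersion-test workflow can be exercised without any
imaging data.

Published tables usually print mean ± SE; :func:`se_to_sd` converts
(SD = SE·sqrt(n)) so printed rows can be mimicked without silently
misreading the ± value.  Values are drawn from a normal distribution by
default; a ``rounded-normal`` family rounds to whole dfu and clamps at 1
for integer-like data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dispersion import TwoSampleResult, conover_squared_ranks, siegel_tukey
from .growth import spawn_rng

__all__ = [
    "GenotypeSpec",
    "SyntheticStudy",
    "GenotypeComparison",
    "generate",
    "compare_genotypes",
    "se_to_sd",
    "read_measurements",
]

_FAMILIES = ("normal", "rounded-normal")


def se_to_sd(se: float, n: int) -> float:
    """Convert a printed standard error to the sample SD: SD = SE·sqrt(n)."""
    return se * math.sqrt(n)


@dataclass(frozen=True)
class GenotypeSpec:
    label: str
    mean_dfu: float
    sd_dfu: float
    n: int
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.mean_dfu <= 0:
            raise ValueError("mean_dfu must be positive")
        if self.sd_dfu < 0:
            raise ValueError("sd_dfu must be non-negative")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")


@dataclass
class SyntheticStudy:
    genotypes: tuple[GenotypeSpec, ...]
    seed: int
    samples: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = [(label, v) for label, vals in self.samples.items() for v in vals]
        return pd.DataFrame(rows, columns=["genotype", "dfu"])

    def to_csv(self, path) -> None:
        # %.17g round-trips float64 exactly through the CSV reader
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_measurements(path) -> dict[str, np.ndarray]:
    """Read a two-column (genotype, dfu) CSV back into per-genotype arrays."""
    df = pd.read_csv(path, float_precision="round_trip")
    return {label: grp["dfu"].to_numpy(dtype=float)
            for label, grp in df.groupby("genotype", sort=False)}


def generate(specs: Sequence[GenotypeSpec], seed: int) -> SyntheticStudy:
    """Draw each genotype's sample; genotype i uses spawn_rng(seed, i)."""
    specs = tuple(specs)
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("genotype labels must be unique")
    samples: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        rng = spawn_rng(seed, i)
        vals = rng.normal(spec.mean_dfu, spec.sd_dfu, size=spec.n)
        if spec.family == "rounded-normal":
            vals = np.maximum(np.rint(vals), 1.0)
        samples[spec.label] = vals
    return SyntheticStudy(genotypes=specs, seed=seed, samples=samples)


@dataclass(frozen=True)
class GenotypeComparison:
    a: str
    b: str
    mean_a: float
    mean_b: float
    t_statistic: float
    t_p_value: float
    conover: TwoSampleResult
    siegel_tukey: TwoSampleResult

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b,
            "mean_a": self.mean_a, "mean_b": self.mean_b,
            "t_statistic": self.t_statistic, "t_p_value": self.t_p_value,
            "conover": self.conover.to_dict(),
            "siegel_tukey": self.siegel_tukey.to_dict(),
        }


def compare_genotypes(study: SyntheticStudy, a: str, b: str) -> GenotypeComparison:
    """Means by classical equal-variance Student's t; dispersion by both
    rank tests."""
    for label in (a, b):
        if label not in study.samples:
            raise KeyError(f"unknown genotype label: {label!r}")
    xa, xb = study.samples[a], study.samples[b]
    t_stat, t_p = stats.ttest_ind(xa, xb, equal_var=True)
    return GenotypeComparison(
        a=a, b=b,
        mean_a=float(np.mean(xa)), mean_b=float(np.mean(xb)),
        t_statistic=float(t_stat), t_p_value=float(t_p),
        conover=conover_squared_ranks(xa, xb),
        siegel_tukey=siegel_tukey(xa, xb),
    )
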