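"""Ensemble bookkeeping and WT-vs-mutant conformation-space comparison.

An ensemble-docking campaign docks each acceptor into every receptor
conformation harvested from the MD trajectories (e.g. 5 replicas x 5 ns
sampled every 50 ps including t=0 gives 505 receptor conformations).  The
per-pose reaction-geometry features are then mapped onto the (d1, a1)
plane — after discarding poses whose hydroxyl is too far from the catalytic
glutamate (d2 prefilter) — and the mutant-minus-WT density difference shows
where the mutation enriches or depletes conformations.  The *enrichment
count* is the raw difference in the number of reactive poses inside the
reactive region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.proportion import proportions_ztest

from .geometry import ReactiveCriteria, ReactiveGeometry

__all__ = [
    "EnsembleDefinition",
    "ensemble_size",
    "ConformationMap2D",
    "build_conformation_map",
    "reactive_population_summary",
    "AnalysisError",
]


class AnalysisError(ValueError):
    """An ensemble-level analysis received unusable input."""


@dataclass(frozen=True)
class EnsembleDefinition:
    """How receptor conformations are harvested from replica trajectories."""

    n_replicas: int
    sim_length_ps: float
    stride_ps: float
    include_t0: bool = True

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError(f"n_replicas must be >= 1, got {self.n_replicas}")
        if self.stride_ps <= 0:
            raise ValueError(f"stride_ps must be positive, got {self.stride_ps}")
        n = self.sim_length_ps / self.stride_ps
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"stride_ps={self.stride_ps} does not divide sim_length_ps={self.sim_length_ps}"
            )


def ensemble_size(defn: EnsembleDefinition) -> int:
    """Number of conformations: n_replicas x (sim_length/stride + [t0])."""
    per_replica = int(round(defn.sim_length_ps / defn.stride_ps)) + int(defn.include_t0)
    return defn.n_replicas * per_replica


@dataclass
class ConformationMap2D:
    """Binned (d1, a1) distributions for two variants and their difference.

    ``density_diff`` is normalized(mutant) - normalized(WT), each variant's
    histogram normalized to unit mass; ``enrichment_count`` is the raw
    difference in reactive-pose counts (mutant - WT).
    """

    d1_edges: np.ndarray
    a1_edges: np.ndarray
    counts_wt: np.ndarray
    counts_mut: np.ndarray
    density_diff: np.ndarray
    criteria: ReactiveCriteria
    enrichment_count: int

    def smoothed_diff(self, sigma_bins: float = 1.0) -> np.ndarray:
        """Gaussian-smoothed density difference — for plotting only; every
        statistic in this module uses the raw counts."""
        return ndimage.gaussian_filter(self.density_diff, sigma=sigma_bins)


def _edges(values: np.ndarray, lo: float, hi: float, width: float) -> np.ndarray:
    """Half-open [lo, hi) bins of the given width, last bin closed; the top
    edge is extended so that binning is exhaustive for the data at hand."""
    top = hi
    if values.size and values.max() > hi:
        top = lo + math.ceil((values.max() - lo) / width) * width
    n = int(round((top - lo) / width))
    return lo + width * np.arange(n + 1)


def build_conformation_map(
    geometries_wt: Sequence[ReactiveGeometry],
    geometries_mut: Sequence[ReactiveGeometry],
    criteria: ReactiveCriteria | None = None,
    d1_bin: float = 0.25,
    a1_bin: float = 5.0,
    d1_range: tuple[float, float] = (0.0, 15.0),
) -> ConformationMap2D:
    """Bin (d1, a1) per variant after the d2 prefilter and take the
    mutant-minus-WT density difference.

    Only poses with d2 below the d2 threshold enter the map.  Default bins
    (0.25 A, 5 deg) place the 4 A / 80-140 deg reactive box exactly on bin
    edges.
    """
    criteria = criteria or ReactiveCriteria()

    def prefilter(geoms: Sequence[ReactiveGeometry], label: str) -> np.ndarray:
        keep = [
            (g.d1, g.a1, g.reactive)
            for g in geoms
            if not math.isnan(g.d2)
            and (g.d2 < criteria.d2_max if criteria.strict else g.d2 <= criteria.d2_max)
        ]
        if not keep:
            raise AnalysisError(f"no {label} poses remain after the d2 prefilter")
        return np.array(keep, dtype=float)

    wt = prefilter(geometries_wt, "WT")
    mut = prefilter(geometries_mut, "mutant")

    d1_edges = _edges(np.concatenate([wt[:, 0], mut[:, 0]]), d1_range[0], d1_range[1], d1_bin)
    a1_edges = _edges(np.array([]), 0.0, 180.0, a1_bin)

    counts_wt, _, _ = np.histogram2d(wt[:, 0], wt[:, 1], bins=(d1_edges, a1_edges))
    counts_mut, _, _ = np.histogram2d(mut[:, 0], mut[:, 1], bins=(d1_edges, a1_edges))
    density_diff = counts_mut / counts_mut.sum() - counts_wt / counts_wt.sum()
    enrichment = int(round(mut[:, 2].sum() - wt[:, 2].sum()))
    return ConformationMap2D(
        d1_edges=d1_edges,
        a1_edges=a1_edges,
        counts_wt=counts_wt.astype(int),
        counts_mut=counts_mut.astype(int),
        density_diff=density_diff,
        criteria=criteria,
        enrichment_count=enrichment,
    )


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 1.0
    _, p = proportions_ztest([k1, k2], [n1, n2])
    return float(p)


def reactive_population_summary(
    per_ligand: Mapping[str, tuple[Sequence[ReactiveGeometry], Sequence[ReactiveGeometry]]],
) -> pd.DataFrame:
    """Per-ligand reactive counts/fractions for WT and mutant.

    Returns one row per ligand with the mutant-minus-WT fraction difference
    and a two-proportion z-test p-value (an added inferential layer on top
    of the raw counts).  ``df.attrs["consistent_direction"]`` flags whether
    the difference has the same sign for every ligand.
    """
    rows = []
    for ligand, (geoms_wt, geoms_mut) in per_ligand.items():
        n_wt, n_mut = len(geoms_wt), len(geoms_mut)
        k_wt = sum(bool(g.reactive) for g in geoms_wt)
        k_mut = sum(bool(g.reactive) for g in geoms_mut)
        frac_wt = k_wt / n_wt if n_wt else math.nan
        frac_mut = k_mut / n_mut if n_mut else math.nan
        rows.append(
            {
                "ligand": ligand,
                "n_wt": n_wt,
                "reactive_wt": k_wt,
                "frac_wt": frac_wt,
                "n_mut": n_mut,
                "reactive_mut": k_mut,
                "frac_mut": frac_mut,
                "diff": frac_mut - frac_wt,
                "p_value": _two_proportion_p(k_wt, n_wt, k_mut, n_mut) if n_wt and n_mut else math.nan,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "ligand", "n_wt", "reactive_wt", "frac_wt",
            "n_mut", "reactive_mut", "frac_mut", "diff", "p_value",
        ],
    )
    nonzero = df["diff"].dropna()
    nonzero = nonzero[nonzero != 0]
    df.attrs["consistent_direction"] = bool(len(df)) and (
        nonzero.empty or (nonzero > 0).all() or (nonzero < 0).all()
    )
    return df
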