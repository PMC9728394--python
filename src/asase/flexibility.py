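"""Per-residue flexibility (RMSF) across replica trajectories and RMSD traces.

RMSF is computed per replica after least-squares superposition of every
frame onto a reference (first frame by default), as the root-mean-square
deviation of each selected atom about its post-superposition mean position.
Replicas are then averaged with a 95% t-confidence interval
(df = n_replicas - 1), and two variants are compared residue-by-residue
with Welch's two-sample t-test on the per-replica RMSF values.

The selection defaults to one designated atom per residue (CA), the
standard per-residue RMSF convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .structure_io import Trajectory

__all__ = [
    "RMSFProfile",
    "FlexibilityComparison",
    "compute_rmsf",
    "aggregate_replicas",
    "compare_flexibility",
    "compute_rmsd_trace",
    "superpose",
]


class AnalysisError(ValueError):
    """A flexibility computation received unusable input."""


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of one frame onto a reference.

    Both arrays have shape (n_atoms, 3); returns the transformed mobile
    coordinates.  Rotation is solved with scipy's align_vectors (SVD).
    """
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_center, mobile - mob_center)
    return rot.apply(mobile - mob_center) + ref_center


def _select(traj: Trajectory, selection: str | Sequence[str]) -> np.ndarray:
    if isinstance(selection, str):
        wanted = {selection}
    else:
        wanted = set(selection)
    idx = np.array([i for i, name in enumerate(traj.atom_names) if name in wanted], dtype=int)
    if idx.size == 0:
        raise AnalysisError(f"selection {sorted(wanted)!r} matches no atoms")
    return idx


def compute_rmsf(
    traj: Trajectory,
    selection: str | Sequence[str] = "CA",
    superpose_frames: bool = True,
    reference_frame: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF for one replica.

    Returns ``(residue_ids, rmsf)`` where
    ``rmsf_i = sqrt(mean_frames |r_i - <r_i>|^2)`` with the mean position
    taken after superposing every frame onto the reference frame over the
    selection.  Requires at least two frames.
    """
    if traj.n_frames < 2:
        raise AnalysisError("RMSF needs at least 2 frames")
    idx = _select(traj, selection)
    sub = traj.coords[:, idx, :]
    if superpose_frames:
        ref = sub[reference_frame]
        aligned = np.empty_like(sub)
        for f in range(sub.shape[0]):
            aligned[f] = superpose(sub[f], ref)
    else:
        aligned = sub
    mean_pos = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    return traj.residue_numbers[idx].copy(), rmsf


@dataclass
class RMSFProfile:
    """Replica-resolved RMSF with mean and 95% t-CI per residue."""

    residue_ids: np.ndarray
    per_replica: np.ndarray  # (n_replicas, n_residues), A
    mean_rmsf: np.ndarray
    ci_halfwidth: np.ndarray

    @property
    def n_replicas(self) -> int:
        return self.per_replica.shape[0]


def aggregate_replicas(
    profiles: Sequence[tuple[np.ndarray, np.ndarray]],
    confidence: float = 0.95,
) -> RMSFProfile:
    """Average per-replica RMSF profiles with a t confidence interval.

    ``profiles`` is a sequence of ``(residue_ids, rmsf)`` pairs as returned
    by :func:`compute_rmsf`; all replicas must share the residue roster.
    The CI half-width is ``t_{1-(1-c)/2, n-1} * sd / sqrt(n)``.
    """
    if len(profiles) < 2:
        raise AnalysisError("need at least 2 replicas to aggregate")
    ids0 = np.asarray(profiles[0][0])
    for ids, _ in profiles[1:]:
        if not np.array_equal(np.asarray(ids), ids0):
            raise AnalysisError("replica residue rosters do not match")
    per_replica = np.vstack([np.asarray(r, dtype=float) for _, r in profiles])
    n = per_replica.shape[0]
    mean = per_replica.mean(axis=0)
    sd = per_replica.std(axis=0, ddof=1)
    tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return RMSFProfile(
        residue_ids=ids0.copy(),
        per_replica=per_replica,
        mean_rmsf=mean,
        ci_halfwidth=tq * sd / np.sqrt(n),
    )


@dataclass
class FlexibilityComparison:
    """Residue-wise mutant-minus-WT flexibility difference with Welch p-values."""

    residue_ids: np.ndarray
    mean_diff: np.ndarray  # mut - WT, A
    p_values: np.ndarray
    significant: np.ndarray  # boolean mask at alpha
    alpha: float


def compare_flexibility(
    wt: RMSFProfile,
    mut: RMSFProfile,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> FlexibilityComparison:
    """Welch two-sample t-test per residue on per-replica RMSF values.

    No multiple-testing correction is applied by default; pass
    ``bh_correct=True`` for Benjamini-Hochberg adjusted p-values.
    Residues where both variants are numerically identical across replicas
    get p = 1 (no evidence of a difference).
    """
    if not np.array_equal(wt.residue_ids, mut.residue_ids):
        raise AnalysisError("WT and mutant residue rosters do not match")
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    diff = mut.mean_rmsf - wt.mean_rmsf
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(mut.per_replica, wt.per_replica, axis=0, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = np.isnan(p) & (diff == 0)
    p[degenerate] = 1.0
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        valid = ~np.isnan(p)
        adjusted = p.copy()
        if valid.any():
            adjusted[valid] = multipletests(p[valid], method="fdr_bh")[1]
        p = adjusted
    significant = np.where(np.isnan(p), False, p < alpha)
    return FlexibilityComparison(
        residue_ids=wt.residue_ids.copy(),
        mean_diff=diff,
        p_values=p,
        significant=significant,
        alpha=alpha,
    )


def compute_rmsd_trace(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    selection: str | Sequence[str] = "CA",
    superpose_frames: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (A) to a reference frame or coordinate set.

    Each frame is optionally least-squares superposed onto the reference
    over the selection before the deviation is measured.
    """
    idx = _select(traj, selection)
    sub = traj.coords[:, idx, :]
    ref = sub[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, dtype=float)
    if ref.shape != sub.shape[1:]:
        raise AnalysisError(f"reference shape {ref.shape} does not match selection {sub.shape[1:]}")
    out = np.empty(sub.shape[0])
    for f in range(sub.shape[0]):
        frame = superpose(sub[f], ref) if superpose_frames else sub[f]
        out[f] = np.sqrt(np.mean(np.sum((frame - ref) ** 2, axis=1)))
    return out
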