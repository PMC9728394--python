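"""Synthetic pose ensembles, trajectories and kinetic data with known truth.

These generators stand in for the docking engine, the MD engine and the
bench assay so that every downstream stage of the pipeline is testable at
desk scale:

* :func:`generate_pose_ensemble` builds docking-style ligand poses around a
  minimal glucosyl-enzyme receptor with exactly known (d1, d2, a1) per pose.
  The geometry is constructed invertibly — the anomeric carbon sits at the
  origin, the leaving-group oxygen on the +y axis, the hydroxyl oxygen is
  solved from the sampled (d1, a1) at a random azimuth, and the catalytic
  glutamate side chain (CD/OE1/OE2) is placed at the sampled d2 from the
  hydroxyl and written into each pose MODEL, the way flexible-side-chain
  docking engines emit flexible residues.
* :func:`generate_trajectory` produces replica trajectories whose residues
  fluctuate as iid Gaussians about a fixed reference, so RMSF has the
  closed form sigma*sqrt(3) per residue.
* :func:`generate_kinetic_data` draws Michaelis-Menten initial velocities
  with multiplicative noise, v = Vmax [S]/(Km+[S]) * (1 + eps).

All generators are deterministic given the spec (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CatalyticSiteMap, ReactiveCriteria
from .structure_io import (
    AtomRecord,
    Pose,
    Trajectory,
    write_pdb,
    write_pdbqt_poses,
    write_xyz_trajectory,
)

__all__ = [
    "PoseEnsembleSpec",
    "TrajectorySpec",
    "KineticSimSpec",
    "SyntheticEnsemble",
    "SyntheticTrajectorySet",
    "generate_pose_ensemble",
    "generate_trajectory",
    "generate_kinetic_data",
    "SUCROSE_DESIGN_MM",
    "MU_DESIGN_MM",
]

#: Donor (sucrose) concentration ladder, mM — spans the 0.4-200 mM assay range.
SUCROSE_DESIGN_MM = (0.4, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)
#: Acceptor (4-methylumbelliferone) ladder, mM — spans 0.1-1.0 mM.
MU_DESIGN_MM = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)

_MAX_REJECTION_DRAWS = 100_000


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseEnsembleSpec:
    """Recipe for a synthetic docking-pose ensemble.

    The three feature distributions are (mean, sd) pairs: distances in A,
    the angle in degrees.  When ``fraction_reactive_target`` is given, each
    pose is first assigned reactive/non-reactive by a Bernoulli draw and its
    features are then sampled from the spec distributions truncated inside
    (or outside) the reactive box, so the downstream reactive fraction is
    Binomial(n, target) by construction.
    """

    n_conformations: int
    ligand_name: str = "LIG"
    n_hydroxyls: int = 1
    d1_dist: tuple[float, float] = (5.0, 2.0)
    d2_dist: tuple[float, float] = (4.0, 1.5)
    a1_dist: tuple[float, float] = (110.0, 25.0)
    fraction_reactive_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformations < 1:
            raise ValueError(f"n_conformations must be positive, got {self.n_conformations}")
        if self.n_hydroxyls < 1:
            raise ValueError(f"n_hydroxyls must be positive, got {self.n_hydroxyls}")
        if not self.ligand_name:
            raise ValueError("ligand_name must be a non-empty identifier")
        for name in ("d1_dist", "d2_dist", "a1_dist"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0, got {sd}")
            if name != "a1_dist" and mean <= 0:
                raise ValueError(f"{name}: mean must be positive, got {mean}")
        if self.fraction_reactive_target is not None and not (
            0.0 <= self.fraction_reactive_target <= 1.0
        ):
            raise ValueError(
                f"fraction_reactive_target must be in [0, 1], got {self.fraction_reactive_target}"
            )


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for replica trajectories of per-residue Gaussian fluctuation."""

    n_residues: int
    n_frames: int
    per_residue_sigma: float | tuple[float, ...] = 0.5
    n_replicas: int = 1
    frame_interval_ps: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError(f"n_residues must be positive, got {self.n_residues}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be positive, got {self.n_frames}")
        if self.n_replicas < 1:
            raise ValueError(f"n_replicas must be positive, got {self.n_replicas}")
        if self.frame_interval_ps <= 0:
            raise ValueError(f"frame_interval_ps must be positive, got {self.frame_interval_ps}")
        sigmas = self.sigmas()
        if np.any(sigmas < 0):
            raise ValueError("per_residue_sigma must be >= 0 elementwise")

    def sigmas(self) -> np.ndarray:
        if np.isscalar(self.per_residue_sigma):
            return np.full(self.n_residues, float(self.per_residue_sigma))
        sig = np.asarray(self.per_residue_sigma, dtype=float)
        if sig.shape != (self.n_residues,):
            raise ValueError(
                f"per_residue_sigma length {sig.size} does not match n_residues {self.n_residues}"
            )
        return sig


@dataclass(frozen=True)
class KineticSimSpec:
    """Recipe for Michaelis-Menten initial-velocity data.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    noise: v = Vmax [S]/(Km+[S]) * (1 + eps), eps ~ N(0, noise_cv).
    """

    Km_true: float
    Vmax_true: float
    substrate_concs: tuple[float, ...]
    noise_cv: float = 0.0
    replicates: int = 1
    substrate: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Km_true <= 0:
            raise ValueError(f"Km_true must be positive, got {self.Km_true}")
        if self.Vmax_true <= 0:
            raise ValueError(f"Vmax_true must be positive, got {self.Vmax_true}")
        if len(self.substrate_concs) == 0:
            raise ValueError("substrate_concs must be non-empty")
        if any(s <= 0 for s in self.substrate_concs):
            raise ValueError("substrate_concs must all be positive")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be positive, got {self.replicates}")


# ---------------------------------------------------------------------------
# pose ensembles
# ---------------------------------------------------------------------------

def _receptor_atoms() -> list[AtomRecord]:
    """Minimal rigid receptor: the glucosyl-aspartate conjugate (residue 284
    analog; anomeric carbon C1 at the origin, ester oxygen OD1 on +y) plus
    the catalytic glutamate backbone (residue 326 analog; its side-chain
    carboxylate is flexible and lives in each pose) and a few inert scaffold
    residues."""
    spec = [
        # serial, name, element, resname, resnum, xyz, hetatm
        (1, "C1", "C", "ASG", 284, (0.000, 0.000, 0.000), True),
        (2, "OD1", "O", "ASG", 284, (0.000, 1.430, 0.000), True),
        (3, "CG", "C", "ASG", 284, (0.000, 2.350, 1.050), True),
        (4, "C2", "C", "ASG", 284, (-0.940, -1.060, 0.350), True),
        (5, "O5", "O", "ASG", 284, (1.210, -0.770, 0.210), True),
        (6, "CA", "C", "GLU", 326, (7.500, 2.000, 1.000), False),
        (7, "CB", "C", "GLU", 326, (6.900, 1.200, 2.000), False),
        (8, "CA", "C", "ALA", 280, (-12.000, 6.000, 3.000), False),
        (9, "CA", "C", "ALA", 281, (-10.500, 8.500, 5.500), False),
        (10, "CA", "C", "ALA", 282, (-8.000, 10.000, 8.000), False),
        (11, "CA", "C", "ALA", 283, (13.000, -7.000, 6.000), False),
    ]
    return [
        AtomRecord(
            serial=s, name=n, element=e, residue_name=rn, residue_number=ri,
            chain="A", xyz=np.array(x), is_hetatm=het,
        )
        for s, n, e, rn, ri, x, het in spec
    ]


def default_site_map() -> CatalyticSiteMap:
    """Site map matching the synthetic receptor written by the generator."""
    return CatalyticSiteMap(
        anomeric_carbon=(284, "C1"),
        leaving_oxygen=(284, "OD1"),
        carboxylate_oxygens=((326, "OE1"), (326, "OE2")),
    )


def _sample_triple(
    rng: np.random.Generator,
    spec: PoseEnsembleSpec,
    criteria: ReactiveCriteria,
    want_reactive: bool | None,
) -> tuple[float, float, float]:
    """Rejection-sample (d1, d2, a1) from the spec distributions.

    Degenerate draws (nonpositive distances, angles outside (0, 180)) are
    resampled rather than clamped, preserving the distribution shape; when a
    reactivity label is requested the triple is additionally conditioned on
    falling inside/outside the reactive box.
    """
    for _ in range(_MAX_REJECTION_DRAWS):
        d1 = rng.normal(*spec.d1_dist)
        d2 = rng.normal(*spec.d2_dist)
        a1 = rng.normal(*spec.a1_dist)
        if d1 <= 0.5 or d2 <= 0.5 or not (1.0 <= a1 <= 179.0):
            continue
        if want_reactive is not None and criteria.passes(d1, d2, a1) != want_reactive:
            continue
        return d1, d2, a1
    raise RuntimeError(
        "could not sample a feasible (d1, d2, a1) triple; the spec distributions "
        "are incompatible with the requested reactive label"
    )


def _perpendicular(u: np.ndarray) -> np.ndarray:
    probe = np.array([0.0, 1.0, 0.0]) if abs(u[1]) < 0.9 else np.array([1.0, 0.0, 0.0])
    w = np.cross(u, probe)
    return w / np.linalg.norm(w)


@dataclass
class SyntheticEnsemble:
    """A generated pose ensemble with its receptor, site map and ground truth.

    ``ground_truth`` has one row per pose (model_index, d1, d2, a1,
    reactive), giving the exact realized geometry of the designated
    (first) hydroxyl.
    """

    spec: PoseEnsembleSpec
    poses: list[Pose]
    receptor: list[AtomRecord]
    site: CatalyticSiteMap
    ground_truth: pd.DataFrame

    def write(self, out_dir: str | Path, prefix: str | None = None) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.spec.ligand_name.lower()
        paths = {
            "receptor": out_dir / "receptor.pdb",
            "poses": out_dir / f"{prefix}_poses.pdbqt",
            "ground_truth": out_dir / f"{prefix}_ground_truth.csv",
            "site": out_dir / "site.yml",
        }
        write_pdb(self.receptor, paths["receptor"])
        write_pdbqt_poses(self.poses, paths["poses"])
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        self.site.to_yaml(paths["site"])
        return paths


def generate_pose_ensemble(
    spec: PoseEnsembleSpec,
    criteria: ReactiveCriteria | None = None,
) -> SyntheticEnsemble:
    """Generate a docking-style pose ensemble with exact geometric truth.

    Each pose contains the ligand (one designated hydroxyl realizing the
    sampled (d1, d2, a1), plus any additional hydroxyls placed far from the
    catalytic site) and the flexible glutamate carboxylate (CD/OE1/OE2)
    placed so that the minimum hydroxyl-carboxylate distance equals the
    sampled d2 exactly.
    """
    criteria = criteria or ReactiveCriteria()
    rng = np.random.default_rng(spec.seed)
    receptor = _receptor_atoms()
    site = default_site_map()
    ligand_res = spec.ligand_name[:3].upper() or "LIG"

    poses: list[Pose] = []
    truth_rows = []
    for i in range(spec.n_conformations):
        want = (
            bool(rng.random() < spec.fraction_reactive_target)
            if spec.fraction_reactive_target is not None
            else None
        )
        d1, d2, a1 = _sample_triple(rng, spec, criteria, want)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        a1_rad = math.radians(a1)
        rho = d1 * math.sin(a1_rad)
        hyd = np.array([rho * math.cos(phi), d1 * math.cos(a1_rad), rho * math.sin(phi)])
        u = hyd / np.linalg.norm(hyd)  # radial, away from the anomeric carbon
        w = _perpendicular(u)

        atoms: list[AtomRecord] = []
        serial = 1

        def add(name: str, element: str, xyz: np.ndarray, resname: str, resnum: int) -> None:
            nonlocal serial
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, element=element, residue_name=resname,
                    residue_number=resnum, chain="L" if resname == ligand_res else "A",
                    xyz=xyz, charge=0.0, pdbqt_type=element.upper(),
                    is_hetatm=(resname == ligand_res),
                )
            )
            serial += 1

        # designated hydroxyl: O-H plus the carbon it hangs off and one more
        add("O1", "O", hyd, ligand_res, 1)
        add("H1", "H", hyd + 0.97 * w, ligand_res, 1)
        add("C2", "C", hyd - 1.43 * u, ligand_res, 1)
        add("C3", "C", hyd - 1.43 * u - 1.40 * w, ligand_res, 1)
        # remaining hydroxyls: parked far from the catalytic site (~>25 A)
        for k in range(1, spec.n_hydroxyls):
            base = np.array([5.0 * (k - 1) - 10.0, -26.0 - 3.0 * (k - 1), 4.0 * (k - 1)])
            base = base + rng.uniform(-0.5, 0.5, size=3)
            add(f"O{k + 1}", "O", base, ligand_res, 1)
            add(f"H{k + 1}", "H", base + np.array([0.0, 0.0, 0.97]), ligand_res, 1)
            add(f"C{k + 3}", "C", base + np.array([1.43, 0.0, 0.0]), ligand_res, 1)
        # flexible glutamate side chain: OE1 at exactly d2 from the hydroxyl,
        # OE2 collinear and farther, CD bridging the two
        oe1 = hyd + d2 * u
        oe2 = hyd + (d2 + 2.2) * u
        cd = hyd + (d2 + 1.1) * u + 0.59 * w
        add("CD", "C", cd, "GLU", 326)
        add("OE1", "O", oe1, "GLU", 326)
        add("OE2", "O", oe2, "GLU", 326)

        score = float(rng.uniform(-9.0, -3.0))
        poses.append(Pose(model_index=i + 1, atoms=atoms, score=round(score, 3)))
        truth_rows.append(
            {
                "model_index": i + 1,
                "d1": d1,
                "d2": d2,
                "a1": a1,
                "reactive": criteria.passes(d1, d2, a1),
            }
        )

    return SyntheticEnsemble(
        spec=spec,
        poses=poses,
        receptor=receptor,
        site=site,
        ground_truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrajectorySet:
    """Generated replica trajectories plus the reference and sigmas used."""

    spec: TrajectorySpec
    trajectories: list[Trajectory]
    reference: np.ndarray  # (n_residues, 3)
    sigmas: np.ndarray  # (n_residues,)

    def write(self, out_dir: str | Path, prefix: str = "replica") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for traj in self.trajectories:
            path = out_dir / f"{prefix}_{traj.replica_id}.xyz"
            write_xyz_trajectory(traj, path)
            paths.append(path)
        return paths


def _reference_coords(n_residues: int) -> np.ndarray:
    i = np.arange(n_residues)
    return np.column_stack([3.8 * i, 1.5 * np.sin(i / 3.0), 1.5 * np.cos(i / 3.0)])


def generate_trajectory(spec: TrajectorySpec) -> SyntheticTrajectorySet:
    """Replica trajectories of iid Gaussian fluctuation about a reference.

    Residue i in every frame is ``reference_i + N(0, sigma_i^2 I_3)``; with
    isotropic sigma the exact RMSF is sigma*sqrt(3).  One CA atom per
    residue; frames are ``frame_interval_ps`` apart starting at t=0.
    """
    rng = np.random.default_rng(spec.seed)
    sigmas = spec.sigmas()
    reference = _reference_coords(spec.n_residues)
    times = np.arange(spec.n_frames) * spec.frame_interval_ps
    trajectories = []
    for r in range(spec.n_replicas):
        noise = rng.normal(size=(spec.n_frames, spec.n_residues, 3)) * sigmas[None, :, None]
        trajectories.append(
            Trajectory(
                replica_id=f"{r + 1}",
                atom_names=["CA"] * spec.n_residues,
                residue_numbers=np.arange(1, spec.n_residues + 1),
                residue_names=["ALA"] * spec.n_residues,
                frame_times=times.copy(),
                coords=reference[None, :, :] + noise,
            )
        )
    return SyntheticTrajectorySet(
        spec=spec, trajectories=trajectories, reference=reference, sigmas=sigmas
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def generate_kinetic_data(spec: KineticSimSpec):
    """Michaelis-Menten initial velocities with multiplicative noise.

    Returns a :class:`~asase.kinetics.KineticDataset` pooled over
    replicates.  With ``noise_cv=0`` the velocities lie exactly on the
    Michaelis-Menten curve.  The rare draw that would push a velocity
    nonpositive is resampled.
    """
    from .kinetics import KineticDataset, michaelis_menten

    rng = np.random.default_rng(spec.seed)
    concs = np.asarray(spec.substrate_concs, dtype=float)
    all_s, all_v, all_rep = [], [], []
    for rep in range(1, spec.replicates + 1):
        v_true = michaelis_menten(concs, spec.Vmax_true, spec.Km_true)
        if spec.noise_cv == 0:
            v = v_true.copy()
        else:
            v = v_true * (1.0 + rng.normal(0.0, spec.noise_cv, size=concs.size))
            for j in np.nonzero(v <= 0)[0]:
                while v[j] <= 0:
                    v[j] = v_true[j] * (1.0 + rng.normal(0.0, spec.noise_cv))
        all_s.append(concs)
        all_v.append(v)
        all_rep.append(np.full(concs.size, rep, dtype=int))
    return KineticDataset(
        substrate=spec.substrate,
        substrate_conc_mM=np.concatenate(all_s),
        velocity=np.concatenate(all_v),
        replicate=np.concatenate(all_rep),
    )
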