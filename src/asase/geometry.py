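"""Reaction-geometry features for glucosyl transfer and pose classification.

For a glucosyl-enzyme conjugate (the glucose moiety covalently bound to the
catalytic aspartate) and a docked acceptor pose, three features decide
whether a pose is a *reactive conformation* — one in which transfer of the
glucosyl unit onto an acceptor hydroxyl is geometrically possible:

* ``d1`` — distance from the acceptor hydroxyl oxygen to the glucosyl
  anomeric carbon (the electrophile),
* ``d2`` — minimum distance from the hydroxyl oxygen to a carboxylate
  oxygen of the catalytic glutamate (the general base that deprotonates
  the attacking hydroxyl),
* ``a1`` — attack angle at the anomeric carbon subtended by the hydroxyl
  oxygen and the leaving-group (aspartate ester) oxygen, an in-line-attack
  proxy.

The default thresholds are d1 < 4 A, d2 < 4 A and 80 deg < a1 < 140 deg,
with strict inequalities.  A pose with several hydroxyls is reactive when
any one of them satisfies all three criteria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .structure_io import STANDARD_AMINO_ACIDS, AtomRecord, Pose

logger = logging.getLogger(__name__)

__all__ = [
    "Selector",
    "ReactiveCriteria",
    "CatalyticSiteMap",
    "ReactiveGeometry",
    "SiteMapError",
    "find_hydroxyl_oxygens",
    "compute_geometry",
    "classify_pose",
    "classify_ensemble",
]

#: (residue_number, atom_name) — resolves an atom in a structure.
Selector = tuple[int, str]

# covalent radii (A) for bond inference; generous default for exotic elements
_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 0.40  # A added to the radius sum
_CARBONYL_CO_MAX = 1.28  # A; a C-O bond shorter than this is treated as C=O


class SiteMapError(ValueError):
    """A catalytic-site selector resolved to zero or several atoms."""


@dataclass(frozen=True)
class ReactiveCriteria:
    """Thresholds defining a reactive conformation.

    With ``strict=True`` (the default) the inequalities are strict, so a
    pose sitting exactly on a boundary is non-reactive.
    """

    d1_max: float = 4.0
    d2_max: float = 4.0
    a1_min: float = 80.0
    a1_max: float = 140.0
    strict: bool = True

    def __post_init__(self) -> None:
        if self.d1_max <= 0:
            raise ValueError(f"d1_max must be positive, got {self.d1_max}")
        if self.d2_max <= 0:
            raise ValueError(f"d2_max must be positive, got {self.d2_max}")
        if not (0 <= self.a1_min < self.a1_max <= 180):
            raise ValueError(
                f"need 0 <= a1_min < a1_max <= 180, got ({self.a1_min}, {self.a1_max})"
            )

    def passes(self, d1: float, d2: float, a1: float) -> bool:
        if self.strict:
            return d1 < self.d1_max and d2 < self.d2_max and self.a1_min < a1 < self.a1_max
        return d1 <= self.d1_max and d2 <= self.d2_max and self.a1_min <= a1 <= self.a1_max


@dataclass(frozen=True)
class CatalyticSiteMap:
    """Atom selectors for the catalytic machinery.

    ``anomeric_carbon`` is the glucosyl carbon bonded to the nucleophile
    aspartate, ``leaving_oxygen`` the aspartate ester oxygen, and
    ``carboxylate_oxygens`` one or two oxygens of the catalytic glutamate.
    Selectors resolve against the pose first (covering flexible-side-chain
    docking output, where flexible residue atoms are written into each
    MODEL) and the rigid receptor second.
    """

    anomeric_carbon: Selector
    leaving_oxygen: Selector
    carboxylate_oxygens: tuple[Selector, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.carboxylate_oxygens) <= 2:
            raise ValueError("carboxylate_oxygens needs one or two selectors")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CatalyticSiteMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            anomeric_carbon=(int(raw["anomeric_carbon"]["residue"]), str(raw["anomeric_carbon"]["atom"])),
            leaving_oxygen=(int(raw["leaving_oxygen"]["residue"]), str(raw["leaving_oxygen"]["atom"])),
            carboxylate_oxygens=tuple(
                (int(item["residue"]), str(item["atom"])) for item in raw["carboxylate_oxygens"]
            ),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "anomeric_carbon": {"residue": self.anomeric_carbon[0], "atom": self.anomeric_carbon[1]},
            "leaving_oxygen": {"residue": self.leaving_oxygen[0], "atom": self.leaving_oxygen[1]},
            "carboxylate_oxygens": [
                {"residue": r, "atom": a} for r, a in self.carboxylate_oxygens
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class ReactiveGeometry:
    """The (d1, d2, a1) feature triple for one pose and its verdict.

    ``hydroxyl_serial`` is the serial of the representative hydroxyl oxygen
    (None when the ligand carries no hydroxyl, in which case the features
    are NaN and the pose is non-reactive).
    """

    pose_id: int
    hydroxyl_serial: int | None
    hydroxyl_name: str | None
    d1: float
    d2: float
    a1: float
    reactive: bool


def _resolve(
    selector: Selector,
    receptor: Sequence[AtomRecord],
    pose: Pose | None = None,
) -> AtomRecord:
    resnum, name = selector
    if pose is not None:
        in_pose = [a for a in pose.atoms if a.residue_number == resnum and a.name == name]
        if len(in_pose) == 1:
            return in_pose[0]
        if len(in_pose) > 1:
            raise SiteMapError(f"selector {selector} matches {len(in_pose)} pose atoms")
    matches = [a for a in receptor if a.residue_number == resnum and a.name == name]
    if len(matches) != 1:
        raise SiteMapError(f"selector {selector} matches {len(matches)} receptor atoms")
    return matches[0]


def find_hydroxyl_oxygens(pose: Pose, exclude_protein: bool = True) -> list[AtomRecord]:
    """Locate hydroxyl oxygens in a docked ligand.

    An oxygen is a hydroxyl when it has a bonded hydrogen (O-H < covalent
    cutoff); in hydrogen-free structures, when its single heavy neighbour is
    a carbon at single-bond distance (a C-O shorter than 1.28 A is treated
    as a carbonyl and excluded).  Protein residues — e.g. flexible receptor
    side chains written into a docking MODEL — are skipped by default.
    """
    atoms = [
        a for a in pose.atoms
        if not (exclude_protein and a.residue_name.upper() in STANDARD_AMINO_ACIDS)
    ]
    oxygens = [a for a in atoms if a.element.upper() == "O"]
    if not oxygens:
        logger.warning("pose %d: ligand has no oxygen atoms", pose.model_index)
        return []
    coords = np.array([a.xyz for a in atoms])
    hydroxyls: list[AtomRecord] = []
    for oxy in oxygens:
        r_o = _COVALENT_RADIUS["O"]
        dists = np.linalg.norm(coords - oxy.xyz, axis=1)
        has_h = False
        heavy_neighbors: list[tuple[AtomRecord, float]] = []
        for other, dist in zip(atoms, dists):
            if other is oxy or dist < 1e-9:
                continue
            r_other = _COVALENT_RADIUS.get(other.element.capitalize(), 0.8)
            if dist < r_o + r_other + _BOND_TOLERANCE:
                if other.element.upper() == "H":
                    has_h = True
                else:
                    heavy_neighbors.append((other, dist))
        if has_h:
            hydroxyls.append(oxy)
        elif (
            len(heavy_neighbors) == 1
            and heavy_neighbors[0][0].element.upper() == "C"
            and heavy_neighbors[0][1] > _CARBONYL_CO_MAX
        ):
            hydroxyls.append(oxy)
    return hydroxyls


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def compute_geometry(
    pose: Pose,
    receptor: Sequence[AtomRecord],
    site: CatalyticSiteMap,
    hydroxyl: AtomRecord | Selector,
    criteria: ReactiveCriteria | None = None,
) -> ReactiveGeometry:
    """Compute (d1, d2, a1) for one candidate hydroxyl of one pose."""
    criteria = criteria or ReactiveCriteria()
    if not isinstance(hydroxyl, AtomRecord):
        hydroxyl = _resolve(hydroxyl, list(pose.atoms))
    anomeric = _resolve(site.anomeric_carbon, receptor, pose)
    leaving = _resolve(site.leaving_oxygen, receptor, pose)
    carboxylates = [_resolve(sel, receptor, pose) for sel in site.carboxylate_oxygens]
    d1 = float(np.linalg.norm(hydroxyl.xyz - anomeric.xyz))
    d2 = float(min(np.linalg.norm(hydroxyl.xyz - c.xyz) for c in carboxylates))
    a1 = _angle_deg(hydroxyl.xyz, anomeric.xyz, leaving.xyz)
    return ReactiveGeometry(
        pose_id=pose.model_index,
        hydroxyl_serial=hydroxyl.serial,
        hydroxyl_name=hydroxyl.name,
        d1=d1,
        d2=d2,
        a1=a1,
        reactive=criteria.passes(d1, d2, a1),
    )


def classify_pose(
    pose: Pose,
    receptor: Sequence[AtomRecord],
    site: CatalyticSiteMap,
    criteria: ReactiveCriteria | None = None,
) -> ReactiveGeometry:
    """Classify a pose over all its hydroxyls (reactive if ANY qualifies).

    The reported features belong to the representative hydroxyl: the one
    with minimal d1 among criteria-satisfying hydroxyls if any, otherwise
    minimal d1 overall; ties break by smaller d2, then by atom serial.
    """
    criteria = criteria or ReactiveCriteria()
    hydroxyls = find_hydroxyl_oxygens(pose)
    if not hydroxyls:
        return ReactiveGeometry(
            pose_id=pose.model_index, hydroxyl_serial=None, hydroxyl_name=None,
            d1=math.nan, d2=math.nan, a1=math.nan, reactive=False,
        )
    geoms = [compute_geometry(pose, receptor, site, oh, criteria) for oh in hydroxyls]
    satisfying = [g for g in geoms if g.reactive]
    pool = satisfying if satisfying else geoms
    best = min(pool, key=lambda g: (g.d1, g.d2, g.hydroxyl_serial))
    best.reactive = bool(satisfying)
    return best


def classify_ensemble(
    poses: Iterable[Pose],
    receptor: Sequence[AtomRecord],
    site: CatalyticSiteMap,
    criteria: ReactiveCriteria | None = None,
):
    """Classify every pose; returns a pandas DataFrame
    (pose_id, hydroxyl, d1, d2, a1, reactive)."""
    import pandas as pd

    rows = []
    for pose in poses:
        g = classify_pose(pose, receptor, site, criteria)
        rows.append(
            {
                "pose_id": g.pose_id,
                "hydroxyl": g.hydroxyl_name or "",
                "d1": g.d1,
                "d2": g.d2,
                "a1": g.a1,
                "reactive": g.reactive,
            }
        )
    return pd.DataFrame(rows, columns=["pose_id", "hydroxyl", "d1", "d2", "a1", "reactive"])
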