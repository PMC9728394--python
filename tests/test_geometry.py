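"""Reaction-geometry features: examples, brute-force oracle, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from asase.geometry import (
    CatalyticSiteMap,
    ReactiveCriteria,
    SiteMapError,
    classify_pose,
    compute_geometry,
    find_hydroxyl_oxygens,
)
from asase.structure_io import STANDARD_AMINO_ACIDS, AtomRecord, Pose


def atom(serial, name, element, xyz, resname="LIG", resnum=1):
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_number=resnum, chain="A", xyz=np.asarray(xyz, dtype=float),
        is_hetatm=resname not in STANDARD_AMINO_ACIDS,
    )


def right_angle_system():
    """Hydroxyl at (3,0,0), anomeric C at origin, leaving O at (0,2,0),
    carboxylate O at (3,3,0): d1=3, a1=90, d2=3."""
    receptor = [
        atom(1, "C1", "C", (0, 0, 0), "ASG", 284),
        atom(2, "OD1", "O", (0, 2, 0), "ASG", 284),
        atom(3, "OE1", "O", (3, 3, 0), "GLU", 326),
    ]
    pose = Pose(
        model_index=1,
        atoms=[
            atom(1, "O1", "O", (3, 0, 0)),
            atom(2, "H1", "H", (3.0, -0.97, 0)),
            atom(3, "C2", "C", (4.4, 0, 0)),
        ],
    )
    site = CatalyticSiteMap(
        anomeric_carbon=(284, "C1"),
        leaving_oxygen=(284, "OD1"),
        carboxylate_oxygens=((326, "OE1"),),
    )
    return pose, receptor, site


def test_right_angle_construction():
    pose, receptor, site = right_angle_system()
    geom = compute_geometry(pose, receptor, site, pose.atoms[0])
    assert geom.d1 == pytest.approx(3.0)
    assert geom.a1 == pytest.approx(90.0)
    assert geom.d2 == pytest.approx(3.0)
    assert geom.reactive


def test_boundary_is_strict_by_default():
    pose, receptor, site = right_angle_system()
    # move the hydroxyl to exactly d1 = 4.0
    pose.atoms[0].xyz = np.array([4.0, 0.0, 0.0])
    strict = compute_geometry(pose, receptor, site, pose.atoms[0])
    assert strict.d1 == pytest.approx(4.0)
    assert not strict.reactive
    lax = compute_geometry(
        pose, receptor, site, pose.atoms[0], ReactiveCriteria(strict=False)
    )
    assert lax.reactive


def test_d2_is_minimum_over_both_carboxylate_oxygens():
    pose, receptor, site = right_angle_system()
    receptor.append(atom(4, "OE2", "O", (3, 1.5, 0), "GLU", 326))
    site2 = CatalyticSiteMap(
        anomeric_carbon=(284, "C1"), leaving_oxygen=(284, "OD1"),
        carboxylate_oxygens=((326, "OE1"), (326, "OE2")),
    )
    geom = compute_geometry(pose, receptor, site2, pose.atoms[0])
    assert geom.d2 == pytest.approx(1.5)  # min(3.0, 1.5)


def test_unresolvable_selector_raises():
    pose, receptor, site = right_angle_system()
    bad = CatalyticSiteMap(
        anomeric_carbon=(999, "C1"), leaving_oxygen=(284, "OD1"),
        carboxylate_oxygens=((326, "OE1"),),
    )
    with pytest.raises(SiteMapError, match="0"):
        compute_geometry(pose, receptor, bad, pose.atoms[0])


def hydroquinone_pose():
    """Para-diol benzene ring with explicit hydroxyl hydrogens."""
    ring = []
    for i in range(6):
        ang = math.radians(60 * i)
        ring.append(atom(i + 1, f"C{i + 1}", "C", (1.4 * math.cos(ang), 1.4 * math.sin(ang), 0)))
    o1 = atom(7, "O1", "O", (2.76, 0.0, 0.0))        # on C1
    h1 = atom(8, "HO1", "H", (3.2, 0.85, 0.0))
    o4 = atom(9, "O4", "O", (-2.76, 0.0, 0.0))       # on C4
    h4 = atom(10, "HO4", "H", (-3.2, -0.85, 0.0))
    return Pose(model_index=1, atoms=ring + [o1, h1, o4, h4])


def test_hydroquinone_has_two_hydroxyls():
    assert len(find_hydroxyl_oxygens(hydroquinone_pose())) == 2


def test_hydroxyl_detection_without_hydrogens_and_carbonyl_exclusion():
    # phenol-like O (single C neighbour at 1.36 A) vs carbonyl O (C=O at 1.23 A)
    pose = Pose(
        model_index=1,
        atoms=[
            atom(1, "C1", "C", (0, 0, 0)),
            atom(2, "O1", "O", (1.36, 0, 0)),   # hydroxyl (H stripped)
            atom(3, "C2", "C", (-1.5, 0, 0)),
            atom(4, "O2", "O", (-1.5, 1.23, 0)),  # carbonyl
        ],
    )
    found = find_hydroxyl_oxygens(pose)
    assert [o.name for o in found] == ["O1"]


def test_ligand_without_oxygen_warns_and_returns_empty(caplog):
    pose = Pose(model_index=1, atoms=[atom(i + 1, f"C{i + 1}", "C", (1.4 * i, 0, 0)) for i in range(6)])
    with caplog.at_level("WARNING"):
        assert find_hydroxyl_oxygens(pose) == []
    assert any("no oxygen" in rec.message for rec in caplog.records)


def test_classify_pose_without_hydroxyls_is_nonreactive():
    pose, receptor, site = right_angle_system()
    pose = Pose(model_index=1, atoms=[atom(1, "C1", "C", (3, 0, 0))])
    geom = classify_pose(pose, receptor, site)
    assert not geom.reactive
    assert geom.hydroxyl_serial is None
    assert math.isnan(geom.d1)


def test_classify_pose_reports_the_reactive_hydroxyl():
    """With one reactive and one non-reactive hydroxyl, the pose is reactive
    and the reported features belong to the qualifying hydroxyl."""
    receptor = [
        atom(1, "C1", "C", (0, 0, 0), "ASG", 284),
        atom(2, "OD1", "O", (0, 2, 0), "ASG", 284),
        atom(3, "OE1", "O", (3, 3, 0), "GLU", 326),
    ]
    site = CatalyticSiteMap((284, "C1"), (284, "OD1"), ((326, "OE1"),))
    pose = Pose(
        model_index=1,
        atoms=[
            atom(1, "O1", "O", (3, 0, 0)),      # reactive (d1=3, a1=90, d2=3)
            atom(2, "H1", "H", (3, -0.97, 0)),
            atom(3, "O2", "O", (0.5, -2, 0)),   # closer (smaller d1) but a1 ~ 166 deg
            atom(4, "H2", "H", (0.5, -2.97, 0)),
        ],
    )
    geom = classify_pose(pose, receptor, site)
    assert geom.reactive
    assert geom.hydroxyl_name == "O1"
    assert geom.d1 == pytest.approx(3.0)


# ---------------------------------------------------------------------------
# brute-force oracle on generated poses
# ---------------------------------------------------------------------------

def brute_force_verdict(pose, receptor, site, criteria):
    """Independent re-check: scan ALL pose oxygens (ligand residues only),
    decide hydroxyl status from raw distances, and evaluate the criteria
    over every hydroxyl/carboxylate pairing with plain numpy."""
    ligand_atoms = [a for a in pose.atoms if a.residue_name not in STANDARD_AMINO_ACIDS]
    union = {(a.residue_number, a.name): a.xyz for a in pose.atoms}
    for a in receptor:
        union.setdefault((a.residue_number, a.name), a.xyz)
    c1 = union[site.anomeric_carbon]
    olg = union[site.leaving_oxygen]
    carbox = [union[s] for s in site.carboxylate_oxygens]
    best = None
    any_reactive = False
    for oxy in ligand_atoms:
        if oxy.element != "O":
            continue
        is_hydroxyl = any(
            other.element == "H" and np.linalg.norm(other.xyz - oxy.xyz) < 1.37
            for other in ligand_atoms if other is not oxy
        )
        if not is_hydroxyl:
            heavies = [
                (b, np.linalg.norm(b.xyz - oxy.xyz))
                for b in ligand_atoms
                if b is not oxy and b.element != "H"
                and np.linalg.norm(b.xyz - oxy.xyz) < 0.66 + 0.76 + 0.40
            ]
            is_hydroxyl = len(heavies) == 1 and heavies[0][0].element == "C" and heavies[0][1] > 1.28
        if not is_hydroxyl:
            continue
        d1 = np.linalg.norm(oxy.xyz - c1)
        d2 = min(np.linalg.norm(oxy.xyz - c) for c in carbox)
        u, v = oxy.xyz - c1, olg - c1
        a1 = math.degrees(
            math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
        )
        ok = criteria.passes(d1, d2, a1)
        any_reactive = any_reactive or ok
        key = (not ok, d1, d2, oxy.serial)
        if best is None or key < best[0]:
            best = (key, d1, d2, a1)
    return any_reactive, best


def test_generated_poses_match_brute_force_oracle(small_ensemble):
    criteria = ReactiveCriteria()
    for pose in small_ensemble.poses:
        geom = classify_pose(pose, small_ensemble.receptor, small_ensemble.site, criteria)
        expect_reactive, best = brute_force_verdict(
            pose, small_ensemble.receptor, small_ensemble.site, criteria
        )
        assert geom.reactive == expect_reactive
        assert geom.d1 == pytest.approx(best[1], abs=1e-9)
        assert geom.d2 == pytest.approx(best[2], abs=1e-9)
        assert geom.a1 == pytest.approx(best[3], abs=1e-9)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    seed=st.integers(0, 2**16),
    angles=st.tuples(
        st.floats(-math.pi, math.pi), st.floats(-math.pi, math.pi), st.floats(-math.pi, math.pi)
    ),
    shift=st.tuples(st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)),
)
def test_rigid_motion_invariance(seed, angles, shift):
    """Rotating and translating receptor and pose together leaves the
    features unchanged to 1e-9."""
    from asase.synthetic import PoseEnsembleSpec, generate_pose_ensemble

    ens = generate_pose_ensemble(PoseEnsembleSpec(n_conformations=1, seed=seed))
    pose, receptor, site = ens.poses[0], ens.receptor, ens.site
    before = classify_pose(pose, receptor, site)

    rot = Rotation.from_euler("xyz", angles)
    t = np.asarray(shift)

    def moved(atoms):
        out = []
        for a in atoms:
            b = AtomRecord(
                serial=a.serial, name=a.name, element=a.element,
                residue_name=a.residue_name, residue_number=a.residue_number,
                chain=a.chain, xyz=rot.apply(a.xyz) + t, is_hetatm=a.is_hetatm,
            )
            out.append(b)
        return out

    pose2 = Pose(model_index=pose.model_index, atoms=moved(pose.atoms), score=pose.score)
    after = classify_pose(pose2, moved(receptor), site)
    assert after.d1 == pytest.approx(before.d1, abs=1e-9)
    assert after.d2 == pytest.approx(before.d2, abs=1e-9)
    assert after.a1 == pytest.approx(before.a1, abs=1e-9)
    assert after.reactive == before.reactive


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    d1=st.floats(0.6, 12.0), d2=st.floats(0.6, 12.0), a1=st.floats(1.0, 179.0),
    extra_d1=st.floats(0.0, 6.0), extra_d2=st.floats(0.0, 6.0), extra_a=st.floats(0.0, 40.0),
)
def test_classification_is_monotone_in_thresholds(d1, d2, a1, extra_d1, extra_d2, extra_a):
    """Relaxing any threshold never turns a reactive triple non-reactive."""
    tight = ReactiveCriteria()
    loose = ReactiveCriteria(
        d1_max=tight.d1_max + extra_d1,
        d2_max=tight.d2_max + extra_d2,
        a1_min=max(0.0, tight.a1_min - extra_a),
        a1_max=min(180.0, tight.a1_max + extra_a),
    )
    if tight.passes(d1, d2, a1):
        assert loose.passes(d1, d2, a1)


def test_criteria_validation():
    with pytest.raises(ValueError):
        ReactiveCriteria(d1_max=-1)
    with pytest.raises(ValueError):
        ReactiveCriteria(a1_min=150, a1_max=140)
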