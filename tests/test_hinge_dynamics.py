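"""Dihedrals, delta-psi, helix bend angles and secondary structure."""

import tempfile

import numpy as np
import pytest

from tecdyn._geometry import build_backbone, rotation_matrix
from tecdyn.hinge_dynamics import (
    HingeDefinition,
    assign_secondary_structure,
    backbone_dihedrals,
    delta_psi_series,
    helix_bend_angle,
    ss_timeline,
)
from tecdyn.io_model import Atom, Structure, Trajectory, write_structure
from tecdyn.synthetic_data import (
    ToyTECParams,
    build_beta_sheet,
    build_toy_tec,
    simulate_trajectory,
    toy_hinge,
)


def _chain_structure(bb, chain="A", resname="ALA"):
    atoms, coords = [], []
    serial = 0
    for i in range(len(bb["CA"])):
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(serial, name, resname, chain, i + 1, name[:1]))
            coords.append(bb[name][i])
    return Structure(atoms, np.array(coords))


def test_ideal_helix_dihedrals():
    s = _chain_structure(build_backbone([-57.0] * 12, [-47.0] * 12))
    dih = backbone_dihedrals(s)
    interior = dih[1:-1]
    assert all(abs(d.psi - (-47.0)) < 3.0 for d in interior)
    assert all(abs(d.phi - (-57.0)) < 3.0 for d in interior)
    # Termini: undefined angles are NaN.
    assert np.isnan(dih[0].phi) and np.isnan(dih[-1].psi)


def test_extended_chain_dihedrals():
    s = _chain_structure(build_backbone([-139.0] * 10, [135.0] * 10))
    for d in backbone_dihedrals(s)[1:-1]:
        assert abs(d.psi) > 120.0


def test_dihedrals_match_independent_torsion_formula():
    """Brute-force four-point torsion (praxeolitic form) on random conformers."""

    def torsion(p0, p1, p2, p3):
        b0 = -(p1 - p0)
        b1 = p2 - p1
        b2 = p3 - p2
        b1 = b1 / np.linalg.norm(b1)
        v = b0 - np.dot(b0, b1) * b1
        w = b2 - np.dot(b2, b1) * b1
        x = np.dot(v, w)
        y = np.dot(np.cross(b1, v), w)
        return np.degrees(np.arctan2(y, x))

    rng = np.random.default_rng(12)
    for _ in range(50):
        phis = rng.uniform(-180, 180, 6)
        psis = rng.uniform(-180, 180, 6)
        bb = build_backbone(phis, psis)
        s = _chain_structure(bb)
        dih = backbone_dihedrals(s)
        for i in range(1, 5):
            want_phi = torsion(bb["C"][i - 1], bb["N"][i], bb["CA"][i], bb["C"][i])
            want_psi = torsion(bb["N"][i], bb["CA"][i], bb["C"][i], bb["N"][i + 1])
            assert dih[i].phi == pytest.approx(want_phi, abs=1e-6)
            assert dih[i].psi == pytest.approx(want_psi, abs=1e-6)


def test_delta_psi_static_and_wrap(static_traj):
    series = delta_psi_series(static_traj, "A:1080")
    np.testing.assert_allclose(series.values, 0.0, atol=1e-9)


def test_delta_psi_wraps_through_180():
    """psi_ref 170 deg -> psi_t -170 deg must read +20, not -340."""
    from tecdyn._geometry import wrap_angle

    assert wrap_angle(-170.0 - 170.0) == pytest.approx(20.0)
    assert wrap_angle(170.0 - (-170.0)) == pytest.approx(-20.0)
    # wrap-consistency: dpsi(a,b) = -dpsi(b,a) for random angle pairs
    rng = np.random.default_rng(1)
    for a, b in rng.uniform(-180, 180, size=(50, 2)):
        assert wrap_angle(a - b) == pytest.approx(-wrap_angle(b - a)) or (
            abs(wrap_angle(a - b)) == pytest.approx(180.0)
        )


def test_scripted_psi_opening_plateaus():
    p = ToyTECParams(n_frames=60, noise_sigma=0.1, psi_schedule=((20, 35.0),), seed=13)
    traj = simulate_trajectory(build_toy_tec(p), p)
    series = delta_psi_series(traj, "A:1079")
    assert np.mean(series.values[:20]) == pytest.approx(0.0, abs=3.0)
    plateau = series.values[25:]
    assert np.mean(plateau) == pytest.approx(35.0, abs=3.0)


def test_straight_helix_bend_small():
    p = ToyTECParams(n_frames=1, noise_sigma=0.0)
    s = build_toy_tec(p)
    assert helix_bend_angle(s, toy_hinge(p)) < 5.0


def test_planted_kink_recovered_and_rotation_invariant():
    p = ToyTECParams(n_frames=4, noise_sigma=0.0, bend_schedule=((0, 30.0),), seed=2)
    s = build_toy_tec(p)
    traj = simulate_trajectory(s, p)
    frame = traj.frame_structure(2)
    hinge = toy_hinge(p)
    bend = helix_bend_angle(frame, hinge)
    assert bend == pytest.approx(30.0, abs=4.0)
    # Global rigid rotation leaves the bend unchanged.
    R = rotation_matrix([1.0, 2.0, 0.5], 73.0)
    rotated = frame.with_coords((R @ frame.coords.T).T + np.array([5.0, -3.0, 9.0]))
    assert helix_bend_angle(rotated, hinge) == pytest.approx(bend, abs=1e-6)


def test_bend_requires_four_calpha_flank():
    with pytest.raises(ValueError, match="fewer than 4"):
        HingeDefinition("bad", "A", (10, 11), (7, 9), (12, 20))
    p = ToyTECParams(n_frames=1, noise_sigma=0.0)
    s = build_toy_tec(p)
    hinge = HingeDefinition("offrange", "A", (1079, 1079), (900, 910), (1082, 1104))
    with pytest.raises(ValueError, match="Calpha"):
        helix_bend_angle(s, hinge)


# --- secondary structure ----------------------------------------------------

def _mdtraj_labels(structure):
    import mdtraj as md

    path = tempfile.mktemp(suffix=".pdb")
    write_structure(structure, path)
    raw = md.compute_dssp(md.load(path), simplified=False)[0]
    fold = {"H": "H", "G": "G", "I": "H", "E": "E", "B": "E", "T": "T",
            "S": "C", " ": "C", "C": "C", "P": "C"}
    return [fold.get(c) for c in raw]


def test_ideal_helix_interior_is_H():
    s = _chain_structure(build_backbone([-57.0] * 20, [-47.0] * 20))
    labels = [lab for _, _, lab in assign_secondary_structure(s)]
    assert all(lab == "H" for lab in labels[2:18])


def test_extended_chain_has_no_helix_labels():
    s = _chain_structure(build_backbone([-139.0] * 12, [135.0] * 12))
    labels = [lab for _, _, lab in assign_secondary_structure(s)]
    assert "H" not in labels and "G" not in labels


def test_sheet_strands_match_reference_dssp():
    """Antiparallel two-strand sheet: strand residues labeled E, agreeing
    with an independent DSSP implementation on >=95% of non-terminal
    residues."""
    sheet = build_beta_sheet(8)
    mine = [lab for _, _, lab in assign_secondary_structure(sheet)]
    ref = _mdtraj_labels(sheet)
    # Non-terminal residues: drop the first and last of each 8-residue strand.
    keep = [i for i in range(16) if i % 8 not in (0, 7)]
    agreement = np.mean([mine[i] == ref[i] for i in keep])
    assert agreement >= 0.95
    assert all(mine[i] == "E" for i in [2, 3, 4, 5, 10, 11, 12, 13])


def test_helix_matches_reference_dssp_on_toy_tec():
    s = build_toy_tec(ToyTECParams(n_frames=1, noise_sigma=0.0))
    mine = [lab for ch, _, lab in assign_secondary_structure(s) if ch == "A"]
    ref = _mdtraj_labels(s)[: len(mine)]  # protein residues come first
    agreement = np.mean([m == r for m, r in zip(mine[1:-1], ref[1:-1])])
    assert agreement >= 0.95


def test_helix_assignment_stable_under_noise():
    """>=95% of interior residues stay H over noisy replicates (sigma 0.2 A)."""
    base = build_backbone([-57.0] * 20, [-47.0] * 20)
    rng = np.random.default_rng(7)
    kept = []
    for _ in range(100):
        noisy = {k: v + rng.normal(0, 0.2, v.shape) for k, v in base.items()}
        labels = [lab for _, _, lab in assign_secondary_structure(_chain_structure(noisy))]
        kept.append(np.mean([lab == "H" for lab in labels[3:17]]))
    assert np.mean(kept) >= 0.95


def test_ss_timeline_melt_and_dimensions():
    """A scripted helix->coil transition at the hinge flips labels at the
    scheduled frame; the timeline is residues x sampled frames."""
    p = ToyTECParams(n_frames=30, noise_sigma=0.0, psi_schedule=((15, 120.0),), seed=4)
    traj = simulate_trajectory(build_toy_tec(p), p)
    tl = ss_timeline(traj, "A", (1070, 1100), stride=1)
    assert tl.labels.shape == (len(tl.residues), 30)
    row = tl.labels[tl.residues.index(1079)]
    assert set(row[:13]) == {"H"}
    assert "H" not in set(row[17:])

    static = ss_timeline(traj, "A", (1070, 1074), stride=2)
    assert static.labels.shape == (5, 15)
    assert set(static.labels[2]) == {"H"}  # pre-hinge residues never melt
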