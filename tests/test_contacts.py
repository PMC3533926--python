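"""Hydrogen bonds, ion pairs, occupancy and switch-residue calls."""

import numpy as np
import pytest

from tecdyn.contacts import (
    ACCEPTOR_TABLE,
    DONOR_TABLE,
    NEGATIVE_GROUPS,
    POSITIVE_GROUPS,
    _PHOSPHATE_O,
    _NUCLEIC_RESNAMES,
    _PROTEIN_RESNAMES,
    ContactCriteria,
    contact_occupancy,
    hydrogen_bonds,
    ion_pairs,
    switch_residues,
)
from tecdyn.io_model import Atom, Structure, Trajectory
from tecdyn.synthetic_data import ToyTECParams, build_toy_tec, simulate_trajectory

from conftest import random_test_structure


def _water_dimer(oo_distance, with_h=True):
    atoms = [Atom(1, "O", "HOH", "W", 1, "O", het=True)]
    coords = [[0.0, 0.0, 0.0]]
    if with_h:
        atoms.append(Atom(2, "H1", "HOH", "W", 1, "H", het=True))
        coords.append([0.96, 0.0, 0.0])  # points straight at the acceptor
    atoms.append(Atom(3, "O", "HOH", "W", 2, "O", het=True))
    coords.append([oo_distance, 0.0, 0.0])
    return Structure(atoms, np.array(coords))


def test_water_dimer_single_hbond():
    records = hydrogen_bonds(_water_dimer(2.8))
    donors = [(r.residue_i, r.residue_j) for r in records if r.residue_i == "W:1"]
    assert ("W:1", "W:2") in donors
    linear = [r for r in records if r.residue_i == "W:1"]
    assert len(linear) == 1 and linear[0].angle == pytest.approx(180.0)


def test_water_dimer_too_far():
    assert hydrogen_bonds(_water_dimer(5.0)) == []


def test_hbond_angle_criterion_rejects_bent_donor():
    s = _water_dimer(2.8)
    # Point the H away from the acceptor.
    s.coords[1] = [-0.96, 0.0, 0.0]
    records = [r for r in hydrogen_bonds(s) if r.residue_i == "W:1"]
    assert records == []


def _ion_pair_structure(distance, resname_j="ASP", name_j="OD1"):
    atoms = [Atom(1, "NZ", "LYS", "A", 1, "N"),
             Atom(2, name_j, resname_j, "A", 5, name_j[:1])]
    coords = np.array([[0.0, 0, 0], [distance, 0, 0]])
    return Structure(atoms, coords)


def test_lys_asp_ion_pair():
    records = ion_pairs(_ion_pair_structure(3.0))
    assert len(records) == 1
    assert records[0].kind == "ionpair"
    assert records[0].distance == pytest.approx(3.0)


def test_like_charges_do_not_pair():
    assert ion_pairs(_ion_pair_structure(3.0, resname_j="LYS", name_j="NZ")) == []


def test_ion_pair_cutoff():
    assert ion_pairs(_ion_pair_structure(4.5)) == []
    assert len(ion_pairs(_ion_pair_structure(4.5), ContactCriteria(ionpair_cutoff=5.0))) == 1


def test_protonated_his_flag():
    atoms = [Atom(1, "NE2", "HIS", "A", 1, "N"), Atom(2, "OD1", "ASP", "A", 5, "O")]
    s = Structure(atoms, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
    assert ion_pairs(s) == []  # neutral by default
    crit = ContactCriteria(protonated_his=frozenset({"A:1"}))
    assert len(ion_pairs(s, crit)) == 1


# --- brute-force oracles ----------------------------------------------------

def brute_force_hbonds(frame, criteria=ContactCriteria()):
    """O(n^2) reference scan sharing only the typing tables with the
    implementation."""
    from tecdyn.io_model import WATER_RESNAMES

    out = set()
    n = frame.n_atoms
    for i in range(n):
        a = frame.atoms[i]
        is_donor = (
            (a.resname in WATER_RESNAMES and a.name.startswith("O"))
            or (a.resname, a.name) in DONOR_TABLE
            or (a.name == "N" and a.resname in _PROTEIN_RESNAMES)
        )
        if not is_donor:
            continue
        hs = []
        for j in range(n):
            b = frame.atoms[j]
            if (b.chain, b.resid) == (a.chain, a.resid) and (
                b.element == "H" or (not b.element and b.name.startswith("H"))
            ):
                if np.linalg.norm(frame.coords[j] - frame.coords[i]) <= 1.25:
                    hs.append(frame.coords[j])
        if not hs and a.name == "N" and a.resname in _PROTEIN_RESNAMES:
            prev = [j for j, b in enumerate(frame.atoms)
                    if b.chain == a.chain and b.resid == a.resid - 1]
            c = [j for j in prev if frame.atoms[j].name == "C"]
            o = [j for j in prev if frame.atoms[j].name == "O"]
            if c and o and np.linalg.norm(frame.coords[c[0]] - frame.coords[i]) <= 2.5:
                d = frame.coords[c[0]] - frame.coords[o[0]]
                hs.append(frame.coords[i] + d / np.linalg.norm(d))
        for j in range(n):
            b = frame.atoms[j]
            if i == j or (b.chain, b.resid) == (a.chain, a.resid):
                continue
            is_acc = (
                (b.resname in WATER_RESNAMES and b.name.startswith("O"))
                or (b.resname, b.name) in ACCEPTOR_TABLE
                or (b.name == "O" and b.resname in _PROTEIN_RESNAMES)
            )
            if not is_acc:
                continue
            if np.linalg.norm(frame.coords[j] - frame.coords[i]) > criteria.hbond_da_cutoff:
                continue
            if hs:
                best = -1.0
                for h in hs:
                    v1 = frame.coords[i] - h
                    v2 = frame.coords[j] - h
                    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    best = max(best, np.degrees(np.arccos(np.clip(cosv, -1, 1))))
                if best < criteria.hbond_angle_min:
                    continue
            out.add((frame.atoms[i].key(), frame.atoms[j].key()))
    return out


def brute_force_ion_pairs(frame, criteria=ContactCriteria()):
    sign = {}
    for i, a in enumerate(frame.atoms):
        s = 0
        if a.resname in POSITIVE_GROUPS and a.name in POSITIVE_GROUPS[a.resname]:
            s = 1
        elif a.resname in NEGATIVE_GROUPS and a.name in NEGATIVE_GROUPS[a.resname]:
            s = -1
        elif a.resname in _NUCLEIC_RESNAMES and a.name in _PHOSPHATE_O:
            s = -1
        if s:
            sign[i] = s
    pairs = set()
    for i in sign:
        for j in sign:
            ri = f"{frame.atoms[i].chain}:{frame.atoms[i].resid_key}"
            rj = f"{frame.atoms[j].chain}:{frame.atoms[j].resid_key}"
            if ri == rj or sign[i] * sign[j] >= 0 or sign[i] < 0:
                continue
            if np.linalg.norm(frame.coords[i] - frame.coords[j]) <= criteria.ionpair_cutoff:
                pairs.add(frozenset((ri, rj)))
    return pairs


def test_hbonds_match_bruteforce_on_random_frames():
    angles_used = 0
    for seed in range(25):
        frame = random_test_structure(seed)
        got = {(r.atom_i, r.atom_j) for r in hydrogen_bonds(frame)}
        want = brute_force_hbonds(frame)
        assert got == want, f"seed {seed}"
        angles_used += len(got)
    assert angles_used > 0  # the scan actually exercised contacts


def test_ion_pairs_match_bruteforce_on_random_frames():
    nonempty = 0
    for seed in range(25):
        frame = random_test_structure(seed)
        got = {frozenset((r.residue_i, r.residue_j)) for r in ion_pairs(frame)}
        want = brute_force_ion_pairs(frame)
        assert got == want, f"seed {seed}"
        nonempty += len(got)
    assert nonempty > 0


def test_hbond_ordering_deterministic():
    frame = random_test_structure(3)
    records = hydrogen_bonds(frame)
    keys = [(r.atom_i, r.atom_j) for r in records]
    assert keys == sorted(keys)


# --- occupancy and switches -------------------------------------------------

def _swap_traj(swap_frame, n_frames=40, seed=0, sigma=0.05):
    p = ToyTECParams(n_frames=n_frames, noise_sigma=sigma,
                     contact_swap=(1079, 1083, 1072, swap_frame), seed=seed)
    return simulate_trajectory(build_toy_tec(p), p)


def test_occupancy_always_present_is_one():
    traj = _swap_traj(swap_frame=40)  # never swaps: K-D1083 pair all frames
    occ = contact_occupancy(traj, "A:1079", "A:1083", kind="ionpair")
    assert occ == 1.0


def test_occupancy_square_wave():
    traj = _swap_traj(swap_frame=20)  # on for the first half
    occ = contact_occupancy(traj, "A:1079", "A:1083", kind="ionpair")
    assert occ == pytest.approx(0.5, abs=1.0 / 40)


def test_occupancy_monotone_in_cutoff():
    traj = _swap_traj(swap_frame=40, n_frames=15)
    occs = [
        contact_occupancy(traj, "A:1079", "A:1083", ContactCriteria(ionpair_cutoff=c),
                          kind="ionpair")
        for c in (4.0, 3.5, 3.0, 2.5)
    ]
    assert all(a >= b for a, b in zip(occs, occs[1:]))


def test_occupancy_missing_residue_raises():
    traj = _swap_traj(swap_frame=40, n_frames=5)
    with pytest.raises(KeyError):
        contact_occupancy(traj, "A:1079", "Z:1", kind="ionpair")


def test_identical_trajectories_produce_no_switches():
    traj = _swap_traj(swap_frame=40, n_frames=20)
    reports = switch_residues(traj, traj, ["A:1079"])
    assert all(r.switch_score == 0.0 and not r.is_switch for r in reports)


def test_planted_switch_flagged_with_high_score():
    """K pairs with D1083 at 0.9 occupancy in ensemble A, with D1072 in
    ensemble B (D1083 occupancy 0.05): score >= 0.85 and flagged."""
    a = _swap_traj(swap_frame=36, n_frames=40, seed=1)  # 90% on D1083
    b = _swap_traj(swap_frame=2, n_frames=40, seed=2)  # 5% on D1083
    reports = switch_residues(a, b, ["A:1079"])
    r = reports[0]
    assert r.is_switch and r.switch_score >= 0.85
    # Score is symmetric under ensemble swap.
    rev = switch_residues(b, a, ["A:1079"])[0]
    assert rev.switch_score == pytest.approx(r.switch_score)


def test_frame_order_permutation_invariance():
    traj = _swap_traj(swap_frame=10, n_frames=20, seed=5)
    rng = np.random.default_rng(0)
    perm = rng.permutation(20)
    shuffled = Trajectory(traj.topology, traj.frames[perm], traj.frame_interval)
    occ1 = contact_occupancy(traj, "A:1079", "A:1083", kind="ionpair")
    occ2 = contact_occupancy(shuffled, "A:1079", "A:1083", kind="ionpair")
    assert occ1 == occ2


def test_switch_candidate_missing_raises():
    traj = _swap_traj(swap_frame=40, n_frames=5)
    with pytest.raises(KeyError):
        switch_residues(traj, traj, ["Q:1"])
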