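"""Hydrogen bonds, ion pairs, contact occupancy and switch-residue calls.

A *switch residue* is a side chain whose ionic or hydrogen-bond partners
differ between two conformational ensembles — here, trajectories of the
closed (catalytic) and open (translocating) trigger-loop elongation
complexes.  The detection pipeline is: geometric contact detection per frame,
per-partner occupancy over each trajectory, then a per-candidate switch score
``max_p |occ_A(p) - occ_B(p)|``.

Geometric criteria (defaults 3.5 A donor-acceptor with a 120 deg donor angle
for hydrogen bonds; 4.0 A between charged-group heavy atoms for ion pairs)
are explicit knobs of :class:`ContactCriteria`, not literature claims.  When
the donor's hydrogen is missing from the input, the backbone amide H is
reconstructed geometrically; side-chain and water donors without hydrogens
fall back to the distance criterion alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import angle_at
from .io_model import Structure, Trajectory, WATER_RESNAMES

__all__ = [
    "ContactCriteria",
    "ContactRecord",
    "SwitchReport",
    "hydrogen_bonds",
    "ion_pairs",
    "contact_occupancy",
    "residue_partner_occupancies",
    "switch_residues",
    "DONOR_TABLE",
    "ACCEPTOR_TABLE",
    "POSITIVE_GROUPS",
    "NEGATIVE_GROUPS",
]


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds for contact detection."""

    hbond_da_cutoff: float = 3.5  # A, donor-acceptor heavy atoms
    hbond_angle_min: float = 120.0  # degrees at the donor (D-H...A)
    ionpair_cutoff: float = 4.0  # A, closest charged-group heavy atoms
    protonated_his: frozenset = frozenset()  # "chain:resid" keys carrying +1

    def __post_init__(self):
        if self.hbond_da_cutoff <= 0 or self.ionpair_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not (0 < self.hbond_angle_min <= 180):
            raise ValueError("hbond_angle_min must be in (0, 180]")


@dataclass(frozen=True)
class ContactRecord:
    kind: str  # "hbond" | "ionpair"
    atom_i: str  # donor / cation-group atom key
    atom_j: str  # acceptor / anion-group atom key
    residue_i: str  # "chain:resid"
    residue_j: str
    distance: float  # A
    angle: float | None = None  # degrees at donor, hbond only


@dataclass
class SwitchReport:
    residue: str
    partners_a: dict
    partners_b: dict
    switch_score: float
    is_switch: bool


# --- built-in donor/acceptor typing -----------------------------------------
# (resname, atom) side-chain donors; the backbone N of any amino-acid residue
# and the water O are donors implicitly.
DONOR_TABLE = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("TRP", "NE1"),
    ("CYS", "SG"),
    ("ATP", "N6"),
    ("DA", "N6"), ("DC", "N4"), ("DG", "N2"), ("DG", "N1"), ("DT", "N3"),
}

ACCEPTOR_TABLE = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
    ("ATP", "N1"), ("ATP", "N3"), ("ATP", "N7"),
    ("DA", "N1"), ("DA", "N3"), ("DA", "N7"), ("DG", "O6"), ("DG", "N7"),
    ("DC", "O2"), ("DC", "N3"), ("DT", "O2"), ("DT", "O4"),
}

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

POSITIVE_GROUPS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "MG": ("MG",),
}
#: His is positive only for resids listed in ContactCriteria.protonated_his.
HIS_GROUP = ("ND1", "NE2")

NEGATIVE_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ATP": ("O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G"),
}
#: Nucleic-acid phosphate oxygens (both PDB naming dialects).
_PHOSPHATE_O = ("OP1", "OP2", "O1P", "O2P")
_NUCLEIC_RESNAMES = {"DA", "DT", "DG", "DC", "A", "G", "C", "U", "ATP"}


def _residue_key(atom) -> str:
    return f"{atom.chain}:{atom.resid_key}"


def _attached_hydrogens(structure: Structure, idx: int) -> list[int]:
    """Hydrogens covalently attached to heavy atom ``idx`` (same residue,
    within 1.25 A)."""
    a = structure.atoms[idx]
    out = []
    for j in structure.residue_atom_map()[f"{a.chain}:{a.resid_key}"]:
        b = structure.atoms[j]
        if b.element == "H" or (not b.element and b.name.startswith("H")):
            if np.linalg.norm(structure.coords[j] - structure.coords[idx]) <= 1.25:
                out.append(j)
    return out


def _backbone_h_direction(structure: Structure, n_idx: int) -> np.ndarray | None:
    """Reconstructed amide H position for a backbone N (or None at chain start)."""
    a = structure.atoms[n_idx]
    prev_c = prev_o = None
    for j in structure.residue_atom_map().get(f"{a.chain}:{a.resid - 1}", []):
        b = structure.atoms[j]
        if b.name == "C":
            prev_c = j
        elif b.name == "O":
            prev_o = j
    if prev_c is None or prev_o is None:
        return None
    if np.linalg.norm(structure.coords[prev_c] - structure.coords[n_idx]) > 2.5:
        return None  # chain break
    d = structure.coords[prev_c] - structure.coords[prev_o]
    return structure.coords[n_idx] + d / np.linalg.norm(d)


def _classify_hbond_atoms(structure: Structure, subset=None):
    """Indices of donor and acceptor heavy atoms under the built-in tables."""
    donors, acceptors = [], []
    unknown = set()
    indices = range(structure.n_atoms) if subset is None else subset
    for i in indices:
        a = structure.atoms[i]
        known = (
            a.resname in _PROTEIN_RESNAMES
            or a.resname in _NUCLEIC_RESNAMES
            or a.resname in WATER_RESNAMES
            or a.resname in ("MG", "UNK")
        )
        if not known:
            unknown.add(a.resname)
        if a.is_water and a.name.startswith("O"):
            donors.append(i)
            acceptors.append(i)
            continue
        if (a.resname, a.name) in DONOR_TABLE:
            donors.append(i)
        if a.name == "N" and a.resname in _PROTEIN_RESNAMES:
            donors.append(i)
        if (a.resname, a.name) in ACCEPTOR_TABLE:
            acceptors.append(i)
        if a.name == "O" and a.resname in _PROTEIN_RESNAMES:
            acceptors.append(i)
    if unknown:
        warnings.warn(f"unknown residue types skipped in H-bond typing: {sorted(unknown)}")
    return donors, acceptors


def hydrogen_bonds(
    frame: Structure,
    criteria: ContactCriteria = ContactCriteria(),
    subset=None,
) -> list[ContactRecord]:
    """All donor-acceptor pairs satisfying the distance and angle criteria.

    Neighbour search uses a k-d tree on acceptor positions; results are
    ordered deterministically by (donor key, acceptor key).  Same-residue
    pairs are excluded.
    """
    donors, acceptors = _classify_hbond_atoms(frame, subset)
    records = []
    if not donors or not acceptors:
        return records
    acc_coords = frame.coords[acceptors]
    tree = cKDTree(acc_coords)
    for d_idx in donors:
        d_atom = frame.atoms[d_idx]
        d_xyz = frame.coords[d_idx]
        h_positions = [frame.coords[h] for h in _attached_hydrogens(frame, d_idx)]
        if not h_positions and d_atom.name == "N" and d_atom.resname in _PROTEIN_RESNAMES:
            h = _backbone_h_direction(frame, d_idx)
            if h is not None:
                h_positions = [h]
        for a_pos in tree.query_ball_point(d_xyz, criteria.hbond_da_cutoff):
            a_idx = acceptors[a_pos]
            a_atom = frame.atoms[a_idx]
            if a_idx == d_idx or _residue_key(a_atom) == _residue_key(d_atom):
                continue
            dist = float(np.linalg.norm(frame.coords[a_idx] - d_xyz))
            if h_positions:
                angle = max(
                    angle_at(d_xyz, h, frame.coords[a_idx]) for h in h_positions
                )
                if angle < criteria.hbond_angle_min:
                    continue
            else:
                angle = None  # no hydrogen available: distance-only criterion
            records.append(
                ContactRecord(
                    kind="hbond",
                    atom_i=d_atom.key(),
                    atom_j=a_atom.key(),
                    residue_i=_residue_key(d_atom),
                    residue_j=_residue_key(a_atom),
                    distance=dist,
                    angle=angle,
                )
            )
    records.sort(key=lambda r: (r.atom_i, r.atom_j))
    return records


def _charged_groups(frame: Structure, criteria: ContactCriteria, subset=None):
    """(residue key, sign, resname, [atom indices]) charged groups."""
    by_res: dict[str, dict] = {}
    indices = range(frame.n_atoms) if subset is None else subset
    for i in indices:
        a = frame.atoms[i]
        rk = _residue_key(a)
        sign = 0
        if a.resname in POSITIVE_GROUPS and a.name in POSITIVE_GROUPS[a.resname]:
            sign = +1
        elif a.resname == "HIS" and rk in criteria.protonated_his and a.name in HIS_GROUP:
            sign = +1
        elif a.resname in NEGATIVE_GROUPS and a.name in NEGATIVE_GROUPS[a.resname]:
            sign = -1
        elif a.resname in _NUCLEIC_RESNAMES and a.name in _PHOSPHATE_O:
            sign = -1
        if sign:
            entry = by_res.setdefault(rk, {"sign": sign, "resname": a.resname, "atoms": []})
            entry["atoms"].append(i)
    return [(rk, v["sign"], v["resname"], v["atoms"]) for rk, v in by_res.items()]


def ion_pairs(
    frame: Structure,
    criteria: ContactCriteria = ContactCriteria(),
    subset=None,
) -> list[ContactRecord]:
    """Oppositely charged residue groups whose closest heavy atoms are within
    the ion-pair cutoff.  One record per residue pair, carrying the closest
    atom pair and its distance."""
    groups = _charged_groups(frame, criteria, subset)
    records = []
    for gi in range(len(groups)):
        rk_i, sign_i, _, atoms_i = groups[gi]
        for gj in range(gi + 1, len(groups)):
            rk_j, sign_j, _, atoms_j = groups[gj]
            if sign_i * sign_j >= 0:
                continue
            diff = frame.coords[atoms_i][:, None, :] - frame.coords[atoms_j][None, :, :]
            dmat = np.linalg.norm(diff, axis=2)
            k = np.unravel_index(np.argmin(dmat), dmat.shape)
            if dmat[k] > criteria.ionpair_cutoff:
                continue
            ai, aj = atoms_i[k[0]], atoms_j[k[1]]
            # Cation side reported first.
            if sign_i < 0:
                ai, aj = aj, ai
                rk_i_, rk_j_ = rk_j, rk_i
            else:
                rk_i_, rk_j_ = rk_i, rk_j
            records.append(
                ContactRecord(
                    kind="ionpair",
                    atom_i=frame.atoms[ai].key(),
                    atom_j=frame.atoms[aj].key(),
                    residue_i=rk_i_,
                    residue_j=rk_j_,
                    distance=float(dmat[k]),
                )
            )
    records.sort(key=lambda r: (r.atom_i, r.atom_j))
    return records


def _frame_contacts(frame, criteria, subset=None):
    return hydrogen_bonds(frame, criteria, subset) + ion_pairs(frame, criteria, subset)


def contact_occupancy(
    traj: Trajectory,
    residue_i: str,
    residue_j: str,
    criteria: ContactCriteria = ContactCriteria(),
    kind: str = "any",
    stride: int = 1,
) -> float:
    """Fraction of sampled frames in which the two residues are in contact.

    ``kind`` restricts to "hbond" or "ionpair"; "any" accepts either.
    """
    # Both residues must exist in the topology.
    for rk in (residue_i, residue_j):
        chain, resid = rk.split(":")
        if not np.any((traj.topology.chains == chain)
                      & (traj.topology.resids == int(resid))):
            raise KeyError(f"residue not in topology: {rk}")
    hits = 0
    n = 0
    pair = frozenset((residue_i, residue_j))
    for k in range(0, traj.n_frames, stride):
        frame = traj.frame_structure(k)
        recs = _frame_contacts(frame, criteria)
        present = any(
            frozenset((r.residue_i, r.residue_j)) == pair
            and (kind == "any" or r.kind == kind)
            for r in recs
        )
        hits += present
        n += 1
    return hits / n


def residue_partner_occupancies(
    traj: Trajectory,
    candidate: str,
    criteria: ContactCriteria = ContactCriteria(),
    stride: int = 1,
    include_water: bool = False,
) -> dict:
    """Occupancy of every contact partner of ``candidate`` ("chain:resid")."""
    top = traj.topology
    chain, resid = candidate.split(":")
    cand_mask = (top.chains == chain) & (top.resids == int(resid))
    if not np.any(cand_mask):
        raise KeyError(f"candidate residue not in topology: {candidate}")
    subset = None
    if not include_water:
        subset = np.nonzero(~np.isin(top.resnames, list(WATER_RESNAMES)))[0]
    counts: dict[str, int] = {}
    n = 0
    for k in range(0, traj.n_frames, stride):
        frame = traj.frame_structure(k)
        seen = set()
        for r in _frame_contacts(frame, criteria, subset):
            if r.residue_i == candidate:
                seen.add(r.residue_j)
            elif r.residue_j == candidate:
                seen.add(r.residue_i)
        for p in seen:
            counts[p] = counts.get(p, 0) + 1
        n += 1
    return {p: c / n for p, c in sorted(counts.items())}


def switch_residues(
    traj_a: Trajectory,
    traj_b: Trajectory,
    candidates,
    criteria: ContactCriteria = ContactCriteria(),
    occupancy_delta: float = 0.5,
    stride: int = 1,
) -> list[SwitchReport]:
    """Classify candidate residues as switches between two ensembles.

    For each candidate, partner occupancies are computed independently in
    each trajectory; the switch score is the largest absolute occupancy
    difference over the union of partners, and ``is_switch`` requires it to
    reach ``occupancy_delta``.  Reports are sorted by score, descending
    (ties by residue key for determinism).  The score is symmetric in the
    two ensembles.
    """
    reports = []
    for cand in candidates:
        occ_a = residue_partner_occupancies(traj_a, cand, criteria, stride)
        occ_b = residue_partner_occupancies(traj_b, cand, criteria, stride)
        partners = set(occ_a) | set(occ_b)
        score = max(
            (abs(occ_a.get(p, 0.0) - occ_b.get(p, 0.0)) for p in partners),
            default=0.0,
        )
        reports.append(
            SwitchReport(
                residue=cand,
                partners_a=occ_a,
                partners_b=occ_b,
                switch_score=score,
                is_switch=score >= occupancy_delta,
            )
        )
    reports.sort(key=lambda r: (-r.switch_score, r.residue))
    return reports
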