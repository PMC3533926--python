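"""Hinge metrics: backbone dihedrals, delta-psi series, helix bend angles and
secondary-structure timelines.

Flexible glycine/proline hinges in the helices flanking the trigger loop (H1,
H2) and near the bridge-helix N-terminus (H3, H4) are tracked through three
complementary metrics:

* the psi backbone dihedral of a hinge residue relative to a reference frame
  (delta-psi), a scalar residue-conformation monitor;
* the bend angle between helix axes fitted to the flanks on either side of a
  hinge, which distinguishes straight (B1) from bent (B2) helix modes;
* per-residue secondary-structure timelines over a trajectory, using a
  Kabsch--Sander hydrogen-bond criterion reduced to the five classes
  {H: alpha-helix, G: 3_10 helix, E: beta-strand, T: turn, C: coil}
  (pi-helix is folded into H).

Input structures routinely lack hydrogens; the backbone amide H needed for
the H-bond energy is reconstructed geometrically (1.0 A from N, anti to the
preceding residue's C=O).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import dihedral, wrap_angle
from .io_model import Structure, Trajectory

__all__ = [
    "HingeDefinition",
    "SecondaryStructureTimeline",
    "ResidueDihedrals",
    "backbone_residues",
    "backbone_dihedrals",
    "delta_psi_series",
    "helix_bend_angle",
    "assign_secondary_structure",
    "ss_timeline",
]

#: Kabsch-Sander electrostatic H-bond energy threshold, kcal/mol.
HBOND_ENERGY_CUTOFF = -0.5
_KS_Q = 0.084 * 332.0

#: Chain break if the peptide C-N distance exceeds this (A).
CHAIN_BREAK_CN = 2.5


@dataclass(frozen=True)
class HingeDefinition:
    """A hinge: the flexible residues plus two flanking ranges used to fit
    helix axes.  Ranges are inclusive (lo, hi) resid pairs on ``chain``."""

    name: str
    chain: str
    residues: tuple[int, int]
    flank_pre: tuple[int, int]
    flank_post: tuple[int, int]

    def __post_init__(self):
        for fl in (self.flank_pre, self.flank_post):
            if fl[1] - fl[0] + 1 < 4:
                raise ValueError(f"hinge {self.name}: flank {fl} has fewer than 4 residues")
        if not (self.flank_pre[1] < self.flank_post[0] or self.flank_post[1] < self.flank_pre[0]):
            raise ValueError(f"hinge {self.name}: flanks overlap")


@dataclass
class SecondaryStructureTimeline:
    """residues x frames character matrix of {H, G, E, T, C} labels."""

    residues: list[int]
    times: np.ndarray
    labels: np.ndarray  # (n_residues, n_frames) of single characters

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (len(self.residues), len(self.times)):
            raise ValueError("label matrix dimensions must be residues x frames")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("resid\t" + "\t".join(f"{t:g}" for t in self.times) + "\n")
            for r, row in zip(self.residues, self.labels):
                fh.write(f"{r}\t" + "\t".join(row) + "\n")


@dataclass
class ResidueDihedrals:
    chain: str
    resid: int
    phi: float  # degrees in (-180, 180]; NaN when undefined (termini)
    psi: float


class _Backbone:
    """Per-residue backbone atom indices for the protein part of a structure.

    A residue participates if it has N, CA and C atoms.  ``prev``/``next``
    link peptide-bonded neighbours (same chain, consecutive list positions,
    C-N distance below the chain-break cutoff).
    """

    def __init__(self, structure: Structure):
        self.structure = structure
        self.chain: list[str] = []
        self.resid: list[int] = []
        self.N: list[int] = []
        self.CA: list[int] = []
        self.C: list[int] = []
        self.O: list[int] = []
        for chain, resid_key, resname, idxs in structure.residue_groups():
            names = {structure.atoms[i].name: i for i in idxs}
            if not {"N", "CA", "C"} <= names.keys():
                continue
            self.chain.append(chain)
            try:
                self.resid.append(int(resid_key))
            except ValueError:
                self.resid.append(int("".join(ch for ch in resid_key if ch.isdigit() or ch == "-")))
            self.N.append(names["N"])
            self.CA.append(names["CA"])
            self.C.append(names["C"])
            self.O.append(names.get("O", -1))
        self.n = len(self.resid)

    def bonded(self, i: int, j: int, coords: np.ndarray) -> bool:
        """True if residue j directly follows residue i through a peptide bond."""
        if j != i + 1 or i < 0 or j >= self.n or self.chain[i] != self.chain[j]:
            return False
        return np.linalg.norm(coords[self.N[j]] - coords[self.C[i]]) <= CHAIN_BREAK_CN

    def lookup(self, chain: str, resid: int) -> int:
        for i in range(self.n):
            if self.chain[i] == chain and self.resid[i] == resid:
                return i
        raise KeyError(f"no backbone residue {chain}:{resid}")


def backbone_residues(structure: Structure) -> _Backbone:
    return _Backbone(structure)


def backbone_dihedrals(frame: Structure, chain: str | None = None, resid_range=None):
    """Standard phi/psi per residue, degrees in (-180, 180].

    phi(i) = torsion C(i-1), N(i), CA(i), C(i); psi(i) = torsion N(i), CA(i),
    C(i), N(i+1).  Chain termini (and residues missing backbone atoms) yield
    NaN for the undefined angle.  Optionally restricted to a chain and an
    inclusive resid range.
    """
    bb = _Backbone(frame)
    xyz = frame.coords
    out = []
    for i in range(bb.n):
        if chain is not None and bb.chain[i] != chain:
            continue
        if resid_range is not None and not (resid_range[0] <= bb.resid[i] <= resid_range[1]):
            continue
        phi = np.nan
        psi = np.nan
        if i > 0 and bb.bonded(i - 1, i, xyz):
            phi = dihedral(xyz[bb.C[i - 1]], xyz[bb.N[i]], xyz[bb.CA[i]], xyz[bb.C[i]])
        if i + 1 < bb.n and bb.bonded(i, i + 1, xyz):
            psi = dihedral(xyz[bb.N[i]], xyz[bb.CA[i]], xyz[bb.C[i]], xyz[bb.N[i + 1]])
        out.append(ResidueDihedrals(bb.chain[i], bb.resid[i], phi, psi))
    return out


def delta_psi_series(traj: Trajectory, residue: str, reference_frame: int = 0):
    """delta-psi(t) = wrap(psi_t - psi_ref) into (-180, 180] for one residue.

    ``residue`` is ``"chain:resid"``.  The reference frame maps to exactly 0;
    frames where psi is undefined are NaN gaps.  Returns a SeriesResult in
    degrees.
    """
    from .trajectory_metrics import SeriesResult

    chain, resid = residue.split(":")
    resid = int(resid)
    bb = _Backbone(traj.topology)
    i = bb.lookup(chain, resid)
    if i + 1 >= bb.n or not bb.bonded(i, i + 1, traj.frames[reference_frame]):
        raise ValueError(f"residue {residue} has no defined psi (chain terminus)")
    quad = (bb.N[i], bb.CA[i], bb.C[i], bb.N[i + 1])

    def psi_of(coords):
        return dihedral(*(coords[q] for q in quad))

    psi_ref = psi_of(traj.frames[reference_frame])
    values = np.array([wrap_angle(psi_of(f) - psi_ref) for f in traj.frames])
    values[reference_frame] = 0.0
    return SeriesResult(times=traj.times, values=values, label=f"dpsi({residue})_deg")


def _flank_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Principal axis of a Calpha set, oriented N->C (first to last residue).

    Calpha positions are smoothed with a one-turn (4-residue) running mean
    first, which cancels the helical spiral so the axis tracks the helix
    axis rather than tilting with a fractional final turn.
    """
    if len(ca_coords) >= 5:
        kernel = np.ones(4) / 4.0
        ca_coords = np.column_stack(
            [np.convolve(ca_coords[:, d], kernel, mode="valid") for d in range(3)]
        )
    centered = ca_coords - ca_coords.mean(axis=0)
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    end_to_end = ca_coords[-1] - ca_coords[0]
    # Degenerate (tied) leading eigenvalues: fall back to end-to-end direction.
    if evals[-1] - evals[-2] < 1e-9 * max(evals[-1], 1.0):
        axis = end_to_end / np.linalg.norm(end_to_end)
    elif np.dot(axis, end_to_end) < 0:
        axis = -axis
    return axis


def helix_bend_angle(frame: Structure, hinge: HingeDefinition) -> float:
    """Angle between helix axes fitted to the two hinge flanks, degrees [0, 180).

    Each flank axis is the principal inertia axis of its Calpha atoms,
    oriented N->C; a perfectly straight helix reads ~0.  Invariant under
    rigid-body motion of the whole frame.
    """
    bb = _Backbone(frame)
    axes = []
    for lo, hi in (hinge.flank_pre, hinge.flank_post):
        idx = [
            bb.CA[i]
            for i in range(bb.n)
            if bb.chain[i] == hinge.chain and lo <= bb.resid[i] <= hi
        ]
        if len(idx) < 4:
            raise ValueError(
                f"hinge {hinge.name}: flank {lo}-{hi} has {len(idx)} Calpha atoms (<4)"
            )
        axes.append(_flank_axis(frame.coords[idx]))
    cosang = np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure, five classes
# ---------------------------------------------------------------------------

def _ks_hbond_matrix(bb: _Backbone, coords: np.ndarray) -> np.ndarray:
    """hb[i, j] True if the N-H of residue i donates to the C=O of residue j
    with Kabsch-Sander energy below the cutoff."""
    n = bb.n
    N = coords[bb.N]
    # Reconstructed amide H: 1.0 A from N, anti to the preceding C=O.
    H = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if bb.bonded(i - 1, i, coords) and bb.O[i - 1] >= 0:
            d = coords[bb.C[i - 1]] - coords[bb.O[i - 1]]
            H[i] = N[i] + d / np.linalg.norm(d)
            has_h[i] = True
    C = coords[bb.C]
    O = np.full((n, 3), np.nan)
    has_o = np.array([o >= 0 for o in bb.O])
    O[has_o] = coords[[o for o in bb.O if o >= 0]]

    hb = np.zeros((n, n), dtype=bool)
    don = np.nonzero(has_h)[0]
    acc = np.nonzero(has_o)[0]
    if len(don) == 0 or len(acc) == 0:
        return hb
    r_on = np.linalg.norm(O[acc][None, :, :] - N[don][:, None, :], axis=2)
    r_ch = np.linalg.norm(C[acc][None, :, :] - H[don][:, None, :], axis=2)
    r_oh = np.linalg.norm(O[acc][None, :, :] - H[don][:, None, :], axis=2)
    r_cn = np.linalg.norm(C[acc][None, :, :] - N[don][:, None, :], axis=2)
    with np.errstate(divide="ignore"):
        E = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    ok = E < HBOND_ENERGY_CUTOFF
    for a, i in enumerate(don):
        for b, j in enumerate(acc):
            if abs(i - j) < 2 and bb.chain[i] == bb.chain[j]:
                continue  # self and adjacent residues cannot count
            hb[i, j] = ok[a, b]
    return hb


def assign_secondary_structure(frame: Structure, warn_missing_o: bool = True):
    """Per-residue {H, G, E, T, C} labels for the protein residues of a frame.

    Backbone H-bonds use the Kabsch-Sander electrostatic energy with the
    amide H reconstructed when absent.  Two consecutive 4-turns (or 5-turns)
    make an alpha (or pi, folded in) helix H; two consecutive 3-turns make G;
    bridge/ladder patterns make E; an isolated turn H-bond makes T; the rest
    is coil C.  Residues missing the carbonyl O are labeled C with a warning.

    Returns a list of (chain, resid, label) triples in residue order.
    """
    bb = _Backbone(frame)
    coords = frame.coords
    n = bb.n
    labels = np.array(["C"] * n, dtype="U1")
    if n == 0:
        return []
    missing_o = [i for i in range(n) if bb.O[i] < 0]
    if missing_o and warn_missing_o:
        warnings.warn(f"{len(missing_o)} residues lack a backbone O; labeled C")

    hb = _ks_hbond_matrix(bb, coords)

    def turn(i, k):
        """k-turn at i: N-H of residue i+k donates to C=O of residue i, with
        the stretch peptide-bonded throughout."""
        if i + k >= n or bb.chain[i] != bb.chain[i + k]:
            return False
        if not all(bb.bonded(m, m + 1, coords) for m in range(i, i + k)):
            return False
        return hb[i + k, i]

    helix = np.zeros(n, dtype=bool)
    g_helix = np.zeros(n, dtype=bool)
    turnish = np.zeros(n, dtype=bool)
    for k, target in ((4, helix), (5, helix), (3, g_helix)):
        for i in range(n):
            if turn(i, k) and turn(i + 1, k):
                target[i + 1 : i + k + 1] = True
        for i in range(n):
            if turn(i, k):
                turnish[i + 1 : i + k] = True

    strand = np.zeros(n, dtype=bool)

    def _hb(a, b):
        return 0 <= a < n and 0 <= b < n and hb[a, b]

    for i in range(n):
        for j in range(n):
            if i == j or (bb.chain[i] == bb.chain[j] and abs(i - j) < 3):
                continue
            antiparallel = (_hb(i, j) and _hb(j, i)) or (
                _hb(i + 1, j - 1) and _hb(j + 1, i - 1)
            )
            parallel = (_hb(i + 1, j) and _hb(j, i - 1)) or (
                _hb(j + 1, i) and _hb(i, j - 1)
            )
            if antiparallel or parallel:
                strand[i] = True
    # Priority: H > E > G > T > C.
    for i in range(n):
        if helix[i]:
            labels[i] = "H"
        elif strand[i]:
            labels[i] = "E"
        elif g_helix[i]:
            labels[i] = "G"
        elif turnish[i]:
            labels[i] = "T"
    for i in missing_o:
        labels[i] = "C"
    return [(bb.chain[i], bb.resid[i], str(labels[i])) for i in range(n)]


def ss_timeline(
    traj: Trajectory,
    chain: str,
    resid_range: tuple[int, int],
    stride: int = 1,
) -> SecondaryStructureTimeline:
    """Secondary structure of a residue range across sampled frames."""
    lo, hi = resid_range
    sampled = range(0, traj.n_frames, stride)
    columns = []
    residues = None
    for k in sampled:
        assign = assign_secondary_structure(traj.frame_structure(k), warn_missing_o=(k == 0))
        rows = [(r, lab) for ch, r, lab in assign if ch == chain and lo <= r <= hi]
        if residues is None:
            residues = [r for r, _ in rows]
        columns.append([lab for _, lab in rows])
    labels = np.array(columns).T if columns else np.zeros((0, 0), dtype="U1")
    times = np.array([k * traj.frame_interval for k in sampled])
    return SecondaryStructureTimeline(residues=residues or [], times=times, labels=labels)
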