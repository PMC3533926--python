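"""Toy elongation-complex generator with planted, recoverable ground truth.

Real inputs for the analyses in this package are multi-gigabyte all-atom
trajectories of a polymerase elongation complex.  This module builds a
*toy TEC* that reproduces the structural roles those analyses touch, at a
scale where every planted truth is known exactly:

* an ideal alpha-helix (canonical 1.5 A rise / 100 deg twist, built from
  phi/psi = -57/-47) standing in for the bridge helix, with a bendable hinge
  and pseudo side-chain charged atoms (LYS NZ / ASP OD1) on designated
  residues that form and break planted ion pairs;
* a rigid base-paired two-strand nucleic ladder (one C3'-named atom per
  pseudo-nucleotide) that drifts along a translocation axis at a scheduled
  rate;
* two MG ions and an ATP-like ligand with an N3-named atom, the centers for
  hydration analysis;
* explicit waters: resident waters pinned at planted distances from a
  center, transient visitors performing reflected random walks, and optional
  bulk waters on a jittered grid;
* isotropic Gaussian thermal noise on every atom.

Standard PDB residue and atom names are used throughout (ALA backbone, LYS /
ASP pseudo side chains, DA / DT ladder, HOH waters, MG) so real-structure
code paths are exercised.  Everything is bit-reproducible from the seed.

Defaults mirror the study conditions of the elongation-complex comparison:
525 frames at 20 ps (10.5 ns), a 38-residue helix numbered 1067-1104, and
the :func:`closed_tec_params` / :func:`open_tec_params` presets plant the
qualitative contrasts of the two ensembles (forward drift ~ +3 A vs ~ -2 A
over the run, a ~30 deg stable bend vs a straight helix, three vs one
resident water at Mg-I, hydrated vs dehydrated ATP N3, and a swapped ion
pair partner).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import build_backbone, fibonacci_sphere, rotation_matrix
from .io_model import Atom, Structure, Trajectory
from .assay_quant import BandTable, RunoffCourse

__all__ = [
    "WaterShell",
    "ToyTECParams",
    "AssaySimParams",
    "build_toy_tec",
    "simulate_trajectory",
    "simulate_assay",
    "build_beta_sheet",
    "closed_tec_params",
    "open_tec_params",
    "toy_downstream_spec",
    "toy_upstream_spec",
    "toy_hinge",
]

_HELIX_FIRST_RESID = 1067  # bridge-helix numbering
_MIN_SEPARATION = 1.5  # A; closer planted placements are a hard error


@dataclass(frozen=True)
class WaterShell:
    """``count`` waters planted at exactly ``distance`` from ``center``.

    Resident waters track the center for the whole run; transient ones start
    in the shell and wander off by a reflected random walk.
    """

    center: str  # atom key
    distance: float  # A
    count: int
    resident: bool = True


@dataclass(frozen=True)
class ToyTECParams:
    """Scenario definition for the toy TEC.  All schedules are lists of
    (frame, value) pairs applied piecewise-constantly from that frame on."""

    helix_length: int = 38
    hinge_position: int = 1079  # resid of the hinge Calpha
    bend_schedule: tuple = ()  # (frame, degrees) rigid flank rotations
    psi_schedule: tuple = ()  # (frame, degrees) rotations about the hinge CA-C bond
    duplex_length: int = 12  # base pairs in the ladder
    translocation_drift: float = 0.0  # A per ns along the translocation axis
    n_waters: tuple = ()  # WaterShell entries
    n_bulk_waters: int = 0  # background waters on a jittered grid
    contact_swap: tuple | None = None  # (residue, partner_a, partner_b, swap_frame)
    noise_sigma: float = 0.1  # A, isotropic per coordinate
    n_frames: int = 525  # 10.5 ns at 20 ps
    frame_interval: float = 20.0  # ps
    seed: int = 0

    def __post_init__(self):
        if self.helix_length < 8 or self.duplex_length < 2:
            raise ValueError("helix_length >= 8 and duplex_length >= 2 required")
        if self.n_frames < 1 or self.frame_interval <= 0 or self.noise_sigma < 0:
            raise ValueError("invalid trajectory parameters")
        for shell in self.n_waters:
            if shell.count < 0 or shell.distance <= 0:
                raise ValueError("invalid water shell")


@dataclass(frozen=True)
class AssaySimParams:
    """Planted truths for synthetic assay tables."""

    true_k: float = 0.1  # 1/s
    amplitude: float = 0.9
    noise_sigma: float = 0.02  # additive, runoff fractions
    times: tuple = (5.0, 10.0, 20.0, 40.0)  # s
    misincorporation_p: float = 0.1
    post_without_ntp: float = 0.25
    post_with_ntp: float = 0.51
    band_noise: float = 0.05  # multiplicative lognormal sigma on band intensities
    n_molecules: int = 100000  # binomial depth for the competition assay
    replicates: int = 3
    seed: int = 0


# --- structure construction -------------------------------------------------

_HELIX_CENTER = np.array([30.0, 0.0, 0.0])
_LADDER_HALF_GAP = 5.0  # A between the strands and the axis
_TRANSLOCATION_AXIS = np.array([1.0, 0.0, 0.0])
_MG1 = np.array([0.0, 0.0, 8.0])
_MG2 = np.array([0.0, 4.0, 8.0])
_ATP_N3 = np.array([6.5, 0.0, 8.0])
_ATP_PA = np.array([3.5, 2.0, 8.0])


def _helix_coordinates(n_res: int):
    """Ideal helix backbone, principal axis aligned to z, centered on
    _HELIX_CENTER.  Returns dict of (n,3) arrays."""
    bb = build_backbone([-57.0] * n_res, [-47.0] * n_res)
    ca = bb["CA"]
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    # Rotate helix axis onto +z.
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        R = np.eye(3)
    else:
        c = np.dot(axis, z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    origin = ca.mean(axis=0)
    out = {}
    for name, arr in bb.items():
        out[name] = (R @ (arr - origin).T).T + _HELIX_CENTER
    return out


def _radial_out(ca: np.ndarray) -> np.ndarray:
    """Unit vector pointing away from the helix axis (z through _HELIX_CENTER)."""
    v = ca - _HELIX_CENTER
    v = np.array([v[0], v[1], 0.0])
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def build_toy_tec(params: ToyTECParams = ToyTECParams()) -> Structure:
    """Construct the toy TEC structure (frame-0 coordinates).

    Raises ValueError if any planted inter-component placement falls below
    1.5 A (a geometrically impossible scenario).
    """
    rng = np.random.default_rng(params.seed)
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = [0]

    def add(name, resname, chain, resid, xyz, element="", het=False):
        serial[0] += 1
        atoms.append(
            Atom(serial=serial[0], name=name, resname=resname, chain=chain,
                 resid=resid, element=element or name[:1], het=het)
        )
        coords.append(np.asarray(xyz, dtype=float))

    # Helix, chain A, ALA backbone; swap residues get pseudo side chains.
    bb = _helix_coordinates(params.helix_length)
    swap = params.contact_swap
    special = {}
    if swap is not None:
        cand, pa, pb, _ = swap
        special = {cand: "LYS", pa: "ASP", pb: "ASP"}
    resids = range(_HELIX_FIRST_RESID, _HELIX_FIRST_RESID + params.helix_length)
    ca_by_resid = {}
    for i, resid in enumerate(resids):
        resname = special.get(resid, "ALA")
        for name in ("N", "CA", "C", "O"):
            add(name, resname, "A", resid, bb[name][i], element=name[:1])
        ca_by_resid[resid] = bb["CA"][i]
    if swap is not None:
        cand, pa, pb, _ = swap
        for r in (cand, pa, pb):
            if r not in ca_by_resid:
                raise ValueError(f"contact_swap residue {r} outside the helix")
        od1 = {r: ca_by_resid[r] + 3.0 * _radial_out(ca_by_resid[r]) for r in (pa, pb)}
        add("OD1", "ASP", "A", pa, od1[pa], element="O")
        add("OD1", "ASP", "A", pb, od1[pb], element="O")
        # Candidate NZ starts on partner_a.
        direction = ca_by_resid[cand] - od1[pa]
        nz = od1[pa] + 3.0 * direction / np.linalg.norm(direction)
        add("NZ", "LYS", "A", cand, nz, element="N")
        if np.linalg.norm(od1[pa] - od1[pb]) < 6.0:
            raise ValueError("contact_swap partners too close for a clean swap")

    # Nucleic ladder: template chain T (DA), non-template chain N (DT).
    half = 0.5 * (params.duplex_length - 1) * 3.4
    for i in range(params.duplex_length):
        x = i * 3.4 - half
        add("C3'", "DA", "T", i + 1, (x, _LADDER_HALF_GAP, 0.0), element="C")
    for i in range(params.duplex_length):
        x = i * 3.4 - half
        add("C3'", "DT", "N", i + 1, (x, -_LADDER_HALF_GAP, 0.0), element="C")

    # Metals and the ATP-like ligand.
    add("MG", "MG", "M", 1, _MG1, element="MG", het=True)
    add("MG", "MG", "M", 2, _MG2, element="MG", het=True)
    add("N3", "ATP", "M", 3, _ATP_N3, element="N", het=True)
    add("PA", "ATP", "M", 3, _ATP_PA, element="P", het=True)

    # Shell waters.
    partial = Structure(atoms, np.array(coords))
    water_resid = 0
    for shell in params.n_waters:
        c = partial.position(shell.center)
        for direction in fibonacci_sphere(shell.count):
            water_resid += 1
            add("O", "HOH", "W", water_resid, c + shell.distance * direction,
                element="O", het=True)

    # Bulk waters: jittered grid in a spherical shell around the active-site
    # region, skipping points near anything already placed.
    if params.n_bulk_waters > 0:
        existing = np.array(coords)
        spacing = 3.1
        grid_1d = np.arange(-25.0, 25.0 + spacing, spacing)
        gx, gy, gz = np.meshgrid(grid_1d, grid_1d, grid_1d, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        r = np.linalg.norm(pts, axis=1)
        pts = pts[(r >= 8.0) & (r <= 25.0)]
        pts = pts[np.argsort(np.linalg.norm(pts, axis=1), kind="stable")]
        placed = 0
        for p in pts:
            if placed >= params.n_bulk_waters:
                break
            if np.min(np.linalg.norm(existing - p, axis=1)) < 3.0:
                continue
            jitter = rng.uniform(-0.3, 0.3, size=3)
            water_resid += 1
            add("O", "HOH", "W", water_resid, p + jitter, element="O", het=True)
            placed += 1
        if placed < params.n_bulk_waters:
            raise ValueError(
                f"could only place {placed}/{params.n_bulk_waters} bulk waters"
            )

    structure = Structure(atoms, np.array(coords), title="toy TEC")
    _check_overlaps(structure)
    return structure


def _check_overlaps(structure: Structure) -> None:
    """Inter-component minimum-distance check (1.5 A).

    Covalently bonded backbone neighbours are exempt; components are helix
    (chain A), ladder (T/N), ligands (M) and waters (W).
    """
    from scipy.spatial import cKDTree

    comp = np.array([{"A": 0, "T": 1, "N": 1, "M": 2, "W": 3}.get(a.chain, 4)
                     for a in structure.atoms])
    tree = cKDTree(structure.coords)
    for i, j in tree.query_pairs(_MIN_SEPARATION):
        if comp[i] != comp[j] or comp[i] == 3:  # waters also checked pairwise
            a, b = structure.atoms[i], structure.atoms[j]
            raise ValueError(
                f"geometric impossibility: atoms {a.key()} and {b.key()} are "
                f"closer than {_MIN_SEPARATION} A"
            )


# --- trajectory simulation --------------------------------------------------

def _schedule_value(schedule, frame: int) -> float:
    """Piecewise-constant schedule lookup (0 before the first entry)."""
    value = 0.0
    for f, v in sorted(schedule):
        if frame >= f:
            value = v
    return value


def simulate_trajectory(structure: Structure, params: ToyTECParams) -> Trajectory:
    """Animate a toy TEC according to the planted schedules.

    Per frame: rotate the post-hinge flank by the scheduled bend (about an
    axis through the hinge Calpha perpendicular to the helix axis) and by the
    scheduled psi change (about the hinge CA-C bond), translate the ladder by
    drift * t along the translocation axis, place the swap residue's NZ next
    to its current partner, move resident waters with their center and
    transient waters by a reflected random walk, then add Gaussian noise.
    Fully deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed + 1)  # independent of build stream
    base = structure.coords.copy()
    n_atoms = structure.n_atoms
    n_frames = params.n_frames

    chains = structure.chains
    names = structure.names
    resids = structure.resids

    hinge = params.hinge_position
    helix_mask = chains == "A"
    post_mask = helix_mask & (resids > hinge)
    hinge_ca = base[np.nonzero(helix_mask & (resids == hinge) & (names == "CA"))[0][0]]
    hinge_c = base[np.nonzero(helix_mask & (resids == hinge) & (names == "C"))[0][0]]
    hinge_o_idx = np.nonzero(helix_mask & (resids == hinge) & (names == "O"))[0]
    psi_mask = post_mask.copy()
    psi_mask[hinge_o_idx] = True  # the hinge carbonyl O follows a psi rotation
    bend_axis = np.array([1.0, 0.0, 0.0])  # perpendicular to the helix z-axis

    ladder_mask = np.isin(chains, ["T", "N"])
    drift_per_ns = params.translocation_drift

    swap = params.contact_swap
    if swap is not None:
        cand, pa, pb, swap_frame = swap
        nz_idx = np.nonzero((chains == "A") & (resids == cand) & (names == "NZ"))[0][0]
        od1 = {
            r: np.nonzero((chains == "A") & (resids == r) & (names == "OD1"))[0][0]
            for r in (pa, pb)
        }
        cand_ca = np.nonzero((chains == "A") & (resids == cand) & (names == "CA"))[0][0]

    # Water bookkeeping: map shell waters to their centers in planting order.
    water_idx = np.nonzero((chains == "W") & (names == "O"))[0]
    resident_of: dict[int, tuple[int, np.ndarray]] = {}
    transient: list[int] = []
    transient_center: list[int] = []
    cursor = 0
    for shell in params.n_waters:
        c_idx = structure.index_of(shell.center)
        for _ in range(shell.count):
            w = water_idx[cursor]
            cursor += 1
            if shell.resident:
                resident_of[w] = (c_idx, base[w] - base[c_idx])
            else:
                transient.append(w)
                transient_center.append(c_idx)
    # Remaining waters are bulk: static apart from thermal noise.

    noise = (
        rng.normal(0.0, params.noise_sigma, size=(n_frames, n_atoms, 3))
        if params.noise_sigma > 0
        else np.zeros((n_frames, n_atoms, 3))
    )
    # Frame 0 is the exact reference configuration (the "initial structure"
    # every displacement metric is defined against); thermal jitter develops
    # from frame 1 on.
    noise[0] = 0.0
    walk_steps = rng.normal(0.0, 0.4, size=(n_frames, max(len(transient), 1), 3))

    frames = np.empty((n_frames, n_atoms, 3))
    transient_pos = base[transient].copy() if transient else np.zeros((0, 3))
    for k in range(n_frames):
        coords = base.copy()
        t_ns = k * params.frame_interval / 1000.0

        psi_deg = _schedule_value(params.psi_schedule, k)
        if psi_deg != 0.0:
            axis = hinge_c - hinge_ca
            R = rotation_matrix(axis, psi_deg)
            coords[psi_mask] = (R @ (coords[psi_mask] - hinge_ca).T).T + hinge_ca

        bend_deg = _schedule_value(params.bend_schedule, k)
        if bend_deg != 0.0:
            R = rotation_matrix(bend_axis, bend_deg)
            coords[post_mask] = (R @ (coords[post_mask] - hinge_ca).T).T + hinge_ca

        if drift_per_ns != 0.0:
            coords[ladder_mask] += drift_per_ns * t_ns * _TRANSLOCATION_AXIS

        if swap is not None:
            partner = pa if k < swap_frame else pb
            p = coords[od1[partner]]
            direction = coords[cand_ca] - p
            coords[nz_idx] = p + 3.0 * direction / np.linalg.norm(direction)

        for w, (c_idx, offset) in resident_of.items():
            coords[w] = coords[c_idx] + offset

        if transient:
            transient_pos = transient_pos + walk_steps[k, : len(transient)]
            # Reflect at a 20 A sphere about the active-site origin.
            r = np.linalg.norm(transient_pos, axis=1)
            over = r > 20.0
            if np.any(over):
                scale = (2 * 20.0 - r[over]) / r[over]
                transient_pos[over] *= scale[:, None]
            # Visitors are sterically excluded from the occupied inner
            # coordination sphere of their center (2.8 A): they sample the
            # shell but never coordinate.
            cpos = coords[transient_center]
            v = transient_pos - cpos
            d = np.linalg.norm(v, axis=1)
            close = d < 2.8
            if np.any(close):
                transient_pos[close] = (
                    cpos[close] + v[close] * (2.8 / d[close])[:, None]
                )
            coords[transient] = transient_pos

        frames[k] = coords + noise[k]
    return Trajectory(structure, frames, frame_interval=params.frame_interval)


# --- presets mirroring the two trigger-loop ensembles ------------------------

def closed_tec_params(seed: int = 0, n_frames: int = 525, **overrides) -> ToyTECParams:
    """Catalytic-like scenario: slight reverse drift, straight helix, one
    resident water at Mg-I, dehydrated ATP N3, ion pair held on partner A."""
    params = ToyTECParams(
        translocation_drift=-0.2,
        bend_schedule=(),
        n_waters=(WaterShell("M:1:MG", 2.0, 1, resident=True),),
        contact_swap=(1079, 1083, 1072, n_frames),  # never swaps
        n_frames=n_frames,
        seed=seed,
    )
    return replace(params, **overrides)


def open_tec_params(seed: int = 0, n_frames: int = 525, **overrides) -> ToyTECParams:
    """Translocating-like scenario: forward drift (~3 A over the run), an
    early stable ~30 deg bend, three resident waters at Mg-I, hydrated ATP
    N3, ion pair swapped to partner B from the start."""
    params = ToyTECParams(
        translocation_drift=0.3,
        bend_schedule=((25, 30.0),),
        n_waters=(
            WaterShell("M:1:MG", 2.0, 3, resident=True),
            WaterShell("M:3:N3", 3.0, 4, resident=True),
        ),
        contact_swap=(1079, 1083, 1072, 0),  # swapped from frame 0
        n_frames=n_frames,
        seed=seed,
    )
    return replace(params, **overrides)


def toy_downstream_spec(params: ToyTECParams = ToyTECParams()):
    """Translocation vector through the template-strand ends, probing the
    non-template middle (the toy analogue of the downstream DNA/DNA vector)."""
    from .translocation import TranslocationVectorSpec

    L = params.duplex_length
    return TranslocationVectorSpec(
        anchor_a="T:1:C3'", anchor_b=f"T:{L}:C3'", probe=f"N:{L // 2}:C3'",
        label="downstream",
    )


def toy_upstream_spec(params: ToyTECParams = ToyTECParams()):
    """Companion vector probing the template middle (upstream analogue)."""
    from .translocation import TranslocationVectorSpec

    L = params.duplex_length
    return TranslocationVectorSpec(
        anchor_a="N:1:C3'", anchor_b=f"N:{L}:C3'", probe=f"T:{L // 2}:C3'",
        label="upstream",
    )


def toy_hinge(params: ToyTECParams = ToyTECParams()):
    """HingeDefinition splitting the toy helix at its hinge residue."""
    from .hinge_dynamics import HingeDefinition

    first = _HELIX_FIRST_RESID
    last = first + params.helix_length - 1
    h = params.hinge_position
    return HingeDefinition(
        name="toy", chain="A", residues=(h, h),
        flank_pre=(first, h - 2), flank_post=(h + 2, last),
    )


# --- ideal beta sheet for secondary-structure validation ---------------------

def build_beta_sheet(n_per_strand: int = 8) -> Structure:
    """Two ideal antiparallel beta strands with in-register backbone H-bonds.

    Strand geometry comes from extended torsions (phi -139, psi 135); the
    second strand's rigid placement is refined numerically so the
    antiparallel N-H...O=C registry hits the canonical 2.9 A N-O distance.
    Deterministic (no randomness).
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    n = n_per_strand
    bb1 = build_backbone([-139.0] * n, [135.0] * n)

    def transform(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        t = x[3:]
        return {k: (R @ v.T).T + t for k, v in bb1.items()}

    # Antiparallel registry: strand1 residue i pairs with strand2 residue
    # n-1-i; H-bonded pairs at even i carry both N(i)->O(j) and N(j)->O(i).
    pairs = [(i, n - 1 - i) for i in range(n)]

    def objective(x):
        bb2 = transform(x)
        cost = 0.0
        for i, j in pairs:
            cost += (np.linalg.norm(bb1["CA"][i] - bb2["CA"][j]) - 5.0) ** 2
            if i % 2 == 0:
                cost += (np.linalg.norm(bb1["N"][i] - bb2["O"][j]) - 2.9) ** 2
                cost += (np.linalg.norm(bb2["N"][j] - bb1["O"][i]) - 2.9) ** 2
        return cost

    # Start: flip 180 deg about z (reverses the strand direction) and offset
    # sideways by a sheet spacing.
    x0 = np.concatenate([np.pi * np.array([0.0, 0.0, 1.0]),
                         bb1["CA"].mean(axis=0) * 2 + np.array([0.0, 4.8, 0.0])])
    best = None
    for dy in (4.2, 4.8, 5.4):
        x_try = x0.copy()
        x_try[4] = bb1["CA"].mean(axis=0)[1] * 2 + dy
        res = minimize(objective, x_try, method="Nelder-Mead",
                       options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    bb2 = transform(best.x)

    atoms, coords = [], []
    serial = 0
    for chain, bb in (("A", bb1), ("B", bb2)):
        for i in range(n):
            for name in ("N", "CA", "C", "O"):
                serial += 1
                atoms.append(Atom(serial=serial, name=name, resname="ALA",
                                  chain=chain, resid=i + 1, element=name[:1]))
                coords.append(bb[name][i])
    return Structure(atoms, np.array(coords), title="ideal antiparallel sheet")


# --- assay simulation --------------------------------------------------------

def simulate_assay(params: AssaySimParams = AssaySimParams()):
    """Synthetic runoff courses and gel band tables with planted truths.

    Returns ``(runoff_courses, band_tables)``.  Runoff fractions follow
    ``A (1 - exp(-k t)) + eps`` clipped to [0, 1]; competition lanes sample
    misincorporation binomially; exonuclease III lanes scatter around the
    planted pre/post fractions.  With all noise parameters at zero the
    planted values are recovered exactly by the corresponding fits.
    """
    rng = np.random.default_rng(params.seed)
    courses = []
    for rep in range(params.replicates):
        t = np.asarray(params.times, dtype=float)
        y = params.amplitude * (1.0 - np.exp(-params.true_k * t))
        if params.noise_sigma > 0:
            y = y + rng.normal(0.0, params.noise_sigma, size=t.shape)
        courses.append(
            RunoffCourse(times=t, runoff_fraction=np.clip(y, 0.0, 1.0),
                         enzyme=f"wt_rep{rep + 1}")
        )

    tables = []
    for rep in range(params.replicates):
        errors = rng.binomial(params.n_molecules, params.misincorporation_p)
        tables.append(
            BandTable(
                lane=f"fidelity_rep{rep + 1}",
                bands={"G10": float(params.n_molecules - errors), "A*10": float(errors)},
            )
        )
    for label, post in (("minusNTP", params.post_without_ntp),
                        ("plusNTP", params.post_with_ntp)):
        for rep in range(params.replicates):
            scale = 1000.0
            mult = (
                np.exp(rng.normal(0.0, params.band_noise, size=2))
                if params.band_noise > 0
                else np.ones(2)
            )
            tables.append(
                BandTable(
                    lane=f"exo3_{label}_rep{rep + 1}",
                    bands={
                        "pre": float(scale * (1.0 - post) * mult[0]),
                        "post": float(scale * post * mult[1]),
                    },
                )
            )
    return courses, tables
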