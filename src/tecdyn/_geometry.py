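"""Low-level vector geometry shared across modules.

All coordinates are in Angstrom, all angles in degrees unless a name says
otherwise.  Nothing here knows about atoms or residues; inputs are plain
numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "rotation_matrix",
    "dihedral",
    "angle_at",
    "place_atom",
    "build_backbone",
    "kabsch",
    "fibonacci_sphere",
]

# Canonical peptide-backbone internal coordinates (Engh & Huber averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def wrap_angle(deg):
    """Wrap an angle (or array of angles) into the half-open interval (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    # np.mod maps exact multiples to -180; the convention here keeps +180.
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(deg) or np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about ``axis`` (Rodrigues formula)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis has zero length")
    x, y, z = axis / n
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of the four points in degrees, in (-180, 180].

    Standard IUPAC sign convention: looking down the p1->p2 axis, a clockwise
    rotation of p3 relative to p0 is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_angle(np.degrees(np.arctan2(-y, x)))


def angle_at(a, b, c) -> float:
    """Planar angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth point from three predecessors and internal coordinates.

    NeRF construction: the new point d satisfies |d-c| = bond, angle(b,c,d) =
    angle_deg and dihedral(a,b,c,d) = torsion_deg.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(phis, psis, omegas=None):
    """Build an ideal polypeptide backbone from torsion lists.

    Returns a dict with (n, 3) arrays for N, CA, C, O.  ``phis[0]`` is unused
    (the first residue has no preceding carbonyl); omega defaults to 180 for
    every peptide bond.  Canonical alpha-helix torsions (-57, -47) yield the
    textbook 1.5 A rise / 100 deg twist helix.
    """
    phis = list(phis)
    psis = list(psis)
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phi and psi lists must have equal length")
    if omegas is None:
        omegas = [180.0] * n_res
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))

    # Seed the first residue in the xy-plane.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    for i in range(n_res - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND_C_N, ANGLE_CA_C_N, psis[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND_N_CA, ANGLE_C_N_CA, omegas[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANGLE_N_CA_C, phis[i + 1])
    for i in range(n_res):
        # Carbonyl O anti to the next amide N (torsion psi - 180).
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psis[i] - 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (R, t, rmsd) with det(R) = +1 such that mobile @ R.T + t best
    fits reference in the least-squares sense.  Raises ValueError for fewer
    than three points or a collinear/degenerate point set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # Collinear sets have (at least) two vanishing covariance singular values
    # in one of the point clouds, making the rotation under-determined.
    if np.linalg.matrix_rank(P, tol=1e-8) < 2 or np.linalg.matrix_rank(Q, tol=1e-8) < 2:
        raise ValueError("degenerate fit: atoms are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    if n <= 0:
        return np.zeros((0, 3))
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - y * y))
    return np.column_stack([r * np.cos(phi), y, r * np.sin(phi)])
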