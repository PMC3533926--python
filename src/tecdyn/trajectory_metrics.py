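"""Superposition, RMSD series and inter-atom distance monitors.

These are the convergence and catalytic-geometry diagnostics for elongation
complex trajectories: RMSD of protein or nucleic-acid subsets against a
reference frame, and distance monitors such as the RNA 3'-O to NTP
alpha-phosphate separation or the Mg-I/Mg-II distance that report whether an
active site retains catalytic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import kabsch
from .io_model import AtomSelection, Structure, Trajectory, select

__all__ = ["SeriesResult", "superpose", "rmsd_series", "distance_series"]


@dataclass
class SeriesResult:
    """A per-frame scalar time series (times in ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ps": self.times, "value": self.values, "label": self.label}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _resolve(structure: Structure, selection) -> np.ndarray:
    """Accept a selection expression, AtomSelection or index array."""
    if isinstance(selection, str):
        sel = select(structure, selection)
        idx = sel.resolved
    elif isinstance(selection, AtomSelection):
        idx = selection.resolved
    else:
        idx = np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise ValueError(f"selection resolves to no atoms: {selection!r}")
    return idx


def superpose(mobile: np.ndarray, reference: np.ndarray, fit_selection=None):
    """Least-squares rigid superposition of mobile onto reference.

    ``fit_selection`` (optional index array) restricts the atoms used for the
    fit; the returned transform applies to full coordinate sets.  Returns
    (R, t, rmsd) with a proper rotation (det +1); the RMSD is over the fit
    atoms after transformation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_selection is not None:
        idx = np.asarray(fit_selection, dtype=int)
        return kabsch(mobile[idx], reference[idx])
    return kabsch(mobile, reference)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    fit_selection: str = "element C and name CA",
    measure_selection=None,
) -> SeriesResult:
    """RMSD of ``measure_selection`` per frame after fitting on ``fit_selection``.

    The fit and measure sets may differ, e.g. fit on the protein backbone and
    measure nucleic-acid mobility.  ``measure_selection`` defaults to the fit
    selection.
    """
    top = traj.topology
    fit_idx = _resolve(top, fit_selection)
    meas_idx = fit_idx if measure_selection is None else _resolve(top, measure_selection)
    ref = traj.frames[reference_frame]
    values = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        R, t, _ = kabsch(traj.frames[k][fit_idx], ref[fit_idx])
        moved = (R @ traj.frames[k][meas_idx].T).T + t
        values[k] = np.sqrt(np.mean(np.sum((moved - ref[meas_idx]) ** 2, axis=1)))
    return SeriesResult(times=traj.times, values=values, label="rmsd_A")


def distance_series(traj: Trajectory, atom_a: str, atom_b: str) -> SeriesResult:
    """Euclidean distance between two atoms, per frame (A).

    Atoms are addressed by ``"chain:resid:name"`` keys; a missing atom raises
    KeyError naming it.  Symmetric in argument order.
    """
    ia = traj.topology.index_of(atom_a)
    ib = traj.topology.index_of(atom_b)
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    return SeriesResult(times=traj.times, values=d, label=f"dist({atom_a},{atom_b})_A")
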