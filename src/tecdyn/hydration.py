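"""Active-site hydration: shell water counts and tightly bound waters.

Trigger-loop closing is expected to exclude water from the polymerase active
site; these monitors quantify that by counting water molecules within a shell
of a named center (the NTP adenine N3, the RNA 3'-O, or the catalytic Mg-I)
per frame, and by flagging waters that stay within an inner coordination
shell for a large fraction of the run ("tightly bound").

A water's position is its O atom — standard practice and robust to inputs
without hydrogens.  Default cutoffs follow first-solvation-shell (3.5 A) and
Mg inner-sphere (2.5 A) conventions; the residence-based bound-water
definition (within ``bound_cutoff`` in at least ``residence_min`` of sampled
frames) is this package's operational definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import Structure, Trajectory
from .trajectory_metrics import SeriesResult

__all__ = ["HydrationParams", "water_count", "hydration_series", "bound_waters"]


@dataclass(frozen=True)
class HydrationParams:
    shell_cutoff: float = 3.5  # A, water O to center
    bound_cutoff: float = 2.5  # A, inner (Mg coordination) shell
    residence_min: float = 0.8  # fraction of sampled frames

    def __post_init__(self):
        if self.bound_cutoff > self.shell_cutoff:
            raise ValueError("bound_cutoff must not exceed shell_cutoff")
        if not (0 < self.residence_min <= 1):
            raise ValueError("residence_min must be in (0, 1]")


def _water_oxygens(structure: Structure):
    """(residue keys, atom indices) of water oxygens, in topology order."""
    keys, idx = [], []
    for i, a in enumerate(structure.atoms):
        if a.is_water and a.name.startswith("O"):
            keys.append(f"{a.chain}:{a.resid_key}")
            idx.append(i)
    return keys, np.array(idx, dtype=int)


def water_count(frame: Structure, center: str, cutoff: float = 3.5) -> int:
    """Number of distinct water residues whose O lies within ``cutoff`` of the
    center atom (key ``"chain:resid:name"``)."""
    c = frame.position(center)
    keys, idx = _water_oxygens(frame)
    if len(idx) == 0:
        return 0
    d = np.linalg.norm(frame.coords[idx] - c, axis=1)
    return int(len({k for k, dist in zip(keys, d) if dist <= cutoff}))


def hydration_series(
    traj: Trajectory, center: str, cutoff: float = 3.5, stride: int = 1
) -> SeriesResult:
    """Shell water count per sampled frame."""
    ci = traj.topology.index_of(center)
    keys, idx = _water_oxygens(traj.topology)
    sampled = range(0, traj.n_frames, stride)
    values = np.zeros(len(sampled))
    for out_k, k in enumerate(sampled):
        if len(idx):
            d = np.linalg.norm(traj.frames[k][idx] - traj.frames[k][ci], axis=1)
            values[out_k] = len({kk for kk, dist in zip(keys, d) if dist <= cutoff})
    times = np.array([k * traj.frame_interval for k in sampled])
    return SeriesResult(times=times, values=values, label=f"waters<{cutoff:g}A({center})")


def bound_waters(
    traj: Trajectory,
    center: str,
    params: HydrationParams = HydrationParams(),
    stride: int = 1,
):
    """Tightly bound waters at a center.

    A water is bound iff its O sits within ``params.bound_cutoff`` of the
    center in at least ``params.residence_min`` of the sampled frames.
    Returns ``(count, {water residue key: residence fraction})`` with the map
    restricted to bound waters, sorted by descending residence.
    """
    ci = traj.topology.index_of(center)
    keys, idx = _water_oxygens(traj.topology)
    sampled = list(range(0, traj.n_frames, stride))
    if len(idx) == 0 or not sampled:
        return 0, {}
    inside = np.zeros(len(idx), dtype=int)
    for k in sampled:
        d = np.linalg.norm(traj.frames[k][idx] - traj.frames[k][ci], axis=1)
        inside += d <= params.bound_cutoff
    residence = inside / len(sampled)
    bound = {
        k: float(r)
        for k, r in zip(keys, residence)
        if r >= params.residence_min
    }
    bound = dict(sorted(bound.items(), key=lambda kv: (-kv[1], kv[0])))
    return len(bound), bound
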