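"""Translocation-vector projection metrics."""

import numpy as np
import pytest

from tecdyn.io_model import Atom, Structure, Trajectory
from tecdyn.synthetic_data import (
    ToyTECParams,
    build_toy_tec,
    simulate_trajectory,
    toy_downstream_spec,
    toy_upstream_spec,
)
from tecdyn.translocation import (
    TranslocationVectorSpec,
    per_basepair_displacement,
    projected_displacement,
    translocation_series,
    translocation_summary,
)

FIT = "chain A and resid 1067-1077 and name CA"  # static pre-hinge flank


def _line_structure(probe_xyz):
    atoms = [
        Atom(1, "C3'", "DA", "T", 1, "C"),
        Atom(2, "C3'", "DA", "T", 2, "C"),
        Atom(3, "C3'", "DT", "N", 1, "C"),
    ]
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], list(probe_xyz)])
    return Structure(atoms, coords)


SPEC = TranslocationVectorSpec("T:1:C3'", "T:2:C3'", "N:1:C3'")


def test_reference_frame_is_exactly_zero():
    ref = _line_structure([5.0, 5.0, 0.0])
    assert projected_displacement(ref, ref, SPEC) == 0.0


def test_collinear_probe_motion():
    ref = _line_structure([5.0, 5.0, 0.0])
    moved = _line_structure([5.0 + 3.4, 5.0, 0.0])
    assert projected_displacement(moved, ref, SPEC) == pytest.approx(3.4)


def test_orthogonal_probe_motion_reads_zero():
    ref = _line_structure([5.0, 5.0, 0.0])
    moved = _line_structure([5.0, 9.0, -2.0])
    assert projected_displacement(moved, ref, SPEC) == pytest.approx(0.0, abs=1e-12)


def test_projection_matches_hand_rolled_dot_product():
    """Independent scalar arithmetic oracle over random displacements."""
    rng = np.random.default_rng(9)
    ref = _line_structure([5.0, 5.0, 0.0])
    u = [1.0, 0.0, 0.0]  # anchors are unit-spaced on x
    for _ in range(100):
        v = rng.normal(size=3) * 3
        moved = _line_structure([5.0 + v[0], 5.0 + v[1], v[2]])
        want = sum(vi * ui for vi, ui in zip(v, u))
        assert projected_displacement(moved, ref, SPEC) == pytest.approx(want, abs=1e-12)


def test_degenerate_axis_raises():
    atoms = [Atom(1, "C3'", "DA", "T", 1, "C"), Atom(2, "C3'", "DA", "T", 2, "C"),
             Atom(3, "C3'", "DT", "N", 1, "C")]
    coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]])
    s = Structure(atoms, coords)
    with pytest.raises(ValueError, match="degenerate"):
        projected_displacement(s, s, SPEC)


def test_antisymmetry_under_anchor_swap():
    ref = _line_structure([5.0, 5.0, 0.0])
    moved = _line_structure([7.2, 4.0, 1.0])
    fwd = projected_displacement(moved, ref, SPEC)
    rev = projected_displacement(
        moved, ref, TranslocationVectorSpec("T:2:C3'", "T:1:C3'", "N:1:C3'")
    )
    assert fwd == pytest.approx(-rev)


def test_static_trajectory_all_zero(static_traj):
    pts = translocation_series(static_traj, toy_downstream_spec(), fit_selection=FIT)
    assert all(p.downstream == pytest.approx(0.0, abs=1e-9) for p in pts)


def test_linear_drift_slope_recovered():
    p = ToyTECParams(n_frames=100, noise_sigma=0.0, translocation_drift=0.3, seed=5)
    traj = simulate_trajectory(build_toy_tec(p), p)
    pts = translocation_series(traj, toy_downstream_spec(p), toy_upstream_spec(p),
                               fit_selection=FIT)
    t_ns = np.array([q.time for q in pts]) / 1000.0
    slope = np.polyfit(t_ns, [q.downstream for q in pts], 1)[0]
    assert slope == pytest.approx(0.3, rel=0.02)


def test_drift_orthogonal_to_axis_reads_zero():
    """Move the ladder perpendicular to the vector: metric stays at noise level."""
    sigma = 0.05
    p = ToyTECParams(n_frames=60, noise_sigma=sigma, seed=6)
    s = build_toy_tec(p)
    traj = simulate_trajectory(s, p)
    frames = traj.frames.copy()
    ladder = np.isin(s.chains, ["T", "N"])
    for k in range(60):
        frames[k][ladder] += np.array([0.0, 0.0, 0.02 * k])  # orthogonal drift
    traj2 = Trajectory(s, frames, 20.0)
    pts = translocation_series(traj2, toy_downstream_spec(p),
                               fit_selection="chain A and name CA")
    values = np.array([q.downstream for q in pts])
    assert np.all(np.abs(values) < 4 * sigma)  # pointwise at noise level
    assert np.mean(values) == pytest.approx(0.0, abs=3 * sigma / np.sqrt(len(values)))


def test_summary_means_and_endpoint():
    from tecdyn.translocation import TranslocationPoint

    one = [TranslocationPoint(0.0, 1.0, 2.0)]
    up, down, end = translocation_summary(one)
    assert (up, down) == (1.0, 2.0) and end.downstream == 2.0
    alternating = [TranslocationPoint(20.0 * i, (-1) ** i * 0.7, (-1) ** i * 1.3)
                   for i in range(10)]
    up, down, _ = translocation_summary(alternating)
    assert up == pytest.approx(0.0) and down == pytest.approx(0.0)
    with pytest.raises(ValueError):
        translocation_summary([])


def test_planted_open_tec_means_recovered():
    """A run planted at ~3 A downstream drift ends near 3 A; the trailing-
    window mean tracks the planted trajectory position to 0.1 A."""
    p = ToyTECParams(n_frames=500, noise_sigma=0.1, translocation_drift=0.3, seed=8)
    traj = simulate_trajectory(build_toy_tec(p), p)
    # No hinge schedule here, so the whole helix serves as the rigid core.
    pts = translocation_series(traj, toy_downstream_spec(p), toy_upstream_spec(p),
                               fit_selection="chain A and name CA")
    _, down, end = translocation_summary(pts, window=50)
    t_window = np.array([q.time for q in pts[-50:]]) / 1000.0
    planted = 0.3 * t_window.mean()
    assert down == pytest.approx(planted, abs=0.1)
    # The endpoint is a single noisy frame: allow a 4-sigma excursion.
    assert end.downstream == pytest.approx(0.3 * pts[-1].time / 1000.0, abs=0.4)


def test_per_basepair_displacement():
    p = ToyTECParams(n_frames=1, noise_sigma=0.0, duplex_length=6)
    s = build_toy_tec(p)
    pairs = [(f"T:{i}:C3'", f"N:{i}:C3'") for i in range(1, 7)]
    spec = toy_downstream_spec(p)
    assert per_basepair_displacement(s, s, pairs, spec) == [0.0] * 6

    moved = s.with_coords(s.coords.copy())
    i3 = [s.index_of(k) for k in pairs[2]]
    moved.coords[i3] += np.array([3.4, 0.0, 0.0])
    vals = per_basepair_displacement(moved, s, pairs, spec)
    assert vals[2] == pytest.approx(3.4)
    assert all(v == pytest.approx(0.0) for i, v in enumerate(vals) if i != 2)

    # Rigid shift of every pair: all values equal dot(shift, u).
    rng = np.random.default_rng(3)
    shift = rng.normal(size=3)
    shifted = s.with_coords(s.coords + shift)
    vals = per_basepair_displacement(shifted, s, pairs, spec)
    u = spec.axis(s)
    want = float(np.dot(shift, u))
    assert all(v == pytest.approx(want, abs=1e-9) for v in vals)

    with pytest.raises(KeyError, match="T:99"):
        per_basepair_displacement(s, s, [("T:99:C3'", "N:1:C3'")], spec)


def test_metric_invariant_to_orthogonal_probe_offset():
    rng = np.random.default_rng(4)
    ref = _line_structure([5.0, 5.0, 0.0])
    for _ in range(20):
        v = rng.normal(size=3)
        base = projected_displacement(
            _line_structure(np.array([5.0, 5.0, 0.0]) + v), ref, SPEC
        )
        ortho = np.array([0.0, *rng.normal(size=2)])  # u is +x
        offset = projected_displacement(
            _line_structure(np.array([5.0, 5.0, 0.0]) + v + ortho), ref, SPEC
        )
        assert offset == pytest.approx(base, abs=1e-12)
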