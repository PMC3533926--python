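import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tecdyn.synthetic_data import ToyTECParams, WaterShell, build_toy_tec, simulate_trajectory


@pytest.fixture(scope="session")
def small_params():
    """A compact but fully featured toy-TEC scenario."""
    return ToyTECParams(
        n_frames=40,
        noise_sigma=0.05,
        translocation_drift=0.3,
        bend_schedule=((10, 30.0),),
        n_waters=(
            WaterShell("M:1:MG", 2.0, 3, resident=True),
            WaterShell("M:3:N3", 3.0, 2, resident=False),
        ),
        contact_swap=(1079, 1083, 1072, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_structure(small_params):
    return build_toy_tec(small_params)


@pytest.fixture(scope="session")
def small_traj(small_structure, small_params):
    return simulate_trajectory(small_structure, small_params)


@pytest.fixture(scope="session")
def static_traj():
    """Noise-free, schedule-free trajectory: every frame equals frame 0."""
    p = ToyTECParams(n_frames=8, noise_sigma=0.0, seed=3)
    return simulate_trajectory(build_toy_tec(p), p)


def random_test_structure(seed, n_res=12, with_waters=True):
    """A random mixed protein/water/ion structure for oracle tests.

    Residues carry real donor/acceptor/charge-bearing names at random
    positions so that contact and hydration code paths all fire.
    """
    from tecdyn.io_model import Atom, Structure

    rng = np.random.default_rng(seed)
    resnames = ["LYS", "ASP", "ARG", "GLU", "SER", "ALA", "HIS", "THR"]
    sidechain = {
        "LYS": ["NZ"], "ASP": ["OD1", "OD2"], "ARG": ["NE", "NH1", "NH2"],
        "GLU": ["OE1", "OE2"], "SER": ["OG"], "ALA": [], "HIS": ["ND1", "NE2"],
        "THR": ["OG1"],
    }
    atoms, coords = [], []
    serial = 0
    for resid in range(1, n_res + 1):
        resname = resnames[int(rng.integers(len(resnames)))]
        center = rng.uniform(-8, 8, 3)
        for name in ["N", "CA", "C", "O"] + sidechain[resname]:
            serial += 1
            atoms.append(Atom(serial=serial, name=name, resname=resname,
                              chain="A", resid=resid, element=name[:1]))
            coords.append(center + rng.uniform(-1.2, 1.2, 3))
    serial += 1
    atoms.append(Atom(serial=serial, name="MG", resname="MG", chain="M",
                      resid=1, element="MG", het=True))
    coords.append(rng.uniform(-8, 8, 3))
    if with_waters:
        for w in range(1, 13):
            serial += 1
            atoms.append(Atom(serial=serial, name="O", resname="HOH", chain="W",
                              resid=w, element="O", het=True))
            coords.append(rng.uniform(-9, 9, 3))
    return Structure(atoms, np.array(coords))
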