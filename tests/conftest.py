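import numpy as np
import pytest

from conjscan.fmo_energetics import Fragment, FragmentScheme
from conjscan.traj_io import Frame, Trajectory


@pytest.fixture
def water_frame():
    return Frame(
        index=0, time=0.0, elements=["O", "H", "H"],
        coords=np.array([[0.0, 0.0, 0.0],
                         [0.9572, 0.0, 0.0],
                         [-0.2399, 0.9266, 0.0]]),
    )


@pytest.fixture
def two_frame_traj(water_frame):
    second = Frame(index=1, time=0.05, elements=list(water_frame.elements),
                   coords=water_frame.coords + 0.1)
    return Trajectory(frames=[water_frame, second])


def make_traj(n_frames, spacing=0.05, n_atoms=3, seed=0, start_at_spacing=True):
    """Synthetic trajectory; frame times start at the native spacing."""
    rng = np.random.default_rng(seed)
    elements = ["C"] * n_atoms
    t0 = spacing if start_at_spacing else 0.0
    frames = [
        Frame(index=i, time=t0 + i * spacing, elements=elements,
              coords=rng.uniform(-5, 5, size=(n_atoms, 3)))
        for i in range(n_frames)
    ]
    return Trajectory(frames=frames)


@pytest.fixture
def mini_scheme():
    """Rh + Cp* pseudo-site, three 3-atom waters, benzene-like X with a
    phenolic O-H; atom indices mirror the toy-system layout."""
    ring = list(range(11, 17))
    return FragmentScheme(
        fragments={
            1: Fragment([0, 1], "CpRh-scaffold"),
            2: Fragment([2, 3, 4], "wat1"),
            3: Fragment([5, 6, 7], "wat2"),
            4: Fragment([8, 9, 10], "wat3"),
            5: Fragment(ring + [17, 18], "X"),
        },
        rh_index=0,
        rings={"phenyl": ring},
        heteroatoms={17: "O"},
        water_oxygens=[2, 5, 8],
        donors=[(17, 18), (2, 3), (2, 4), (5, 6), (5, 7), (8, 9), (8, 10)],
        acceptors=[17, 2, 5, 8],
    )


def place_frame(distmap, n_atoms=19, rh=0):
    """Frame with chosen atoms at given distances from Rh (at origin),
    every unspecified atom far away (20 Å), distinct directions."""
    rng = np.random.default_rng(42)
    coords = np.zeros((n_atoms, 3))
    for a in range(1, n_atoms):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        coords[a] = u * distmap.get(a, 20.0)
    elements = ["Rh"] + ["C"] * (n_atoms - 1)
    return Frame(index=0, time=0.0, elements=elements, coords=coords)
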