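import numpy as np
import pytest

from mcshape import VoxelMask
from mcshape.simulate import PhantomSpec, make_phantom

# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def heron_area(vertices, triangles):
    """Mesh area via Heron's formula from side lengths only."""
    total = 0.0
    for i, j, k in triangles:
        a = np.linalg.norm(vertices[j] - vertices[i])
        b = np.linalg.norm(vertices[k] - vertices[j])
        c = np.linalg.norm(vertices[i] - vertices[k])
        s = (a + b + c) / 2.0
        total += np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
    return total


def brute_force_diameter(points):
    """O(n^2) all-pairs maximum distance."""
    pts = np.asarray(points, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        d = np.linalg.norm(pts[i + 1 :] - pts[i], axis=1)
        if len(d):
            best = max(best, d.max())
    return best


def brute_force_tau_b(x, y):
    """Kendall tau-b by direct concordant/discordant/tie counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    conc = disc = tx = ty = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def sphere_mask():
    """Solid sphere, r = 10 mm, isotropic 0.5 mm spacing."""
    return make_phantom(PhantomSpec(semi_axes=(10.0, 10.0, 10.0), spacing=(0.5, 0.5, 0.5)))


@pytest.fixture(scope="session")
def ellipsoid_mask():
    """Axis-aligned solid ellipsoid, semi-axes (20, 12, 8) mm, 0.25 mm spacing."""
    return make_phantom(PhantomSpec(semi_axes=(20.0, 12.0, 8.0), spacing=(0.25, 0.25, 0.25)))


@pytest.fixture
def single_voxel_mask():
    occ = np.zeros((3, 3, 3), dtype=bool)
    occ[1, 1, 1] = True
    return VoxelMask(occ, (1.0, 1.0, 1.0))


@pytest.fixture
def block_mask():
    """2x2x2 occupied block inside a margin."""
    occ = np.zeros((6, 6, 6), dtype=bool)
    occ[2:4, 2:4, 2:4] = True
    return VoxelMask(occ, (1.0, 1.0, 1.0))
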