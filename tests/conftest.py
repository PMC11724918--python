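import numpy as np
import pytest

import spherogen as sg


@pytest.fixture(scope="session")
def small_phantom():
    """20-cell spheroid phantom in a 32^3 box (session-cached)."""
    spec = sg.PhantomSpec(shape=(32, 32, 32), sphere_radius=13, n_cells=20, seed=1)
    return sg.make_phantom_spheroid(spec)


@pytest.fixture(scope="session")
def placement_phantom():
    """50-cell spheroid phantom at realistic cell scale (session-cached)."""
    spec = sg.PhantomSpec(shape=(64, 64, 64), sphere_radius=28, n_cells=50, seed=1)
    return sg.make_phantom_spheroid(spec)


@pytest.fixture(scope="session")
def prototypes():
    spec = sg.PhantomSpec(seed=1)
    return sg.make_phantom_prototypes(spec)


def brute_force_counts(lattice, offsets):
    """Independent recount of per-cell volume/area and contact pairs.

    Pure-numpy oracle mirroring the energy definition: A[i] counts
    unlike neighbour pairs with one end in cell i (out-of-box neighbours
    are medium); cc/cm are unordered pair counts.
    """
    lattice = np.asarray(lattice)
    n_labels = int(lattice.max()) + 1
    V = np.bincount(lattice.ravel(), minlength=n_labels)
    V[0] = 0
    A = np.zeros(n_labels, dtype=np.int64)
    cc = 0.0
    cm = 0.0
    nz, ny, nx = lattice.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = lattice[z, y, x]
                for dz, dy, dx in offsets:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        c = lattice[zz, yy, xx]
                        if c != a:
                            if a != 0:
                                A[a] += 1
                            if a != 0 and c != 0:
                                cc += 0.5
                            else:
                                cm += 0.5
                    elif a != 0:
                        A[a] += 1
                        cm += 1.0
    return V, A, cc, cm
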