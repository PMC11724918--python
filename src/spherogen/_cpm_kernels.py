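"""Numba kernels for the 3D Cellular Potts lattice.

Conventions shared with :mod:`spherogen.cpm`:

* lattice values are cell ids, 0 = medium; sites outside the box count
  as medium (fixed, no-flux walls);
* contact tallies ``cc2``/``cm2`` are *doubled* pair counts for
  in-bounds unordered unlike pairs (each pair is seen once from each
  end during a full scan) while a pair with a virtual outside site is
  counted with weight 2 directly, so the contact energy is
  ``J_cc * cc2 / 2 + J_cm * cm2 / 2``;
* ``A[i]`` counts unlike neighbour pairs with one end in cell ``i`` at
  the contact neighbour order (virtual outside sites included).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# max distinct labels a single flip can touch: a, b and <= 32 neighbours
_MAX_TOUCHED = 40


def neighbor_offsets(order: int) -> np.ndarray:
    """Neighbour shells by squared Euclidean distance (CompuCell3D convention).

    Order ``k`` collects all integer offsets with squared distance in
    ``{1, ..., k}``: 6 / 18 / 26 / 32 neighbours for orders 1-4.
    """
    if order < 1:
        raise ValueError("neighbor order must be >= 1")
    offs = []
    reach = int(np.ceil(np.sqrt(order)))
    for dz in range(-reach, reach + 1):
        for dy in range(-reach, reach + 1):
            for dx in range(-reach, reach + 1):
                d2 = dz * dz + dy * dy + dx * dx
                if 1 <= d2 <= order:
                    offs.append((dz, dy, dx))
    return np.array(offs, dtype=np.int64)


@njit(cache=True)
def recount(lattice, offs, n_labels):
    """Brute-force (V, A, cc2, cm2) from the lattice alone."""
    nz, ny, nx = lattice.shape
    V = np.zeros(n_labels, dtype=np.int64)
    A = np.zeros(n_labels, dtype=np.int64)
    cc2 = np.int64(0)
    cm2 = np.int64(0)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = lattice[z, y, x]
                if a != 0:
                    V[a] += 1
                for k in range(offs.shape[0]):
                    zz = z + offs[k, 0]
                    yy = y + offs[k, 1]
                    xx = x + offs[k, 2]
                    if zz < 0 or zz >= nz or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                        if a != 0:  # pair with a virtual medium site, seen once
                            A[a] += 1
                            cm2 += 2
                    else:
                        c = lattice[zz, yy, xx]
                        if c != a:
                            if a != 0:
                                A[a] += 1
                            if a != 0 and c != 0:
                                cc2 += 1  # unordered pair seen twice in the scan
                            else:
                                cm2 += 1
    return V, A, cc2, cm2


@njit(cache=True)
def _acc(labs, dA, nlab, lab, delta):
    for i in range(nlab):
        if labs[i] == lab:
            dA[i] += delta
            return nlab
    labs[nlab] = lab
    dA[nlab] = delta
    return nlab + 1


@njit(cache=True)
def flip_delta(lattice, V, A, Vt, At, lam_V, lam_A, J_cc, J_cm,
               offs, z, y, x, b, labs, dA):
    """Incremental energy change of setting site (z,y,x) to label b.

    Fills ``labs[:nlab]`` / ``dA[:nlab]`` with the per-label area-count
    changes needed to commit the flip; returns (dH, dcc2, dcm2, nlab).
    """
    nz, ny, nx = lattice.shape
    a = lattice[z, y, x]
    nlab = 0
    dcc2 = np.int64(0)
    dcm2 = np.int64(0)
    for k in range(offs.shape[0]):
        zz = z + offs[k, 0]
        yy = y + offs[k, 1]
        xx = x + offs[k, 2]
        if zz < 0 or zz >= nz or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
            if a != 0:
                nlab = _acc(labs, dA, nlab, a, -1)
                dcm2 -= 2
            if b != 0:
                nlab = _acc(labs, dA, nlab, b, 1)
                dcm2 += 2
        else:
            c = lattice[zz, yy, xx]
            if c != a:
                if a != 0:
                    nlab = _acc(labs, dA, nlab, a, -1)
                if c != 0:
                    nlab = _acc(labs, dA, nlab, c, -1)
                if a != 0 and c != 0:
                    dcc2 -= 2
                else:
                    dcm2 -= 2
            if c != b:
                if b != 0:
                    nlab = _acc(labs, dA, nlab, b, 1)
                if c != 0:
                    nlab = _acc(labs, dA, nlab, c, 1)
                if b != 0 and c != 0:
                    dcc2 += 2
                else:
                    dcm2 += 2
    dH = J_cc * dcc2 * 0.5 + J_cm * dcm2 * 0.5
    if a != 0:
        v = np.float64(V[a])
        dH += lam_V * ((v - 1.0 - Vt[a]) ** 2 - (v - Vt[a]) ** 2)
    if b != 0:
        v = np.float64(V[b])
        dH += lam_V * ((v + 1.0 - Vt[b]) ** 2 - (v - Vt[b]) ** 2)
    for i in range(nlab):
        lab = labs[i]
        aa = np.float64(A[lab])
        dH += lam_A * ((aa + dA[i] - At[lab]) ** 2 - (aa - At[lab]) ** 2)
    return dH, dcc2, dcm2, nlab


@njit(cache=True)
def commit_flip(lattice, V, A, labs, dA, nlab, z, y, x, b):
    a = lattice[z, y, x]
    lattice[z, y, x] = b
    if a != 0:
        V[a] -= 1
    if b != 0:
        V[b] += 1
    for i in range(nlab):
        A[labs[i]] += dA[i]


@njit(cache=True)
def run_attempts(lattice, V, A, Vt, At, lam_V, lam_A, J_cc, J_cm, T,
                 potts_offs, contact_offs, n_attempts, seed, tallies,
                 uniform_labels, n_labels):
    """n_attempts Metropolis site-update attempts (one MCS = lattice size).

    ``tallies`` is int64[3]: doubled cell-cell pairs, doubled cell-medium
    pairs, accepted-flip counter (updated in place).  ``uniform_labels``
    selects the symmetric uniform-label proposal used for equilibrium
    validation instead of the default copy-from-neighbour kernel.
    """
    np.random.seed(seed)
    nz, ny, nx = lattice.shape
    labs = np.empty(_MAX_TOUCHED, dtype=np.int64)
    dA = np.zeros(_MAX_TOUCHED, dtype=np.int64)
    for _ in range(n_attempts):
        z = np.random.randint(0, nz)
        y = np.random.randint(0, ny)
        x = np.random.randint(0, nx)
        if uniform_labels:
            b = np.random.randint(0, n_labels)
        else:
            k = np.random.randint(0, potts_offs.shape[0])
            zz = z + potts_offs[k, 0]
            yy = y + potts_offs[k, 1]
            xx = x + potts_offs[k, 2]
            if zz < 0 or zz >= nz or yy < 0 or yy >= ny or xx < 0 or xx >= nx:
                b = np.int64(0)  # copy from the surrounding medium
            else:
                b = lattice[zz, yy, xx]
        a = lattice[z, y, x]
        if b == a:
            continue  # null attempt, still consumes one of the N per-MCS tries
        dH, dcc2, dcm2, nlab = flip_delta(
            lattice, V, A, Vt, At, lam_V, lam_A, J_cc, J_cm,
            contact_offs, z, y, x, b, labs, dA,
        )
        if dH <= 0.0 or np.random.random() < np.exp(-dH / T):
            commit_flip(lattice, V, A, labs, dA, nlab, z, y, x, b)
            tallies[0] += dcc2
            tallies[1] += dcm2
            tallies[2] += 1
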