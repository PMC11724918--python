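"""3D Cellular Potts Model (CPM) of a packed-cell spheroid.

Each lattice site holds a cell id (0 = medium).  The configuration
evolves by Metropolis-accepted label-copy proposals that minimise the
free-energy Hamiltonian

    H = sum_i lambda_V (V_i - V_i^target)^2
      + sum_i lambda_A (A_i - A_i^target)^2
      + sum_{i<j} J_cc A_ij  +  sum_i J_cm A_im

where V_i / A_i are the volume (voxel count) and surface area (unlike
neighbour-pair count at the contact neighbour order) of cell i, A_ij and
A_im are cell-cell and cell-medium contact areas, and the target values
are assigned by a random derangement of the initial actual values: every
cell is pushed away from its own starting shape while the ensemble's
volume/area distribution is preserved.

One Monte Carlo step (MCS) is N site-update attempts, N = lattice size.
Boundaries are fixed walls: sites outside the box count as medium for
contact terms and as medium copy sources.  Cells may shrink to zero
volume; a vanished cell keeps its (now unreachable) target so the energy
stays consistent with incremental updates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _cpm_kernels as K
from .rng import derive_seed
from .volumes import LabelVolume

__all__ = [
    "CPMParams",
    "CPMState",
    "assign_targets",
    "hamiltonian",
    "propose_and_apply",
    "run_mcs",
    "export_borders",
    "rasterize_membrane",
]

log = logging.getLogger("spherogen")


@dataclass
class CPMParams:
    """Potts simulation parameters.

    Defaults are the calibrated values for HT-29 spheroid geometry:
    lambda_V = 10.0, lambda_A = 0.001, J_cc = 2.0, J_cm = 55.0,
    T = 30.0, Potts neighbour order 3, contact neighbour order 4,
    1000 MCS.
    """

    lambda_V: float = 10.0
    lambda_A: float = 0.001
    J_cc: float = 2.0
    J_cm: float = 55.0
    T: float = 30.0
    potts_neighbor_order: int = 3
    contact_neighbor_order: int = 4
    mcs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature T must be > 0")
        if self.potts_neighbor_order < 1 or self.contact_neighbor_order < 1:
            raise ValueError("neighbor orders must be >= 1")
        if self.mcs < 0:
            raise ValueError("mcs must be >= 0")


class CPMState:
    """Lattice plus per-cell caches the Metropolis steps mutate.

    Caches: per-cell volume ``V`` and contact-order area ``A`` (indexed
    by label id), target arrays ``Vt``/``At``, and doubled contact-pair
    tallies ``cc2``/``cm2``.  ``check_consistency`` recounts everything
    from the lattice.
    """

    def __init__(self, lattice: np.ndarray, spacing=(1.0, 1.0, 1.0),
                 contact_neighbor_order: int = 4):
        lattice = np.ascontiguousarray(np.asarray(lattice, dtype=np.int64))
        if lattice.ndim != 3:
            raise ValueError("lattice must be 3D")
        if lattice.size and lattice.min() < 0:
            raise ValueError("negative labels are not allowed")
        self.lattice = lattice
        self.spacing = tuple(float(s) for s in spacing)
        self.contact_neighbor_order = int(contact_neighbor_order)
        self._contact_offs = K.neighbor_offsets(self.contact_neighbor_order)
        self.n_labels = int(lattice.max()) + 1 if lattice.size else 1
        V, A, cc2, cm2 = K.recount(self.lattice, self._contact_offs, self.n_labels)
        self.V = V
        self.A = A
        self.cc2 = int(cc2)
        self.cm2 = int(cm2)
        # default targets: the initial actual values (a near-equilibrium start)
        self.Vt = V.astype(np.float64)
        self.At = A.astype(np.float64)

    @classmethod
    def from_labels(cls, vol: LabelVolume, contact_neighbor_order: int = 4) -> "CPMState":
        return cls(vol.data.copy(), vol.spacing, contact_neighbor_order)

    def to_labels(self) -> LabelVolume:
        return LabelVolume(self.lattice.copy(), self.spacing)

    def copy(self) -> "CPMState":
        new = object.__new__(CPMState)
        new.lattice = self.lattice.copy()
        new.spacing = self.spacing
        new.contact_neighbor_order = self.contact_neighbor_order
        new._contact_offs = self._contact_offs
        new.n_labels = self.n_labels
        new.V = self.V.copy()
        new.A = self.A.copy()
        new.cc2 = self.cc2
        new.cm2 = self.cm2
        new.Vt = self.Vt.copy()
        new.At = self.At.copy()
        return new

    def cell_labels(self) -> np.ndarray:
        """Ids of cells currently holding at least one voxel."""
        return np.flatnonzero(self.V > 0)

    def check_consistency(self) -> bool:
        """True when all caches equal a brute-force recount."""
        V, A, cc2, cm2 = K.recount(self.lattice, self._contact_offs, self.n_labels)
        return (
            np.array_equal(V, self.V)
            and np.array_equal(A, self.A)
            and int(cc2) == self.cc2
            and int(cm2) == self.cm2
        )


def assign_targets(state: CPMState, seed: int) -> CPMState:
    """Set each cell's targets to the initial actuals of another cell.

    The assignment is a uniformly drawn derangement (resampled until no
    fixed point), so every cell gets target values different from its
    own initial values while the multiset of targets equals the multiset
    of initial actuals.  With fewer than two cells this is the identity
    (with a warning).  Mutates and returns *state*.
    """
    cells = state.cell_labels()
    n = len(cells)
    if n < 2:
        warnings.warn("assign_targets needs >= 2 cells; targets left unchanged")
        return state
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            break
    src = cells[perm]
    state.Vt[cells] = state.V[src].astype(np.float64)
    state.At[cells] = state.A[src].astype(np.float64)
    return state


def hamiltonian(state: CPMState, params: CPMParams, from_scratch: bool = False) -> float:
    """Total energy of the current configuration.

    ``from_scratch`` recounts volumes, areas and contact pairs from the
    lattice instead of trusting the incremental caches.
    """
    if from_scratch:
        V, A, cc2, cm2 = K.recount(state.lattice, state._contact_offs, state.n_labels)
    else:
        V, A, cc2, cm2 = state.V, state.A, state.cc2, state.cm2
    dv = V.astype(np.float64) - state.Vt
    da = A.astype(np.float64) - state.At
    dv[0] = 0.0  # medium is unconstrained
    da[0] = 0.0
    return float(
        params.lambda_V * np.sum(dv**2)
        + params.lambda_A * np.sum(da**2)
        + params.J_cc * cc2 / 2.0
        + params.J_cm * cm2 / 2.0
    )


def propose_and_apply(state, params, rng, proposal: str = "copy"):
    """One Metropolis site-update attempt; mutates *state* on acceptance.

    A target site is drawn uniformly; the proposed label is either
    copied from a uniformly drawn neighbour at the Potts neighbour order
    (``proposal="copy"``, out-of-box neighbours are medium) or drawn
    uniformly from the label alphabet (``proposal="uniform"``, the
    symmetric variant used for Boltzmann-equilibrium validation).
    Equal-label proposals are null attempts.  Accepts with probability
    1 when dH <= 0, else exp(-dH / T).

    Returns ``(state, accepted, dH)``.
    """
    nz, ny, nx = state.lattice.shape
    z = int(rng.integers(nz))
    y = int(rng.integers(ny))
    x = int(rng.integers(nx))
    if proposal == "uniform":
        b = int(rng.integers(state.n_labels))
    elif proposal == "copy":
        offs = K.neighbor_offsets(params.potts_neighbor_order)
        k = int(rng.integers(len(offs)))
        zz, yy, xx = z + offs[k, 0], y + offs[k, 1], x + offs[k, 2]
        if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
            b = int(state.lattice[zz, yy, xx])
        else:
            b = 0
    else:
        raise ValueError(f"unknown proposal kind {proposal!r}")
    a = int(state.lattice[z, y, x])
    if b == a:
        return state, False, 0.0
    labs = np.empty(K._MAX_TOUCHED, dtype=np.int64)
    dA = np.zeros(K._MAX_TOUCHED, dtype=np.int64)
    dH, dcc2, dcm2, nlab = K.flip_delta(
        state.lattice, state.V, state.A, state.Vt, state.At,
        params.lambda_V, params.lambda_A, params.J_cc, params.J_cm,
        state._contact_offs, z, y, x, b, labs, dA,
    )
    accept = dH <= 0.0 or rng.random() < np.exp(-dH / params.T)
    if accept:
        K.commit_flip(state.lattice, state.V, state.A, labs, dA, nlab, z, y, x, b)
        state.cc2 += int(dcc2)
        state.cm2 += int(dcm2)
    return state, bool(accept), float(dH)


def delta_h(state: CPMState, params: CPMParams, site, new_label: int) -> float:
    """Incremental energy change of a hypothetical flip (state untouched)."""
    z, y, x = site
    labs = np.empty(K._MAX_TOUCHED, dtype=np.int64)
    dA = np.zeros(K._MAX_TOUCHED, dtype=np.int64)
    dH, _, _, _ = K.flip_delta(
        state.lattice, state.V, state.A, state.Vt, state.At,
        params.lambda_V, params.lambda_A, params.J_cc, params.J_cm,
        state._contact_offs, int(z), int(y), int(x), int(new_label), labs, dA,
    )
    return float(dH)


def run_mcs(state: CPMState, params: CPMParams, snapshot_at=()):
    """Advance *state* by ``params.mcs`` Monte Carlo steps.

    One MCS performs N site-update attempts (N = lattice site count) in
    a compiled batch.  Per-MCS random streams are derived from
    ``params.seed`` and the MCS index, so runs are reproducible and
    independent of snapshot choices.  Snapshots (label volumes) are
    captured after the MCS indices listed in ``snapshot_at``; index 0
    means the starting configuration.

    Returns ``(state, snapshots)`` with snapshots as a list of
    ``(mcs_index, LabelVolume)``.
    """
    if state.contact_neighbor_order != params.contact_neighbor_order:
        raise ValueError(
            "state was built with contact order "
            f"{state.contact_neighbor_order}, params ask for "
            f"{params.contact_neighbor_order}"
        )
    snap_set = set(int(s) for s in snapshot_at)
    snapshots = []
    if 0 in snap_set:
        snapshots.append((0, state.to_labels()))
    n_sites = state.lattice.size
    potts_offs = K.neighbor_offsets(params.potts_neighbor_order)
    tallies = np.zeros(3, dtype=np.int64)
    for step in range(params.mcs):
        tallies[0] = state.cc2
        tallies[1] = state.cm2
        tallies[2] = 0
        K.run_attempts(
            state.lattice, state.V, state.A, state.Vt, state.At,
            params.lambda_V, params.lambda_A, params.J_cc, params.J_cm,
            params.T, potts_offs, state._contact_offs,
            n_sites, derive_seed(params.seed, step), tallies,
            False, state.n_labels,
        )
        state.cc2 = int(tallies[0])
        state.cm2 = int(tallies[1])
        if step + 1 in snap_set:
            snapshots.append((step + 1, state.to_labels()))
    gone = np.flatnonzero((state.V == 0) & (state.Vt > 0))
    if len(gone):
        log.info("cells vanished during simulation: %s", [int(g) for g in gone])
    return state, snapshots


def export_borders(lattice: LabelVolume) -> LabelVolume:
    """Cell-border image: the per-cell constant-intensity label volume itself.

    Each cell is a set of voxels sharing one intensity (its id), medium
    is 0 — exactly the lattice, returned as a fresh volume.
    """
    return lattice.copy()


def rasterize_membrane(lattice: LabelVolume) -> LabelVolume:
    """Binary membrane: nonzero voxels with a 6-neighbour of a different label.

    Neighbours outside the volume count as medium, so cells touching the
    box wall are bounded by membrane there too.
    """
    data = lattice.data
    is_border = np.zeros(data.shape, dtype=bool)
    for axis in range(3):
        a = data.take(range(0, data.shape[axis] - 1), axis=axis)
        b = data.take(range(1, data.shape[axis]), axis=axis)
        diff = a != b
        pad_lo = [slice(None)] * 3
        pad_lo[axis] = slice(0, data.shape[axis] - 1)
        pad_hi = [slice(None)] * 3
        pad_hi[axis] = slice(1, data.shape[axis])
        is_border[tuple(pad_lo)] |= diff
        is_border[tuple(pad_hi)] |= diff
        # volume walls behave as medium
        wall = [slice(None)] * 3
        wall[axis] = 0
        is_border[tuple(wall)] |= data[tuple(wall)] != 0
        wall[axis] = data.shape[axis] - 1
        is_border[tuple(wall)] |= data[tuple(wall)] != 0
    out = (is_border & (data != 0)).astype(np.int64)
    return LabelVolume(out, lattice.spacing)
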