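"""Prototype-based nucleus placement inside simulated cells.

For each cell of a simulated cell-border volume, a nucleus prototype
(a masked intensity subvolume cut out of one real or phantom nucleus) is
drawn from the database, rotated so its major principal axis aligns with
the cell's, scaled to a predefined fraction of the cell volume, and
dropped near the cell centre.  A candidate position is accepted when at
least ``overlap_threshold`` of the prototype's voxels land on cell
voxels not yet claimed by other nuclei — this enforces the containment
rule and prevents nucleus-nucleus collisions in one test.  After a
bounded number of position and prototype retries the cell is skipped.

Accepted placements write intensity by max-blending the full prototype
(soft boundary) while the fresh nucleus label covers only mask-inside-
cell voxels and *equals the parent cell label*, keeping borders,
membranes and nucleus labels joinable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "NucleusPrototype",
    "PlacementConfig",
    "principal_axes",
    "orient_scale_prototype",
    "sample_position",
    "overlap_fraction",
    "place_nuclei",
]

log = logging.getLogger("spherogen")


@dataclass
class NucleusPrototype:
    """Masked intensity subvolume: the unit of the placement database."""

    intensity: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(np.uint8)
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")
        if self.mask.sum() == 0:
            raise ValueError("prototype mask is empty")
        if np.any(self.intensity[self.mask == 0] != 0):
            raise ValueError("intensity must be exactly 0 outside the mask")
        n_comp = ndimage.label(self.mask, structure=np.ones((3, 3, 3)))[1]
        if n_comp != 1:
            raise ValueError("prototype mask must be a single connected component")

    @property
    def volume(self) -> int:
        return int(self.mask.sum())


@dataclass
class PlacementConfig:
    """Knobs of the placement procedure.

    The mechanisms are fixed; the quantities are tunable: nucleus/cell
    volume fraction ``volume_ratio``, acceptance ``overlap_threshold``
    (fraction of the prototype volume that must land on free cell
    voxels), positional spread ``sigma_frac`` (fraction of the cell's
    equivalent-sphere radius), and the retry budgets.
    """

    volume_ratio: float = 0.35
    overlap_threshold: float = 0.8
    sigma_frac: float = 0.15
    max_positions: int = 10
    max_prototypes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.max_positions < 1 or self.max_prototypes < 1:
            raise ValueError("retry budgets must be >= 1")
        if self.volume_ratio <= 0:
            raise ValueError("volume_ratio must be > 0")


def principal_axes(coords: np.ndarray):
    """(directions, lengths) of a voxel set's principal axes.

    Rows of ``directions`` are unit eigenvectors of the coordinate
    covariance, major first; ``lengths`` are the matching sqrt
    eigenvalues (0 for degenerate sets).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if len(coords) < 2:
        return np.eye(3), np.zeros(3)
    cov = np.cov(coords.T, ddof=0)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    return vec[:, order].T, np.sqrt(np.clip(lam[order], 0.0, None))


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal-angle rotation matrix taking unit vector u onto unit vector v."""
    if np.dot(u, v) < 0:  # principal axes are undirected
        v = -v
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        return np.eye(3)
    axis = axis / s
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _transform(proto: NucleusPrototype, R: np.ndarray, s: float) -> NucleusPrototype:
    """Rotate by R and scale isotropically by s around the subvolume centre.

    One centre-based affine resampling: nearest neighbour for the mask,
    linear for the intensity (re-masked afterwards).
    """
    shape = np.array(proto.mask.shape, dtype=float)
    out_extent = np.maximum(np.ceil(s * (np.abs(R) @ shape)).astype(int) + 2, 1)
    in_center = (shape - 1) / 2.0
    out_center = (out_extent - 1) / 2.0
    A = R.T / s  # output voxel -> input coordinate (rotation inverse == transpose)
    offset = in_center - A @ out_center
    mask = ndimage.affine_transform(
        proto.mask, A, offset=offset, output_shape=tuple(out_extent),
        order=0, mode="constant", cval=0,
    )
    if mask.sum() == 0:  # shrunk below a voxel; keep a single voxel
        return NucleusPrototype(
            np.full((1, 1, 1), float(proto.intensity.max())),
            np.ones((1, 1, 1), dtype=np.uint8),
            proto.spacing,
        )
    inten = ndimage.affine_transform(
        proto.intensity, A, offset=offset, output_shape=tuple(out_extent),
        order=1, mode="constant", cval=0.0,
    )
    inten[mask == 0] = 0.0
    np.clip(inten, 0.0, None, out=inten)
    return NucleusPrototype(inten, mask, proto.spacing)


def orient_scale_prototype(
    proto: NucleusPrototype,
    cell_axes,
    target_volume: float,
    tol: float = 0.05,
) -> NucleusPrototype:
    """Align the prototype's major axis with the cell's and match a target volume.

    ``cell_axes`` is a ``(directions, lengths)`` pair as returned by
    :func:`principal_axes`.  Near-spherical cells (major and minor
    lengths within 5% of each other) skip the rotation.  The isotropic
    scale factor is refined until the voxelised mask volume is within
    ``tol`` (default 5%) of ``target_volume``, where discretisation
    permits.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be > 0")
    dirs, lengths = cell_axes
    p_dirs, p_lengths = principal_axes(np.argwhere(proto.mask > 0))
    degenerate = lengths[0] <= 0 or (lengths[0] - lengths[2]) / lengths[0] < 0.05
    R = np.eye(3) if degenerate else _rotation_between(
        p_dirs[0], np.asarray(dirs[0], dtype=float)
    )
    s = float(np.cbrt(target_volume / proto.volume))
    best = None
    for _ in range(8):
        cand = _transform(proto, R, s)
        err = abs(cand.volume - target_volume) / target_volume
        if best is None or err < best[0]:
            best = (err, cand)
        if err <= tol:
            break
        s *= float(np.cbrt(target_volume / cand.volume))
    return best[1]


def sample_position(cell_coords: np.ndarray, sigma_frac: float, rng) -> tuple[int, int, int]:
    """Draw an integer voxel position near the cell centroid.

    Isotropic Gaussian centred at the centroid with
    sigma = sigma_frac * r_eq (equivalent-sphere radius), rejection-
    sampled until inside the cell's bounding box.  ``sigma_frac = 0``
    degenerates to the centroid voxel.
    """
    cell_coords = np.asarray(cell_coords)
    if len(cell_coords) == 0:
        raise ValueError("cell is empty")
    centroid = cell_coords.mean(axis=0)
    if sigma_frac <= 0:
        return tuple(int(round(c)) for c in centroid)
    r_eq = (3.0 * len(cell_coords) / (4.0 * np.pi)) ** (1.0 / 3.0)
    sigma = sigma_frac * r_eq
    lo = cell_coords.min(axis=0)
    hi = cell_coords.max(axis=0)
    while True:
        p = rng.normal(centroid, sigma)
        q = np.rint(p).astype(int)
        if np.all(q >= lo) and np.all(q <= hi):
            return tuple(int(v) for v in q)


def _mask_slices(mask_shape, position, vol_shape):
    """Clipped (volume slice, mask slice) pair for a mask centred at position."""
    half = [(n - 1) // 2 for n in mask_shape]
    vol_sl, mask_sl = [], []
    for ax in range(3):
        start = position[ax] - half[ax]
        stop = start + mask_shape[ax]
        v0, v1 = max(start, 0), min(stop, vol_shape[ax])
        if v1 <= v0:
            return None
        vol_sl.append(slice(v0, v1))
        mask_sl.append(slice(v0 - start, v1 - start))
    return tuple(vol_sl), tuple(mask_sl)


def overlap_fraction(proto_mask: np.ndarray, position, cell_mask: np.ndarray,
                     occupied: np.ndarray) -> float:
    """Fraction of prototype voxels landing on free voxels of the cell.

    Voxels already claimed by placed nuclei count as unavailable; mask
    voxels falling outside the volume count as misses.
    """
    total = int(proto_mask.sum())
    if total == 0:
        raise ValueError("prototype mask is empty")
    sl = _mask_slices(proto_mask.shape, position, cell_mask.shape)
    if sl is None:
        return 0.0
    vol_sl, mask_sl = sl
    m = proto_mask[mask_sl] > 0
    free = cell_mask[vol_sl] & ~occupied[vol_sl]
    return int(np.logical_and(m, free).sum()) / total


def place_nuclei(cells: LabelVolume, protos, cfg: PlacementConfig):
    """Place one nucleus per cell; returns (intensity, instance labels).

    Cells are processed in ascending label order.  Per cell: draw a
    prototype uniformly, orient and scale it, then try up to
    ``max_positions`` positions, accepting the first whose overlap
    fraction reaches ``overlap_threshold``; after exhausting positions
    move to the next prototype (up to ``max_prototypes``), else skip the
    cell.  The nucleus label equals the parent cell label and covers
    mask-inside-cell voxels only; intensity is max-blended over the full
    mask extent.
    """
    if len(protos) == 0:
        raise ValueError("prototype database is empty")
    labels = cells.labels()
    if len(labels) == 0:
        raise ValueError("no cells to populate")
    rng = np.random.default_rng(cfg.seed)
    intensity = np.zeros(cells.shape, dtype=np.float64)
    nuc_labels = np.zeros(cells.shape, dtype=np.int64)
    objects = ndimage.find_objects(cells.data)
    skipped = []
    for lab in labels:
        lab = int(lab)
        cell_mask = cells.data == lab
        coords = np.argwhere(cells.data[objects[lab - 1]] == lab)
        coords += np.array([s.start for s in objects[lab - 1]])
        axes = principal_axes(coords)
        target = cfg.volume_ratio * len(coords)
        occupied = nuc_labels > 0
        placed = False
        for _ in range(cfg.max_prototypes):
            proto = protos[int(rng.integers(len(protos)))]
            fitted = orient_scale_prototype(proto, axes, target)
            for _ in range(cfg.max_positions):
                pos = sample_position(coords, cfg.sigma_frac, rng)
                if overlap_fraction(fitted.mask, pos, cell_mask, occupied) >= cfg.overlap_threshold:
                    sl = _mask_slices(fitted.mask.shape, pos, cells.shape)
                    vol_sl, mask_sl = sl
                    m = fitted.mask[mask_sl] > 0
                    np.maximum(
                        intensity[vol_sl],
                        np.where(m, fitted.intensity[mask_sl], 0.0),
                        out=intensity[vol_sl],
                    )
                    write = m & cell_mask[vol_sl] & (nuc_labels[vol_sl] == 0)
                    nuc_labels[vol_sl][write] = lab
                    placed = True
                    break
            if placed:
                break
        if not placed:
            skipped.append(lab)
    if skipped:
        log.info("no nucleus placed in %d cell(s): %s", len(skipped), skipped)
    return (
        IntensityVolume(intensity, cells.spacing),
        LabelVolume(nuc_labels, cells.spacing),
    )
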