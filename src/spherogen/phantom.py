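"""Synthetic spheroid phantoms and nucleus prototypes.

Real spheroid recordings are not required anywhere in the package: this
module produces (a) a Voronoi-in-sphere label mask that emulates the
packed-cell geometry of a mono-culture spheroid, used as the starting
configuration of the Potts simulation, and (b) ellipsoidal nucleus
prototypes with band-limited intensity texture, standing in for the
manually annotated prototype database.

Voronoi (nearest-seed) tessellation is used rather than a growth model:
Voronoi cells intersected with a ball are convex, hence connected and
roughly isotropic like packed spheroid interiors, and the construction
is cheap and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .placement import NucleusPrototype
from .volumes import LabelVolume

__all__ = ["PhantomSpec", "make_phantom_spheroid", "make_phantom_prototypes"]


@dataclass
class PhantomSpec:
    """Geometry of the synthetic spheroid and its prototype database.

    Attributes
    ----------
    shape
        Volume shape (z, y, x) in voxels.
    sphere_radius
        Radius of the spheroid ball in voxels; must fit inside ``shape``.
    n_cells
        Number of Voronoi cells (>= 1).
    seed
        Seed for seed-point sampling and prototype texturing.
    n_prototypes
        Number of nucleus prototypes to generate.
    axes_range
        (min, max) semi-axis length range in voxels for prototype
        ellipsoids; each of the three semi-axes is drawn uniformly.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    sphere_radius: float = 28.0
    n_cells: int = 50
    seed: int = 0
    n_prototypes: int = 10
    axes_range: tuple[float, float] = (3.0, 6.0)
    lloyd_iterations: int = 3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        center = np.array(self.shape) / 2.0
        if any(self.sphere_radius > c for c in center):
            raise ValueError("sphere does not fit inside shape")
        lo, hi = self.axes_range
        if not (0 < lo <= hi):
            raise ValueError(f"degenerate axes range {self.axes_range}")


def _ball_voxels(shape, radius):
    """Integer coordinates (N, 3) of voxels whose centres lie in the ball."""
    center = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.indices(shape)
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    inside = d2 <= radius**2
    return np.argwhere(inside), center


def _sample_in_ball(rng, center, radius, n):
    """n points uniform in the ball, by rejection from the bounding cube."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 3))
        keep = cand[np.sum(cand**2, axis=1) <= radius**2]
        take = min(len(keep), n - got)
        pts[got : got + take] = keep[:take] + center
        got += take
    return pts


def make_phantom_spheroid(spec: PhantomSpec) -> LabelVolume:
    """Voronoi-in-sphere label mask: ``n_cells`` labels partitioning a digital ball.

    Seed points are sampled uniformly inside the sphere; every in-ball
    voxel takes the label of its nearest seed (1-based, ties to the
    lowest label); voxels outside the sphere are medium (0).  Seeds whose
    Voronoi cell captures no voxel are resampled so every label 1..n_cells
    is non-empty.

    ``lloyd_iterations`` rounds of Lloyd relaxation (each seed moved to
    its cell's centroid) turn the raw Poisson-Voronoi mosaic into a
    centroidal tessellation whose rounder, more evenly sized cells match
    the geometry of densely packed spheroid interiors; 0 keeps the raw
    mosaic.
    """
    coords, center = _ball_voxels(spec.shape, spec.sphere_radius)
    if spec.n_cells > len(coords):
        raise ValueError(
            f"n_cells={spec.n_cells} exceeds ball voxel count {len(coords)}"
        )
    rng = np.random.default_rng(spec.seed)
    seeds = _sample_in_ball(rng, center, spec.sphere_radius, spec.n_cells)
    for _ in range(spec.lloyd_iterations):
        _, nearest = cKDTree(seeds).query(coords)
        for i in range(spec.n_cells):
            sel = coords[nearest == i]
            if len(sel):
                seeds[i] = sel.mean(axis=0)
            else:
                seeds[i] = _sample_in_ball(rng, center, spec.sphere_radius, 1)[0]
    for _ in range(200):
        # cKDTree breaks exact ties by lowest index == lowest label
        _, nearest = cKDTree(seeds).query(coords)
        counts = np.bincount(nearest, minlength=spec.n_cells)
        empty = np.flatnonzero(counts == 0)
        if len(empty) == 0:
            break
        seeds[empty] = _sample_in_ball(rng, center, spec.sphere_radius, len(empty))
    else:  # pragma: no cover - essentially unreachable at sane densities
        raise RuntimeError("could not find a seed set with all cells non-empty")
    data = np.zeros(spec.shape, dtype=np.int64)
    data[tuple(coords.T)] = nearest + 1
    return LabelVolume(data)


def _ellipsoid_mask(semi_axes):
    """Axis-aligned solid ellipsoid mask with one-voxel margin."""
    a = np.asarray(semi_axes, dtype=float)
    half = np.ceil(a).astype(int) + 1
    shape = 2 * half + 1
    center = half.astype(float)
    zz, yy, xx = np.indices(shape)
    r2 = (
        ((zz - center[0]) / a[0]) ** 2
        + ((yy - center[1]) / a[1]) ** 2
        + ((xx - center[2]) / a[2]) ** 2
    )
    return (r2 <= 1.0).astype(np.uint8)


def make_phantom_prototypes(spec: PhantomSpec) -> list[NucleusPrototype]:
    """Ellipsoidal nucleus prototypes with smooth random interior texture.

    Each prototype is a solid axis-aligned ellipsoid support mask whose
    semi-axes are drawn uniformly from ``spec.axes_range``; the intensity
    inside is band-limited noise (Gaussian-smoothed white noise) rescaled
    to [0.3, 1.0], mimicking chromatin texture, and exactly 0 outside.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x70726F74]))
    protos: list[NucleusPrototype] = []
    lo, hi = spec.axes_range
    for _ in range(spec.n_prototypes):
        semi = np.sort(rng.uniform(lo, hi, size=3))[::-1]  # major axis along z
        mask = _ellipsoid_mask(semi)
        noise = rng.standard_normal(mask.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=1.5)
        inside = smooth[mask > 0]
        span = inside.max() - inside.min()
        if span <= 0:  # pragma: no cover - constant noise field
            tex = np.full_like(inside, 0.65)
        else:
            tex = 0.3 + 0.7 * (inside - inside.min()) / span
        intensity = np.zeros(mask.shape, dtype=np.float64)
        intensity[mask > 0] = tex
        protos.append(NucleusPrototype(intensity=intensity, mask=mask))
    return protos
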