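"""Quality measures: slice-wise Kernel Inception Distance and CTC-style
SEG/DET segmentation scores.

KID compares two image sets in a feature space via the unbiased squared
maximum mean discrepancy with the cubic polynomial kernel
``k(a, b) = (a.b / d + 1)^3``.  Because the canonical feature network is
2D, 3D volumes are scored slice by slice and the per-direction results
for the three major plane families (xy, xz, yz) are averaged.  The
feature extractor is pluggable: any deterministic map from a 2D slice to
a fixed-length vector.  The default extractor is a fixed random
orthogonal projection of the down-sampled slice — deterministic and
download-free; an InceptionV3 adapter can be substituted where
pretrained weights are available.

SEG is the mean Jaccard index over ground-truth objects matched by
strict majority overlap; DET is the normalised detection-error cost
AOGM-D with the standard weights 5 (split), 10 (false negative),
1 (false positive) — external Cell Tracking Challenge conventions, not
quantities derived here.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.transform import resize

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "RandomProjectionExtractor",
    "mmd2_unbiased",
    "kid_volume",
    "seg_score",
    "det_score",
    "eval_protocol_crop",
]

log = logging.getLogger("spherogen")


class RandomProjectionExtractor:
    """Deterministic stand-in feature extractor for KID.

    Resizes a 2D slice to ``target_shape``, flattens it and projects it
    onto ``d`` fixed random orthogonal directions (seeded QR factor).
    """

    def __init__(self, d: int = 64, target_shape=(32, 32), seed: int = 0):
        self.d = int(d)
        self.target_shape = tuple(target_shape)
        n_in = int(np.prod(self.target_shape))
        if self.d > n_in:
            raise ValueError("d must not exceed the flattened slice size")
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((n_in, self.d)))
        self._proj = q

    def __call__(self, slice2d: np.ndarray) -> np.ndarray:
        small = resize(
            np.asarray(slice2d, dtype=np.float64),
            self.target_shape,
            order=1,
            mode="reflect",
            anti_aliasing=False,
            preserve_range=True,
        )
        return small.ravel() @ self._proj


def _poly_kernel(a: np.ndarray, b: np.ndarray, d: int) -> np.ndarray:
    # einsum keeps the per-element reduction order identical across the
    # three Gram blocks, so identical feature sets cancel exactly
    return (np.einsum("id,jd->ij", a, b) / d + 1.0) ** 3


def mmd2_unbiased(f_real: np.ndarray, f_synth: np.ndarray, d: int | None = None) -> float:
    """Unbiased squared MMD with the cubic polynomial kernel.

    Within-set sums exclude the diagonal.  For equal sample sizes the
    equal-size U-statistic (cross diagonal also excluded) is used, which
    is exactly 0 on element-wise identical sets; for unequal sizes the
    standard unbiased estimator with the full cross term is used.
    """
    X = np.asarray(f_real, dtype=np.float64)
    Y = np.asarray(f_synth, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("feature sets must be 2D (n_samples, dim)")
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError("each feature set needs at least 2 vectors")
    if d is None:
        d = X.shape[1]
    Kxx = _poly_kernel(X, X, d)
    Kyy = _poly_kernel(Y, Y, d)
    Kxy = _poly_kernel(X, Y, d)
    if n == m:
        diff = Kxx + Kyy - Kxy - Kxy.T  # exactly 0 elementwise when X == Y
        np.fill_diagonal(diff, 0.0)
        return float(diff.sum() / (n * (n - 1)))
    sum_xx = Kxx.sum() - np.trace(Kxx)
    sum_yy = Kyy.sum() - np.trace(Kyy)
    return float(
        sum_xx / (n * (n - 1)) + sum_yy / (m * (m - 1)) - 2.0 * Kxy.mean()
    )


def _direction_slices(vol: np.ndarray, axis: int):
    return [np.take(vol, i, axis=axis) for i in range(vol.shape[axis])]


def kid_volume(
    real: IntensityVolume,
    synth: IntensityVolume,
    fx=None,
    subset_size: int = 50,
    n_subsets: int = 20,
    rng=None,
    paired: bool = False,
    return_components: bool = False,
):
    """Slice-wise KID between two volumes, averaged over xy, xz and yz planes.

    For each plane family, features of every slice of both volumes are
    extracted and the unbiased MMD^2 is averaged over ``n_subsets``
    random subsets of ``subset_size`` slices (reduced with a warning
    when a volume has fewer slices).  ``paired=True`` draws identical
    subset indices for both volumes (requires equal slice counts), so
    identical volumes score exactly 0.
    """
    fx = fx or RandomProjectionExtractor()
    rng = rng if rng is not None else np.random.default_rng(0)
    per_direction = {}
    for name, axis in (("xy", 0), ("xz", 1), ("yz", 2)):
        F_r = np.stack([fx(s) for s in _direction_slices(real.data, axis)])
        F_s = np.stack([fx(s) for s in _direction_slices(synth.data, axis)])
        m = min(subset_size, len(F_r), len(F_s))
        if m < subset_size:
            log.warning("kid: subset_size reduced from %d to %d for %s slices",
                        subset_size, m, name)
        if m < 2:
            raise ValueError("need at least 2 slices per direction")
        vals = []
        for _ in range(n_subsets):
            idx_r = rng.choice(len(F_r), size=m, replace=False)
            if paired:
                if len(F_r) != len(F_s):
                    raise ValueError("paired draws require equal slice counts")
                idx_s = idx_r
            else:
                idx_s = rng.choice(len(F_s), size=m, replace=False)
            vals.append(mmd2_unbiased(F_r[idx_r], F_s[idx_s], d=fx.d if hasattr(fx, "d") else None))
        per_direction[name] = float(np.mean(vals))
    total = float(np.mean(list(per_direction.values())))
    if return_components:
        return total, per_direction
    return total


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    """Sparse contingency of voxel overlaps between nonzero labels."""
    both = (gt > 0) | (pred > 0)
    g = gt[both].ravel()
    p = pred[both].ravel()
    pairs, counts = np.unique(np.stack([g, p]), axis=1, return_counts=True)
    return pairs[0], pairs[1], counts


def _match_majority(gt: np.ndarray, pred: np.ndarray):
    """CTC matching: GT object R matches pred S iff |R n S| > 0.5 |R|.

    Returns (gt_labels, gt_sizes, matches dict gt->(pred, inter), pred_sizes).
    """
    gt_labels, gt_sizes_arr = np.unique(gt[gt > 0], return_counts=True)
    if len(gt_labels) == 0:
        raise ValueError("ground truth has no objects")
    gt_sizes = dict(zip(gt_labels.tolist(), gt_sizes_arr.tolist()))
    pred_labels, pred_sizes_arr = np.unique(pred[pred > 0], return_counts=True)
    pred_sizes = dict(zip(pred_labels.tolist(), pred_sizes_arr.tolist()))
    gi, pi, cnt = _overlap_table(gt, pred)
    matches = {}
    for g, p, c in zip(gi.tolist(), pi.tolist(), cnt.tolist()):
        if g == 0 or p == 0:
            continue
        if c * 2 > gt_sizes[g]:  # strict majority: at most one such S exists
            matches[g] = (p, c)
    return gt_sizes, matches, pred_sizes


def seg_score(gt: LabelVolume, pred: LabelVolume) -> float:
    """Mean Jaccard over GT objects matched by strict majority overlap.

    Unmatched GT objects contribute 0; the score lies in [0, 1] and is
    invariant under relabeling of either input.
    """
    if gt.shape != pred.shape:
        raise ValueError("volumes must share shape")
    gt_sizes, matches, pred_sizes = _match_majority(gt.data, pred.data)
    total = 0.0
    for g, size in gt_sizes.items():
        if g in matches:
            p, inter = matches[g]
            total += inter / (size + pred_sizes[p] - inter)
    return total / len(gt_sizes)


def det_score(gt: LabelVolume, pred: LabelVolume) -> float:
    """Normalised detection accuracy 1 - min(AOGM-D, AOGM-D0) / AOGM-D0.

    AOGM-D = 5 * NS + 10 * FN + 1 * FP with NS the number of required
    splits (a predicted label claimed by k >= 2 GT objects costs k - 1),
    FN unmatched GT objects, FP predicted labels matching no GT object;
    AOGM-D0 = 10 * |GT| is the cost of building the detection from
    nothing.
    """
    if gt.shape != pred.shape:
        raise ValueError("volumes must share shape")
    gt_sizes, matches, pred_sizes = _match_majority(gt.data, pred.data)
    n_gt = len(gt_sizes)
    fn = n_gt - len(matches)
    claimed = {}
    for g, (p, _) in matches.items():
        claimed[p] = claimed.get(p, 0) + 1
    ns = sum(k - 1 for k in claimed.values())
    fp = sum(1 for p in pred_sizes if p not in claimed)
    aogm_d = 5.0 * ns + 10.0 * fn + 1.0 * fp
    aogm_d0 = 10.0 * n_gt
    return 1.0 - min(aogm_d, aogm_d0) / aogm_d0


def eval_protocol_crop(pred_full: LabelVolume, gt_patch: LabelVolume, offset):
    """Score a whole-image segmentation against a ground-truth patch.

    The prediction is made on the whole image and *then* cropped at
    ``offset`` to the patch shape (objects truncated by the crop are
    scored as cropped), so border nuclei are segmented in full context.
    Returns ``(SEG, DET)``.
    """
    offset = tuple(int(o) for o in offset)
    if any(o < 0 for o in offset) or any(
        o + s > f for o, s, f in zip(offset, gt_patch.shape, pred_full.shape)
    ):
        raise ValueError("patch at offset exceeds the full volume")
    sl = tuple(slice(o, o + s) for o, s in zip(offset, gt_patch.shape))
    cropped = LabelVolume(pred_full.data[sl], gt_patch.spacing)
    return seg_score(gt_patch, cropped), det_score(gt_patch, cropped)
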