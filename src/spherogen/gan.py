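"""Label-co-generating GAN objectives and instance-label post-processing.

The generator of a membrane-to-nuclei translation GAN is given a second
output channel: alongside the synthetic nuclei signal y_hat it emits a
soft binary nucleus-label channel v_hat that shares the decoder's
feature maps, so image and label stay aligned.  An extra unconditional
discriminator D_Seg judges the label channel against a pool of (possibly
unpaired) real binary label masks.

Objectives are implemented in their literal log form with epsilon
clamping (practical trainers often substitute least-squares or BCE
surrogates; the log form is the contract here):

conditional GAN:
    min_G max_{D, D_Seg}  L_cGAN(G, D) + L_sGAN(G, D_Seg) + lambda_L1 L_L1(G)
cycle-consistency GAN:
    min_G max_D  L_GAN_A + L_GAN_B + L_GAN_S + lambda_cyc L_cyc

Post-processing turns the generated soft label channel into instance
labels: threshold, subtract the binary membrane (splitting touching
nuclei), binary opening against artifacts, then assign each remaining
foreground voxel its simulated cell label — foreground over medium is
removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "GanBatch",
    "LossWeights",
    "split_generator_output",
    "loss_cgan",
    "loss_l1",
    "loss_sgan",
    "objective_cgan",
    "objective_cyclegan",
    "postprocess_instance_labels",
]


@dataclass
class LossWeights:
    lambda_L1: float = 100.0
    lambda_cyc: float = 10.0
    eps_clamp: float = 1e-7

    def __post_init__(self) -> None:
        if self.lambda_L1 < 0 or self.lambda_cyc < 0:
            raise ValueError("loss weights must be non-negative")
        if not (0.0 < self.eps_clamp < 0.5):
            raise ValueError("eps_clamp must be in (0, 0.5)")


@dataclass
class GanBatch:
    """Volumes and discriminator outputs entering the objectives.

    Discriminator outputs are per-sample arrays of probabilities in
    (0, 1); they are epsilon-clamped before any log.  The cycle fields
    (``x``, ``x_tilde``, ``y_tilde`` and the A/B discriminator outputs)
    are only needed by the cycle-consistency objective.
    """

    y: np.ndarray | None = None        # real nuclei signal
    y_hat: np.ndarray | None = None    # generated nuclei channel
    d_real: np.ndarray | None = None   # D(y, x)
    d_fake: np.ndarray | None = None   # D(y_hat, x)
    dseg_real: np.ndarray | None = None  # D_Seg(v)
    dseg_fake: np.ndarray | None = None  # D_Seg(v_hat)
    x: np.ndarray | None = None        # condition (binary membrane)
    x_tilde: np.ndarray | None = None  # G_B2A(G_A2B(x)) image cycle
    y_tilde: np.ndarray | None = None  # G_A2B(G_B2A(y)) image cycle
    da_real: np.ndarray | None = None  # D_A(x)
    da_fake: np.ndarray | None = None  # D_A(x_hat)
    db_real: np.ndarray | None = None  # D_B(y)
    db_fake: np.ndarray | None = None  # D_B(y_hat)


def _as_volume_data(v):
    if isinstance(v, (IntensityVolume, LabelVolume)):
        return v.data
    return np.asarray(v, dtype=np.float64)


def _log_term(p_real, p_fake, eps: float) -> float:
    p_real = np.clip(np.asarray(p_real, dtype=np.float64), eps, 1.0 - eps)
    p_fake = np.clip(np.asarray(p_fake, dtype=np.float64), eps, 1.0 - eps)
    return float(np.mean(np.log(p_real)) + np.mean(np.log(1.0 - p_fake)))


def split_generator_output(two_channel: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    """Split a (2, z, y, x) generator output into (nuclei, soft label).

    Channel 0 is the nuclei signal, channel 1 the soft binary label in
    [0, 1]; both come back as :class:`IntensityVolume` of equal shape.
    """
    arr = np.asarray(two_channel, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[0] != 2:
        raise ValueError(f"expected a (2, z, y, x) stack, got shape {arr.shape}")
    return (
        IntensityVolume(arr[0], spacing),
        IntensityVolume(arr[1], spacing),
    )


def loss_cgan(batch: GanBatch, eps: float = 1e-7) -> float:
    """Adversarial term: E[log D(y, x)] + E[log(1 - D(y_hat, x))]."""
    return _log_term(batch.d_real, batch.d_fake, eps)


def loss_l1(y, y_hat) -> float:
    """Mean absolute voxel difference between real and generated nuclei."""
    y = _as_volume_data(y)
    y_hat = _as_volume_data(y_hat)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean(np.abs(y - y_hat)))


def loss_sgan(batch: GanBatch, eps: float = 1e-7) -> float:
    """Label-channel term: E[log D_Seg(v)] + E[log(1 - D_Seg(v_hat))].

    D_Seg sees no condition, so the real labels v may come from any
    unpaired pool; the term depends on neither x nor y.
    """
    return _log_term(batch.dseg_real, batch.dseg_fake, eps)


def objective_cgan(batch: GanBatch, w: LossWeights | None = None):
    """Total conditional-GAN objective and its components.

    total = L_cGAN + L_sGAN + lambda_L1 * L_L1.
    """
    w = w or LossWeights()
    comp = {
        "cgan": loss_cgan(batch, w.eps_clamp),
        "sgan": loss_sgan(batch, w.eps_clamp),
        "l1": loss_l1(batch.y, batch.y_hat),
    }
    total = comp["cgan"] + comp["sgan"] + w.lambda_L1 * comp["l1"]
    return total, comp


def objective_cyclegan(batch: GanBatch, w: LossWeights | None = None):
    """Total cycle-consistency objective and its components.

    total = L_GAN_A + L_GAN_B + L_GAN_S + lambda_cyc * L_cyc with
    L_cyc = E|x - x_tilde| + E|y - y_tilde|.
    """
    w = w or LossWeights()
    for name in ("x", "x_tilde", "y", "y_tilde"):
        if getattr(batch, name) is None:
            raise ValueError(f"cycle objective requires batch field {name!r}")
    comp = {
        "gan_a": _log_term(batch.da_real, batch.da_fake, w.eps_clamp),
        "gan_b": _log_term(batch.db_real, batch.db_fake, w.eps_clamp),
        "gan_s": loss_sgan(batch, w.eps_clamp),
        "cyc": loss_l1(batch.x, batch.x_tilde) + loss_l1(batch.y, batch.y_tilde),
    }
    total = comp["gan_a"] + comp["gan_b"] + comp["gan_s"] + w.lambda_cyc * comp["cyc"]
    return total, comp


def postprocess_instance_labels(
    v_hat,
    membrane: LabelVolume,
    cells: LabelVolume,
    threshold: float = 0.5,
    opening_radius: int = 1,
) -> LabelVolume:
    """Instance labels from the generated soft label channel.

    Steps: binarise at ``threshold``; subtract the binary membrane
    (splitting nuclei that touch across a cell boundary); binary opening
    with a ball of ``opening_radius`` voxels (0 skips); assign each
    remaining foreground voxel the simulated cell label underneath it.
    Foreground over medium — artifacts — is removed by that assignment.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    v = _as_volume_data(v_hat)
    if v.shape != membrane.shape or v.shape != cells.shape:
        raise ValueError("v_hat, membrane and cells must share one shape")
    b = v >= threshold
    b &= membrane.data == 0
    if opening_radius > 0:
        b = ndimage.binary_opening(b, structure=ball(opening_radius))
    out = np.where(b & (cells.data > 0), cells.data, 0)
    return LabelVolume(out, cells.spacing)
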