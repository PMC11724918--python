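"""Imaging simulation: optical and sensor effects of a confocal microscope.

Applied to the pristine placed-nuclei image, in the order a real
acquisition imposes them: depth-dependent brightness reduction, blurring
by the point-spread function, downsampling to the acquisition grid, and
shot + read-out noise.

The depth attenuation is exponential, ``exp(-z * spacing_z /
attenuation_depth)`` measured from the first z-plane; the functional
form and decay length are configuration options.  The PSF is a
normalised anisotropic Gaussian truncated at 4 sigma.  Noise follows the
standard photon model: Poisson shot noise at a configurable photon gain
plus additive Gaussian read-out noise, clipped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volumes import IntensityVolume, LabelVolume

__all__ = [
    "ImagingConfig",
    "attenuate",
    "convolve_psf",
    "downsample",
    "downsample_labels",
    "add_noise",
    "simulate_imaging",
]

log = logging.getLogger("spherogen")


@dataclass
class ImagingConfig:
    """Imaging-simulation parameters.

    attenuation_depth: decay length in um (inf disables attenuation).
    psf_sigma: Gaussian PSF sigma in um, (z, y, x); 0 disables blurring.
    downsample: integer block factors (z, y, x); 1 disables.
    noise_gain: photon scaling of the Poisson shot noise; 0 disables.
    noise_sigma: additive Gaussian (read-out) noise std; 0 disables.
    """

    attenuation_depth: float = np.inf
    psf_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    downsample: tuple[int, int, int] = (1, 1, 1)
    noise_gain: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation_depth <= 0:
            raise ValueError("attenuation_depth must be > 0 (inf disables)")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be non-negative")
        if any(int(f) != f or f < 1 for f in self.downsample):
            raise ValueError("downsample factors must be integers >= 1")
        self.downsample = tuple(int(f) for f in self.downsample)
        if self.noise_gain < 0 or self.noise_sigma < 0:
            raise ValueError("noise parameters must be non-negative")


def attenuate(img: IntensityVolume, depth_len: float) -> IntensityVolume:
    """Multiply plane z by exp(-z * spacing_z / depth_len); inf is identity."""
    if depth_len <= 0:
        raise ValueError("depth_len must be > 0")
    if not np.isfinite(depth_len):
        return img.copy()
    z = np.arange(img.shape[0], dtype=np.float64) * img.spacing[0]
    factors = np.exp(-z / depth_len)
    return IntensityVolume(img.data * factors[:, None, None], img.spacing)


def convolve_psf(img: IntensityVolume, sigma) -> IntensityVolume:
    """Convolve with a normalised anisotropic Gaussian PSF.

    ``sigma`` is (z, y, x) in um and is converted to voxels with the
    volume's spacing; the kernel is truncated at 4 sigma and sums to 1,
    so constant images are fixed points and interior-supported signal
    mass is conserved.
    """
    sigma = tuple(float(s) for s in sigma)
    if any(s < 0 for s in sigma):
        raise ValueError("sigma must be non-negative")
    sigma_vox = [s / sp for s, sp in zip(sigma, img.spacing)]
    if all(s == 0 for s in sigma_vox):
        return img.copy()
    out = ndimage.gaussian_filter(
        img.data, sigma=sigma_vox, truncate=4.0, mode="constant", cval=0.0
    )
    return IntensityVolume(np.clip(out, 0.0, None), img.spacing)


def _crop_divisible(data: np.ndarray, factors) -> np.ndarray:
    new_shape = [n - n % f for n, f in zip(data.shape, factors)]
    if tuple(new_shape) != data.shape:
        log.info("downsample: cropping trailing remainder %s -> %s",
                 data.shape, tuple(new_shape))
    return data[tuple(slice(0, n) for n in new_shape)]


def downsample(img: IntensityVolume, factors) -> IntensityVolume:
    """Block-average by integer factors; spacing is scaled accordingly."""
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    data = _crop_divisible(img.data, factors)
    nz, ny, nx = (n // f for n, f in zip(data.shape, factors))
    blocks = data.reshape(nz, factors[0], ny, factors[1], nx, factors[2])
    out = blocks.mean(axis=(1, 3, 5))
    spacing = tuple(s * f for s, f in zip(img.spacing, factors))
    return IntensityVolume(out, spacing)


def downsample_labels(labels: LabelVolume, factors) -> LabelVolume:
    """Majority-vote block downsampling of a label volume (ties -> lowest label)."""
    factors = tuple(int(f) for f in factors)
    data = _crop_divisible(labels.data, factors)
    nz, ny, nx = (n // f for n, f in zip(data.shape, factors))
    blocks = data.reshape(nz, factors[0], ny, factors[1], nx, factors[2])
    flat = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(nz, ny, nx, -1)
    # scipy's mode returns the smallest modal value, a deterministic tie-break
    out = stats.mode(flat, axis=-1, keepdims=False).mode
    spacing = tuple(s * f for s, f in zip(labels.spacing, factors))
    return LabelVolume(out, spacing)


def add_noise(img: IntensityVolume, gain: float, sigma: float, rng) -> IntensityVolume:
    """Poisson shot noise at photon gain plus Gaussian read-out noise.

    ``out = Poisson(img / gain) * gain + N(0, sigma)``, clipped at 0;
    ``gain = 0`` disables shot noise, ``sigma = 0`` the additive part.
    """
    if gain < 0 or sigma < 0:
        raise ValueError("gain and sigma must be non-negative")
    data = img.data
    if gain > 0:
        data = rng.poisson(data / gain).astype(np.float64) * gain
    if sigma > 0:
        data = data + rng.normal(0.0, sigma, size=data.shape)
    return IntensityVolume(np.clip(data, 0.0, None), img.spacing)


def simulate_imaging(img: IntensityVolume, cfg: ImagingConfig, labels: LabelVolume | None = None):
    """Full imaging pipeline: attenuate -> PSF -> downsample -> noise.

    With ``labels`` given, the instance labels are downsampled alongside
    by majority vote so image and label shapes stay matched, and an
    ``(image, labels)`` pair is returned; otherwise just the image.
    An all-neutral config is the identity.
    """
    out = attenuate(img, cfg.attenuation_depth)
    out = convolve_psf(out, cfg.psf_sigma)
    out = downsample(out, cfg.downsample)
    rng = np.random.default_rng(cfg.seed)
    out = add_noise(out, cfg.noise_gain, cfg.noise_sigma, rng)
    if labels is None:
        return out
    return out, downsample_labels(labels, cfg.downsample)
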