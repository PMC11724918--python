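"""Smoke-scale GAN training harness.

Validates that the objectives in :mod:`spherogen.gan` are optimisable
end to end: a miniature generator/discriminator pair plays the minimax
game on tiny volumes for a handful of iterations, and the per-iteration
component losses are returned (finiteness is the only assertion).

The built-in backend is a deliberately small numpy model family —
per-voxel logistic generators and pooled-statistic logistic
discriminators — updated by simultaneous-perturbation (SPSA) estimates
of the minimax objective, so the harness runs with no deep-learning
framework.  Any other backend can be plugged in by supplying a
(generator, discriminator) pair honouring the same I/O contract.
"""

from __future__ import annotations

import numpy as np

from .gan import GanBatch, LossWeights, objective_cgan

__all__ = ["smoke_train_harness"]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _make_toy_data(rng, batch: int, shape):
    """Paired toy membrane/nuclei/label volumes for the smoke run."""
    x = (rng.random((batch, *shape)) < 0.25).astype(np.float64)
    y = np.clip(1.0 - x + 0.1 * rng.standard_normal((batch, *shape)), 0.0, 1.0)
    v = (y > 0.5).astype(np.float64)
    return x, y, v


def _generator(theta, x, z):
    y_hat = _sigmoid(theta[0] + theta[1] * x + theta[2] * z)
    v_hat = _sigmoid(theta[3] + theta[4] * x + theta[5] * z)
    return y_hat, v_hat


def _disc(phi, img, cond):
    axes = tuple(range(1, img.ndim))
    feats = np.stack(
        [img.mean(axis=axes), img.std(axis=axes), (img * cond).mean(axis=axes)],
        axis=1,
    )
    return _sigmoid(phi[0] + feats @ phi[1:4])


def _dseg(psi, v):
    axes = tuple(range(1, v.ndim))
    feats = np.stack([v.mean(axis=axes), v.std(axis=axes)], axis=1)
    return _sigmoid(psi[0] + feats @ psi[1:3])


def smoke_train_harness(
    iters: int = 50,
    shape=(8, 8, 8),
    batch: int = 4,
    weights: LossWeights | None = None,
    seed: int = 0,
    backend: str = "numpy",
):
    """Run a miniature adversarial training loop; returns per-iteration losses.

    Each entry of the returned list holds the components of the
    conditional objective (``total``, ``cgan``, ``sgan``, ``l1``).
    Raises if any loss goes non-finite.  Volumes are capped at 16^3 and
    iterations at 200 — this is a contract smoke test, not a trainer.
    """
    if backend != "numpy":
        raise NotImplementedError(
            f"training backend {backend!r} is not available; the built-in "
            "backend is 'numpy'"
        )
    if any(s > 16 for s in shape):
        raise ValueError("smoke harness volumes are capped at 16^3")
    if iters > 200:
        raise ValueError("smoke harness is capped at 200 iterations")
    w = weights or LossWeights()
    rng = np.random.default_rng(seed)
    x, y, v = _make_toy_data(rng, batch, tuple(shape))
    theta = 0.1 * rng.standard_normal(6)   # generator
    phi = 0.1 * rng.standard_normal(4)     # conditional discriminator
    psi = 0.1 * rng.standard_normal(3)     # segmentation discriminator

    def evaluate(th, ph, ps, z):
        y_hat, v_hat = _generator(th, x, z)
        b = GanBatch(
            y=y, y_hat=y_hat,
            d_real=_disc(ph, y, x), d_fake=_disc(ph, y_hat, x),
            dseg_real=_dseg(ps, v), dseg_fake=_dseg(ps, v_hat),
        )
        return objective_cgan(b, w)

    lr, delta = 0.05, 0.01
    trajectory = []
    for _ in range(int(iters)):
        z = rng.standard_normal(x.shape)
        # SPSA ascent for the discriminators on the adversarial terms
        for vec in (phi, psi):
            pert = rng.choice([-1.0, 1.0], size=vec.shape)
            up, _ = evaluate(theta, phi + (delta * pert if vec is phi else 0),
                             psi + (delta * pert if vec is psi else 0), z)
            dn, _ = evaluate(theta, phi - (delta * pert if vec is phi else 0),
                             psi - (delta * pert if vec is psi else 0), z)
            vec += lr * (up - dn) / (2 * delta) * pert
        # SPSA descent for the generator on the full objective
        pert = rng.choice([-1.0, 1.0], size=theta.shape)
        up, _ = evaluate(theta + delta * pert, phi, psi, z)
        dn, _ = evaluate(theta - delta * pert, phi, psi, z)
        theta -= lr * (up - dn) / (2 * delta) * pert
        total, comp = evaluate(theta, phi, psi, z)
        entry = {"total": total, **comp}
        if not all(np.isfinite(val) for val in entry.values()):
            raise FloatingPointError(f"non-finite loss in smoke harness: {entry}")
        trajectory.append(entry)
    return trajectory
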