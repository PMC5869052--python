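"""Loss functions and the alternating GAN optimization step.

The soft Dice loss is the differentiable surrogate for the Dice overlap:
per class ``c``, ``d_c = (2 Σ p_c g_c + ε) / (Σ p_c + Σ g_c + ε)`` with
one-hot reference ``g`` and ``ε = 1e-5``; the loss is ``1 − mean_c d_c``,
averaged over all classes including background.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DICE_EPS = 1e-5


class LossError(RuntimeError):
    pass


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, X, Y, Z) integer labels -> (N, C, X, Y, Z) one-hot float32."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise LossError(
            f"labels outside [0, {n_classes}): found "
            f"[{labels.min()}, {labels.max()}]"
        )
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=ad.DTYPE)
    np.put_along_axis(out, labels[:, np.newaxis].astype(np.int64), 1.0, axis=1)
    return out


def soft_dice_loss(
    pred_probs: Tensor, labels: np.ndarray, n_classes: int, eps: float = DICE_EPS
) -> Tensor:
    """1 − mean per-class soft Dice between probabilities and labels.

    ``pred_probs`` must already sum to one over the class axis (apply
    :func:`voxpipe.nn.autodiff.softmax` to raw scores first).
    """
    g = one_hot(labels, n_classes)
    axes = (0, 2, 3, 4)
    inter = ad.sum_(ad.mul(pred_probs, Tensor(g)), axis=axes)       # (C,)
    denom = ad.sum_(pred_probs, axis=axes) + Tensor(g.sum(axis=axes))
    dice_c = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - ad.mean(dice_c)


def rmse_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Root mean square error over (optionally masked) voxels."""
    target_t = Tensor(np.asarray(target, dtype=ad.DTYPE).reshape(pred.shape))
    diff = pred - target_t
    sq = ad.mul(diff, diff)
    if mask is not None:
        mask = np.broadcast_to(
            np.asarray(mask, dtype=ad.DTYPE).reshape(
                (1, 1) + tuple(np.asarray(mask).shape[-3:])
            ),
            pred.shape,
        )
        n = float(mask.sum())
        if n == 0:
            raise LossError("empty RMSE mask")
        return ad.sqrt(ad.sum_(ad.mul(sq, Tensor(mask.copy()))) * (1.0 / n))
    return ad.sqrt(ad.mean(sq))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    t = np.asarray(targets, dtype=ad.DTYPE).reshape(logits.shape)
    z = logits.data
    val = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = float(z.size)

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        return [(logits, g * (sig - t) / n)]

    return ad._op(np.array(val.mean(), dtype=ad.DTYPE), (logits,), backward)


def gan_alternating_step(
    generator,
    discriminator,
    real_batch: np.ndarray,
    noise_batch: np.ndarray,
    gen_optimizer,
    disc_optimizer,
    conditioning: np.ndarray | None = None,
) -> tuple[float, float]:
    """One alternating GAN update: discriminator step, then generator step.

    Step 1 updates only the discriminator against real-vs-generated binary
    cross-entropy (generated samples detached); step 2 updates only the
    generator with the non-saturating objective (maximize the
    discriminator's belief that generated samples are real).
    """
    def gen_input(z):
        if conditioning is None:
            return Tensor(z)
        cond = np.broadcast_to(
            np.asarray(conditioning, dtype=ad.DTYPE), (z.shape[0],) + np.asarray(conditioning).shape
        ).reshape(z.shape[0], -1)
        return Tensor(np.concatenate([z, cond], axis=1))

    # step 1: discriminator only
    fake = generator.forward(gen_input(noise_batch)).detach()
    discriminator.zero_grad()
    d_real = discriminator.forward(Tensor(real_batch))
    d_fake = discriminator.forward(fake)
    d_loss = bce_with_logits(d_real, np.ones(d_real.shape)) + \
        bce_with_logits(d_fake, np.zeros(d_fake.shape))
    d_loss.backward()
    disc_optimizer.step()

    # step 2: generator only; discriminator gradients are discarded
    generator.zero_grad()
    discriminator.zero_grad()
    g_out = generator.forward(gen_input(noise_batch))
    g_loss = bce_with_logits(discriminator.forward(g_out), np.ones((g_out.shape[0], 1)))
    g_loss.backward()
    gen_optimizer.step()
    discriminator.zero_grad()

    return float(d_loss.data), float(g_loss.data)
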