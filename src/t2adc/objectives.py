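"""Loss terms for unpaired translation training.

* ``info_nce`` — temperature-scaled contrastive cross-entropy for one query
  against one positive and M negatives.
* ``patch_nce`` — the patch-wise contrastive loss over tapped encoder
  layers; negatives are the other sampled locations of the same image.
* ``self_regularization`` — pixel-level L2 penalty tying the output to the
  source image.
* ``lsgan_terms`` — least-squares adversarial losses on patch score maps.
* ``total_loss`` — weighted composite generator objective.

All differentiable paths run through :class:`t2adc.nn.Tensor`; every
function also accepts plain arrays and returns a Tensor whose ``item()``
is the scalar loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import FeatureStack
from .nn import Tensor

__all__ = [
    "ContrastiveBatch", "LossConfig",
    "info_nce", "patch_nce", "self_regularization", "lsgan_terms",
    "total_loss",
]


@dataclass
class ContrastiveBatch:
    v: np.ndarray          # (L_e,) query
    v_plus: np.ndarray     # (L_e,) positive
    v_minus: np.ndarray    # (M, L_e) negatives
    tau: float = 0.07

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=np.float64)
        self.v_plus = np.asarray(self.v_plus, dtype=np.float64)
        self.v_minus = np.atleast_2d(np.asarray(self.v_minus, dtype=np.float64))
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.v_minus.shape[0] < 1:
            raise ValueError("need at least one negative (M >= 1)")
        for name, a in (("v", self.v), ("v_plus", self.v_plus),
                        ("v_minus", self.v_minus)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class LossConfig:
    tau: float = 0.07
    lambda_x: float = 1.0
    lambda_y: float = 1.0
    lambda_sr: float = 1.0
    lambda_adv: float = 1.0

    def __post_init__(self):
        for name in ("lambda_x", "lambda_y", "lambda_sr", "lambda_adv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def info_nce(batch: ContrastiveBatch) -> float:
    """-log( e^{v.v+/tau} / (e^{v.v+/tau} + sum_n e^{v.v_n-/tau}) ).

    Stabilized by max-subtraction so arbitrarily large logits are safe.
    """
    pos = float(batch.v @ batch.v_plus) / batch.tau
    neg = (batch.v_minus @ batch.v) / batch.tau
    logits = np.concatenate([[pos], neg])
    m = logits.max()
    lse = m + np.log(np.exp(logits - m).sum())
    return float(lse - pos)


def patch_nce(feats_query: FeatureStack, feats_key: FeatureStack,
              tau: float = 0.07) -> Tensor:
    """Mean contrastive loss over layers x batch x locations.

    For location s the positive is the key embedding at s; negatives are
    the key embeddings at the other S-1 sampled locations of the same
    image.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if feats_query.layers != feats_key.layers:
        raise ValueError(
            f"layer mismatch: {feats_query.layers} vs {feats_key.layers}"
        )
    total = None
    count = 0
    for l in feats_query.layers:
        if not np.array_equal(feats_query.locations[l], feats_key.locations[l]):
            raise ValueError(f"location indices differ at layer {l}")
        zq = feats_query.embeddings[l]   # (N, S, D)
        zk = feats_key.embeddings[l]
        n, s, _ = zq.shape
        logits = (zq @ zk.transpose(0, 2, 1)) * (1.0 / tau)   # (N, S, S)
        m = Tensor(logits.data.max(axis=-1, keepdims=True))   # constant shift
        lse = ((logits - m).exp().sum(axis=-1)).log() + m.reshape(n, s)
        r = np.arange(s)
        diag = logits[:, r, r]
        layer_loss = (lse - diag).sum()
        total = layer_loss if total is None else total + layer_loss
        count += n * s
    return total * (1.0 / count)


def self_regularization(x, gx) -> Tensor:
    """Mean squared pixel deviation of the output from the source image."""
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    gt = gx if isinstance(gx, Tensor) else Tensor(np.asarray(gx))
    if xt.shape != gt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {gt.shape}")
    d = xt - gt
    return (d * d).mean()


def lsgan_terms(d_real, d_fake) -> tuple[Tensor, Tensor]:
    """Least-squares adversarial losses (labels: real=1, fake=0, target=1).

    Returns ``(d_loss, g_loss)``; in a training step the discriminator loss
    must be evaluated on detached fake scores.
    """
    r = d_real if isinstance(d_real, Tensor) else Tensor(np.asarray(d_real))
    f = d_fake if isinstance(d_fake, Tensor) else Tensor(np.asarray(d_fake))
    d_loss = 0.5 * ((r - 1.0) ** 2).mean() + 0.5 * (f**2).mean()
    g_loss = 0.5 * ((f - 1.0) ** 2).mean()
    return d_loss, g_loss


def total_loss(g_adv, sr, nce_x, nce_y, cfg: LossConfig) -> Tensor:
    """Composite generator objective: adversarial + weighted SR + weighted
    patch-contrastive terms for both domains."""

    def t(v):
        return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=float))

    return (cfg.lambda_adv * t(g_adv) + cfg.lambda_sr * t(sr)
            + cfg.lambda_x * t(nce_x) + cfg.lambda_y * t(nce_y))
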