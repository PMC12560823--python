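"""Reconstruction objectives for the three modalities and their combination.

Per molecule the pretraining loss is

    L = L_ce_1D + L_sce_2D + L_denoise_3D,
    L_ce_1D      = - sum_{i in M1D} log p(t_i)          (masked-token CE, summed)
    L_sce_2D     = sum_{i in M2D} (1 - cos(h_i, h_i*))^gamma
    L_mse        = (1/n) sum_i ||c_i - c_i*||^2         (over ALL n atoms)
    L_cos        = 1 - (1/n) sum_i cos(c_i, c_i*)
    L_denoise_3D = lambda_l2 * L_mse + lambda_cos * L_cos

where * marks the clean-view target.  The 1D and 2D terms are sums over the
masked positions of one molecule; batches average the per-molecule sums.
The denoising terms run over all atoms, so the decoder must keep unnoised
atoms in place as well as restore noised ones.

All functions accept autodiff Tensors (gradients flow to predictions, never
to targets) or plain arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, log_softmax, tensor
from .errors import ConfigurationError, InputError

__all__ = [
    "LossReport",
    "loss_1d_ce",
    "loss_2d_sce",
    "loss_3d_mse",
    "loss_3d_cos",
    "loss_3d_denoise",
    "total_loss",
]

_EPS = 1e-12


@dataclass
class LossReport:
    """Scalar loss components of one step (or one molecule)."""

    l_ce_1d: float
    l_sce_2d: float
    l_mse: float
    l_cos: float
    l_denoise_3d: float
    total: float
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "l_ce_1d": self.l_ce_1d,
            "l_sce_2d": self.l_sce_2d,
            "l_mse": self.l_mse,
            "l_cos": self.l_cos,
            "l_denoise_3d": self.l_denoise_3d,
            "total": self.total,
            "counts": self.counts,
        }


def loss_1d_ce(logits, targets: list[int], mask: set[int] | frozenset[int]) -> Tensor:
    """Masked-token cross entropy, summed over the masked positions."""
    logits = tensor(logits)
    if logits.shape[0] != len(targets):
        raise InputError("logits and targets disagree on sequence length")
    if not mask:
        warnings.warn("empty 1D mask: cross-entropy term is 0 for this molecule")
        return Tensor(0.0)
    idx = sorted(mask)
    if any(not 0 <= i < len(targets) for i in idx):
        raise InputError("mask position out of range")
    logp = log_softmax(logits[np.asarray(idx)], axis=-1)
    rows = np.arange(len(idx))
    cols = np.asarray([targets[i] for i in idx])
    return -(logp[rows, cols].sum())


def loss_2d_sce(pred, target, mask: set[int] | frozenset[int], gamma: float = 2.0) -> Tensor:
    """Structural contrastive embedding loss over masked atoms:
    sum_i (1 - cos(h_i, h_i_target))^gamma."""
    pred, target = tensor(pred), tensor(target)
    if pred.shape != target.shape:
        raise InputError("prediction and target shapes differ")
    if not mask:
        warnings.warn("empty 2D mask: reconstruction term is 0 for this molecule")
        return Tensor(0.0)
    idx = np.asarray(sorted(mask))
    p, t = pred[idx], target[idx]
    t_norm = np.linalg.norm(t.data, axis=1)
    if np.any(t_norm < _EPS):
        warnings.warn("zero-norm target row in 2D loss; epsilon guard applied")
    cos = (p * t).sum(axis=1) / (
        ((p ** 2).sum(axis=1) + _EPS).sqrt() * ((t ** 2).sum(axis=1) + _EPS).sqrt()
    )
    return ((1.0 - cos) ** gamma).sum()


def loss_3d_mse(pred, target) -> Tensor:
    """Mean over atoms of the squared coordinate error."""
    pred, target = tensor(pred), tensor(target)
    if pred.shape != target.shape:
        raise InputError(f"shape mismatch {pred.shape} vs {target.shape}")
    return ((pred - target) ** 2).sum(axis=1).mean()


def loss_3d_cos(pred, target) -> Tensor:
    """1 minus the mean cosine between predicted and true coordinate vectors."""
    pred, target = tensor(pred), tensor(target)
    if pred.shape != target.shape:
        raise InputError(f"shape mismatch {pred.shape} vs {target.shape}")
    norms = np.linalg.norm(pred.data, axis=1) * np.linalg.norm(target.data, axis=1)
    if np.any(norms < _EPS):
        warnings.warn("zero-norm coordinate row in cosine loss; epsilon guard applied")
    cos = (pred * target).sum(axis=1) / (
        ((pred ** 2).sum(axis=1) + _EPS).sqrt() * ((target ** 2).sum(axis=1) + _EPS).sqrt()
    )
    return 1.0 - cos.mean()


def loss_3d_denoise(mse, cos, lambda_l2: float = 1.0, lambda_cos: float = 1.0) -> Tensor:
    """Weighted combination of the two coordinate-denoising terms."""
    if lambda_l2 < 0 or lambda_cos < 0:
        raise ConfigurationError("denoising weights must be nonnegative")
    return lambda_l2 * tensor(mse) + lambda_cos * tensor(cos)


def total_loss(
    ce_1d,
    sce_2d,
    mse=None,
    cos=None,
    lambda_l2: float = 1.0,
    lambda_cos: float = 1.0,
    counts: dict[str, int] | None = None,
    use_3d: bool = True,
) -> tuple[Tensor, LossReport]:
    """Sum the modality objectives into the pretraining total.

    When the 3D modality is disabled its term is exactly 0 and the report
    flags it via ``counts['use_3d'] = 0``.
    """
    ce_1d, sce_2d = tensor(ce_1d), tensor(sce_2d)
    if use_3d:
        if mse is None or cos is None:
            raise InputError("3D enabled but denoising components missing")
        denoise = loss_3d_denoise(mse, cos, lambda_l2, lambda_cos)
        mse_v, cos_v = tensor(mse).item(), tensor(cos).item()
    else:
        denoise = Tensor(0.0)
        mse_v = cos_v = 0.0
    tot = ce_1d + sce_2d + denoise
    counts = dict(counts or {})
    counts["use_3d"] = int(use_3d)
    report = LossReport(
        l_ce_1d=ce_1d.item(),
        l_sce_2d=sce_2d.item(),
        l_mse=mse_v,
        l_cos=cos_v,
        l_denoise_3d=denoise.item(),
        total=tot.item(),
        counts=counts,
    )
    return tot, report
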