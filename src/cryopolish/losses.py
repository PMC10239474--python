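"""Training objective: smooth-L1 distance plus a non-local SSIM loss.

The smooth L1 term penalises per-voxel differences (quadratic below 1.0,
linear above).  The SSIM term compares whole slices through their global
contrast and structure,

    SSIMLoss(X, Y) = 1 - (2 sigma_XY + eps) / (sigma_X^2 + sigma_Y^2 + eps),

with eps = 1e-6 guarding the degenerate constant-slice case.  Standard
deviations and the covariance use the 1/(N^3 - 1) normalisation; the
ratio itself is normalisation-independent.  The total loss is the plain
sum of the two terms, each averaged over the batch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor

__all__ = ["SsimParams", "LossReport", "smooth_l1", "ssim_loss", "total_loss",
           "smooth_l1_t", "ssim_loss_t", "total_loss_t"]


@dataclasses.dataclass
class SsimParams:
    epsilon: float = 1e-6

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclasses.dataclass
class LossReport:
    smooth_l1: float
    ssim_loss: float

    @property
    def total(self) -> float:
        return self.smooth_l1 + self.ssim_loss


def _check_shapes(x, y):
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def smooth_l1_t(x: Tensor, y: Tensor) -> Tensor:
    """Differentiable smooth L1 loss, mean over all voxels (and batch)."""
    _check_shapes(x, y)
    d = x.data - y.data
    absd = np.abs(d)
    mask = absd < 1.0
    l = np.where(mask, 0.5 * d * d, absd - 0.5)
    out = np.asarray(l.mean(), dtype=x.dtype)
    n = d.size

    def bwd(g):
        gl = np.where(mask, d, np.sign(d)) * (g / n)
        if x.requires_grad:
            x._accumulate(gl.astype(x.dtype))
        if y.requires_grad:
            y._accumulate((-gl).astype(y.dtype))

    return x._make(out, (x, y), bwd)


def ssim_loss_t(x: Tensor, y: Tensor,
                params: SsimParams | None = None) -> Tensor:
    """Differentiable SSIM loss over whole slices, batch-averaged.

    Inputs are ``(..., N, N, N)``; statistics are global per slice (no
    sliding windows).
    """
    params = params or SsimParams()
    _check_shapes(x, y)
    axes = (-3, -2, -1)
    n = int(np.prod(x.shape[-3:]))
    mx = x.mean(axis=axes, keepdims=True)
    my = y.mean(axis=axes, keepdims=True)
    xc = x - mx
    yc = y - my
    var_x = (xc * xc).sum(axis=axes) * (1.0 / (n - 1))
    var_y = (yc * yc).sum(axis=axes) * (1.0 / (n - 1))
    cov = (xc * yc).sum(axis=axes) * (1.0 / (n - 1))
    eps = params.epsilon
    ratio = (2.0 * cov + eps) * (var_x + var_y + eps).power(-1.0)
    return (1.0 - ratio).mean()


def total_loss_t(x: Tensor, y: Tensor,
                 params: SsimParams | None = None) -> tuple[Tensor, LossReport]:
    """Sum of smooth L1 and SSIM losses; returns the graph node and a report."""
    sl1 = smooth_l1_t(x, y)
    ssim = ssim_loss_t(x, y, params)
    total = sl1 + ssim
    return total, LossReport(float(sl1.data), float(ssim.data))


# -- plain-array wrappers ----------------------------------------------------

def smooth_l1(x: np.ndarray, y: np.ndarray) -> float:
    return float(smooth_l1_t(Tensor(np.asarray(x)), Tensor(np.asarray(y))).data)


def ssim_loss(x: np.ndarray, y: np.ndarray,
              params: SsimParams | None = None) -> float:
    return float(ssim_loss_t(Tensor(np.asarray(x, dtype=np.float64)),
                             Tensor(np.asarray(y, dtype=np.float64)),
                             params).data)


def total_loss(x: np.ndarray, y: np.ndarray,
               params: SsimParams | None = None) -> LossReport:
    xt = Tensor(np.asarray(x, dtype=np.float64))
    yt = Tensor(np.asarray(y, dtype=np.float64))
    return LossReport(float(smooth_l1_t(xt, yt).data),
                      float(ssim_loss_t(xt, yt, params).data))
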