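"""Optimization objectives for self-supervised model fitting.

Two objectives are provided.  The plain masked MSE averages, over the n
acquisition volumes, the squared signal residual over the voxels of the
configured mask.  The constrained weighted least-squares (CWLS) loss for
the kurtosis model combines a per-voxel softmax-weighted residual (the
weights come from a log-linear OLS pre-fit and stay frozen during the
network optimization) with a regularizer that penalizes negative
apparent kurtosis along a fixed set of 60 directions:

    L_cwls = L_content + λ · L_bound,     λ = 1000 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import models
from .gradients import GradientTable
from .sphere import bound_directions

__all__ = [
    "LossConfig",
    "mse_loss",
    "build_design_matrix",
    "ols_log_estimate",
    "wls_weights",
    "content_loss_cwls",
    "bound_penalty",
    "cwls_loss",
    "compute_cwls_weights",
]

#: Clamp floor applied to signals before logarithms (normalized units,
#: i.e. 1e-6 of the tissue-median b0 level).
LOG_FLOOR = 1e-6


@dataclass
class LossConfig:
    """Which objective to optimize and its knobs.

    ``loss_mask`` selects the voxel set: ``"tissue"`` (brain tissue
    excluding CSF — the tensor/kurtosis convention) or ``"brain"`` (the
    NODDI convention).  ``cwls_log=True`` evaluates the weighted
    residual on log-signals instead of raw signals.
    """

    kind: str = "mse"
    lambda_bound: float = 1000.0
    n_bound_dirs: int = 60
    loss_mask: str = "tissue"
    cwls_log: bool = False
    noddi_quad_order: int = 28

    def __post_init__(self):
        if self.kind not in ("mse", "cwls"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.lambda_bound < 0 or self.n_bound_dirs < 1:
            raise ValueError("lambda_bound >= 0 and n_bound_dirs >= 1 required")
        if self.loss_mask not in ("tissue", "brain"):
            raise ValueError(f"unknown loss mask {self.loss_mask!r}")


def _masked_mean_sq(resid, mask):
    """Mean of resid² over (masked voxels × trailing volume axis)."""
    mask = np.asarray(mask, bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty loss mask")
    m = mask.astype(float)[..., None]
    n = resid.shape[-1]
    return ad.vsum((resid * m) ** 2) * (1.0 / (count * n))


def mse_loss(signal, predicted, mask):
    """Masked MSE between measured and synthesized signals.

    Arrays are (..., n) with the mask over the leading voxel axes; the
    result is the mean over volumes of the per-volume masked MSE.
    """
    return _masked_mean_sq(predicted - signal, mask)


def build_design_matrix(gradients: GradientTable, model: str) -> np.ndarray:
    """Log-linearized design matrix: n×7 (tensor) or n×22 (kurtosis).

    Row i of the tensor design is [−b_i·(v⊗v with cross-term
    multiplicities), 1]; the kurtosis design inserts the quartic columns
    (b_i²/6)·(v⊗v⊗v⊗v with multiplicities), which multiply the
    combined coefficients W = MD²·K.  The last column multiplies ln S0.
    """
    b = gradients.bvals
    cols = [-b[:, None] * models.tensor_design(gradients.bvecs)]
    if model == "kurtosis":
        cols.append(
            (b[:, None] ** 2 / 6.0) * models.kurtosis_design(gradients.bvecs)
        )
    elif model != "tensor":
        raise ValueError(f"no linear design for model {model!r}")
    cols.append(np.ones((gradients.n, 1)))
    X = np.concatenate(cols, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        import warnings

        warnings.warn("gradient scheme leaves the design matrix rank-deficient")
    return X


def ols_log_estimate(
    signal: np.ndarray, X: np.ndarray, floor: float = LOG_FLOOR
) -> np.ndarray:
    """Ordinary least squares on log-signals: P̂ = (XᵀX)⁻¹ Xᵀ ln S.

    ``signal`` is (..., n); returns (..., p).  Solved with a QR-based
    least-squares factorization; signals are clamped at ``floor`` before
    the logarithm.
    """
    s = np.maximum(np.asarray(signal, float), floor)
    lnS = np.log(s)
    coef, *_ = np.linalg.lstsq(X, lnS.reshape(-1, X.shape[0]).T, rcond=None)
    return coef.T.reshape(s.shape[:-1] + (X.shape[1],))


def wls_weights(predicted_ols: np.ndarray) -> np.ndarray:
    """Per-voxel softmax over the n volumes of the OLS-predicted signals."""
    p = np.asarray(predicted_ols, float)
    p = p - p.max(axis=-1, keepdims=True)
    e = np.exp(p)
    return e / e.sum(axis=-1, keepdims=True)


def content_loss_cwls(signal, predicted, weights, mask, log_domain: bool = False):
    """Weighted residual term: Σ_i MSE over voxels of (ω_i S_i, ω_i Ŝ_i)."""
    mask = np.asarray(mask, bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty loss mask")
    if log_domain:
        signal = np.log(np.maximum(np.asarray(signal, float), LOG_FLOOR))
        predicted = ad.log(ad.clip_min(predicted, LOG_FLOOR))
    resid = (predicted - signal) * weights
    m = mask.astype(float)[..., None]
    # sum over volumes of per-volume masked means = total/count
    return ad.vsum((resid * m) ** 2) * (1.0 / count)


def bound_penalty(k_app, mask):
    """Mean over masked voxels of Σ_dirs ReLU(−K_app)."""
    mask = np.asarray(mask, bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty loss mask")
    m = mask.astype(float)[..., None]
    return ad.vsum(ad.relu(-k_app) * m) * (1.0 / count)


def compute_cwls_weights(dwi_signal: np.ndarray, gradients: GradientTable) -> np.ndarray:
    """OLS pre-fit softmax weights, computed once and then frozen.

    Runs the log-linear kurtosis OLS on the (sub-sampled) input data and
    returns softmax(Ŝ_ols) per voxel; these are constants with respect
    to the network parameters (no gradient flows through them).
    """
    X = build_design_matrix(gradients, "kurtosis")
    coef = ols_log_estimate(dwi_signal, X)
    predicted = np.exp(np.clip(coef @ X.T, -50.0, 50.0))
    return wls_weights(predicted)


def cwls_loss(
    signal,
    predicted,
    params: models.KurtosisParams,
    config: LossConfig,
    weights: np.ndarray,
    mask,
    bound_dirs: np.ndarray | None = None,
):
    """Constrained weighted loss: content + λ · bound.

    ``weights`` are the frozen per-voxel softmax weights from
    :func:`compute_cwls_weights`; ``bound_dirs`` defaults to the fixed
    60-direction set.
    """
    if bound_dirs is None:
        bound_dirs = bound_directions(config.n_bound_dirs)
    content = content_loss_cwls(
        signal, predicted, weights, mask, log_domain=config.cwls_log
    )
    if config.lambda_bound == 0:
        return content
    k_app = models.apparent_kurtosis(params.k, bound_dirs)
    return content + bound_penalty(k_app, mask) * config.lambda_bound
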