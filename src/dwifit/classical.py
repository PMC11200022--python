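"""Conventional per-voxel estimators: baselines and test oracles.

* :func:`ols_tensor_fit` — log-linear ordinary least squares, the
  classic ``dtifit``-style tensor estimator.
* :func:`iwls_kurtosis_fit` — OLS-seeded iteratively weighted least
  squares for the kurtosis model (weights = squared predicted signals).
* :func:`grid_search_noddi` — exhaustive minimum of the signal MSE over
  a parameter grid for the Watson-NODDI model, with optional
  coordinate-descent refinement.

Voxels outside the mask are returned as zeros; each fit also returns a
boolean validity map.
"""

from __future__ import annotations

import numpy as np

from . import models
from .losses import LOG_FLOOR, build_design_matrix, ols_log_estimate
from .sphere import uniform_sphere_directions
from .volume import DwiVolume

__all__ = [
    "ols_tensor_fit",
    "iwls_kurtosis_fit",
    "grid_search_noddi",
    "default_noddi_grids",
]

MD2_FLOOR = 1e-12  # guard for the W = MD²·K → K conversion


def _coef_to_tensor_params(coef: np.ndarray) -> models.TensorParams:
    return models.TensorParams(d=coef[..., :6], s0=np.exp(coef[..., 6]))


def _coef_to_kurtosis_params(coef: np.ndarray) -> models.KurtosisParams:
    d = coef[..., :6]
    md2 = ((d[..., 0] + d[..., 1] + d[..., 2]) / 3.0) ** 2
    k = coef[..., 6:21] / np.maximum(md2, MD2_FLOOR)[..., None]
    return models.KurtosisParams(d=d, k=k, s0=np.exp(coef[..., 21]))


def ols_tensor_fit(
    dwi: DwiVolume, mask: np.ndarray | None = None
) -> tuple[models.TensorParams, np.ndarray]:
    """Per-voxel OLS tensor fit; returns (params, validity map)."""
    mask = dwi.brain_mask if mask is None else np.asarray(mask, bool)
    X = build_design_matrix(dwi.gradients, "tensor")
    coef = np.zeros(dwi.spatial_shape + (7,))
    coef[mask] = ols_log_estimate(dwi.signal[mask], X)
    valid = mask & np.isfinite(coef).all(axis=-1)
    coef[~valid] = 0.0
    params = _coef_to_tensor_params(coef)
    if isinstance(params.s0, np.ndarray):
        params.s0[~valid] = 0.0
    return params, valid


def _batched_wls(X: np.ndarray, lnS: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Solve min ||W(lnS − Xp)||² per row, W² = w2 (V×n)."""
    # normal equations per voxel: (Xᵀ W² X) p = Xᵀ W² lnS
    A = np.einsum("vn,ni,nj->vij", w2, X, X)
    rhs = np.einsum("vn,ni,vn->vi", w2, X, lnS)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def iwls_kurtosis_fit(
    dwi: DwiVolume, mask: np.ndarray | None = None, iterations: int = 10
) -> tuple[models.KurtosisParams, np.ndarray]:
    """OLS-seeded iteratively weighted least squares for the kurtosis model.

    Each iteration re-solves the log-linear system with weights equal to
    the squared currently predicted signals.  A voxel whose weighted
    residual grows three-fold over its OLS residual falls back to the
    OLS solution and is flagged invalid.
    """
    mask = dwi.brain_mask if mask is None else np.asarray(mask, bool)
    X = build_design_matrix(dwi.gradients, "kurtosis")
    S = np.maximum(dwi.signal[mask], LOG_FLOOR)
    lnS = np.log(S)
    coef_ols = ols_log_estimate(dwi.signal[mask], X)
    coef = coef_ols.copy()
    resid_ols = (
        ((lnS - coef_ols @ X.T) * np.exp(np.clip(coef_ols @ X.T, -50, 50))) ** 2
    ).sum(-1)
    diverged = np.zeros(len(coef), dtype=bool)
    for _ in range(int(iterations)):
        pred = np.exp(np.clip(coef @ X.T, -50.0, 50.0))
        coef = _batched_wls(X, lnS, pred**2)
        bad = ~np.isfinite(coef).all(axis=-1)
        coef[bad] = coef_ols[bad]
        diverged |= bad
    if iterations > 0:
        pred = np.exp(np.clip(coef @ X.T, -50.0, 50.0))
        resid = (((lnS - coef @ X.T) * pred) ** 2).sum(-1)
        blown = resid > 3.0 * np.maximum(resid_ols, 1e-300)
        coef[blown] = coef_ols[blown]
        diverged |= blown
    full = np.zeros(dwi.spatial_shape + (22,))
    full[mask] = coef
    valid = mask.copy()
    valid[mask] = ~diverged
    params = _coef_to_kurtosis_params(full)
    params.s0[~mask] = 0.0
    return params, valid


def default_noddi_grids() -> dict:
    """The default brute-force grids: fractions 0:0.05:1, 16 log-spaced
    κ in [0.25, 64], a 100-direction hemisphere set for µ."""
    return {
        "f_iso": np.linspace(0.0, 1.0, 21),
        "f_ic": np.linspace(0.0, 1.0, 21),
        "kappa": np.geomspace(0.25, 64.0, 16),
        "mu": uniform_sphere_directions(100, seed=100),
    }


def _noddi_attenuation_table(grids, bvecs, bvals, consts, quad_order=28):
    """Signal table over the full grid, shape (Nfiso, Nfic, Nmu, Nk, n)."""
    mu = np.asarray(grids["mu"], float)
    kap = np.asarray(grids["kappa"], float)
    fic = np.asarray(grids["f_ic"], float)
    fiso = np.asarray(grids["f_iso"], float)
    n_mu, n_k, n_fic = len(mu), len(kap), len(fic)
    theta = np.arctan2(mu[:, 1], mu[:, 0])
    phi = np.arcsin(np.clip(mu[:, 2], -1, 1))
    # tissue attenuation for each (mu, kappa, f_ic) at f_iso = 0
    p = models.NoddiParams(
        f_iso=np.zeros((n_mu, n_k, n_fic)),
        f_ic=np.broadcast_to(fic, (n_mu, n_k, n_fic)).copy(),
        theta=np.broadcast_to(theta[:, None, None], (n_mu, n_k, n_fic)).copy(),
        phi=np.broadcast_to(phi[:, None, None], (n_mu, n_k, n_fic)).copy(),
        kappa=np.broadcast_to(kap[None, :, None], (n_mu, n_k, n_fic)).copy(),
    )
    tissue = models.noddi_signal(p, bvecs, bvals, 1.0, consts, quad_order)
    a_iso = np.exp(-np.asarray(bvals, float) * consts.d_iso)
    table = (
        (1.0 - fiso[:, None, None, None, None]) * tissue[None]
        + fiso[:, None, None, None, None] * a_iso
    )
    return table.astype(np.float32)


def _refine_voxel(s_norm, best, grids, bvecs, bvals, consts, rounds=2):
    """Coordinate descent on (f_iso, f_ic, κ) around the grid optimum."""
    fiso, fic, mu, kap = best

    def mse(fi, fc, kp):
        theta = np.arctan2(mu[1], mu[0])
        phi = float(np.arcsin(np.clip(mu[2], -1, 1)))
        p = models.NoddiParams(
            f_iso=np.atleast_1d(fi), f_ic=np.atleast_1d(fc),
            theta=np.atleast_1d(theta), phi=np.atleast_1d(phi),
            kappa=np.atleast_1d(kp),
        )
        pred = models.noddi_signal(p, bvecs, bvals, 1.0, consts)
        return float(((pred[0] - s_norm) ** 2).mean())

    def line(search_vals, current, which):
        vals = []
        for v in search_vals:
            args = [fiso, fic, kap]
            args[which] = v
            vals.append(mse(*args))
        return search_vals[int(np.argmin(vals))]

    for _ in range(rounds):
        fiso = line(np.clip(fiso + np.linspace(-0.05, 0.05, 7), 0, 1), fiso, 0)
        fic = line(np.clip(fic + np.linspace(-0.05, 0.05, 7), 0, 1), fic, 1)
        kap = line(np.clip(kap * np.geomspace(0.7, 1.4, 7), 0.05, 128), kap, 2)
    return fiso, fic, mu, kap


def grid_search_noddi(
    dwi: DwiVolume,
    mask: np.ndarray | None = None,
    grids: dict | None = None,
    consts: models.NoddiConstants = models.NoddiConstants(),
    refine: bool = False,
    quad_order: int = 28,
    chunk: int = 4096,
) -> tuple[models.NoddiParams, np.ndarray]:
    """Brute-force NODDI estimation: exhaustive MSE minimum over a grid.

    Voxel signals are normalized by their mean-b0 before matching, so
    S0 never enters the search.  With ``refine=True`` a short
    coordinate descent polishes (f_iso, f_ic, κ) per voxel.
    """
    mask = dwi.brain_mask if mask is None else np.asarray(mask, bool)
    grids = default_noddi_grids() if grids is None else grids
    bvecs, bvals = dwi.gradients.bvecs, dwi.gradients.bvals
    table = _noddi_attenuation_table(grids, bvecs, bvals, consts, quad_order)
    shape = table.shape[:-1]
    flat = table.reshape(-1, table.shape[-1])  # (Ng, n)
    s0 = np.maximum(dwi.mean_b0()[mask], LOG_FLOOR)
    s_norm = (dwi.signal[mask] / s0[:, None]).astype(np.float32)
    g2 = (flat**2).sum(-1)
    best_idx = np.empty(len(s_norm), dtype=np.int64)
    best_score = np.full(len(s_norm), np.inf, dtype=np.float32)
    for lo in range(0, flat.shape[0], chunk):
        block = flat[lo : lo + chunk]
        scores = g2[lo : lo + chunk][None, :] - 2.0 * (s_norm @ block.T)
        idx = scores.argmin(axis=1)
        val = np.take_along_axis(scores, idx[:, None], 1)[:, 0]
        better = val < best_score
        best_score[better] = val[better]
        best_idx[better] = idx[better] + lo
    # table layout is (f_iso, mu, kappa, f_ic, n)
    ii = np.unravel_index(best_idx, shape)
    fiso = grids["f_iso"][ii[0]].astype(float)
    mu = np.asarray(grids["mu"], float)[ii[1]]
    kap = grids["kappa"][ii[2]].astype(float)
    fic = grids["f_ic"][ii[3]].astype(float)
    if refine:
        for j in range(len(s_norm)):
            fiso[j], fic[j], mu[j], kap[j] = _refine_voxel(
                np.asarray(s_norm[j], float),
                (fiso[j], fic[j], mu[j], kap[j]),
                grids, bvecs, bvals, consts,
            )
    out = {
        "f_iso": np.zeros(dwi.spatial_shape),
        "f_ic": np.zeros(dwi.spatial_shape),
        "theta": np.zeros(dwi.spatial_shape),
        "phi": np.zeros(dwi.spatial_shape),
        "kappa": np.zeros(dwi.spatial_shape),
    }
    out["f_iso"][mask] = fiso
    out["f_ic"][mask] = fic
    out["theta"][mask] = np.arctan2(mu[:, 1], mu[:, 0])
    out["phi"][mask] = np.arcsin(np.clip(mu[:, 2], -1, 1))
    out["kappa"][mask] = kap
    return models.NoddiParams(**out), mask.copy()
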