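"""Scalar maps and evaluation statistics.

Derives the standard rotation-invariant maps from fitted parameters
(DTI: FA/MD/AD/V1; DKI: additionally MK/AK/RK; NODDI: ODI) and
implements the evaluation statistics used throughout: masked MAE with
outlier-exclusion rules, angular error between principal eigenvectors,
and SSIM on standardized images.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from . import models
from .sphere import metric_directions

__all__ = [
    "dti_metrics",
    "dki_metrics",
    "odi_from_kappa",
    "mae",
    "angular_error",
    "ssim_standardized",
]


def dti_metrics(params: models.TensorParams) -> dict:
    """FA, MD, AD and the principal eigenvector V1 from a tensor map."""
    T = params.tensor_matrices()
    finite = np.isfinite(T).all(axis=(-2, -1))
    Tf = np.where(finite[..., None, None], T, 0.0)
    evals, evecs = np.linalg.eigh(Tf)  # ascending
    md = evals.mean(axis=-1)
    ad_ = evals[..., 2]
    num = ((evals - md[..., None]) ** 2).sum(-1)
    den = (evals**2).sum(-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / np.where(den > 0, den, np.inf))
    v1 = evecs[..., :, 2]
    out = {"FA": fa, "MD": md, "AD": ad_, "V1": v1}
    for key in ("FA", "MD", "AD"):
        out[key] = np.where(finite, out[key], np.nan)
    return out


def _radial_ring(v1: np.ndarray, n: int = 16) -> np.ndarray:
    """n unit directions evenly spaced in the plane perpendicular to v1."""
    helper = np.zeros(3)
    helper[np.argmin(np.abs(v1))] = 1.0
    e1 = np.cross(v1, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v1, e1)
    ang = np.pi * np.arange(n) / n
    return np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)


def dki_metrics(
    params: models.KurtosisParams,
    n_dirs: int = 256,
    radial_tol_deg: float = 1.0,
) -> dict:
    """DTI maps plus mean / axial / radial kurtosis.

    The directional kurtosis along v is the signed MD²·K_app(v)/D_app(v)²
    (apparent kurtosis normalized by the directional diffusivity).  MK
    averages it over the fixed ``n_dirs`` direction set; AK evaluates it
    along V1; RK averages set directions within ``radial_tol_deg`` of
    the plane perpendicular to V1, falling back to an exact
    perpendicular ring when the set has no direction in that band.
    Directions with non-positive D_app are excluded from the means.
    """
    base = dti_metrics(models.TensorParams(d=params.d, s0=params.s0))
    dirs = metric_directions(n_dirs)
    d = np.asarray(params.d, float)
    k = np.asarray(params.k, float)
    md2 = ((d[..., 0] + d[..., 1] + d[..., 2]) / 3.0) ** 2

    def directional_k(vset, dvals, kvals, md2vals):
        d_app = dvals @ models.tensor_design(vset).T
        k_app = kvals @ models.kurtosis_design(vset).T
        with np.errstate(invalid="ignore", divide="ignore"):
            out = md2vals[..., None] * k_app / d_app**2
        return np.where(d_app > 0, out, np.nan)

    kdir = directional_k(dirs, d, k, md2)  # (..., n_dirs)
    mk = np.nanmean(kdir, axis=-1)

    v1 = base["V1"]
    flat_d = d.reshape(-1, 6)
    flat_k = k.reshape(-1, 15)
    flat_md2 = md2.reshape(-1)
    flat_v1 = v1.reshape(-1, 3)
    ak = np.empty(len(flat_d))
    rk = np.empty(len(flat_d))
    sin_tol = np.sin(np.radians(radial_tol_deg))
    for i in range(len(flat_d)):
        ak[i] = directional_k(
            flat_v1[i][None], flat_d[i], flat_k[i], flat_md2[i]
        )[0]
        in_plane = np.abs(dirs @ flat_v1[i]) <= sin_tol
        ring = dirs[in_plane] if in_plane.any() else _radial_ring(flat_v1[i])
        rk[i] = np.nanmean(
            directional_k(ring, flat_d[i], flat_k[i], flat_md2[i])
        )
    base.update(
        MK=mk,
        AK=ak.reshape(md2.shape),
        RK=rk.reshape(md2.shape),
    )
    return base


def odi_from_kappa(kappa) -> np.ndarray:
    """Orientation dispersion index: ODI = (2/π)·arctan(1/κ)."""
    kappa = np.asarray(kappa, float)
    with np.errstate(divide="ignore"):
        return (2.0 / np.pi) * np.arctan(1.0 / kappa)


def mae(
    map_a,
    map_b,
    mask,
    exclusion: str = "none",
    ref_f_iso: np.ndarray | None = None,
) -> float:
    """Masked mean absolute error with the study's exclusion rules.

    ``exclusion``:
      * ``"none"`` — plain masked MAE;
      * ``"dki_p97"`` — drop voxelwise errors above the 97th percentile
        of the masked error distribution (kurtosis-metric outliers);
      * ``"noddi_fiso08"`` — drop voxels whose reference isotropic
        fraction (``ref_f_iso``) exceeds 0.8, where the remaining NODDI
        parameters are arbitrary.
    """
    mask = np.asarray(mask, bool)
    err = np.abs(np.asarray(map_a, float) - np.asarray(map_b, float))[mask]
    if exclusion == "noddi_fiso08":
        if ref_f_iso is None:
            raise ValueError("noddi_fiso08 exclusion needs ref_f_iso")
        err = err[np.asarray(ref_f_iso, float)[mask] <= 0.8]
    elif exclusion == "dki_p97":
        finite = err[np.isfinite(err)]
        if finite.size:
            err = finite[finite <= np.percentile(finite, 97)]
        else:
            err = finite
    elif exclusion != "none":
        raise ValueError(f"unknown exclusion rule {exclusion!r}")
    err = err[np.isfinite(err)]
    if err.size == 0:
        raise ValueError("no voxels left after exclusion")
    return float(err.mean())


def angular_error(v1_a, v1_b, mask=None, mean: bool = True):
    """Angle (degrees) between orientation vectors, sign-invariant."""
    a = np.asarray(v1_a, float)
    b = np.asarray(v1_b, float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs((a * b).sum(-1)) / (na * nb)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang = np.where((na > 0) & (nb > 0), ang, np.nan)
    if mask is None:
        return ang
    ang = ang[np.asarray(mask, bool)]
    return float(np.nanmean(ang)) if mean else ang


def ssim_standardized(image_a, image_b, tissue_mask) -> float:
    """SSIM after per-image standardization within the tissue mask.

    Each image is standardized with its tissue mean/std, then mapped
    through x → (x+3)/6 (values outside [0,1] from |z| > 3 tails pass
    through unclamped); SSIM uses Gaussian weighting (σ = 1.5) with the
    standard constants, averaged over the tissue mask.
    """
    mask = np.asarray(tissue_mask, bool)
    if not mask.any():
        raise ValueError("empty tissue mask")

    def standardize(img):
        img = np.asarray(img, float)
        mu = img[mask].mean()
        sd = img[mask].std()
        if sd == 0:
            raise ValueError("zero intensity variance within the mask")
        return ((img - mu) / sd + 3.0) / 6.0

    a = standardize(image_a)
    b = standardize(image_b)
    win = min(7, min(a.shape) - (1 - min(a.shape) % 2))  # largest odd ≤ extent
    _, smap = structural_similarity(
        a,
        b,
        data_range=1.0,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        win_size=win,
        full=True,
    )
    return float(smap[mask].mean())
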