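"""Differentiable forward models: diffusion tensor, kurtosis, Watson-NODDI.

Each model maps per-voxel parameters plus an acquisition scheme
(b-values b_i, unit directions v_i) to predicted signals:

* tensor:    S_i = S0 · exp(−b_i Σ_jk v_ij v_ik D_jk)
* kurtosis:  S_i = S0 · exp(−b_i Σ v v D + (1/6) b_i² MD² K_app(v_i)),
             K_app(v) = Σ_jklm v_j v_k v_l v_m K_jklm  (fully symmetric K)
* NODDI:     S_i = S0 ((1−f_iso)(f_ic A_ic + (1−f_ic) A_ec) + f_iso A_iso)
             with an intra-cellular Watson-dispersed stick, a tortuosity
             extra-cellular zeppelin averaged over the Watson
             distribution, and an isotropic CSF compartment.

All functions are written against :mod:`dwifit.autodiff`, so they accept
plain arrays (fast numpy path) or ``Var`` nodes (differentiable path
used by the self-supervised optimization).  Parameter arrays carry
arbitrary leading voxel axes; the trailing axis is the channel axis.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .sphere import sphere_quadrature

__all__ = [
    "TENSOR_CHANNELS",
    "KURTOSIS_CHANNELS",
    "NODDI_CHANNELS",
    "kurtosis_index_multisets",
    "TensorParams",
    "KurtosisParams",
    "NoddiParams",
    "NoddiConstants",
    "tensor_design",
    "kurtosis_design",
    "tensor_signal",
    "apparent_kurtosis",
    "kurtosis_signal",
    "hyp1f1",
    "hyp1f1_grad_kappa",
    "watson_density",
    "noddi_signal",
    "scale_outputs",
    "n_params",
    "save_param_maps",
    "load_param_maps",
]

TENSOR_CHANNELS = ["D11", "D22", "D33", "D12", "D13", "D23", "S0"]


def kurtosis_index_multisets() -> list[tuple[int, ...]]:
    """The 15 sorted 4-index multisets over axes {0,1,2}."""
    return list(itertools.combinations_with_replacement(range(3), 4))


def _multiplicity(ms: tuple[int, ...]) -> int:
    counts = [ms.count(a) for a in set(ms)]
    out = math.factorial(4)
    for c in counts:
        out //= math.factorial(c)
    return out


KURTOSIS_CHANNELS = (
    TENSOR_CHANNELS[:6]
    + ["K" + "".join(str(i + 1) for i in ms) for ms in kurtosis_index_multisets()]
    + ["S0"]
)
NODDI_CHANNELS = ["f_iso", "f_ic", "theta", "phi", "kappa"]

_N_PARAMS = {"tensor": 7, "kurtosis": 22, "noddi": 5}


def n_params(model: str) -> int:
    """Number of unknowns the network estimates per voxel (7 / 22 / 5)."""
    try:
        return _N_PARAMS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None


# ---------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------


@dataclass
class TensorParams:
    """Six unique diffusion-tensor elements (mm²/s) and S0.

    ``d`` has trailing axis [D11, D22, D33, D12, D13, D23]; no PSD
    constraint is imposed (linear fits may produce non-PSD tensors).
    """

    d: object  # (..., 6)
    s0: object  # (...)

    def tensor_matrices(self) -> np.ndarray:
        d = np.asarray(self.d if not isinstance(self.d, ad.Var) else self.d.value)
        m = np.zeros(d.shape[:-1] + (3, 3))
        m[..., 0, 0] = d[..., 0]
        m[..., 1, 1] = d[..., 1]
        m[..., 2, 2] = d[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = d[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = d[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = d[..., 5]
        return m


@dataclass
class KurtosisParams:
    """Tensor elements, the 15 sorted-index kurtosis elements, and S0."""

    d: object  # (..., 6)
    k: object  # (..., 15), order of kurtosis_index_multisets()
    s0: object  # (...)


@dataclass
class NoddiParams:
    """Watson-NODDI unknowns: fractions, mean orientation angles, κ.

    ``theta`` is azimuth and ``phi`` elevation; the mean orientation is
    µ = (cosφ cosθ, cosφ sinθ, sinφ).  Orientation sign is irrelevant
    (the Watson distribution is antipodally symmetric).
    """

    f_iso: object
    f_ic: object
    theta: object
    phi: object
    kappa: object

    def mu(self):
        ct, st = ad.cos(self.theta), ad.sin(self.theta)
        cp, sp = ad.cos(self.phi), ad.sin(self.phi)
        return ad.stack([cp * ct, cp * st, sp], axis=-1)


@dataclass(frozen=True)
class NoddiConstants:
    """Fixed diffusivities of the Watson-NODDI model (mm²/s).

    The canonical in-vivo values: intra/extra-cellular axial
    diffusivity 1.7e-3, CSF isotropic diffusivity 3.0e-3.
    """

    d_par: float = 1.7e-3
    d_iso: float = 3.0e-3

    def __post_init__(self):
        if self.d_par <= 0 or self.d_iso <= 0:
            raise ValueError("diffusivities must be positive")


# ---------------------------------------------------------------------
# design rows shared by signal synthesis and linear fitting
# ---------------------------------------------------------------------


def tensor_design(bvecs: np.ndarray) -> np.ndarray:
    """Quadratic-form rows: signal exponent = −b · (design @ d)."""
    v = np.atleast_2d(np.asarray(bvecs, float))
    return np.stack(
        [
            v[:, 0] ** 2,
            v[:, 1] ** 2,
            v[:, 2] ** 2,
            2 * v[:, 0] * v[:, 1],
            2 * v[:, 0] * v[:, 2],
            2 * v[:, 1] * v[:, 2],
        ],
        axis=1,
    )


def kurtosis_design(bvecs: np.ndarray) -> np.ndarray:
    """Quartic-form rows with multiset multiplicities: K_app = design @ k."""
    v = np.atleast_2d(np.asarray(bvecs, float))
    cols = []
    for ms in kurtosis_index_multisets():
        col = _multiplicity(ms) * np.prod([v[:, a] for a in ms], axis=0)
        cols.append(col)
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------
# signal models
# ---------------------------------------------------------------------


#: Symmetric clamp on signal exponents.  Physical exponents for in-vivo
#: diffusivities and b ≤ 3000 s/mm² stay well inside ±15; the clamp only
#: guards the early optimization steps, when unconstrained network
#: outputs would overflow the exponential (gradient is zero outside).
EXPONENT_CLAMP = 15.0


def tensor_signal(params: TensorParams, bvecs, bvals):
    """Gaussian (tensor) signal for every voxel × acquisition volume."""
    Q = tensor_design(bvecs)  # (n, 6)
    b = np.atleast_1d(np.asarray(bvals, float))
    expo = ad.matmul(params.d, (Q * b[:, None]).T) * (-1.0)
    s0 = params.s0
    return _mul_s0(ad.exp(ad.clip(expo, -EXPONENT_CLAMP, EXPONENT_CLAMP)), s0)


def _mul_s0(attenuation, s0):
    if isinstance(s0, ad.Var) or (np.ndim(s0) > 0 and np.asarray(s0).ndim > 0):
        return attenuation * _expand_last(s0)
    return attenuation * s0


def _expand_last(x):
    if isinstance(x, ad.Var):
        return x.reshape(x.shape + (1,))
    x = np.asarray(x)
    return x[..., None]


def apparent_kurtosis(k, bvecs):
    """Directional apparent kurtosis K_app(v) for unit directions."""
    Q4 = kurtosis_design(bvecs)  # (m, 15)
    return ad.matmul(k, Q4.T)


def kurtosis_signal(params: KurtosisParams, bvecs, bvals):
    """Kurtosis-model signal; MD is computed from the tensor part."""
    Q = tensor_design(bvecs)
    b = np.atleast_1d(np.asarray(bvals, float))
    quad = ad.matmul(params.d, (Q * b[:, None]).T)
    md = (params.d[..., 0] + params.d[..., 1] + params.d[..., 2]) * (1.0 / 3.0)
    kapp = apparent_kurtosis(params.k, bvecs)
    expo = -quad + kapp * _expand_last(md**2) * ((b**2) / 6.0)
    return _mul_s0(ad.exp(ad.clip(expo, -EXPONENT_CLAMP, EXPONENT_CLAMP)), params.s0)


def hyp1f1(a: float, b: float, x):
    """Confluent hypergeometric ₁F₁(a; b; x) (differentiable in x)."""
    return ad.hyp1f1_half(x, a, b)


def hyp1f1_grad_kappa(kappa):
    """d/dκ ₁F₁(0.5, 1.5, κ) = (1/3) ₁F₁(1.5, 2.5, κ)."""
    return ad.hyp1f1_half(kappa, 1.5, 2.5) * (1.0 / 3.0)


def watson_density(n, mu, kappa):
    """Watson density W(n | µ, κ) = exp(κ(µ·n)²) / (4π ₁F₁(½,³⁄₂,κ))."""
    n = np.atleast_2d(np.asarray(n, float))
    dot2 = ad.matmul(mu, n.T) ** 2
    norm = ad.hyp1f1_half(kappa, 0.5, 1.5) * (4.0 * np.pi)
    return ad.exp(dot2 * _expand_if(kappa, dot2)) / _expand_if(norm, dot2)


def _expand_if(x, like):
    """Broadcast a (...,) quantity against a (..., m) quantity."""
    ndim_like = like.ndim if isinstance(like, (ad.Var, np.ndarray)) else np.ndim(like)
    ndim_x = x.ndim if isinstance(x, (ad.Var, np.ndarray)) else np.ndim(x)
    if ndim_x == ndim_like - 1:
        return _expand_last(x)
    return x


def _watson_tau1(kappa):
    """E[(µ·n)²] under Watson(κ): ₁F₁(³⁄₂,⁵⁄₂,κ) / (3 ₁F₁(½,³⁄₂,κ))."""
    return ad.hyp1f1_half(kappa, 1.5, 2.5) / (ad.hyp1f1_half(kappa, 0.5, 1.5) * 3.0)


def noddi_signal(
    params: NoddiParams,
    bvecs,
    bvals,
    s0,
    consts: NoddiConstants = NoddiConstants(),
    quad_order: int = 28,
    ec_dispersion: bool = True,
):
    """Watson-NODDI signal for every voxel × acquisition volume.

    The intra-cellular compartment is a stick dispersed by the Watson
    distribution, integrated with a fixed sphere quadrature; because the
    integrand is exp(κ(µ·n)² − b d∥(v·n)²), the acquisition-dependent
    factor is precomputed once and the per-voxel factor reduces to a
    single matrix product, which keeps training fast.  The
    extra-cellular compartment is the Watson-orientation-averaged
    tortuosity zeppelin (radial diffusivity d∥·(1−f_ic));
    ``ec_dispersion=False`` switches off the κ-average (zeppelin aligned
    with µ).  ``s0`` is an input map, not a fitted parameter.
    """
    nodes, weights = sphere_quadrature(quad_order)
    b = np.atleast_1d(np.asarray(bvals, float))
    v = np.atleast_2d(np.asarray(bvecs, float))
    mu = params.mu()
    kappa = params.kappa

    # intra-cellular: Watson-dispersed stick.  The acquisition factor E
    # is parameter-free and precomputed; per voxel only exp(κ u²) and
    # one matmul remain.
    E = np.exp(-(b[:, None] * consts.d_par) * (v @ nodes.T) ** 2)  # (n, Q)
    u2 = ad.matmul(mu, nodes.T) ** 2  # (..., Q)
    w_watson = ad.exp(u2 * _expand_if(kappa, u2))
    norm = ad.hyp1f1_half(kappa, 0.5, 1.5) * (4.0 * np.pi)
    raw = ad.matmul(w_watson * weights, E.T)  # (..., n)
    a_ic = raw / _expand_if(norm, raw)

    # extra-cellular: orientation-averaged tortuosity zeppelin
    tau1 = _watson_tau1(kappa) if ec_dispersion else 1.0
    d_perp_i = (1.0 - params.f_ic) * consts.d_par
    delta = consts.d_par - d_perp_i  # = d_par * f_ic
    d_par_m = d_perp_i + delta * tau1
    d_perp_m = d_perp_i + delta * (1.0 - tau1) * 0.5
    mu_dot_v2 = ad.matmul(mu, v.T) ** 2  # (..., n)
    dd = _expand_if(d_perp_m, mu_dot_v2) + _expand_if(d_par_m - d_perp_m, mu_dot_v2) * mu_dot_v2
    a_ec = ad.exp(dd * (-b))

    # CSF
    a_iso = np.exp(-b * consts.d_iso)  # (n,)

    f_iso = _expand_if(params.f_iso, a_ec)
    f_ic = _expand_if(params.f_ic, a_ec)
    tissue = a_ic * f_ic + a_ec * (1.0 - f_ic)
    total = tissue * (1.0 - f_iso) + f_iso * a_iso
    return _mul_s0(total, s0)


# ---------------------------------------------------------------------
# network-output scaling
# ---------------------------------------------------------------------


#: Raw network diffusivity channels are in µm²/ms (the natural O(1)
#: scale for white matter); this converts them to mm²/s.
DIFFUSIVITY_SCALE = 1e-3


def scale_outputs(model: str, raw):
    """Map raw network output channels to model parameters.

    Tensor and kurtosis channels receive no squashing: the diffusivity
    channels are read in µm²/ms and linearly converted to mm²/s
    (kurtosis and S0 channels pass through unchanged).  For NODDI the
    fractions go through a sigmoid; the concentration channel x maps to
    sigmoid(x) for x<0 and 0.5+x for x≥0 (continuous at 0, unbounded
    above so large concentrations stay reachable); the two orientation
    angles pass through unchanged.
    """
    nc = raw.shape[-1]
    if nc != n_params(model):
        raise ValueError(
            f"model {model!r} expects {n_params(model)} channels, got {nc}"
        )
    if model == "tensor":
        return TensorParams(d=raw[..., :6] * DIFFUSIVITY_SCALE, s0=raw[..., 6])
    if model == "kurtosis":
        return KurtosisParams(
            d=raw[..., :6] * DIFFUSIVITY_SCALE, k=raw[..., 6:21], s0=raw[..., 21]
        )
    x = raw[..., 4]
    xv = x.value if isinstance(x, ad.Var) else np.asarray(x)
    kappa = ad.where(xv < 0, ad.sigmoid(x), x + 0.5)
    return NoddiParams(
        f_iso=ad.sigmoid(raw[..., 0]),
        f_ic=ad.sigmoid(raw[..., 1]),
        theta=raw[..., 2],
        phi=raw[..., 3],
        kappa=kappa,
    )


# ---------------------------------------------------------------------
# parameter-map serialization (multi-channel NIfTI + JSON sidecar)
# ---------------------------------------------------------------------


def _params_to_array(model: str, params) -> np.ndarray:
    def val(x):
        return x.value if isinstance(x, ad.Var) else np.asarray(x)

    if model == "tensor":
        return np.concatenate([val(params.d), val(params.s0)[..., None]], axis=-1)
    if model == "kurtosis":
        return np.concatenate(
            [val(params.d), val(params.k), val(params.s0)[..., None]], axis=-1
        )
    return np.stack(
        [val(params.f_iso), val(params.f_ic), val(params.theta), val(params.phi),
         val(params.kappa)],
        axis=-1,
    )


def _params_from_array(model: str, arr: np.ndarray):
    if model == "tensor":
        return TensorParams(d=arr[..., :6], s0=arr[..., 6])
    if model == "kurtosis":
        return KurtosisParams(d=arr[..., :6], k=arr[..., 6:21], s0=arr[..., 21])
    return NoddiParams(
        f_iso=arr[..., 0], f_ic=arr[..., 1], theta=arr[..., 2], phi=arr[..., 3],
        kappa=arr[..., 4],
    )


_CHANNELS = {
    "tensor": TENSOR_CHANNELS,
    "kurtosis": KURTOSIS_CHANNELS,
    "noddi": NODDI_CHANNELS,
}


def save_param_maps(model: str, params, path, affine=None) -> None:
    """Write a parameter map as multi-channel NIfTI + JSON channel sidecar."""
    from .volume import save_nifti

    arr = _params_to_array(model, params)
    save_nifti(arr, path, affine=affine)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    sidecar.write_text(
        json.dumps({"model": model, "channels": _CHANNELS[model]}, indent=2) + "\n"
    )


def load_param_maps(path):
    """Read a parameter map written by :func:`save_param_maps`."""
    import nibabel as nib

    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    meta = json.loads(sidecar.read_text())
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return meta["model"], _params_from_array(meta["model"], arr)
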