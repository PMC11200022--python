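"""Synthetic diffusion phantoms with known ground truth.

The simulator reproduces a multi-tensor protocol: every voxel holds one
to three identical-eigenvalue tensors with randomly oriented principal
axes, sampled on a 236-volume scheme (18 b=0, 90 b=1000 s/mm²
"HCP-like" directions whose prefixes are uniform, plus 128 additional
uniform b=1000 s/mm² directions), optionally corrupted with Rician
noise at a chosen SNR.  Kurtosis and Watson-NODDI phantoms reuse the
forward models of :mod:`dwifit.models`, so the simulator and the
fitters share one signal definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .gradients import GradientTable
from .sphere import uniform_sphere_directions
from .volume import DwiVolume

__all__ = [
    "SimSpec",
    "PhantomTruth",
    "default_scheme",
    "two_shell_scheme",
    "three_shell_scheme",
    "random_multi_tensor",
    "multi_tensor_signal",
    "add_rician_noise",
    "make_phantom",
    "make_kurtosis_phantom",
    "make_noddi_phantom",
]

#: Documented seeds of the shipped synthetic acquisition schemes.
HCP_LIKE_SEED = 90
EXTRA_SET_SEED = 128

#: Per-tensor eigenvalues of the multi-tensor phantom (mm²/s).
DEFAULT_EIGVALS = (1.5e-3, 3.0e-4, 3.0e-4)


@dataclass(frozen=True)
class SimSpec:
    """Simulation conditions for :func:`make_phantom` and friends.

    Defaults are the study conditions: a 64×64×128 grid, eigenvalues
    [1.5e-3, 3e-4, 3e-4] mm²/s, one to three tensors per voxel, unit S0.
    ``snr=None`` produces noise-free data; the noisy conditions are SNR
    10 and 20.
    """

    grid: tuple[int, int, int] = (64, 64, 128)
    eigvals: tuple[float, float, float] = DEFAULT_EIGVALS
    n_tensors_choices: tuple[int, ...] = (1, 2, 3)
    snr: float | None = None
    seed: int = 0
    s0: float = 1.0
    scheme: GradientTable | None = None

    def __post_init__(self):
        if any(g <= 0 for g in self.grid):
            raise ValueError("grid dimensions must be positive")
        ev = np.asarray(self.eigvals, float)
        if np.any(ev <= 0) or np.any(np.diff(ev) > 0):
            raise ValueError("eigenvalues must be positive, sorted descending")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if not set(self.n_tensors_choices) <= {1, 2, 3}:
            raise ValueError("n_tensors_choices must be a subset of {1,2,3}")


@dataclass
class PhantomTruth:
    """Ground truth retained alongside a simulated volume."""

    tensors: list  # per voxel: (T, 3, 3) symmetric PSD tensors
    signal_clean: np.ndarray  # noise-free signal, X×Y×Z×n
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    v1: np.ndarray  # X×Y×Z×3 unit principal eigenvectors


def default_scheme() -> GradientTable:
    """The 236-sample single-shell scheme: 18 b=0 + 90 + 128 at b=1000."""
    hcp = uniform_sphere_directions(90, HCP_LIKE_SEED)
    extra = uniform_sphere_directions(128, EXTRA_SET_SEED)
    bvals = np.concatenate([np.zeros(18), np.full(218, 1000.0)])
    bvecs = np.concatenate([np.zeros((18, 3)), hcp, extra])
    return GradientTable(bvals, bvecs)


def _shell_scheme(n_b0: int, shells: dict[float, int]) -> GradientTable:
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for i, (b, n) in enumerate(sorted(shells.items())):
        bvals.append(np.full(n, b))
        bvecs.append(uniform_sphere_directions(n, HCP_LIKE_SEED + i))
    return GradientTable(np.concatenate(bvals), np.concatenate(bvecs))


def two_shell_scheme(n_b0: int = 3, n_per_shell: int = 30) -> GradientTable:
    """b = 1000 + 2000 s/mm² kurtosis scheme."""
    return _shell_scheme(n_b0, {1000.0: n_per_shell, 2000.0: n_per_shell})


def three_shell_scheme(n_b0: int = 3, n_per_shell: int = 15) -> GradientTable:
    """b = 1000 + 2000 + 3000 s/mm² NODDI scheme."""
    return _shell_scheme(
        n_b0, {1000.0: n_per_shell, 2000.0: n_per_shell, 3000.0: n_per_shell}
    )


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit axis from azimuth θ and elevation Φ (radians)."""
    return np.array(
        [np.cos(phi) * np.cos(theta), np.cos(phi) * np.sin(theta), np.sin(phi)]
    )


def _tensor_from_axis(axis: np.ndarray, eigvals, rng: np.random.Generator):
    """Symmetric PSD tensor with given principal axis and eigenvalues."""
    e1 = axis / np.linalg.norm(axis)
    helper = rng.standard_normal(3)
    helper -= e1 * (helper @ e1)
    while np.linalg.norm(helper) < 1e-8:  # pragma: no cover - measure zero
        helper = rng.standard_normal(3)
        helper -= e1 * (helper @ e1)
    e2 = helper / np.linalg.norm(helper)
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=1)
    return R @ np.diag(eigvals) @ R.T


def random_multi_tensor(
    seed_or_rng,
    n_tensors_choices=(1, 2, 3),
    eigvals=DEFAULT_EIGVALS,
    angles: tuple[float, float] | None = None,
) -> list[np.ndarray]:
    """Draw the tensor set of one voxel.

    The tensor count is uniform over ``n_tensors_choices``; each
    principal axis has azimuth θ ~ U(0°, 360°) and elevation
    Φ ~ U(−90°, 90°) sampled independently (rectangle-uniform in the
    angles, which is deliberately not area-uniform on the sphere).
    ``angles`` pins (θ, Φ) in radians for a single-tensor draw.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    count = int(rng.choice(list(n_tensors_choices)))
    out = []
    for _ in range(count):
        if angles is not None:
            theta, phi = angles
        else:
            theta = rng.uniform(0.0, 2 * np.pi)
            phi = rng.uniform(-np.pi / 2, np.pi / 2)
        out.append(_tensor_from_axis(_axis_from_angles(theta, phi), eigvals, rng))
    return out


def multi_tensor_signal(
    tensors, gradients: GradientTable, s0: float = 1.0
) -> np.ndarray:
    """Equal-fraction multi-tensor signal S = s0 · (1/T) Σ_t exp(−b vᵀD_t v)."""
    if len(tensors) == 0:
        raise ValueError("need at least one tensor")
    v, b = gradients.bvecs, gradients.bvals
    quad = np.stack([np.einsum("ij,jk,ik->i", v, D, v) for D in tensors])
    return s0 * np.exp(-b * quad).mean(axis=0)


def add_rician_noise(signal, s0: float, snr: float, seed_or_rng) -> np.ndarray:
    """Rician-corrupt a signal: sqrt((S+ε₁)² + ε₂²), ε ~ N(0, (s0/snr)²)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sigma = s0 / snr
    signal = np.asarray(signal, float)
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def _truth_maps_from_signal(signal_clean, scheme):
    """Ground-truth scalar maps: OLS tensor fit of the noise-free data."""
    from .classical import ols_tensor_fit
    from .metrics import dti_metrics

    vol = DwiVolume(signal_clean, scheme)
    params, _ = ols_tensor_fit(vol)
    return dti_metrics(params)


def make_phantom(spec: SimSpec = SimSpec()) -> tuple[DwiVolume, PhantomTruth]:
    """Simulate a multi-tensor volume; masks are all-true.

    Ground-truth scalar maps (FA/MD/AD/V1) are derived from the
    noise-free signal with the OLS tensor fit, mirroring how a
    reference fit on noise-free data defines the truth.
    """
    scheme = spec.scheme if spec.scheme is not None else default_scheme()
    rng = np.random.default_rng(spec.seed)
    nvox = int(np.prod(spec.grid))
    tensors = []
    clean = np.empty((nvox, scheme.n))
    for i in range(nvox):
        ts = random_multi_tensor(rng, spec.n_tensors_choices, spec.eigvals)
        tensors.append(np.stack(ts))
        clean[i] = multi_tensor_signal(ts, scheme, spec.s0)
    clean = clean.reshape(spec.grid + (scheme.n,))
    signal = (
        clean
        if spec.snr is None
        else add_rician_noise(clean, spec.s0, spec.snr, rng)
    )
    m = _truth_maps_from_signal(clean, scheme)
    truth = PhantomTruth(
        tensors=tensors,
        signal_clean=clean,
        fa=m["FA"],
        md=m["MD"],
        ad=m["AD"],
        v1=m["V1"],
    )
    return DwiVolume(signal, scheme), truth


def _sym_outer4(u: np.ndarray) -> np.ndarray:
    """15 sorted-index elements of u⊗u⊗u⊗u (K_app(v) = (u·v)⁴)."""
    return np.array(
        [np.prod([u[a] for a in ms]) for ms in models.kurtosis_index_multisets()]
    )


_K_ISO = None


def _iso_kurtosis() -> np.ndarray:
    """15-element kurtosis with K_app(v) ≡ 1 for all unit v."""
    global _K_ISO
    if _K_ISO is None:
        k = np.zeros(15)
        names = models.KURTOSIS_CHANNELS[6:21]
        for nm in ("K1111", "K2222", "K3333"):
            k[names.index(nm)] = 1.0
        for nm in ("K1122", "K1133", "K2233"):
            k[names.index(nm)] = 1.0 / 3.0
        _K_ISO = k
    return _K_ISO


def make_kurtosis_phantom(
    spec: SimSpec,
    k_iso_range: tuple[float, float] = (0.3, 1.5),
    k_aniso_max: float = 1.5,
) -> tuple[DwiVolume, models.KurtosisParams]:
    """Kurtosis recovery phantom on the two-shell scheme.

    Per voxel: a single anisotropic tensor, plus a kurtosis tensor
    K = a·K_iso + c·(u⊗u⊗u⊗u) whose apparent kurtosis lies in
    [a, a+c] ⊆ [0, 3] along every direction.  Signals come from
    :func:`dwifit.models.kurtosis_signal`.
    """
    if not (0 <= k_iso_range[0] <= k_iso_range[1]) or k_iso_range[1] + k_aniso_max > 3:
        raise ValueError("apparent-kurtosis targets must stay within [0, 3]")
    scheme = spec.scheme if spec.scheme is not None else two_shell_scheme()
    rng = np.random.default_rng(spec.seed)
    nvox = int(np.prod(spec.grid))
    d = np.empty((nvox, 6))
    k = np.empty((nvox, 15))
    for i in range(nvox):
        D = random_multi_tensor(rng, (1,), spec.eigvals)[0]
        d[i] = [D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]]
        a = rng.uniform(*k_iso_range)
        c = rng.uniform(0.0, k_aniso_max)
        u = _axis_from_angles(
            rng.uniform(0, 2 * np.pi), rng.uniform(-np.pi / 2, np.pi / 2)
        )
        k[i] = a * _iso_kurtosis() + c * _sym_outer4(u)
    shape = spec.grid + (-1,)
    params = models.KurtosisParams(
        d=d.reshape(shape), k=k.reshape(shape), s0=np.full(spec.grid, spec.s0)
    )
    clean = models.kurtosis_signal(params, scheme.bvecs, scheme.bvals)
    signal = (
        clean if spec.snr is None else add_rician_noise(clean, spec.s0, spec.snr, rng)
    )
    return DwiVolume(signal, scheme), params


def make_noddi_phantom(
    spec: SimSpec,
    f_range: tuple[float, float] = (0.05, 0.95),
    kappa_range: tuple[float, float] = (0.5, 16.0),
    consts: models.NoddiConstants = models.NoddiConstants(),
) -> tuple[DwiVolume, models.NoddiParams]:
    """Watson-NODDI recovery phantom on the three-shell scheme.

    Fractions are uniform in ``f_range``, κ log-uniform in
    ``kappa_range``, orientations rectangle-uniform in (θ, Φ).  Signals
    come from :func:`dwifit.models.noddi_signal`.
    """
    if not (0.05 <= f_range[0] <= f_range[1] <= 0.95):
        raise ValueError("fractions must lie within [0.05, 0.95]")
    if not (0.5 <= kappa_range[0] <= kappa_range[1] <= 16.0):
        raise ValueError("kappa must lie within [0.5, 16]")
    scheme = spec.scheme if spec.scheme is not None else three_shell_scheme()
    rng = np.random.default_rng(spec.seed)
    nvox = int(np.prod(spec.grid))
    params = models.NoddiParams(
        f_iso=rng.uniform(*f_range, nvox).reshape(spec.grid),
        f_ic=rng.uniform(*f_range, nvox).reshape(spec.grid),
        theta=rng.uniform(0, 2 * np.pi, nvox).reshape(spec.grid),
        phi=rng.uniform(-np.pi / 2, np.pi / 2, nvox).reshape(spec.grid),
        kappa=np.exp(
            rng.uniform(np.log(kappa_range[0]), np.log(kappa_range[1]), nvox)
        ).reshape(spec.grid),
    )
    clean = models.noddi_signal(
        params, scheme.bvecs, scheme.bvals, spec.s0, consts
    )
    signal = (
        clean if spec.snr is None else add_rician_noise(clean, spec.s0, spec.snr, rng)
    )
    return DwiVolume(signal, scheme), params
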