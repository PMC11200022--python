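"""Forward-model correctness against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import special as sp

from dwifit import autodiff as ad
from dwifit import models
from dwifit.sphere import sphere_quadrature, uniform_sphere_directions


def brute_tensor_signal(d6, s0, v, b):
    """Explicit double-sum of the quadratic form (independent oracle)."""
    D = np.array(
        [
            [d6[0], d6[3], d6[4]],
            [d6[3], d6[1], d6[5]],
            [d6[4], d6[5], d6[2]],
        ]
    )
    expo = sum(
        v[j] * v[k] * D[j, k] for j in range(3) for k in range(3)
    )
    return s0 * np.exp(-b * expo)


def brute_kapp(k15, v):
    """Full 81-term quartic sum with sorted-index lookup."""
    table = {
        ms: k15[i] for i, ms in enumerate(models.kurtosis_index_multisets())
    }
    return sum(
        v[j] * v[k] * v[l] * v[m] * table[tuple(sorted((j, k, l, m)))]
        for j, k, l, m in itertools.product(range(3), repeat=4)
    )


def brute_kurtosis_signal(d6, k15, s0, v, b):
    md = (d6[0] + d6[1] + d6[2]) / 3.0
    quad = -np.log(brute_tensor_signal(d6, 1.0, v, b)) / b if b > 0 else 0.0
    return s0 * np.exp(-b * quad + (b**2 / 6.0) * md**2 * brute_kapp(k15, v))


def _random_tensor_draw(rng):
    d = np.array([1.5e-3, 1.0e-3, 5e-4, 1e-4, -1e-4, 5e-5]) * rng.uniform(
        0.5, 1.5, 6
    )
    return d


def test_tensor_signal_matches_brute_force(rng):
    vs = uniform_sphere_directions(20, 3)
    for _ in range(100):
        d = _random_tensor_draw(rng)
        s0 = rng.uniform(0.5, 2.0)
        v = vs[rng.integers(20)]
        b = rng.choice([0.0, 1000.0, 2000.0])
        got = models.tensor_signal(
            models.TensorParams(d=d, s0=s0), v[None], np.array([b])
        )[0]
        assert abs(got - brute_tensor_signal(d, s0, v, b)) < 1e-12


def test_tensor_signal_examples():
    p = models.TensorParams(d=np.array([1.5e-3, 3e-4, 3e-4, 0, 0, 0]), s0=1.0)
    out = models.tensor_signal(p, np.array([[1.0, 0, 0]]), np.array([1000.0]))
    assert abs(out[0] - 0.223130) < 1e-6
    # b = 0 returns S0 for any tensor
    out0 = models.tensor_signal(p, np.array([[0.57735] * 3]), np.array([0.0]))
    assert abs(out0[0] - 1.0) < 1e-15
    # isotropic tensor attenuates equally in every direction
    iso = models.TensorParams(d=np.array([7e-4] * 3 + [0.0] * 3), s0=2.0)
    dirs = uniform_sphere_directions(5, 1)
    vals = models.tensor_signal(iso, dirs, np.full(5, 1000.0))
    assert np.allclose(vals, 2.0 * np.exp(-0.7), atol=1e-14)


def test_apparent_kurtosis_matches_81_term_sum(rng):
    vs = uniform_sphere_directions(15, 5)
    for _ in range(100):
        k15 = rng.standard_normal(15)
        v = vs[rng.integers(15)]
        got = models.apparent_kurtosis(k15, v[None])[0]
        assert abs(got - brute_kapp(k15, v)) < 1e-12


def test_apparent_kurtosis_examples():
    names = models.KURTOSIS_CHANNELS[6:21]
    k = np.zeros(15)
    assert models.apparent_kurtosis(k, np.array([[1.0, 0, 0]]))[0] == 0.0
    k[names.index("K1111")] = 1.0
    assert abs(models.apparent_kurtosis(k, np.array([[1.0, 0, 0]]))[0] - 1) < 1e-15
    k2 = np.zeros(15)
    k2[names.index("K1111")] = 1.0
    k2[names.index("K2222")] = 1.0
    v = np.array([[2**-0.5, 2**-0.5, 0.0]])
    assert abs(models.apparent_kurtosis(k2, v)[0] - 0.5) < 1e-14


def test_kurtosis_signal_matches_brute_force(rng):
    vs = uniform_sphere_directions(12, 9)
    for _ in range(100):
        d = _random_tensor_draw(rng)
        k15 = rng.uniform(-0.5, 2.0, 15)
        s0 = rng.uniform(0.5, 2.0)
        v = vs[rng.integers(12)]
        b = rng.choice([1000.0, 2000.0])
        got = models.kurtosis_signal(
            models.KurtosisParams(d=d, k=k15, s0=s0), v[None], np.array([b])
        )[0]
        assert abs(got - brute_kurtosis_signal(d, k15, s0, v, b)) < 1e-12


def test_kurtosis_reduces_to_tensor_when_k_zero(rng):
    vs = uniform_sphere_directions(10, 2)
    b = np.array([0.0, 1000.0, 2000.0] * 3 + [1000.0])
    for _ in range(100):
        d = _random_tensor_draw(rng)
        s0 = rng.uniform(0.5, 2.0)
        kp = models.KurtosisParams(d=d, k=np.zeros(15), s0=s0)
        tp = models.TensorParams(d=d, s0=s0)
        a = models.kurtosis_signal(kp, vs, b[: len(vs)])
        bsig = models.tensor_signal(tp, vs, b[: len(vs)])
        assert np.max(np.abs(a - bsig)) < 1e-14


def test_kurtosis_signal_scalar_example():
    names = models.KURTOSIS_CHANNELS[6:21]
    k = np.zeros(15)
    for nm, val in [("K1111", 1), ("K2222", 1), ("K3333", 1),
                    ("K1122", 1 / 3), ("K1133", 1 / 3), ("K2233", 1 / 3)]:
        k[names.index(nm)] = val
    p = models.KurtosisParams(d=np.array([1e-3] * 3 + [0.0] * 3), k=k, s0=1.0)
    v = np.array([[0.6, 0.8, 0.0]])
    out = models.kurtosis_signal(p, v, np.array([1000.0]))
    assert abs(out[0] - np.exp(-5.0 / 6.0)) < 1e-12


def _rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _rotate_d6(d6, R):
    D = models.TensorParams(d=d6[None], s0=np.ones(1)).tensor_matrices()[0]
    D2 = R @ D @ R.T
    return np.array([D2[0, 0], D2[1, 1], D2[2, 2], D2[0, 1], D2[0, 2], D2[1, 2]])


def test_tensor_rotation_equivariance(rng):
    vs = uniform_sphere_directions(8, 4)
    b = np.full(8, 1000.0)
    for _ in range(20):
        d = _random_tensor_draw(rng)
        R = _rotation(rng)
        p = models.TensorParams(d=d, s0=1.0)
        p_rot = models.TensorParams(d=_rotate_d6(d, R), s0=1.0)
        a = models.tensor_signal(p, vs, b)
        bsig = models.tensor_signal(p_rot, vs @ R.T, b)
        assert np.max(np.abs(a - bsig)) < 1e-8


def test_noddi_rotation_equivariance(rng):
    vs = uniform_sphere_directions(8, 4)
    b = np.full(8, 2000.0)
    for _ in range(5):
        theta, phi = rng.uniform(0, 2 * np.pi), rng.uniform(-1.2, 1.2)
        kappa = rng.uniform(1, 8)
        p = models.NoddiParams(
            f_iso=np.array([0.2]), f_ic=np.array([0.6]),
            theta=np.array([theta]), phi=np.array([phi]), kappa=np.array([kappa]),
        )
        R = _rotation(rng)
        mu = np.asarray(p.mu())[0]
        mu_r = R @ mu
        p_rot = models.NoddiParams(
            f_iso=p.f_iso, f_ic=p.f_ic,
            theta=np.array([np.arctan2(mu_r[1], mu_r[0])]),
            phi=np.array([np.arcsin(np.clip(mu_r[2], -1, 1))]),
            kappa=p.kappa,
        )
        a = models.noddi_signal(p, vs, b, 1.0)
        bsig = models.noddi_signal(p_rot, vs @ R.T, b, 1.0)
        assert np.max(np.abs(a - bsig)) < 1e-8


def test_hyp1f1_values_against_erfi_identity():
    """F(0.5,1.5,x) = (√π/2)·erfi(√x)/√x for x > 0."""
    assert models.hyp1f1(0.5, 1.5, 0.0) == 1.0
    for x in [0.5, 1.0, 4.0, 25.0]:
        expected = np.sqrt(np.pi) / 2 * sp.erfi(np.sqrt(x)) / np.sqrt(x)
        assert abs(models.hyp1f1(0.5, 1.5, x) - expected) < 1e-10 * expected
    assert abs(models.hyp1f1(0.5, 1.5, 1.0) - 1.462652) < 1e-6


def test_hyp1f1_grad_kappa_form():
    got = models.hyp1f1_grad_kappa(np.array([0.0, 2.0]))
    expected = sp.hyp1f1(1.5, 2.5, [0.0, 2.0]) / 3.0
    assert np.allclose(got, expected, rtol=1e-12)


def test_watson_density_properties():
    mu = np.array([0.0, 0.0, 1.0])
    # kappa -> 0 gives the uniform density 1/(4π)
    w = models.watson_density(np.array([[1.0, 0, 0]]), mu, np.array(1e-12))
    assert abs(w[0] - 1 / (4 * np.pi)) < 1e-10
    # ratio between parallel and perpendicular evaluation is e^kappa
    w2 = models.watson_density(
        np.array([[0, 0, 1.0], [1.0, 0, 0]]), mu, np.array(3.0)
    )
    assert abs(w2[0] / w2[1] - np.e**3) < 1e-10
    # antipodal symmetry
    w3 = models.watson_density(
        np.array([[0.3, 0.4, np.sqrt(0.75)], [-0.3, -0.4, -np.sqrt(0.75)]]),
        mu, np.array(5.0),
    )
    assert abs(w3[0] - w3[1]) < 1e-14
    # integrates to one over the sphere
    nodes, wq = sphere_quadrature()
    dens = models.watson_density(nodes, mu, np.array(16.0))
    assert abs(np.asarray(dens) @ wq - 1.0) < 1e-4


def test_noddi_signal_collapses():
    b = np.array([0.0, 1000.0, 3000.0])
    vs = np.array([[0, 0, 0.0], [1.0, 0, 0], [0, 1.0, 0]])
    # b=0 returns s0
    p = models.NoddiParams(
        f_iso=np.array([0.3]), f_ic=np.array([0.6]),
        theta=np.array([1.0]), phi=np.array([-0.4]), kappa=np.array([2.0]),
    )
    out = models.noddi_signal(p, vs, b, 2.5)
    assert abs(out[0, 0] - 2.5) < 1e-12
    # f_iso = 1 collapses to the CSF ball
    p_iso = models.NoddiParams(
        f_iso=np.array([1.0]), f_ic=np.array([0.5]),
        theta=np.array([0.3]), phi=np.array([0.2]), kappa=np.array([4.0]),
    )
    out = models.noddi_signal(p_iso, vs, b, 1.0)
    assert np.max(np.abs(out[0] - np.exp(-b * 3.0e-3))) < 1e-12


def test_noddi_large_kappa_stick_limit():
    """A nearly parallel stick shows almost no attenuation across it."""
    p = models.NoddiParams(
        f_iso=np.array([0.0]), f_ic=np.array([1.0]),
        theta=np.array([0.0]), phi=np.array([0.0]), kappa=np.array([64.0]),
    )
    out = models.noddi_signal(p, np.array([[0, 0, 1.0]]), np.array([1000.0]), 1.0)
    assert abs(out[0, 0] - 1.0) < 0.02


def test_noddi_kappa_gradient_matches_finite_differences():
    b = np.array([0.0, 1000.0, 2000.0, 3000.0])
    vs = np.array([[0, 0, 0.0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])

    def f(kv):
        p = models.NoddiParams(
            f_iso=ad.Var(np.array([0.2])), f_ic=ad.Var(np.array([0.6])),
            theta=ad.Var(np.array([0.7])), phi=ad.Var(np.array([0.1])),
            kappa=kv,
        )
        return ad.vsum(models.noddi_signal(p, vs, b, 1.0))

    for kappa in [0.5, 1.0, 4.0, 16.0]:
        auto, num = ad.grad_check(f, np.array([kappa]), eps=1e-4)
        assert abs(auto[0] - num[0]) / abs(num[0]) < 1e-5


def test_intracellular_attenuation_monotone_in_b():
    p = models.NoddiParams(
        f_iso=np.array([0.0]), f_ic=np.array([1.0]),
        theta=np.array([0.4]), phi=np.array([0.2]), kappa=np.array([3.0]),
    )
    v = np.array([[0.6, 0.8, 0.0]])
    bgrid = np.linspace(0, 5000, 21)
    vals = np.array(
        [models.noddi_signal(p, v, np.array([b]), 1.0)[0, 0] for b in bgrid]
    )
    assert np.all(np.diff(vals) <= 1e-12)


def test_scale_outputs_tensor_and_kurtosis_units():
    raw = np.zeros((2, 7))
    raw[:, :6] = 1.5  # µm²/ms
    raw[:, 6] = 0.9
    p = models.scale_outputs("tensor", raw)
    assert np.allclose(np.asarray(p.d), 1.5e-3)
    assert np.allclose(np.asarray(p.s0), 0.9)
    rawk = np.zeros((1, 22))
    rawk[0, 6] = 2.0  # kurtosis channel is dimensionless, unscaled
    pk = models.scale_outputs("kurtosis", rawk)
    assert pk.k[0, 0] == 2.0


@pytest.mark.parametrize(
    "x,expected",
    [(0.0, 0.5), (3.0, 3.5), (-np.log(3.0), 0.25)],
)
def test_scale_outputs_noddi_kappa(x, expected):
    raw = np.zeros((1, 5))
    raw[0, 4] = x
    p = models.scale_outputs("noddi", raw)
    assert abs(float(np.asarray(p.kappa)[0]) - expected) < 1e-12


def test_scale_outputs_rejects_wrong_width():
    with pytest.raises(ValueError):
        models.scale_outputs("tensor", np.zeros((1, 5)))


def test_param_map_serialization_round_trip(tmp_path, rng):
    p = models.KurtosisParams(
        d=rng.random((3, 3, 3, 6)) * 1e-3,
        k=rng.random((3, 3, 3, 15)),
        s0=rng.random((3, 3, 3)),
    )
    models.save_param_maps("kurtosis", p, tmp_path / "maps.nii.gz")
    model, back = models.load_param_maps(tmp_path / "maps.nii.gz")
    assert model == "kurtosis"
    assert np.allclose(back.d, p.d) and np.allclose(back.k, p.k)
    sidecar = (tmp_path / "maps.json").read_text()
    assert "K1111" in sidecar
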