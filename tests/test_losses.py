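"""Objectives: masked MSE, log-linear designs, OLS, CWLS components."""

import numpy as np
import pytest
from scipy import optimize

from dwifit import autodiff as ad
from dwifit import losses, models, phantom
from dwifit.gradients import GradientTable
from dwifit.sphere import bound_directions, uniform_sphere_directions


def test_mse_loss_hand_examples():
    mask = np.ones((1, 1, 1), bool)
    s = np.zeros((1, 1, 1, 1))
    s[..., 0] = 1.0
    assert losses.mse_loss(s, s, mask) == 0.0
    assert losses.mse_loss(s, np.zeros_like(s), mask) == 1.0
    # two volumes, residuals (1, 0) and (0, 2) on one voxel -> (1+4)/2
    s2 = np.zeros((1, 1, 1, 2))
    pred = np.zeros_like(s2)
    s2[..., 0] = 1.0
    pred[..., 1] = 2.0
    assert losses.mse_loss(s2, pred, mask) == 2.5


def test_mse_loss_rejects_empty_mask():
    with pytest.raises(ValueError):
        losses.mse_loss(
            np.ones((2, 2, 2, 3)), np.ones((2, 2, 2, 3)), np.zeros((2, 2, 2), bool)
        )


def test_design_matrix_rows(scheme32):
    X = losses.build_design_matrix(scheme32, "tensor")
    assert X.shape == (32, 7)
    # b = 0 row: only the ln S0 column
    assert np.allclose(X[0, :6], 0.0) and X[0, 6] == 1.0
    # v = (1,0,0) at b = 1000: D11 coefficient -1000, cross terms 0
    import warnings as _w

    table = GradientTable(np.array([1000.0]), np.array([[1.0, 0, 0]]))
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # single row is rank-deficient by design
        row = losses.build_design_matrix(table, "tensor")[0]
    assert row[0] == -1000.0 and np.allclose(row[1:6], 0.0)
    Xk = losses.build_design_matrix(phantom.two_shell_scheme(), "kurtosis")
    assert Xk.shape[1] == 22


def test_design_matrix_warns_on_rank_deficiency():
    table = GradientTable(
        np.array([1000.0, 1000.0]), np.array([[1.0, 0, 0], [1.0, 0, 0]])
    )
    with pytest.warns(UserWarning):
        losses.build_design_matrix(table, "tensor")


def test_ols_recovers_noise_free_tensor(dirs30):
    table = GradientTable(
        np.concatenate([[0.0], np.full(30, 1000.0)]),
        np.concatenate([np.zeros((1, 3)), dirs30]),
    )
    d = np.array([1.5e-3, 3e-4, 3e-4, 0, 0, 0])
    s0 = 1.7
    sig = models.tensor_signal(models.TensorParams(d=d, s0=s0), table.bvecs, table.bvals)
    X = losses.build_design_matrix(table, "tensor")
    coef = losses.ols_log_estimate(sig, X)
    assert np.max(np.abs(coef[:6] - d)) / np.max(np.abs(d)) < 1e-10
    assert abs(np.exp(coef[6]) - s0) < 1e-10
    # constant signal over b > 0 implies a zero tensor
    const = np.ones(31)
    coef0 = losses.ols_log_estimate(const, X)
    assert np.max(np.abs(coef0[:6])) < 1e-12


def test_ols_kurtosis_round_trip(kurtosis_phantom_clean):
    vol, truth = kurtosis_phantom_clean
    X = losses.build_design_matrix(vol.gradients, "kurtosis")
    coef = losses.ols_log_estimate(vol.signal, X)
    md2 = ((coef[..., 0] + coef[..., 1] + coef[..., 2]) / 3.0) ** 2
    k = coef[..., 6:21] / np.maximum(md2, 1e-12)[..., None]
    assert np.max(np.abs(coef[..., :6] - truth.d)) < 1e-10
    assert np.max(np.abs(k - truth.k)) < 1e-8


def test_wls_weights_softmax():
    w = losses.wls_weights(np.zeros((4, 5)))
    assert np.allclose(w, 0.2)
    w2 = losses.wls_weights(np.array([np.log(3.0), 0.0]))
    assert np.allclose(w2, [0.75, 0.25])
    w3 = losses.wls_weights(np.random.default_rng(1).random((10, 8)))
    assert np.allclose(w3.sum(axis=-1), 1.0)


def test_content_loss_uniform_weights_algebra(rng):
    """With uniform weights the weighted loss is the hand expansion."""
    mask = np.ones((2, 1, 1), bool)
    s = rng.random((2, 1, 1, 2))
    pred = rng.random((2, 1, 1, 2))
    w = np.full_like(s, 0.5)
    got = losses.content_loss_cwls(s, pred, w, mask)
    # sum over volumes of per-volume mean over voxels of (0.5 r)^2
    expected = (0.25 * (pred - s) ** 2).sum(axis=-1).mean()
    r = (pred - s) * 0.5
    expected = sum(
        (r[..., i] ** 2).mean() for i in range(2)
    )
    assert abs(got - expected) < 1e-14
    assert losses.content_loss_cwls(s, s, w, mask) == 0.0


def test_content_loss_homogeneity(rng):
    mask = np.ones((3, 1, 1), bool)
    s = rng.random((3, 1, 1, 4))
    pred = rng.random((3, 1, 1, 4))
    w = losses.wls_weights(rng.random((3, 1, 1, 4)))
    base = losses.content_loss_cwls(s, pred, w, mask)
    quad = losses.content_loss_cwls(2 * s, 2 * pred, w, mask)
    assert abs(quad / base - 4.0) < 1e-10


def test_bound_penalty_hand_example():
    mask = np.ones((1,), bool).reshape(1)
    kapp = np.full((1, 60), 0.3)
    assert losses.bound_penalty(kapp, np.ones((1,), bool)) == 0.0
    kapp[0, 7] = -0.5
    assert abs(losses.bound_penalty(kapp, np.ones((1,), bool)) - 0.5) < 1e-14
    # penalty decreases as the negative value moves toward zero
    kapp2 = kapp.copy()
    kapp2[0, 7] = -0.2
    assert losses.bound_penalty(kapp2, np.ones((1,), bool)) < losses.bound_penalty(
        kapp, np.ones((1,), bool)
    )


def test_cwls_composition(rng):
    mask = np.ones((2, 1, 1), bool)
    scheme = phantom.two_shell_scheme(n_b0=2, n_per_shell=15)
    s = rng.uniform(0.3, 1.0, (2, 1, 1, scheme.n))
    pred_np = rng.uniform(0.3, 1.0, (2, 1, 1, scheme.n))
    w = losses.compute_cwls_weights(s, scheme)
    assert np.allclose(w.sum(axis=-1), 1.0)
    params = models.KurtosisParams(
        d=np.broadcast_to(np.array([1e-3] * 3 + [0.0] * 3), (2, 1, 1, 6)).copy(),
        k=rng.uniform(-0.5, 1.0, (2, 1, 1, 15)),
        s0=np.ones((2, 1, 1)),
    )
    cfg0 = losses.LossConfig(kind="cwls", lambda_bound=0.0)
    cfg = losses.LossConfig(kind="cwls", lambda_bound=1000.0)
    content = losses.cwls_loss(s, pred_np, params, cfg0, w, mask)
    full = losses.cwls_loss(s, pred_np, params, cfg, w, mask)
    assert abs(content - losses.content_loss_cwls(s, pred_np, w, mask)) < 1e-14
    kapp = models.apparent_kurtosis(params.k, bound_directions())
    bound = losses.bound_penalty(kapp, mask)
    assert abs(full - (content + 1000.0 * bound)) < 1e-10
    assert full >= content
    # all-positive apparent kurtosis makes the penalty vanish
    params_pos = models.KurtosisParams(
        d=params.d, k=np.zeros((2, 1, 1, 15)), s0=params.s0
    )
    same = losses.cwls_loss(s, pred_np, params_pos, cfg, w, mask)
    assert abs(same - content) < 1e-14


def test_loss_gradients_match_finite_differences(rng, scheme32):
    """Autodiff gradients of both objectives on a tiny batch."""
    mask = np.ones((2, 1, 1), bool)
    sig = rng.uniform(0.2, 1.0, (2, 1, 1, scheme32.n))

    def mse_obj(raw):
        p = models.scale_outputs("tensor", raw.reshape(2, 1, 1, 7))
        pred = models.tensor_signal(p, scheme32.bvecs, scheme32.bvals)
        return losses.mse_loss(sig, pred, mask)

    raw0 = rng.uniform(-0.3, 1.0, 14)
    auto, num = ad.grad_check(mse_obj, raw0, eps=1e-6)
    scale = np.maximum(np.abs(num), 1e-3)
    assert np.max(np.abs(auto - num) / scale) < 1e-4

    scheme_k = phantom.two_shell_scheme(n_b0=1, n_per_shell=12)
    sig_k = rng.uniform(0.2, 1.0, (1, 1, 1, scheme_k.n))
    w = losses.compute_cwls_weights(sig_k, scheme_k)
    cfg = losses.LossConfig(kind="cwls", lambda_bound=10.0)

    def cwls_obj(raw):
        p = models.scale_outputs("kurtosis", raw.reshape(1, 1, 1, 22))
        pred = models.kurtosis_signal(p, scheme_k.bvecs, scheme_k.bvals)
        return losses.cwls_loss(sig_k, pred, p, cfg, w, np.ones((1, 1, 1), bool))

    raw0 = rng.uniform(-0.3, 0.8, 22)
    auto, num = ad.grad_check(cwls_obj, raw0, eps=1e-6)
    scale = np.maximum(np.abs(num), 1e-3)
    assert np.max(np.abs(auto - num) / scale) < 1e-4


def test_minimizing_mse_on_noise_free_data_reaches_zero(dirs30):
    """Per-voxel optimization drives the self-supervised objective to ~0."""
    table = GradientTable(
        np.concatenate([[0.0], np.full(30, 1000.0)]),
        np.concatenate([np.zeros((1, 3)), dirs30]),
    )
    d_true = np.array([1.4e-3, 4e-4, 3e-4, 1e-4, -5e-5, 2e-5])
    sig = models.tensor_signal(
        models.TensorParams(d=d_true, s0=1.1), table.bvecs, table.bvals
    ).reshape(1, 1, 1, -1)
    mask = np.ones((1, 1, 1), bool)

    def objective(x):
        leaf = ad.Var(x.reshape(1, 1, 1, 7), requires_grad=True)
        p = models.scale_outputs("tensor", leaf)
        pred = models.tensor_signal(p, table.bvecs, table.bvals)
        loss = losses.mse_loss(sig, pred, mask)
        loss.backward()
        return float(loss.value), leaf.grad.ravel().copy()

    x0 = np.concatenate([np.ones(6) * 0.5, [0.8]])
    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-18, "gtol": 1e-14})
    assert res.fun < 1e-10
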