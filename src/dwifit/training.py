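"""Self-supervised subject-specific optimization and transfer learning.

The fitting loop never sees reference parameter maps: the network maps
the acquired volumes to model parameters, the forward model synthesizes
the signals those parameters imply, and Adam minimizes the masked
discrepancy between acquired and synthesized signals.  Volumes are cut
into fixed-size blocks (one optimizer step per block, batch size one),
optionally doubled by left-right flipping, with a staged learning rate
(1e-3 for the first 10 000 block-steps, 1e-4 afterwards by default) and
optional Monte-Carlo validation: an 80/20 block re-split each epoch,
keeping the weights with the lowest validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import losses as losses_mod
from . import models
from .gradients import GradientTable
from .network import (
    DEFAULT_MC_SAMPLES,
    McResult,
    Network,
    NetworkSpec,
    build_network,
    mc_inference,
)
from .volume import DwiVolume, extract_blocks

__all__ = [
    "TrainSpec",
    "Adam",
    "augment_flip",
    "fit_subject",
    "pretrain",
    "fine_tune",
    "synthesize_training_targets",
]


@dataclass
class TrainSpec:
    """Optimization schedule and data handling knobs.

    ``stage1_blocks`` / ``stage2_blocks`` count optimizer steps (one
    block each) at ``lr_stage1`` / ``lr_stage2``.  ``use_mc_validation``
    of ``None`` resolves to the per-model default: enabled for tensor
    and kurtosis, disabled for NODDI (where the validation checkpointing
    tends to lock in local minima).
    """

    lr_stage1: float = 1e-3
    lr_stage2: float = 1e-4
    stage1_blocks: int = 10000
    stage2_blocks: int = 6000
    finetune_lr: float = 1e-4
    block_size: int = 64
    val_fraction: float = 0.2
    use_mc_validation: bool | None = None
    augment_flip: bool = True
    seed: int = 0
    mc_samples: int = DEFAULT_MC_SAMPLES
    track_full_loss: bool = False

    def __post_init__(self):
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")
        if min(self.lr_stage1, self.lr_stage2, self.finetune_lr) <= 0:
            raise ValueError("learning rates must be positive")


class Adam:
    """Adam optimizer over a list of autodiff leaves."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _lr_axis(dwi: DwiVolume) -> int:
    """Voxel axis closest to the anatomical left-right (world x) axis."""
    aff = dwi.affine[:3, :3]
    axis = int(np.argmax(np.abs(aff[0])))
    if np.abs(aff[0]).max() == 0:
        warnings.warn("degenerate affine orientation; flipping along axis 0")
        return 0
    return axis


def _cut(arr: np.ndarray, origin, size: int) -> np.ndarray:
    """Zero-padded cutout of a 3-D (+channels) array."""
    out_shape = (size, size, size) + arr.shape[3:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    ox, oy, oz = origin
    sx = min(size, arr.shape[0] - ox)
    sy = min(size, arr.shape[1] - oy)
    sz = min(size, arr.shape[2] - oz)
    out[:sx, :sy, :sz] = arr[ox : ox + sx, oy : oy + sy, oz : oz + sz]
    return out


def _build_samples(dwi, mask, block_size, weights=None, s0=None):
    bset = extract_blocks(dwi, block_size)
    samples = []
    for blk, origin in zip(bset.blocks, bset.origins):
        sample = {
            "signal": blk,
            "mask": _cut(mask.astype(float), origin, block_size).astype(bool),
        }
        if weights is not None:
            sample["weights"] = _cut(weights, origin, block_size)
        if s0 is not None:
            sample["s0"] = _cut(s0, origin, block_size)
        samples.append(sample)
    return samples


def augment_flip(samples: list[dict], lr_axis: int = 0) -> list[dict]:
    """Double a sample list by mirroring each block left-right.

    Only the image content is mirrored; the gradient table is left
    untouched (a mirrored signal block is still a physically valid
    signal pattern whose implied fiber orientations are mirrored, so
    the self-supervised objective stays consistent).
    """
    out = list(samples)
    for s in samples:
        out.append({k: np.flip(v, axis=lr_axis).copy() for k, v in s.items()})
    return out


def _make_loss_fn(model: str, gradients: GradientTable, lossconfig):
    bvecs, bvals = gradients.bvecs, gradients.bvals

    def loss_fn(network: Network, sample: dict, dropout_rng):
        x = np.moveaxis(sample["signal"], -1, 0)
        raw = network.forward(x, dropout_rng=dropout_rng)
        raw = raw.transpose((1, 2, 3, 0))  # (X, Y, Z, c4)
        params = models.scale_outputs(model, raw)
        if model == "tensor":
            pred = models.tensor_signal(params, bvecs, bvals)
        elif model == "kurtosis":
            pred = models.kurtosis_signal(params, bvecs, bvals)
        else:
            pred = models.noddi_signal(
                params, bvecs, bvals, sample["s0"],
                quad_order=lossconfig.noddi_quad_order,
            )
        if lossconfig.kind == "cwls":
            return losses_mod.cwls_loss(
                sample["signal"], pred, params, lossconfig,
                sample["weights"], sample["mask"],
            )
        return losses_mod.mse_loss(sample["signal"], pred, sample["mask"])

    return loss_fn


def _clone_weights(network: Network):
    return [p.value.copy() for p in network.parameters]


def _restore_weights(network: Network, weights) -> None:
    for p, w in zip(network.parameters, weights):
        p.value = w.copy()


def _optimize(
    network: Network,
    samples: list[dict],
    loss_fn,
    schedule,  # callable: step index -> learning rate
    total_steps: int,
    rng: np.random.Generator,
    val_fraction: float = 0.0,
    mc_validation: bool = False,
    track_full_loss: bool = False,
) -> dict:
    """The shared block-wise Adam loop; returns the training history.

    ``train_loss`` is the running mean of the mini-block losses within
    each epoch; ``full_loss`` (when tracked) is the deterministic loss
    over the whole training set evaluated after each epoch.
    """
    opt = Adam(network.parameters)
    history = {"train_loss": [], "val_loss": [], "lr": [], "full_loss": []}
    best_val, best_weights = np.inf, None
    step = 0
    consecutive_bad = 0
    while step < total_steps:
        order = rng.permutation(len(samples))
        n_val = int(round(val_fraction * len(samples))) if mc_validation else 0
        # keep at least one training block
        n_val = min(n_val, len(samples) - 1)
        val_idx, train_idx = order[:n_val], order[n_val:]
        epoch_losses = []
        for i in train_idx:
            if step >= total_steps:
                break
            lr = schedule(step)
            dropout_rng = np.random.default_rng(rng.integers(2**31))
            opt.zero_grad()
            loss = loss_fn(network, samples[i], dropout_rng)
            lv = float(loss.value)
            if not np.isfinite(lv):
                consecutive_bad += 1
                if consecutive_bad >= 2:
                    raise RuntimeError(
                        f"non-finite loss twice in a row at step {step}"
                    )
                warnings.warn(f"skipping non-finite loss at step {step}")
                step += 1
                continue
            consecutive_bad = 0
            loss.backward()
            opt.step(lr)
            epoch_losses.append(lv)
            history["lr"].append(lr)
            step += 1
        if epoch_losses:
            history["train_loss"].append(float(np.mean(epoch_losses)))
        if track_full_loss:
            history["full_loss"].append(
                float(
                    np.mean(
                        [float(loss_fn(network, s, None).value) for s in samples]
                    )
                )
            )
        if mc_validation and n_val > 0:
            vls = [
                float(loss_fn(network, samples[i], None).value) for i in val_idx
            ]
            vl = float(np.mean(vls))
            history["val_loss"].append(vl)
            if vl < best_val:
                best_val = vl
                best_weights = _clone_weights(network)
    if mc_validation and best_weights is not None:
        _restore_weights(network, best_weights)
    return history


def _resolve_mc_validation(model: str, flag) -> bool:
    return (model != "noddi") if flag is None else bool(flag)


def _prepare(dwi, model, lossconfig, trainspec):
    mask = dwi.tissue_mask if lossconfig.loss_mask == "tissue" else dwi.brain_mask
    weights = None
    if lossconfig.kind == "cwls":
        weights = losses_mod.compute_cwls_weights(dwi.signal, dwi.gradients)
    s0 = dwi.mean_b0() if model == "noddi" else None
    samples = _build_samples(dwi, mask, trainspec.block_size, weights, s0)
    if trainspec.augment_flip:
        samples = augment_flip(samples, _lr_axis(dwi))
    return samples


def fit_subject(
    dwi: DwiVolume,
    model: str,
    netspec: NetworkSpec | None = None,
    lossconfig: losses_mod.LossConfig | None = None,
    trainspec: TrainSpec | None = None,
    network: Network | None = None,
) -> tuple[Network, McResult]:
    """Subject-specific self-supervised fit; returns (network, MC result).

    Expects a normalized volume (unit-scale b0).  The staged schedule
    runs ``stage1_blocks`` steps at ``lr_stage1`` then ``stage2_blocks``
    at ``lr_stage2``.  The trained network's ``history`` attribute holds
    per-epoch train/validation losses and the per-step learning rate.
    """
    netspec = netspec if netspec is not None else NetworkSpec(model=model)
    lossconfig = (
        lossconfig
        if lossconfig is not None
        else losses_mod.LossConfig(loss_mask="brain" if model == "noddi" else "tissue")
    )
    trainspec = trainspec if trainspec is not None else TrainSpec()
    if netspec.model != model:
        raise ValueError(f"netspec is for {netspec.model!r}, not {model!r}")
    rng = np.random.default_rng(trainspec.seed)
    samples = _prepare(dwi, model, lossconfig, trainspec)
    if network is None:
        network = build_network(netspec, dwi.gradients.n, seed=int(rng.integers(2**31)))
    elif network.n_in != dwi.gradients.n:
        raise ValueError(
            f"checkpoint expects {network.n_in} input volumes, data has "
            f"{dwi.gradients.n}"
        )
    loss_fn = _make_loss_fn(model, dwi.gradients, lossconfig)

    def schedule(step):
        return (
            trainspec.lr_stage1
            if step < trainspec.stage1_blocks
            else trainspec.lr_stage2
        )

    history = _optimize(
        network,
        samples,
        loss_fn,
        schedule,
        trainspec.stage1_blocks + trainspec.stage2_blocks,
        rng,
        val_fraction=trainspec.val_fraction,
        mc_validation=_resolve_mc_validation(model, trainspec.use_mc_validation),
        track_full_loss=trainspec.track_full_loss,
    )
    network.history = history
    mc = mc_inference(network, dwi, l=trainspec.mc_samples, seed=trainspec.seed)
    return network, mc


def pretrain(
    dwi_list: list[DwiVolume],
    model: str,
    netspec: NetworkSpec | None = None,
    lossconfig: losses_mod.LossConfig | None = None,
    trainspec: TrainSpec | None = None,
) -> Network:
    """Pre-train one network on blocks pooled across subjects.

    Runs ``stage1_blocks`` steps at the stage-1 learning rate over the
    pooled (augmented) block set.
    """
    if not dwi_list:
        raise ValueError("need at least one subject")
    n_in = dwi_list[0].gradients.n
    for d in dwi_list[1:]:
        if d.gradients.n != n_in:
            raise ValueError("all subjects must share the acquisition size")
    netspec = netspec if netspec is not None else NetworkSpec(model=model)
    lossconfig = (
        lossconfig
        if lossconfig is not None
        else losses_mod.LossConfig(loss_mask="brain" if model == "noddi" else "tissue")
    )
    trainspec = trainspec if trainspec is not None else TrainSpec()
    rng = np.random.default_rng(trainspec.seed)
    samples = []
    for d in dwi_list:
        samples.extend(_prepare(d, model, lossconfig, trainspec))
    network = build_network(netspec, n_in, seed=int(rng.integers(2**31)))
    loss_fn = _make_loss_fn(model, dwi_list[0].gradients, lossconfig)
    history = _optimize(
        network,
        samples,
        loss_fn,
        lambda step: trainspec.lr_stage1,
        trainspec.stage1_blocks,
        rng,
        val_fraction=trainspec.val_fraction,
        mc_validation=_resolve_mc_validation(model, trainspec.use_mc_validation),
        track_full_loss=trainspec.track_full_loss,
    )
    network.history = history
    return network


def fine_tune(
    network: Network,
    dwi: DwiVolume,
    trainspec: TrainSpec | None = None,
    lossconfig: losses_mod.LossConfig | None = None,
) -> tuple[Network, McResult]:
    """Fine-tune a pre-trained network on one subject (stage-2 LR only).

    ``stage2_blocks`` optimizer steps at ``finetune_lr``; zero steps
    reduce to direct application of the pre-trained network.
    """
    trainspec = trainspec if trainspec is not None else TrainSpec()
    model = network.spec.model
    lossconfig = (
        lossconfig
        if lossconfig is not None
        else losses_mod.LossConfig(loss_mask="brain" if model == "noddi" else "tissue")
    )
    if network.n_in != dwi.gradients.n:
        raise ValueError(
            f"transfer mismatch: checkpoint expects {network.n_in} input "
            f"volumes, target data has {dwi.gradients.n}"
        )
    rng = np.random.default_rng(trainspec.seed)
    samples = _prepare(dwi, model, lossconfig, trainspec)
    loss_fn = _make_loss_fn(model, dwi.gradients, lossconfig)
    history = _optimize(
        network,
        samples,
        loss_fn,
        lambda step: trainspec.finetune_lr,
        trainspec.stage2_blocks,
        rng,
        val_fraction=trainspec.val_fraction,
        mc_validation=_resolve_mc_validation(model, trainspec.use_mc_validation),
        track_full_loss=trainspec.track_full_loss,
    )
    network.history = history
    mc = mc_inference(network, dwi, l=trainspec.mc_samples, seed=trainspec.seed)
    return network, mc


def synthesize_training_targets(
    model: str,
    params,
    gradients: GradientTable,
    s0_map: np.ndarray | None = None,
) -> DwiVolume:
    """Forward-model signals of reference parameters on a new scheme.

    Enables cross-scheme transfer: reference parameters fitted on one
    acquisition generate noise-free training volumes along an arbitrary
    target gradient table.  For NODDI, ``s0_map`` supplies the
    non-diffusion-weighted signal.
    """
    if model == "tensor":
        sig = models.tensor_signal(params, gradients.bvecs, gradients.bvals)
    elif model == "kurtosis":
        sig = models.kurtosis_signal(params, gradients.bvecs, gradients.bvals)
    elif model == "noddi":
        if s0_map is None:
            raise ValueError("noddi synthesis needs an s0 map")
        sig = models.noddi_signal(params, gradients.bvecs, gradients.bvals, s0_map)
    else:
        raise ValueError(f"unknown model {model!r}")
    return DwiVolume(np.maximum(np.asarray(sig, float), 0.0), gradients)
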