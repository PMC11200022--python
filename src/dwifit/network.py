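"""The plain convolutional mapping network and MC-dropout inference.

The mapping network G takes the n acquired volumes as channels and
outputs one channel per model parameter.  It is deliberately small:
M layers of 3×3×3 convolution (spatial context, receptive field
2M+1 voxels per axis) followed by N layers of 1×1×1 convolution
(per-voxel channel mixing), M+N = 7 by default, ReLU after every layer
except the last.  Every layer whose output width is c2 is paired with a
dropout layer (rate p); keeping dropout active at inference and
averaging l stochastic passes gives the MC-dropout estimate, and the
per-voxel standard deviation of the passes is the uncertainty map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from . import models
from .volume import DwiVolume

__all__ = ["NetworkSpec", "Network", "McResult", "build_network", "predict",
           "mc_inference", "save_checkpoint", "load_checkpoint"]

#: Default number of MC-dropout inference passes.
DEFAULT_MC_SAMPLES = 20


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    ``M`` 3×3×3 conv layers then ``N`` 1×1×1 layers; channel widths
    c1 (first), c2/c3 (hidden, defaults 256/64), c4 (output, fixed by
    the model: 7 tensor / 22 kurtosis / 5 NODDI); dropout rate ``p``.
    """

    model: str = "tensor"
    M: int = 0
    N: int = 7
    c1: int = 32
    c2: int = 256
    c3: int = 64
    p: float = 0.05

    def __post_init__(self):
        if self.M < 0 or self.N < 1:
            raise ValueError("need M >= 0 and N >= 1")
        if not 0 <= self.p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        models.n_params(self.model)  # validates the model name

    @property
    def c4(self) -> int:
        return models.n_params(self.model)

    @property
    def widths(self) -> list[int]:
        """Output width of each of the M+N layers.

        The 7-layer schedule is c1, c2, c2, c2, c2, c3, c4; other
        depths keep the first/last widths and pad/truncate the c2 run.
        """
        depth = self.M + self.N
        if depth < 3:
            return [self.c1, self.c4][-depth:]
        mid = [self.c2] * (depth - 3)
        return [self.c1] + mid + [self.c3, self.c4]


@dataclass
class McResult:
    """MC-dropout summary: per-voxel mean and std over l inferences."""

    mean_params: object
    std_params: object
    l: int


class _Layer:
    """One convolution layer: kernel k=3 (spatial) or k=1 (per-voxel)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        bound = 1.0 / np.sqrt(fan_in)
        self.w = ad.Var(
            rng.uniform(-bound, bound, size=(c_out, c_in, k, k, k)),
            requires_grad=True,
        )
        self.b = ad.Var(rng.uniform(-bound, bound, size=c_out), requires_grad=True)
        self.k = k

    def __call__(self, x):
        if self.k == 1:
            # pointwise layer: a plain channel matmul is much faster
            c_in = self.w.shape[1]
            spatial = x.shape[1:]
            flat = x.reshape(c_in, int(np.prod(spatial)))
            wmat = self.w.reshape(self.w.shape[0], c_in)
            out = ad.matmul(wmat, flat) + self.b.reshape(-1, 1)
            return out.reshape((self.w.shape[0],) + spatial)
        return ad.conv3d(ad.pad_spatial(x, (self.k - 1) // 2), self.w, self.b)


class Network:
    """The M+N-layer mapping network with seeded initialization."""

    def __init__(self, spec: NetworkSpec, n_in: int, seed: int = 0):
        self.spec = spec
        self.n_in = n_in
        rng = np.random.default_rng(seed)
        widths = spec.widths
        self.layers: list[_Layer] = []
        c_prev = n_in
        for i, c_out in enumerate(widths):
            k = 3 if i < spec.M else 1
            self.layers.append(_Layer(c_prev, c_out, k, rng))
            c_prev = c_out
        # dropout pairs with every layer whose output width is c2
        self.dropout_layers = [
            i for i, c in enumerate(widths[:-1]) if c == spec.c2
        ]

    @property
    def parameters(self) -> list[ad.Var]:
        out = []
        for lay in self.layers:
            out.extend([lay.w, lay.b])
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters))

    def forward(self, x, dropout_rng: np.random.Generator | None = None):
        """Map (n_in, X, Y, Z) signals to (c4, X, Y, Z) raw outputs.

        ``dropout_rng`` activates (inverted) dropout; ``None`` runs the
        deterministic evaluation path.
        """
        h = x if isinstance(x, ad.Var) else ad.Var(np.asarray(x, float))
        last = len(self.layers) - 1
        for i, lay in enumerate(self.layers):
            h = lay(h)
            if i != last:
                h = ad.relu(h)
                if (
                    dropout_rng is not None
                    and self.spec.p > 0
                    and i in self.dropout_layers
                ):
                    keep = (
                        dropout_rng.random(h.shape) >= self.spec.p
                    ).astype(float) / (1.0 - self.spec.p)
                    h = h * keep
        return h


def build_network(spec: NetworkSpec, n_in: int, seed: int = 0) -> Network:
    """Construct a seeded network for ``n_in`` input volumes."""
    return Network(spec, n_in, seed)


def _to_channels_first(block: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(block, -1, 0))


def predict(
    network: Network,
    block: np.ndarray,
    dropout_active: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Apply the network to an X×Y×Z×n block; returns X×Y×Z×c4.

    Deterministic when ``dropout_active`` is false (or p = 0); seeded
    and reproducible when active.
    """
    if block.shape[-1] != network.n_in:
        raise ValueError(
            f"block has {block.shape[-1]} channels, network expects {network.n_in}"
        )
    rng = np.random.default_rng(seed) if dropout_active else None
    out = network.forward(_to_channels_first(block), dropout_rng=rng)
    return np.moveaxis(out.value, 0, -1)


def _param_fields(model: str, params) -> dict:
    def val(x):
        return x.value if isinstance(x, ad.Var) else np.asarray(x, float)

    if model == "tensor":
        return {"d": val(params.d), "s0": val(params.s0)}
    if model == "kurtosis":
        return {"d": val(params.d), "k": val(params.k), "s0": val(params.s0)}
    return {f: val(getattr(params, f)) for f in
            ("f_iso", "f_ic", "theta", "phi", "kappa")}


def _fields_to_params(model: str, fields: dict):
    if model == "tensor":
        return models.TensorParams(**fields)
    if model == "kurtosis":
        return models.KurtosisParams(**fields)
    return models.NoddiParams(**fields)


def mc_inference(
    network: Network,
    dwi: DwiVolume,
    l: int = DEFAULT_MC_SAMPLES,
    seed: int = 0,
) -> McResult:
    """Monte-Carlo-dropout inference over the full volume.

    Runs ``l`` dropout-active passes (l = 20 by default), scales raw
    outputs to model parameters, and returns their per-voxel mean and
    standard deviation.  With p = 0 every pass is identical and the std
    is zero; l = 1 is the single stochastic pass.
    """
    if l < 1:
        raise ValueError("need l >= 1 inference passes")
    model = network.spec.model
    sums: dict[str, np.ndarray] = {}
    sq_sums: dict[str, np.ndarray] = {}
    for j in range(l):
        raw = predict(network, dwi.signal, dropout_active=True, seed=seed + j)
        fields = _param_fields(model, models.scale_outputs(model, raw))
        for key, arr in fields.items():
            if key not in sums:
                sums[key] = np.zeros_like(arr)
                sq_sums[key] = np.zeros_like(arr)
            sums[key] += arr
            sq_sums[key] += arr**2
    mean = {k: v / l for k, v in sums.items()}
    std = {
        k: np.sqrt(np.maximum(sq_sums[k] / l - mean[k] ** 2, 0.0))
        for k in sums
    }
    return McResult(
        mean_params=_fields_to_params(model, mean),
        std_params=_fields_to_params(model, std),
        l=l,
    )


def save_checkpoint(network: Network, path) -> None:
    """Write weights as .npz with an embedded JSON NetworkSpec header."""
    arrays = {}
    for i, lay in enumerate(network.layers):
        arrays[f"w{i}"] = lay.w.value
        arrays[f"b{i}"] = lay.b.value
    header = json.dumps({"spec": asdict(network.spec), "n_in": network.n_in})
    arrays["header"] = np.frombuffer(header.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Network:
    """Rebuild a network (architecture + weights) from a checkpoint."""
    data = np.load(path)
    meta = json.loads(bytes(data["header"]).decode())
    net = Network(NetworkSpec(**meta["spec"]), meta["n_in"])
    for i, lay in enumerate(net.layers):
        lay.w.value = data[f"w{i}"].astype(float)
        lay.b.value = data[f"b{i}"].astype(float)
    return net
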