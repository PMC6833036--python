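"""Eight-stage dual-branch 1-D convolutional classifier.

Each stage applies a width-16 convolution (stride 1), then feeds its
output to two parallel subsampling branches — a strided convolution and a
max-pooling layer, both stride 2 — whose outputs are concatenated along
channels, batch-normalized, rectified and dropped out.  After the last
stage a flatten + linear head produces two logits and a softmax gives the
rest/stress probabilities.

The normative dimension contract: with input width ``w = fs * window_s``
the stage-``N`` feature map has width ``w / 2**N`` and ``8 * 2**k``
channels with ``k = ceil(N/2) - 1`` (default ``channel_mode='equations'``).
``channel_mode='table3'`` builds the wider literal variant in which every
convolution carries the full ``8 * 2**k`` filters so stage outputs have
twice as many channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import DTYPE

N_STAGES = 8


class ConfigError(ValueError):
    pass


def stage_channels(n: int, channel_mode: str = "equations") -> int:
    """Concatenated channel count of stage ``n``'s output."""
    if not 1 <= n <= N_STAGES:
        raise ValueError(f"stage index {n} out of range 1..{N_STAGES}")
    k = (n + 1) // 2 - 1
    base = 8 * 2 ** k
    if channel_mode == "equations":
        return base
    if channel_mode == "table3":
        return 2 * base
    raise ConfigError(f"unknown channel_mode {channel_mode!r}")


@dataclass(frozen=True)
class StageSpec:
    """Hyperparameters of one stage."""

    index: int
    out_channels: int
    filter_width: int = 16
    conv_stride: int = 1
    subsample_stride: int = 2
    dropout_rate: float = 0.3

    @property
    def branch_channels(self) -> int:
        return self.out_channels // 2


@dataclass(frozen=True)
class ModelConfig:
    window_s: int
    fs: int = 256
    n_stages: int = N_STAGES
    n_classes: int = 2
    input_channels: int = 1
    channel_mode: str = "equations"
    dropout_rate: float = 0.3
    bn_momentum: float = 0.99

    def __post_init__(self):
        if self.channel_mode not in ("equations", "table3"):
            raise ConfigError(f"unknown channel_mode {self.channel_mode!r}")
        if self.input_width % 2 ** self.n_stages != 0:
            raise ConfigError(
                f"input width {self.input_width} not divisible by "
                f"2**{self.n_stages}")

    @property
    def input_width(self) -> int:
        return self.fs * self.window_s

    def stage_specs(self) -> list[StageSpec]:
        return [StageSpec(index=n,
                          out_channels=stage_channels(n, self.channel_mode),
                          dropout_rate=self.dropout_rate)
                for n in range(1, self.n_stages + 1)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


def stage_output_shape(cfg: ModelConfig, n: int) -> tuple[int, int]:
    """(width, channels) of the stage-``n`` feature map."""
    if not 1 <= n <= cfg.n_stages:
        raise ValueError(f"stage index {n} out of range 1..{cfg.n_stages}")
    return cfg.input_width // 2 ** n, stage_channels(n, cfg.channel_mode)


class _Stage:
    """conv -> (strided conv || max pool) -> concat -> BN -> ReLU -> dropout."""

    def __init__(self, spec: StageSpec, in_channels: int, bn_momentum: float):
        b = spec.branch_channels
        self.spec = spec
        self.conv1 = nn.Conv1D(in_channels, b, spec.filter_width,
                               spec.conv_stride)
        self.sconv = nn.Conv1D(b, b, spec.filter_width, spec.subsample_stride)
        self.pool = nn.MaxPool1D(spec.filter_width, spec.subsample_stride)
        self.bn = nn.BatchNorm1D(spec.out_channels, momentum=bn_momentum)
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(spec.dropout_rate)

    def forward(self, x, training=False, rng=None):
        a = self.conv1.forward(x, training)
        c = self.sconv.forward(a, training)
        p = self.pool.forward(a, training)
        y = np.concatenate([c, p], axis=2)
        y = self.bn.forward(y, training)
        y = self.relu.forward(y, training)
        return self.dropout.forward(y, training, rng=rng)

    def backward(self, dout):
        d = self.dropout.backward(dout)
        d = self.relu.backward(d)
        d = self.bn.backward(d)
        b = self.spec.branch_channels
        da = self.sconv.backward(d[:, :, :b]) + self.pool.backward(d[:, :, b:])
        return self.conv1.backward(da)

    def named_layers(self):
        return [("conv1", self.conv1), ("sconv", self.sconv), ("bn", self.bn)]


class StressNet:
    """The full network; parameters keyed by ``stage{N}.{layer}.{role}``."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.stages: list[_Stage] = []
        in_ch = cfg.input_channels
        for spec in cfg.stage_specs():
            stage = _Stage(spec, in_ch, cfg.bn_momentum)
            self.stages.append(stage)
            in_ch = spec.out_channels
        out_w = cfg.input_width // 2 ** cfg.n_stages
        self.head = nn.Dense(out_w * in_ch, cfg.n_classes)
        self.frozen_stages: frozenset[int] = frozenset()
        self.stage_outputs: list[np.ndarray] | None = None

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                collect: bool = False, start_stage: int = 1) -> np.ndarray:
        """Return logits ``[m, n_classes]`` for a batch ``[m, w, 1]``.

        ``start_stage > 1`` resumes from cached stage-``start_stage - 1``
        features (used when a frozen prefix has been precomputed).
        """
        x = np.asarray(x, DTYPE)
        expected_w = (self.cfg.input_width if start_stage == 1
                      else self.cfg.input_width // 2 ** (start_stage - 1))
        if x.ndim != 3 or x.shape[1] != expected_w:
            raise ValueError(
                f"expected batch of shape [m, {expected_w}, c] for "
                f"start_stage={start_stage}, got {x.shape}")
        self.stage_outputs = [] if collect else None
        for stage in self.stages[start_stage - 1:]:
            x = stage.forward(x, training, rng)
            if collect:
                self.stage_outputs.append(x)
        self._head_in_shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        return self.head.forward(flat, training)

    def prefix_features(self, x: np.ndarray, n_stages: int,
                        batch_size: int = 128) -> np.ndarray:
        """Inference-mode features after stage ``n_stages``, batched."""
        x = np.asarray(x, DTYPE)
        out = None
        for i in range(0, x.shape[0], batch_size):
            xb = x[i:i + batch_size]
            for stage in self.stages[:n_stages]:
                xb = stage.forward(xb, training=False)
            if out is None:
                out = np.empty((x.shape[0],) + xb.shape[1:], DTYPE)
            out[i:i + batch_size] = xb
        return out

    def backward(self, dlogits: np.ndarray, min_stage: int = 1) -> None:
        """Backpropagate; stages below ``min_stage`` are skipped entirely."""
        d = self.head.backward(dlogits)
        d = d.reshape(self._head_in_shape)
        for n in range(len(self.stages), 0, -1):
            if n < min_stage:
                break
            d = self.stages[n - 1].backward(d)

    # -- parameter registry -------------------------------------------------

    def named_parameter_layers(self):
        """Yield (key_prefix, stage_index_or_None, layer) in a fixed order."""
        for i, stage in enumerate(self.stages, start=1):
            for lname, layer in stage.named_layers():
                yield f"stage{i}.{lname}", i, layer
        yield "head", None, self.head

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for prefix, _, layer in self.named_parameter_layers():
            for pname, p in layer.params().items():
                state[f"{prefix}.{pname}"] = p.copy()
            if isinstance(layer, nn.BatchNorm1D):
                state[f"{prefix}.running_mean"] = layer.running_mean.copy()
                state[f"{prefix}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, _, layer in self.named_parameter_layers():
            for pname, p in layer.params().items():
                p[...] = state[f"{prefix}.{pname}"]
            if isinstance(layer, nn.BatchNorm1D):
                layer.running_mean[...] = state[f"{prefix}.running_mean"]
                layer.running_var[...] = state[f"{prefix}.running_var"]

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 64,
                       start_stage: int = 1) -> None:
        """Re-estimate batch-norm running statistics over ``x``.

        With only a handful of optimizer steps per epoch, momentum-based
        running averages lag the true activation statistics badly enough
        to destroy inference-mode accuracy; this sets each unfrozen BN
        layer's running mean/var to the average of its batch statistics
        over one dropout-free pass.  Frozen stages are left untouched.
        """
        bns = [s.bn for s in self.stages if not s.bn.frozen]
        if not bns:
            return
        for bn in bns:
            bn._collect = ([], [])
        try:
            for i in range(0, x.shape[0], batch_size):
                self.forward(x[i:i + batch_size], training=False,
                             start_stage=start_stage)
        finally:
            for bn in bns:
                means, variances = bn._collect
                if means:
                    bn.running_mean[...] = np.mean(means, axis=0)
                    bn.running_var[...] = np.mean(variances, axis=0)
                bn._collect = None

    def set_frozen_stages(self, stages: frozenset[int]) -> None:
        self.frozen_stages = frozenset(stages)
        for i, stage in enumerate(self.stages, start=1):
            stage.bn.frozen = i in self.frozen_stages

    def trainable_parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        out = []
        for prefix, stage_idx, layer in self.named_parameter_layers():
            if stage_idx is not None and stage_idx in self.frozen_stages:
                continue
            grads = layer.grads()
            for pname, p in layer.params().items():
                out.append((f"{prefix}.{pname}", p, grads[pname]))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for _, _, layer in self.named_parameter_layers()
                   for p in layer.params().values())


def build_model(cfg: ModelConfig) -> StressNet:
    return StressNet(cfg)


def he_initialize(net: StressNet, seed: int) -> StressNet:
    """Draw every conv/linear weight from N(0, 2/fan_in); zero biases.

    Batch-norm scale/shift reset to 1/0 and running statistics to 0/1.
    Deterministic: a fixed seed yields bit-identical parameters.
    """
    rng = np.random.default_rng(seed)
    for _, _, layer in net.named_parameter_layers():
        if isinstance(layer, (nn.Conv1D, nn.Dense)):
            std = np.sqrt(2.0 / layer.fan_in)
            layer.W[...] = rng.normal(0.0, std, size=layer.W.shape)
            layer.b[...] = 0.0
        elif isinstance(layer, nn.BatchNorm1D):
            layer.reset()
    return net


def he_initialize_head(net: StressNet, seed: int) -> StressNet:
    """Re-initialize only the classifier head (transfer-learning reset)."""
    rng = np.random.default_rng(seed)
    std = np.sqrt(2.0 / net.head.fan_in)
    net.head.W[...] = rng.normal(0.0, std, size=net.head.W.shape)
    net.head.b[...] = 0.0
    return net


def predict(net: StressNet, batch: np.ndarray,
            batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities ``[m, 2]`` (rows sum to 1) and argmax labels."""
    batch = np.asarray(batch, DTYPE)
    probs = np.empty((batch.shape[0], net.cfg.n_classes), np.float64)
    for i in range(0, batch.shape[0], batch_size):
        logits = net.forward(batch[i:i + batch_size], training=False)
        probs[i:i + batch_size] = nn.softmax(logits.astype(np.float64))
    return probs, probs.argmax(axis=1)


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(net: StressNet, path, regime: str | None = None,
                    extra: dict | None = None) -> None:
    meta = {"config": json.loads(net.cfg.to_json()),
            "regime": regime,
            "extra": extra or {}}
    arrays = {f"param::{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[StressNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    cfg = ModelConfig(**meta["config"])
    net = build_model(cfg)
    net.load_state_dict(state)
    return net, meta


def state_checksums(state: dict[str, np.ndarray]) -> dict[str, str]:
    """SHA-256 of each tensor's raw bytes (freezing regression oracle)."""
    import hashlib
    return {k: hashlib.sha256(np.ascontiguousarray(v).tobytes()).hexdigest()
            for k, v in state.items()}
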