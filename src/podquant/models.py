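"""Patch classifiers and their training protocol.

Two architectures classify 32x32 RGB patches into the four inflorescence
part classes (base, body, stem, tip):

* ``LeNet`` — the classic shallow baseline: two conv+maxpool stages followed
  by two fully connected layers and a softmax head.  Filter counts (20/50/500)
  follow the canonical reference implementation.
* ``DenseNet`` — a DenseNet-Basic classifier: an initial 16-filter 3x3
  convolution, three dense blocks with growth rate k=12 operating at spatial
  sizes 32, 16 and 8, joined by transition layers (batch norm -> 1x1 conv ->
  dropout -> 2x2 average pool, channel count preserved), finished with batch
  norm, ReLU, global average pooling and a softmax head.

Training uses SGD with momentum 0.9, weight decay 1e-5, base learning rate
0.001 and a step-down schedule that divides the rate by 10 at each third of
the epoch budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .patches import NormalizationStats

CLASS_NAMES = ("base", "body", "stem", "tip")


@dataclass(frozen=True)
class LeNetConfig:
    conv1_filters: int = 20
    conv2_filters: int = 50
    fc_units: int = 500
    n_classes: int = 4
    input_size: int = 32

    arch: str = "lenet"


@dataclass(frozen=True)
class DenseNetConfig:
    growth_rate: int = 12
    n_blocks: int = 3
    layers_per_block: int = 12
    initial_filters: int = 16
    dropout_rate: float = 0.2
    n_classes: int = 4
    input_size: int = 32

    arch: str = "densenet"


@dataclass(frozen=True)
class TrainConfig:
    """Solver settings; batch-size/epoch defaults differ per architecture
    (64/15 for LeNet, 8/30 for the dense network)."""

    base_lr: float = 0.001
    lr_gamma: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 1e-5
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    init_weights: str | None = None  # optional pretrained-weights file


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant thirds: lr = base_lr * gamma**s, s = floor(3e/E), s<=2."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    step = min(2, (3 * epoch) // cfg.epochs)
    return cfg.base_lr * cfg.lr_gamma ** step


class _Classifier:
    """Shared forward/predict/state plumbing for both architectures."""

    config: LeNetConfig | DenseNetConfig

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameter_layers(self) -> list[nn.Layer]:  # pragma: no cover
        raise NotImplementedError

    def _all_layers(self) -> list[nn.Layer]:  # pragma: no cover
        raise NotImplementedError

    # -- state ------------------------------------------------------------
    def _stateful_layers(self) -> list[nn.Layer]:
        return [l for l in self._all_layers()
                if l.params or isinstance(l, nn.BatchNorm2d)]

    def get_state(self) -> list[dict[str, np.ndarray]]:
        state = []
        for layer in self._stateful_layers():
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, nn.BatchNorm2d):
                d["running_mean"] = layer.running_mean.copy()
                d["running_var"] = layer.running_var.copy()
            state.append(d)
        return state

    def set_state(self, state) -> None:
        layers = self._stateful_layers()
        if len(layers) != len(state):
            raise ValueError("state does not match architecture")
        for layer, d in zip(layers, state):
            for k in layer.params:
                layer.params[k][...] = d[k]
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = d["running_mean"]
                layer.running_var[...] = d["running_var"]

    def predict_logits(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = _to_batch(patches, self.config.input_size)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i:i + batch_size], train=False))
        return np.concatenate(out, axis=0)


def _to_batch(patches: np.ndarray, size: int) -> np.ndarray:
    patches = np.asarray(patches, dtype=np.float32)
    if patches.ndim != 4 or patches.shape[1:] != (size, size, 3):
        raise ValueError(f"expected (N, {size}, {size}, 3) patches, got {patches.shape}")
    return np.ascontiguousarray(patches)


class LeNet(_Classifier):
    def __init__(self, config: LeNetConfig, rng: np.random.Generator):
        self.config = config
        s = config.input_size
        s_out = ((s - 4) // 2 - 4) // 2  # two valid 5x5 convs + 2x2 pools
        self.net = nn.Sequential([
            nn.Conv2d(3, config.conv1_filters, 5, rng),
            nn.MaxPool2(),
            nn.Conv2d(config.conv1_filters, config.conv2_filters, 5, rng),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Dense(config.conv2_filters * s_out * s_out, config.fc_units, rng),
            nn.ReLU(),
            nn.Dense(config.fc_units, config.n_classes, rng),
        ])

    def forward(self, x, train):
        return self.net.forward(x, train)

    def backward(self, dlogits):
        return self.net.backward(dlogits)

    def parameter_layers(self):
        return self.net.parameter_layers()

    def _all_layers(self):
        return self.net.layers


class _DenseLayer:
    """Composite function BN -> ReLU -> 3x3 conv (pad 1) -> dropout, emitting k maps."""

    def __init__(self, cin: int, k: int, dropout: float, rng: np.random.Generator):
        self.ops = nn.Sequential([
            nn.BatchNorm2d(cin),
            nn.ReLU(),
            nn.Conv2d(cin, k, 3, rng, pad=1),
            nn.Dropout(dropout, rng),
        ])

    def forward(self, x, train):
        return self.ops.forward(x, train)

    def backward(self, dout):
        return self.ops.backward(dout)


class _DenseBlock:
    """Within the block, layer i consumes the concatenation of the block
    input and all preceding layers' outputs."""

    def __init__(self, cin: int, n_layers: int, k: int, dropout: float,
                 rng: np.random.Generator):
        self.k = k
        self.layers = []
        c = cin
        for _ in range(n_layers):
            self.layers.append(_DenseLayer(c, k, dropout, rng))
            c += k
        self.cout = c

    def forward(self, x, train):
        feats = x
        self._cins = []
        for layer in self.layers:
            self._cins.append(feats.shape[-1])
            out = layer.forward(feats, train)
            feats = np.concatenate([feats, out], axis=3)
        return feats

    def backward(self, dfeats):
        for layer, cin in zip(reversed(self.layers), reversed(self._cins)):
            dfeats = dfeats[..., :cin] + layer.backward(
                np.ascontiguousarray(dfeats[..., cin:]))
        return dfeats


class _Transition:
    """Batch norm -> 1x1 conv (channel-preserving) -> dropout -> 2x2 avg pool."""

    def __init__(self, c: int, dropout: float, rng: np.random.Generator):
        self.ops = nn.Sequential([
            nn.BatchNorm2d(c),
            nn.Conv2d(c, c, 1, rng),
            nn.Dropout(dropout, rng),
            nn.AvgPool2(),
        ])

    def forward(self, x, train):
        return self.ops.forward(x, train)

    def backward(self, dout):
        return self.ops.backward(dout)


class DenseNet(_Classifier):
    def __init__(self, config: DenseNetConfig, rng: np.random.Generator):
        self.config = config
        k, lpb, drop = config.growth_rate, config.layers_per_block, config.dropout_rate
        self.initial = nn.Conv2d(3, config.initial_filters, 3, rng, pad=1)
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[_Transition] = []
        c = config.initial_filters
        self.block_input_channels = []
        for b in range(config.n_blocks):
            self.block_input_channels.append(c)
            block = _DenseBlock(c, lpb, k, drop, rng)
            self.blocks.append(block)
            c = block.cout
            if b < config.n_blocks - 1:
                self.transitions.append(_Transition(c, drop, rng))
        self.final_bn = nn.BatchNorm2d(c)
        self.final_relu = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Dense(c, config.n_classes, rng)
        size = config.input_size
        self.block_feature_sizes = tuple(size // 2 ** b for b in range(config.n_blocks))

    def forward(self, x, train):
        self._block_shapes = []
        x = self.initial.forward(x, train)
        for b, block in enumerate(self.blocks):
            self._block_shapes.append(x.shape)
            x = block.forward(x, train)
            if b < len(self.transitions):
                x = self.transitions[b].forward(x, train)
        x = self.final_bn.forward(x, train)
        x = self.final_relu.forward(x, train)
        x = self.gap.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits):
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        d = self.final_relu.backward(d)
        d = self.final_bn.backward(d)
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.transitions):
                d = self.transitions[b].backward(d)
            d = self.blocks[b].backward(d)
        return self.initial.backward(d)

    def block_io_shapes(self, x: np.ndarray):
        """(channels_in, height) actually seen by each dense block on a forward pass."""
        self.forward(_to_batch(x, self.config.input_size), train=False)
        return [(s[3], s[1]) for s in self._block_shapes]

    def _all_layers(self):
        layers = [self.initial]
        for b, block in enumerate(self.blocks):
            for dl in block.layers:
                layers.extend(dl.ops.layers)
            if b < len(self.transitions):
                layers.extend(self.transitions[b].ops.layers)
        layers.extend([self.final_bn, self.head])
        return layers

    def parameter_layers(self):
        return [l for l in self._all_layers() if l.params]


def build_model(config: LeNetConfig | DenseNetConfig,
                seed: int = 0) -> _Classifier:
    """Instantiate a classifier with seeded random initialization."""
    rng = np.random.default_rng(seed)
    if isinstance(config, LeNetConfig):
        return LeNet(config, rng)
    if isinstance(config, DenseNetConfig):
        return DenseNet(config, rng)
    raise TypeError(f"unknown config type {type(config)!r}")


def predict_proba(model: _Classifier, patches: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Class probabilities (base, body, stem, tip) for normalized patches."""
    return nn.softmax(model.predict_logits(patches, batch_size))


def _evaluate(model, x, y, batch_size):
    logits = model.predict_logits(x, batch_size)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train_classifier(model: _Classifier,
                     train_set: tuple[np.ndarray, np.ndarray],
                     val_set: tuple[np.ndarray, np.ndarray],
                     cfg: TrainConfig):
    """Train with SGD + momentum under the thirds learning-rate schedule.

    Returns ``(model, history)`` where history is a list of per-epoch dicts
    (train loss, validation loss, validation accuracy, learning rate).  The
    weights achieving the best validation accuracy are restored at the end.
    Deterministic for a fixed ``cfg.seed``.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    x_train = _to_batch(x_train, model.config.input_size)
    x_val_nhwc = np.asarray(x_val, dtype=np.float32)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)

    if cfg.init_weights:
        state, _, _, _ = _read_model_file(cfg.init_weights)
        model.set_state(state)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7261]))
    opt = nn.SGD(model.parameter_layers(), lr=cfg.base_lr,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    history = []
    best_acc, best_state = -1.0, None
    n = x_train.shape[0]
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        running, nb = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {nb}")
            model.backward(dlogits)
            opt.step()
            running += loss
            nb += 1
        val_loss, val_acc = _evaluate(model, x_val_nhwc, y_val, 256)
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": running / max(nb, 1),
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.get_state()
    if best_state is not None:
        model.set_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# serialization: one .npz holding weights, configs and normalization stats
# ---------------------------------------------------------------------------

def save_model(path, model: _Classifier, train_config: TrainConfig | None = None,
               stats: NormalizationStats | None = None) -> None:
    arrays = {}
    for i, d in enumerate(model.get_state()):
        for k, v in d.items():
            arrays[f"layer{i:03d}/{k}"] = v
    meta = {"arch_config": asdict(model.config)}
    if train_config is not None:
        meta["train_config"] = asdict(train_config)
    if stats is not None:
        arrays["stats/channel_means"] = np.asarray(stats.channel_means)
        arrays["stats/channel_sds"] = np.asarray(stats.channel_sds)
        arrays["stats/mean_patch"] = np.asarray(stats.mean_patch)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def _read_model_file(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        state: dict[int, dict[str, np.ndarray]] = {}
        stats = None
        for key in z.files:
            if key.startswith("layer"):
                layer_id, name = key.split("/", 1)
                state.setdefault(int(layer_id[5:]), {})[name] = z[key]
        if "stats/mean_patch" in z.files:
            stats = NormalizationStats(
                channel_means=z["stats/channel_means"],
                channel_sds=z["stats/channel_sds"],
                mean_patch=z["stats/mean_patch"],
            )
    ordered = [state[i] for i in sorted(state)]
    arch = meta["arch_config"]
    tc = meta.get("train_config")
    return ordered, arch, tc, stats


def load_model(path):
    """Load a saved classifier; returns (model, train_config, stats)."""
    state, arch, tc, stats = _read_model_file(path)
    if arch.pop("arch") == "lenet":
        config = LeNetConfig(**arch)
    else:
        config = DenseNetConfig(**arch)
    model = build_model(config, seed=0)
    model.set_state(state)
    train_config = TrainConfig(**tc) if tc else None
    return model, train_config, stats
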