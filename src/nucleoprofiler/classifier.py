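"""Residual CNN for two-class epigenetic-state classification.

The reference architecture ("9conv_1f") is a compact ResNet: a 7x7 stem
convolution — sized so the first receptive field spans several optical
resolution elements of ~50 nm/px super-resolution data — followed by four
residual blocks of two 3x3 convolutions each (nine convolutions and nine
batch-norm layers in total) and a single fully connected layer producing
one binary logit. Shortcuts are parameter-free (stride slicing plus channel
zero-padding), so the layer census is exactly 9 conv / 9 BN / 1 FC.
Variants add global average pooling ("9conv_gap_1f") or double the block
count ("17conv_gap_1f").

Single-channel inputs are fed as pseudo-RGB (the plane duplicated across
three channels), matching how single-marker images are presented to a
three-channel network. Training uses Adam with binary cross-entropy, an
initial learning rate of 1e-4 cosine-decayed to 1e-6, batch size 128 and
300 epochs by default; all of these scale down for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .synthgen import GroundTruth, NucleusImage

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "EvalReport",
    "ResidualCNN",
    "to_pseudo_rgb",
    "build_model",
    "train_and_evaluate",
    "dataset_to_arrays",
]

ARCHITECTURES = {
    # arch id: (widths per block, strides per block, global average pool)
    "9conv_1f": ((16, 24, 32, 32), (2, 2, 2, 2), False),
    "9conv_gap_1f": ((16, 24, 32, 32), (2, 2, 2, 2), True),
    "17conv_gap_1f": ((16, 16, 24, 24, 32, 32, 48, 48),
                      (2, 1, 2, 1, 2, 1, 2, 1), True),
}
STEM_WIDTH = 8
STEM_KERNEL = 7


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice and input geometry of the classifier."""

    architecture: str = "9conv_1f"
    input_size: int = 600
    in_channels: int = 3

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {sorted(ARCHITECTURES)}")

    @property
    def n_conv(self) -> int:
        widths, _, _ = ARCHITECTURES[self.architecture]
        return 1 + 2 * len(widths)


@dataclass(frozen=True)
class TrainConfig:
    """Training regimen; defaults mirror the full-scale recipe.

    lr decays from ``lr_start`` to ``lr_end`` over all steps with a cosine
    schedule. ``input_scale`` converts raw image units to unit-scale network
    inputs and is part of the model contract (the same scale must be used
    at inference).
    """

    epochs: int = 300
    batch_size: int = 128
    lr_start: float = 1e-4
    lr_end: float = 1e-6
    val_fraction: float = 0.2
    input_scale: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.lr_end > self.lr_start:
            raise ValueError("lr_end must not exceed lr_start")


@dataclass
class EvalReport:
    """Held-out evaluation: accuracy, precision, AUC and confusion counts."""

    accuracy: float
    precision: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int
    loss_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def to_pseudo_rgb(single_channel: np.ndarray) -> np.ndarray:
    """Duplicate a single 2D plane across three channels -> (3, H, W)."""
    arr = np.asarray(single_channel)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image, got shape "
                         f"{arr.shape}")
    return np.repeat(arr[None, :, :], 3, axis=0)


class _ResBlock:
    """conv3x3(stride s) -> BN -> ReLU -> conv3x3 -> BN -> (+shortcut) -> ReLU.

    The shortcut is parameter-free: stride slicing in space and zero-padding
    in channels (ResNet option A), so residual blocks add no conv layers
    beyond the two declared ones.
    """

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self._m1 = self._m2 = None
        self._x_shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x, train), train)
        m1 = h > 0
        h = h * m1
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        sc = x[:, :, ::self.stride, ::self.stride]
        if self.c_out > self.c_in:
            pad = np.zeros((x.shape[0], self.c_out - self.c_in,
                            sc.shape[2], sc.shape[3]), dtype=np.float32)
            sc = np.concatenate([sc, pad], axis=1)
        out = h + sc
        m2 = out > 0
        out = out * m2
        if train:
            self._m1, self._m2 = m1, m2
            self._x_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout * self._m2
        # conv path
        dc = self.bn2.backward(d)
        dc = self.conv2.backward(dc)
        dc = dc * self._m1
        dc = self.bn1.backward(dc)
        dx = self.conv1.backward(dc)
        # shortcut path
        dsc = d[:, :self.c_in]
        dshort = np.zeros(self._x_shape, dtype=np.float32)
        dshort[:, :, ::self.stride, ::self.stride] = dsc
        return dx + dshort

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2]


class ResidualCNN:
    """The compact residual classifier; see the module docstring."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths, strides, self.gap = ARCHITECTURES[spec.architecture]
        self.stem = nn.Conv2d(spec.in_channels, STEM_WIDTH, STEM_KERNEL,
                              stride=2, rng=rng)
        self.stem_bn = nn.BatchNorm2d(STEM_WIDTH)
        self.blocks: list[_ResBlock] = []
        c = STEM_WIDTH
        size = -(-spec.input_size // 2)  # ceil division through the stem
        for w, s in zip(widths, strides):
            self.blocks.append(_ResBlock(c, w, s, rng))
            c = w
            size = -(-size // s)
        self.feat_channels = c
        self.feat_size = size
        fc_in = c if self.gap else c * size * size
        self.fc = nn.Linear(fc_in, 1, rng=rng)
        self._stem_mask = None
        self._feat_shape = None

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                return_activations: bool = False):
        """Logits for a (N, C, H, W) batch; optionally also the activation
        maps of the last convolutional block (the Score-CAM target layer)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        h = self.stem_bn.forward(self.stem.forward(x, train), train)
        m = h > 0
        h = h * m
        if train:
            self._stem_mask = m
        for blk in self.blocks:
            h = blk.forward(h, train)
        act = h
        self._feat_shape = h.shape
        if self.gap:
            feat = h.mean(axis=(2, 3))
        else:
            feat = h.reshape(h.shape[0], -1)
        logits = self.fc.forward(feat, train)[:, 0]
        if return_activations:
            return logits, act
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits[:, None])
        n, c, hh, ww = self._feat_shape
        if self.gap:
            d = np.broadcast_to(d[:, :, None, None] / (hh * ww),
                                self._feat_shape).astype(np.float32)
        else:
            d = d.reshape(self._feat_shape).astype(np.float32)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        d = d * self._stem_mask
        d = self.stem_bn.backward(d)
        self.stem.backward(d)

    # ---- bookkeeping ---------------------------------------------------
    def layers(self):
        out = [self.stem, self.stem_bn]
        for blk in self.blocks:
            out.extend(blk.layers())
        out.append(self.fc)
        return out

    def params(self):
        return [p for lyr in self.layers() for p in lyr.params()]

    def grads(self):
        return [g for lyr in self.layers() for g in lyr.grads()]

    def layer_census(self) -> dict[str, int]:
        counts = {"conv": 0, "bn": 0, "fc": 0}
        for lyr in self.layers():
            if isinstance(lyr, nn.Conv2d):
                counts["conv"] += 1
            elif isinstance(lyr, nn.BatchNorm2d):
                counts["bn"] += 1
            elif isinstance(lyr, nn.Linear):
                counts["fc"] += 1
        return counts

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            probs.append(nn.sigmoid(logits))
        return np.concatenate(probs)

    def state_dict(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params()]
        for lyr in self.layers():
            if isinstance(lyr, nn.BatchNorm2d):
                state.extend([lyr.running_mean.copy(), lyr.running_var.copy()])
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        n_params = len(self.params())
        for p, s in zip(self.params(), state[:n_params]):
            p[...] = s
        i = n_params
        for lyr in self.layers():
            if isinstance(lyr, nn.BatchNorm2d):
                lyr.running_mean[...] = state[i]
                lyr.running_var[...] = state[i + 1]
                i += 2


def build_model(spec: ModelSpec, seed: int = 0) -> ResidualCNN:
    """Construct the classifier with deterministic seed-driven init."""
    return ResidualCNN(spec, seed=seed)


def dataset_to_arrays(collection: list[tuple[NucleusImage, GroundTruth]],
                      channel: str = "H3K27ac",
                      input_scale: float = 1e-3
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stack a labeled collection into (X, y) pseudo-RGB arrays.

    ``channel`` may be a single marker name (pseudo-RGB duplication) or
    "composite" for the native three-channel H3K27ac/CTCF/DNA stack.
    """
    xs, ys = [], []
    for img, gt in collection:
        if channel == "composite":
            arr = np.stack([img.channels["H3K27ac"], img.channels["CTCF"],
                            img.channels["DNA"]])
        else:
            arr = to_pseudo_rgb(img.channels[channel])
        xs.append(arr.astype(np.float32) * input_scale)
        ys.append(gt.class_label)
    return np.stack(xs), np.array(ys, dtype=np.float32)


def _stratified_split(y: np.ndarray, val_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(val_idx)))


def evaluate(model: ResidualCNN, x: np.ndarray, y: np.ndarray,
             batch_size: int = 64) -> EvalReport:
    """Accuracy, precision, AUC and confusion counts at threshold 0.5."""
    p = model.predict_proba(x, batch_size)
    pred = (p >= 0.5).astype(int)
    yi = y.astype(int)
    tp = int(((pred == 1) & (yi == 1)).sum())
    tn = int(((pred == 0) & (yi == 0)).sum())
    fp = int(((pred == 1) & (yi == 0)).sum())
    fn = int(((pred == 0) & (yi == 1)).sum())
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    auc = float(roc_auc_score(yi, p)) if len(np.unique(yi)) == 2 else float("nan")
    return EvalReport(accuracy=float(acc), precision=float(prec), auc=auc,
                      tp=tp, tn=tn, fp=fp, fn=fn)


def train_and_evaluate(x: np.ndarray, y: np.ndarray, spec: ModelSpec,
                       cfg: TrainConfig) -> tuple[ResidualCNN, EvalReport]:
    """Train on a stratified 80:20 split and evaluate on the held-out part.

    Adam + binary cross-entropy with a cosine learning-rate decay from
    ``lr_start`` to ``lr_end`` over all optimization steps. Deterministic
    given (x, y, spec, cfg) in single-threaded execution.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(y, cfg.val_fraction, rng)
    model = build_model(spec, seed=cfg.seed)
    params, grads = model.params(), model.grads()
    opt = nn.Adam(params, lr=cfg.lr_start)
    steps_per_epoch = max(1, int(np.ceil(len(tr) / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    loss_history = []
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(tr)
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            frac = step / max(total_steps - 1, 1)
            opt.lr = cfg.lr_end + 0.5 * (cfg.lr_start - cfg.lr_end) * (
                1 + np.cos(np.pi * frac))
            logits = model.forward(x[idx], train=True)
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            nn.Adam.zero_grads(grads)
            model.backward(dlogits)
            opt.step(grads)
            epoch_loss += loss * len(idx)
            step += 1
        loss_history.append(epoch_loss / len(tr))
    report = evaluate(model, x[va], y[va])
    report.loss_history = loss_history
    return model, report
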