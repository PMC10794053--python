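"""Small density-regression counter and its trainer.

This is a deliberately tiny convolutional encoder (stride-2 blocks) with a
multiscale dilated-convolution regression head: parallel 3x3 branches at
different dilation rates are summed so the head sees several receptive
fields at once, then a 1x1 projection and a final rectifier produce a
non-negative density grid at 1/stride resolution.  The point is not the
architecture — it is the smallest trainable stand-in that lets the
composite transport loss be exercised end-to-end on synthetic scenes.

Everything (convolutions, backprop, Adam) is plain NumPy; determinism is
controlled by the config seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations_io import PointAnnotation, load_image, read_points
from .density import DensityMap, density_from_points
from .uot import LossBreakdown, composite_loss_and_grad

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LossConfig",
    "CountingNet",
    "build_model",
    "train",
    "TrainingRecord",
    "predict_count",
    "load_model",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    encoder_channels: tuple[int, ...] = (8, 16, 16)
    head_dilations: tuple[int, ...] = (1, 2, 3)
    head_channels: int = 8
    output_stride: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.head_dilations) < 1:
            raise ValueError("need at least one dilation branch")
        stages = len(self.encoder_channels) - 1  # stride-2 stages after the stem
        if self.output_stride != 2**stages:
            raise ValueError(
                f"output_stride {self.output_stride} does not match "
                f"{stages} stride-2 encoder stages (expected {2 ** stages})"
            )


@dataclass
class LossConfig:
    lambda1: float = 0.1
    lambda2: float = 0.01
    eps: float = 0.05
    tau: float = 0.5
    cost_kind: str = "perspective"
    tol: float = 1e-6
    max_iter: int = 150


@dataclass
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 1e-5
    epochs: int = 30
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# Conv primitives (im2col based)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, dilation: int, pad: int):
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    span = dilation * (k - 1) + 1
    oh = (H + 2 * pad - span) // stride + 1
    ow = (W + 2 * pad - span) // stride + 1
    cols = np.empty((N, C, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[
                :, :,
                i * dilation : i * dilation + stride * oh : stride,
                j * dilation : j * dilation + stride * ow : stride,
            ]
    return cols, (N, C, H, W, oh, ow)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, dilation: int, pad: int):
    N, C, H, W, oh, ow = shape
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[
                :, :,
                i * dilation : i * dilation + stride * oh : stride,
                j * dilation : j * dilation + stride * ow : stride,
            ] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + H, pad : pad + W]


class _Conv:
    """3x3 (or 1x1) convolution with stride/dilation and He-normal init."""

    def __init__(self, c_in, c_out, k, stride, dilation, rng):
        self.k, self.stride, self.dilation = k, stride, dilation
        self.pad = dilation * (k - 1) // 2
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self._cache = None

    def forward(self, x):
        cols, shape = _im2col(x, self.k, self.stride, self.dilation, self.pad)
        self._cache = (cols, shape)
        y = np.einsum("ocij,ncijhw->nohw", self.W, cols, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        cols, shape = self._cache
        self.dW = np.einsum("nohw,ncijhw->ocij", dy, cols, optimize=True)
        self.db = dy.sum(axis=(0, 2, 3))
        dcols = np.einsum("ocij,nohw->ncijhw", self.W, dy, optimize=True)
        return _col2im(dcols, shape, self.k, self.stride, self.dilation, self.pad)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class CountingNet:
    """Encoder + multiscale dilated head mapping RGB to a density grid."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = [3, *config.encoder_channels]
        self.encoder = [
            _Conv(chans[i], chans[i + 1], 3, 1 if i == 0 else 2, 1, rng)
            for i in range(len(chans) - 1)
        ]
        self.branches = [
            _Conv(config.encoder_channels[-1], config.head_channels, 3, 1, d, rng)
            for d in config.head_dilations
        ]
        self.project = _Conv(config.head_channels, 1, 1, 1, 1, rng)
        self._relu_masks: list[np.ndarray] = []

    # -- forward / backward over N x 3 x H x W batches -----------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._relu_masks = []
        h = x
        for conv in self.encoder:
            h = conv.forward(h)
            mask = h > 0
            self._relu_masks.append(mask)
            h = h * mask
        s = None
        for conv in self.branches:
            z = conv.forward(h)
            s = z if s is None else s + z
        mask = s > 0
        self._relu_masks.append(mask)
        s = s * mask
        out = self.project.forward(s)
        mask = out > 0
        self._relu_masks.append(mask)
        return out * mask

    def backward(self, dout: np.ndarray) -> None:
        masks = self._relu_masks
        d = dout * masks[-1]
        d = self.project.backward(d)
        d = d * masks[-2]
        dh = None
        for conv in self.branches:
            dz = conv.backward(d)
            dh = dz if dh is None else dh + dz
        d = dh
        for conv, mask in zip(reversed(self.encoder), reversed(masks[:-2])):
            d = d * mask
            d = conv.backward(d)

    @property
    def layers(self):
        return [*self.encoder, *self.branches, self.project]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config)))

    def load_params(self, path: str | Path) -> None:
        data = np.load(path)
        for i, p in enumerate(self.params):
            p[...] = data[f"p{i}"]


def build_model(config: ModelConfig) -> CountingNet:
    """Construct a counter with deterministic (seeded) initialization."""
    return CountingNet(config)


def load_model(path: str | Path) -> CountingNet:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
    cfg["head_dilations"] = tuple(cfg["head_dilations"])
    model = CountingNet(ModelConfig(**cfg))
    model.load_params(path)
    return model


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------


def _normalize(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float64).transpose(2, 0, 1) / 255.0 - 0.5


def _load_sample(root: Path, row, stride: int):
    image = load_image(root / row["image"])
    points = read_points(root / row["points_file"])
    gt = density_from_points(points, stride=stride)
    return _normalize(image), points, gt


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainingRecord:
    """Per-epoch means of the loss terms plus validation MAE."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, epoch: int, terms: dict, val_mae: float | None) -> None:
        self.epochs.append({"epoch": epoch, **terms, "val_mae": val_mae})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def predict_count(model: CountingNet, image: np.ndarray) -> tuple[DensityMap, float]:
    """Predicted density map and its integral (the shoot count estimate).

    Images whose sides are not multiples of the output stride are padded
    reflectively on the bottom/right before the forward pass.
    """
    stride = model.config.output_stride
    if image.ndim == 3 and image.shape[2] == 3 and image.dtype == np.uint8:
        x = _normalize(image)
    elif image.ndim == 3 and image.shape[0] == 3:
        x = np.asarray(image, dtype=np.float64)
    else:
        x = _normalize(np.asarray(image, dtype=np.uint8))
    _, H, W = x.shape
    ph = (-H) % stride
    pw = (-W) % stride
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    out = model.forward(x[None])[0, 0]
    dm = DensityMap(out, stride=stride)
    return dm, float(out.sum())


def train(
    model: CountingNet,
    manifest: pd.DataFrame,
    data_root: str | Path,
    config: TrainConfig,
    train_ids: list[str] | None = None,
    val_ids: list[str] | None = None,
) -> TrainingRecord:
    """Run the supervised loop with the composite transport loss.

    ``manifest`` is the CSV written by the synthetic generator (or an
    equivalent listing of images and point files).  If id lists are not
    given, the last fifth of the manifest becomes the validation fold.
    Per-image gradients flow through the loss's envelope rule into plain
    backprop; losses are logged per epoch as means over training images.
    """
    root = Path(data_root)
    ids = list(manifest["image_id"])
    if train_ids is None or val_ids is None:
        n_val = max(1, len(ids) // 5)
        train_ids, val_ids = ids[:-n_val], ids[-n_val:]
    if not train_ids:
        raise ValueError("empty training set")
    if set(train_ids) & set(val_ids):
        raise ValueError("train and validation ids overlap")
    by_id = {row["image_id"]: row for _, row in manifest.iterrows()}
    stride = model.config.output_stride
    train_data = [_load_sample(root, by_id[i], stride) for i in train_ids]
    val_data = [_load_sample(root, by_id[i], stride) for i in val_ids]

    lc = config.loss
    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    record = TrainingRecord()
    order = np.arange(len(train_data))
    for epoch in range(1, config.epochs + 1):
        rng.shuffle(order)
        sums = {"count_loss": 0.0, "ot_loss": 0.0, "pixel_mse": 0.0, "total": 0.0}
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [train_data[i] for i in idx]
            x = np.stack([b[0] for b in batch])
            pred = model.forward(x)
            dout = np.zeros_like(pred)
            for bi, (_, points, gt) in enumerate(batch):
                pd_map = DensityMap(pred[bi, 0], stride=stride)
                breakdown, grad, _ = composite_loss_and_grad(
                    pd_map, points, gt,
                    lambda1=lc.lambda1, lambda2=lc.lambda2, eps=lc.eps, tau=lc.tau,
                    cost_kind=lc.cost_kind, tol=lc.tol, max_iter=lc.max_iter,
                )
                if not np.isfinite(breakdown.total):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, image {points.image_id}"
                    )
                dout[bi, 0] = grad / len(idx)
                for key in ("count_loss", "ot_loss", "pixel_mse", "total"):
                    sums[key] += getattr(breakdown, key)
            model.backward(dout)
            opt.step(model.grads)
        n = len(train_data)
        terms = {k: v / n for k, v in sums.items()}
        val_mae = float(
            np.mean(
                [abs(predict_count(model, b[0])[1] - b[1].count) for b in val_data]
            )
        ) if val_data else None
        record.append(epoch, terms, val_mae)
    return record
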