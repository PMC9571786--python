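"""Stage-2 classifier: a compact residual CNN on scalogram RGB images,
separating benign E from grade-1 chondrosarcoma.

The canonical deployment of this stage is a large ImageNet-pretrained
residual network fine-tuned at a very small learning rate.  This package
trains compact residual networks from scratch instead (no pretrained
weights are bundled), keeping the elements that matter downstream: a
224x224x3 input, residual blocks, a 7x7 final feature map feeding global
average pooling and a linear head (so class activation maps have the usual
7x7 geometry), dropout before the head, and the same optimizer family.

Backbones: ``resnet_small`` (default), ``se_resnet_small`` (residual
blocks with squeeze-and-excitation channel attention), ``effnet_small``
(a narrower width-scaled variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .tfr import RGBImage, bilinear_resize

__all__ = [
    "TransferSpec",
    "TrainConfig2d",
    "ImageAugmentConfig",
    "Model2d",
    "build_transfer_model",
    "augment_image",
    "preprocess_image",
    "train_2d",
    "predict_2d",
    "BACKBONES",
]


@dataclass(frozen=True)
class TransferSpec:
    backbone: str = "resnet_small"
    pretrained: bool = False
    dropout_p: float = 0.2

    def __post_init__(self):
        if self.pretrained:
            raise ValueError(
                "no pretrained weights are bundled with this package; "
                "use pretrained=False (models train from scratch)")


@dataclass
class TrainConfig2d:
    """Stage-2 optimization settings.

    The 5e-7 default learning rate is a fine-tuning rate (appropriate when
    starting from strong pretrained features).  For the from-scratch
    training this package performs, use :func:`from_scratch_config`.
    """

    batch_size: int = 64
    learning_rate: float = 5e-7
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.0
    epochs: int = 100
    seed: int = 0
    augment: bool = True


def from_scratch_config(**overrides) -> TrainConfig2d:
    """Training preset for randomly initialized backbones (lr 1e-3)."""
    cfg = TrainConfig2d(learning_rate=1e-3, **overrides)
    return cfg


@dataclass
class ImageAugmentConfig:
    """2D augmentations: small random crop (max 2% of each axis), resize
    back to 224, per-image z-score, additive Gaussian noise (sigma 0.1 on
    the normalized values), and a sharpness adjustment."""

    crop_max_frac: float = 0.02
    resize_to: int = 224
    gauss_noise_sigma: float = 0.1
    sharpness_range: tuple = (0.8, 1.2)

    def __post_init__(self):
        if not 0.0 <= self.crop_max_frac < 0.5:
            raise ValueError("crop_max_frac must be in [0, 0.5)")


class _ResidualBlock(nn.Module):
    """conv3-BN-ReLU-conv3-BN plus skip (1x1 conv when the shape changes)."""

    def __init__(self, in_ch, out_ch, rng, stride=1, se_reduction=0):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, stride=1, padding=1)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride, padding=0)
        self.se = _SqueezeExcite(out_ch, se_reduction, rng) if se_reduction else None

    def parameters(self):
        mods = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            mods.append(self.proj)
        if self.se is not None:
            mods.append(self.se)
        return [p for m in mods for p in m.parameters()]

    def forward(self, x, training=False):
        out = self.relu1.forward(self.bn1.forward(
            self.conv1.forward(x, training), training), training)
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        if self.se is not None:
            out = self.se.forward(out, training)
        skip = x if self.proj is None else self.proj.forward(x, training)
        self._sum_mask = (out + skip) > 0
        return (out + skip) * self._sum_mask

    def backward(self, grad):
        grad = grad * self._sum_mask
        g = grad
        if self.se is not None:
            g = self.se.backward(g)
        g = self.conv2.backward(self.bn2.backward(g))
        g = self.conv1.backward(self.relu1.backward(self.bn1.backward(g)))
        g_skip = grad if self.proj is None else self.proj.backward(grad)
        return g + g_skip


class _SqueezeExcite(nn.Module):
    """Channel attention: GAP -> fc -> ReLU -> fc -> sigmoid -> rescale."""

    def __init__(self, channels, reduction, rng):
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()

    def forward(self, x, training=False):
        self._x = x
        self._pooled = x.mean(axis=(2, 3))
        self._h = np.maximum(self.fc1.forward(self._pooled), 0.0)
        self._s = nn.sigmoid(self.fc2.forward(self._h))
        return x * self._s[:, :, None, None]

    def backward(self, grad):
        x, s = self._x, self._s
        dx_direct = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3)) * s * (1.0 - s)
        dh = self.fc2.backward(ds) * (self._h > 0)
        dpool = self.fc1.backward(dh)
        h, w = x.shape[2], x.shape[3]
        return dx_direct + dpool[:, :, None, None] / (h * w)


class Model2d:
    """Backbone + GAP + dropout + linear head over 224x224x3 inputs."""

    def __init__(self, blocks, head, dropout, n_classes, spec):
        self.blocks = blocks            # list of Modules ending with a (N,C,7,7) map
        self.gap = nn.GlobalAvgPool2d()
        self.dropout = dropout
        self.head = head
        self.n_classes = n_classes
        self.spec = spec
        self.trained = False
        self.freeze_backbone = False

    def parameters(self):
        ps = [] if self.freeze_backbone else \
            [p for m in self.blocks for p in m.parameters()]
        return ps + self.head.parameters()

    def zero_grad(self):
        for m in self.blocks:
            for p in m.parameters():
                p.grad[...] = 0.0
        for p in self.head.parameters():
            p.grad[...] = 0.0

    def features(self, x, training=False) -> np.ndarray:
        """Final convolutional feature maps, shape (N, C, 7, 7)."""
        for m in self.blocks:
            x = m.forward(x, training)
        return x

    def forward(self, x, training=False):
        f = self.features(x, training)
        pooled = self.gap.forward(f, training)
        return self.head.forward(self.dropout.forward(pooled, training), training)

    def backward(self, grad):
        g = self.dropout.backward(self.head.backward(grad))
        g = self.gap.backward(g)
        for m in reversed(self.blocks):
            g = m.backward(g)
        return g

    def head_weights(self) -> np.ndarray:
        """Linear head weight matrix, shape (n_feature_channels, n_classes)."""
        return self.head.W.value

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        outs = []
        for i in range(0, len(X), batch_size):
            z = self.forward(X[i:i + batch_size], training=False)
            outs.append(nn.softmax(z))
        return np.concatenate(outs)

    def save(self, path):
        state = {}
        for j, m in enumerate(self.blocks):
            for k, v in m.state_dict().items():
                state[f"b{j}_{k}"] = v
        for k, v in self.head.state_dict().items():
            state[f"h_{k}"] = v
        np.savez(path, **state)

    def load(self, path):
        with np.load(path) as data:
            for j, m in enumerate(self.blocks):
                m.load_state_dict({k: data[f"b{j}_{k}"]
                                   for k in m.state_dict()})
            self.head.load_state_dict({k: data[f"h_{k}"]
                                       for k in self.head.state_dict()})
        self.trained = True


def _resnet_small(rng, widths=(16, 16, 32, 64), se=0):
    blocks = [
        nn.Conv2d(3, widths[0], 7, rng, stride=4, padding=3),
        nn.BatchNorm2d(widths[0]),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, padding=1),                       # 224 -> 28
        _ResidualBlock(widths[0], widths[1], rng, 1, se),    # 28
        _ResidualBlock(widths[1], widths[1], rng, 1, se),
        _ResidualBlock(widths[1], widths[2], rng, 2, se),    # 14
        _ResidualBlock(widths[2], widths[3], rng, 2, se),    # 7
    ]
    return blocks, widths[3]


def _effnet_small(rng):
    blocks = [
        nn.Conv2d(3, 8, 7, rng, stride=4, padding=3),
        nn.BatchNorm2d(8),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, padding=1),
        _ResidualBlock(8, 16, rng, 1),
        _ResidualBlock(16, 24, rng, 2),
        _ResidualBlock(24, 32, rng, 2),
    ]
    return blocks, 32


BACKBONES = {
    "resnet_small": lambda rng: _resnet_small(rng),
    "se_resnet_small": lambda rng: _resnet_small(rng, se=4),
    "effnet_small": _effnet_small,
}


def build_transfer_model(spec: TransferSpec = TransferSpec(),
                         n_classes: int = 2, seed: int = 0) -> Model2d:
    """Build a stage-2 model with an ``n_classes``-wide linear head."""
    if spec.backbone not in BACKBONES:
        raise ValueError(
            f"unknown backbone {spec.backbone!r}; choose from {sorted(BACKBONES)}")
    rng = np.random.default_rng(seed)
    blocks, feat = BACKBONES[spec.backbone](rng)
    head = nn.Linear(feat, n_classes, rng)
    dropout = nn.Dropout(spec.dropout_p, rng)
    return Model2d(blocks, head, dropout, n_classes, spec)


# ---------------------------------------------------------------------------
# Image preprocessing / augmentation
# ---------------------------------------------------------------------------

def _zscore_image(px: np.ndarray) -> np.ndarray:
    mu, sd = px.mean(), px.std()
    return np.zeros_like(px) if sd == 0 else (px - mu) / sd


def preprocess_image(image: RGBImage) -> np.ndarray:
    """Evaluation-path normalization: per-image z-score, no randomness."""
    return _zscore_image(np.asarray(image.pixels, dtype=float))


def _box_blur3(px: np.ndarray) -> np.ndarray:
    out = np.zeros_like(px)
    pad = np.pad(px, ((1, 1), (1, 1), (0, 0)), mode="edge")
    for dy in range(3):
        for dx in range(3):
            out += pad[dy:dy + px.shape[0], dx:dx + px.shape[1]]
    return out / 9.0


def augment_image(image: RGBImage, cfg: ImageAugmentConfig | None = None,
                  rng: np.random.Generator | None = None) -> RGBImage:
    """Random crop (<= 2% offsets), resize to 224, z-score, noise, sharpness."""
    cfg = ImageAugmentConfig() if cfg is None else cfg
    rng = np.random.default_rng() if rng is None else rng
    px = np.asarray(image.pixels, dtype=float)
    h, w = px.shape[:2]
    max_oy, max_ox = int(cfg.crop_max_frac * h), int(cfg.crop_max_frac * w)
    oy = int(rng.integers(0, max_oy + 1)) if max_oy else 0
    ox = int(rng.integers(0, max_ox + 1)) if max_ox else 0
    cropped = px[oy:h, ox:w]
    if cropped.shape[:2] != (cfg.resize_to, cfg.resize_to):
        cropped = bilinear_resize(cropped, cfg.resize_to, cfg.resize_to)
    out = _zscore_image(cropped)
    if cfg.gauss_noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.gauss_noise_sigma, size=out.shape)
    lo, hi = cfg.sharpness_range
    factor = float(rng.uniform(lo, hi))
    if factor != 1.0:
        blur = _box_blur3(out)
        out = blur + factor * (out - blur)
    return RGBImage(out)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def _to_nchw(images) -> np.ndarray:
    arr = np.stack([np.asarray(im.pixels if isinstance(im, RGBImage) else im,
                               dtype=float) for im in images])
    return arr.transpose(0, 3, 1, 2)


def train_2d(model: Model2d, images, labels, cfg: TrainConfig2d | None = None,
             sampler_weights=None,
             augment_cfg: ImageAugmentConfig | None = None) -> list:
    """Train on RGB images; returns the per-epoch mean loss history.

    For two classes the loss is binary cross-entropy on the logit
    difference (identical to categorical cross-entropy over two logits);
    three or more classes use categorical cross-entropy.  Sampling is
    class-balanced by default.
    """
    from .cascade import weighted_sampler_weights

    cfg = TrainConfig2d() if cfg is None else cfg
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    if sampler_weights is None:
        sampler_weights = weighted_sampler_weights(labels)
    probs = np.asarray(sampler_weights, dtype=float)
    probs = probs / probs.sum()
    augment_cfg = ImageAugmentConfig() if augment_cfg is None else augment_cfg
    rng = np.random.default_rng(cfg.seed)
    model.dropout.rng = rng  # single stream: seed fixes dropout too
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                  eps=cfg.eps, weight_decay=cfg.weight_decay)
    raw = [im if isinstance(im, RGBImage) else RGBImage(im) for im in images]
    n = len(raw)
    batches_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    history = []
    for _ in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(batches_per_epoch):
            idx = rng.choice(n, size=min(cfg.batch_size, n), replace=True, p=probs)
            if cfg.augment:
                batch = [augment_image(raw[i], augment_cfg, rng).pixels for i in idx]
            else:
                batch = [preprocess_image(raw[i]) for i in idx]
            X = np.stack(batch).transpose(0, 3, 1, 2)
            y = labels[idx]
            logits = model.forward(X, training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
        history.append(epoch_loss / batches_per_epoch)
    model.trained = True
    return history


def predict_2d(model: Model2d, images):
    """Per-image class label (argmax; ties -> lowest index) + probabilities."""
    normed = [preprocess_image(im if isinstance(im, RGBImage) else RGBImage(im))
              for im in images]
    X = np.stack(normed).transpose(0, 3, 1, 2)
    if X.shape[2] != 224 or X.shape[3] != 224 or X.shape[1] != 3:
        raise ValueError("stage-2 inputs must be 224x224x3 images")
    probs = model.predict_proba(X)
    return probs.argmax(axis=1), probs
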