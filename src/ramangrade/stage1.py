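"""Stage-1 classifier: a small 1D CNN separating EG1 from G2G3 spectra.

Architecture: one convolutional layer (1 input channel, 4 output channels,
kernel length 6, valid padding, unit stride, ReLU), a max-pool of kernel 3
and stride 3, then fully connected layers of size 1024, 256 and 128, each
followed by batch normalization and ReLU, and a final single-logit head
read through a sigmoid.  The positive class is EG1; a probability of
exactly 0.5 predicts positive (tie rule, so confusion matrices reproduce).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .spectra import BinaryTask, SpectraDataset, augment_noise, augment_shift

__all__ = [
    "Cnn1dSpec",
    "TrainConfig1d",
    "Cnn1dModel",
    "conv_pool_output_length",
    "build_cnn1d",
    "train_binary_1d",
    "predict_1d",
]


@dataclass(frozen=True)
class Cnn1dSpec:
    in_channels: int = 1
    conv_out_channels: int = 4
    conv_kernel: int = 6
    pool_kernel: int = 3
    pool_stride: int = 3
    fc_sizes: tuple = (1024, 256, 128)
    batch_norm_after_fc: bool = True


@dataclass
class TrainConfig1d:
    """Stage-1 optimization settings (Adam, binary cross-entropy)."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    epochs: int = 150
    seed: int = 0
    # on-the-fly 1D augmentations: additive noise proportional to the peak
    # and integer grid shifts mimicking wavelength-calibration error
    noise_relative_scale: float = 0.05
    shift_max_steps: int = 5

    def __post_init__(self):
        if min(self.batch_size, self.learning_rate, self.eps, self.epochs) <= 0 \
                and self.epochs != 0:
            raise ValueError("batch size, learning rate, eps must be positive")


def conv_pool_output_length(input_length: int, spec: Cnn1dSpec = Cnn1dSpec()) -> int:
    """Per-channel length after conv (valid, stride 1) and max-pool."""
    after_conv = input_length - spec.conv_kernel + 1
    return (after_conv - spec.pool_kernel) // spec.pool_stride + 1


class Cnn1dModel:
    """1D CNN with a linear logit head; sigmoid applied at prediction time."""

    def __init__(self, net: nn.Sequential, input_length: int, spec: Cnn1dSpec,
                 n_out: int = 1):
        self.net = net
        self.input_length = input_length
        self.spec = spec
        self.n_out = n_out
        self.trained = False

    def forward(self, x, training=False):
        return self.net.forward(x, training)

    def backward(self, grad):
        return self.net.backward(grad)

    def parameters(self):
        return self.net.parameters()

    def zero_grad(self):
        self.net.zero_grad()

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid (binary) or softmax (multiclass) probabilities, eval mode."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_length:
            raise ValueError(
                f"input length {X.shape[1]} != model length {self.input_length}")
        outs = []
        for i in range(0, len(X), batch_size):
            z = self.net.forward(X[i:i + batch_size, None, :], training=False)
            outs.append(nn.sigmoid(z[:, 0]) if self.n_out == 1 else nn.softmax(z))
        return np.concatenate(outs)

    def save(self, path):
        np.savez(path, **self.net.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.net.load_state_dict({k: data[k] for k in data.files})
        self.trained = True


def build_cnn1d(input_length: int, spec: Cnn1dSpec = Cnn1dSpec(),
                seed: int = 0, n_out: int = 1) -> Cnn1dModel:
    """Deterministically build the stage-1 network for a given input length.

    ``n_out=1`` is the binary EG1-vs-G2G3 head; ``n_out=3`` gives the
    three-class variant used as a baseline.
    """
    pooled = conv_pool_output_length(input_length, spec)
    if pooled < 1:
        min_len = spec.conv_kernel + spec.pool_kernel - 1
        raise ValueError(f"input length {input_length} too short; need >= {min_len}")
    rng = np.random.default_rng(seed)
    layers = [
        nn.Conv1d(spec.in_channels, spec.conv_out_channels, spec.conv_kernel, rng),
        nn.ReLU(),
        nn.MaxPool1d(spec.pool_kernel, spec.pool_stride),
        nn.Flatten(),
    ]
    width = spec.conv_out_channels * pooled
    for fc in spec.fc_sizes:
        layers.append(nn.Linear(width, fc, rng))
        if spec.batch_norm_after_fc:
            layers.append(nn.BatchNorm1d(fc))
        layers.append(nn.ReLU())
        width = fc
    layers.append(nn.Linear(width, n_out, rng))
    return Cnn1dModel(nn.Sequential(*layers), input_length, spec, n_out)


def _sample_batch(rng, n, batch_size, probs):
    return rng.choice(n, size=batch_size, replace=True, p=probs)


def train_binary_1d(model: Cnn1dModel, train: SpectraDataset, task: BinaryTask,
                    cfg: TrainConfig1d | None = None,
                    sampler_weights=None) -> list:
    """Train the binary stage-1 model; returns the per-epoch mean loss history.

    Sampling is class-balanced (inverse class frequency by default), and the
    noise/shift augmentations are drawn fresh per batch.  A fixed seed fixes
    sampling and augmentation, so the loss history is reproducible.
    """
    from .cascade import weighted_sampler_weights

    cfg = TrainConfig1d() if cfg is None else cfg
    labels = np.array([task.label(sp.grade) for sp in train])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both task classes")
    if sampler_weights is None:
        sampler_weights = weighted_sampler_weights(labels)
    probs = np.asarray(sampler_weights, dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                  eps=cfg.eps, weight_decay=cfg.weight_decay)
    n = len(train)
    batches_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    history = []
    for _ in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(batches_per_epoch):
            idx = _sample_batch(rng, n, cfg.batch_size, probs)
            X = np.empty((len(idx), 1, model.input_length))
            y = labels[idx]
            for row, i in enumerate(idx):
                sp = train[i]
                if cfg.shift_max_steps > 0:
                    sp = augment_shift(sp, cfg.shift_max_steps, rng)
                if cfg.noise_relative_scale > 0:
                    sp = augment_noise(sp, cfg.noise_relative_scale,
                                       "proportional_to_peak", rng)
                X[row, 0] = sp.intensities
            logits = model.forward(X, training=True)
            loss, dlogits = nn.bce_with_logits(logits[:, 0], y)
            model.zero_grad()
            model.backward(dlogits[:, None])
            opt.step()
            epoch_loss += loss
        history.append(epoch_loss / batches_per_epoch)
    model.trained = True
    return history


def predict_1d(model: Cnn1dModel, spectra, threshold: float = 0.5):
    """Per-spectrum positive-class probability and binary label.

    Accepts a SpectraDataset or an (n, length) array of normalized spectra.
    ``probability >= threshold`` predicts the positive class (ties go
    positive).  Stateless: the output does not depend on ordering.
    """
    if isinstance(spectra, SpectraDataset):
        X = spectra.intensity_matrix()
    else:
        X = np.asarray(spectra, dtype=float)
    probs = model.predict_proba(X)
    return probs, probs >= threshold
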