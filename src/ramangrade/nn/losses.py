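"""Losses (mean-reduced) returning (loss, gradient-w.r.t.-logits)."""

from __future__ import annotations

import numpy as np


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bce_with_logits(logits, targets):
    """Binary cross-entropy on sigmoid(logits); targets in {0, 1}."""
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(targets, dtype=float).ravel()
    # log(1 + exp(-|z|)) formulation is stable for large |z|
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / len(z)
    return float(loss), grad.reshape(np.shape(logits))


def softmax_cross_entropy(logits, labels):
    """Categorical cross-entropy; labels are integer class indices."""
    p = softmax(np.asarray(logits, dtype=float))
    n = p.shape[0]
    idx = (np.arange(n), np.asarray(labels, dtype=int))
    loss = float(-np.mean(np.log(np.clip(p[idx], 1e-300, None))))
    grad = p.copy()
    grad[idx] -= 1.0
    return loss, grad / n
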