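"""Class activation maps over the stage-2 classifier.

A CAM weights the final convolutional feature maps by the linear head's
weights for one class, producing a low-resolution (7x7 for the default
backbone) saliency grid over the scalogram image.  Because the wavelet
transform preserves horizontal position, salient CAM columns map back to
wavenumber intervals of the underlying 1D spectrum — the proportional
column-to-wavenumber mapping used here is a stated convention, the
correspondence being approximate by nature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stage2 import Model2d, preprocess_image
from .tfr import RGBImage, bilinear_resize, jet_colormap

__all__ = ["CamMap", "compute_cam", "overlay_cam", "cam_to_wavenumber_interval"]


@dataclass
class CamMap:
    """Saliency grid normalized to [0, 1] for one explained class."""

    values: np.ndarray
    class_index: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("CAM values must be 2D")
        if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("CAM values must be normalized to [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


def compute_cam(model: Model2d, image: RGBImage, class_index: int) -> CamMap:
    """CAM = sum_k w[k, class] * F_k over final feature maps, min-max scaled."""
    try:
        feats = model.features(
            preprocess_image(image).transpose(2, 0, 1)[None], training=False)[0]
        weights = model.head_weights()[:, class_index]
    except AttributeError as exc:
        raise TypeError(
            "model does not expose final feature maps and a linear head; "
            "CAM needs a global-pooled architecture") from exc
    cam = np.einsum("c,chw->hw", weights, feats)
    lo, hi = cam.min(), cam.max()
    cam = np.zeros_like(cam) if hi == lo else (cam - lo) / (hi - lo)
    return CamMap(cam, class_index)


def overlay_cam(cam: CamMap, image: RGBImage, alpha: float = 0.5,
                smooth_sigma: float = 2.0) -> RGBImage:
    """Upsample, smooth and JET-color the CAM, alpha-blended over the image.

    alpha = 0 returns the original image; alpha = 1 the pure colormapped CAM.
    """
    h, w = image.pixels.shape[:2]
    up = bilinear_resize(cam.values, h, w)
    if smooth_sigma > 0:
        up = gaussian_filter(up, smooth_sigma)
        lo, hi = up.min(), up.max()
        if hi > lo:
            up = (up - lo) / (hi - lo)
    heat = jet_colormap(np.clip(up, 0.0, 1.0))
    return RGBImage((1.0 - alpha) * image.pixels + alpha * heat)


def cam_to_wavenumber_interval(cam: CamMap, grid, threshold: float = 0.6) -> list:
    """Map salient CAM columns onto wavenumber intervals.

    Columns whose maximum CAM value reaches ``threshold`` are projected
    proportionally onto the wavenumber axis (column j of m covers
    [nu_min + (j/m) * span, nu_min + ((j+1)/m) * span]); adjacent salient
    columns merge into one interval.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    grid = np.asarray(grid, dtype=float)
    nu_min, span = grid[0], grid[-1] - grid[0]
    col_max = cam.values.max(axis=0)
    m = len(col_max)
    hot = col_max >= threshold
    intervals = []
    j = 0
    while j < m:
        if hot[j]:
            start = j
            while j + 1 < m and hot[j + 1]:
                j += 1
            intervals.append((nu_min + start / m * span,
                              nu_min + (j + 1) / m * span))
        j += 1
    return intervals
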