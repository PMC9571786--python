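"""Explain a stage-2 decision with a class activation map.

Trains the image classifier on a cohort whose only E-vs-G1 difference is
the hydroxyapatite band at 960 cm^-1 (grade-1 calcification), then checks
that the 7x7 CAM's salient columns map back to a wavenumber interval
containing that band — the planted-feature recovery that makes the
saliency meaningful.
"""

from ramangrade import BandSpec, CohortConfig, compute_cam, overlay_cam
from ramangrade.cam import cam_to_wavenumber_interval
from ramangrade.simulate import generate_cohort, split_by_meta
from ramangrade.spectra import zscore_normalize
from ramangrade.pipeline import ScalogramRenderer
from ramangrade.stage2 import build_transfer_model, from_scratch_config, train_2d
from ramangrade.tfr import WaveletParams, save_png
import numpy as np

neutral = {"E": 1.0, "G1": 1.0, "G2G3": 1.0}
cfg = CohortConfig(
    bands=[BandSpec(728.0, 12.0, 1.0, dict(neutral)),
           BandSpec(1206.0, 12.0, 0.8, dict(neutral)),
           BandSpec(1660.0, 18.0, 0.6, dict(neutral)),
           BandSpec(2940.0, 30.0, 0.8, dict(neutral)),
           BandSpec(960.0, 12.0, 0.6, {"E": 0.05, "G1": 1.0, "G2G3": 0.05})],
    baseline_amplitude={"E": 1.5, "G1": 1.5, "G2G3": 1.5},
    train_counts={"E": 20, "G1": 20, "G2G3": 4},
    test_counts={"E": 8, "G1": 8, "G2G3": 4})

train, test = (s.map(zscore_normalize) for s in split_by_meta(generate_cohort(cfg, seed=0)))
renderer = ScalogramRenderer(WaveletParams(nv=16))
eg1 = train.subset(np.isin(train.labels(), ["E", "G1"]))
images = [renderer(sp) for sp in eg1]
labels = np.array([0 if c == "E" else 1 for c in eg1.labels()])
model = build_transfer_model(n_classes=2, seed=0)
train_2d(model, images, labels, from_scratch_config(epochs=15, seed=0, batch_size=32))

sample = next(sp for sp in test if sp.grade == "G1")
img = renderer(sample)
cam = compute_cam(model, img, class_index=1)  # explain the G1 call
intervals = cam_to_wavenumber_interval(cam, test.shared_grid, threshold=0.6)
print("salient wavenumber intervals (cm^-1):",
      [(round(lo), round(hi)) for lo, hi in intervals])
grid = test.shared_grid
j = int(np.argmax(cam.values.max(axis=0)))
span = grid[-1] - grid[0]
peak = (grid[0] + j / 7 * span, grid[0] + (j + 1) / 7 * span)
print(f"most salient column -> [{peak[0]:.0f}, {peak[1]:.0f}] cm^-1 "
      f"(planted band at 960: {'inside' if peak[0] <= 960 <= peak[1] else 'outside'})")
save_png(overlay_cam(cam, img, alpha=0.5), "cam_overlay.png")
print("wrote cam_overlay.png")
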