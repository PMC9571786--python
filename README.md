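# ramangrade

Cascaded deep-learning grading of chondrogenic bone tumors from Raman
spectra, for spectroscopists and ML researchers working on spectral
tissue diagnostics.

Raman spectroscopy fingerprints the biochemistry of cartilaginous tumor
tissue: collagen (728, 830, 1206 cm⁻¹) and chondroitin sulfate
(1380 cm⁻¹) degrade as malignancy rises, grade-1 chondrosarcoma shows
hydroxyapatite (960 cm⁻¹) from calcification, and DNA/RNA signal grows
with proliferation. `ramangrade` implements a two-stage cascade over the
three clinically relevant categories {E, G1, G2G3} (benign enchondroma,
grade-1, and high-grade chondrosarcoma):

1. **Stage 1 — 1D CNN on raw normalized spectra.** A single-convolution
   network (1→4 channels, kernel 6; max-pool 3/3; FC 1024/256/128 with
   batch norm; sigmoid) separates EG1 from G2G3.
2. **Stage 2 — 2D CNN on wavelet images.** Spectra routed as EG1 are
   transformed with a generalized-Morse-wavelet CWT
   W(a,b) = (1/a)∫ s(t) ψ*((t−b)/a) dt, synchrosqueezed along the
   frequency axis, rendered as 224×224 JET-colored scalogram images, and
   classified E vs G1 by a compact residual CNN (global average pooling,
   7×7 final feature map — so class activation maps work as usual).

Final per-class accuracies combine multiplicatively
(Acc_E^f = Acc_E²·Acc_EG1¹, Acc_G1^f = Acc_G1²·Acc_EG1¹,
Acc_G2G3^f = Acc_G2G3¹) and the overall figure is the class-count-weighted
mean Acc^f = Σ n_c·Acc_c^f / Σ n_c.

The package also provides the shallow comparison methods (PCA+SVM,
PCA+LDA, LDA, MLP, and the 1D CNN run three-class), CAM saliency mapped
back to wavenumber intervals, and a seeded synthetic cohort simulator
that reproduces the grade-dependent band structure and the
400-spectrum / patient-disjoint split design of the motivating study, so
every stage is testable without clinical data.

## Worked example

Recombining stage-level per-class accuracies into final cascade figures
(`python examples/03_table_recombination.py`):

```
full cascade (stage-1 100/100, stage-2 100/83.3):
AccE_f     100.0%
AccG1_f     83.3%
AccG2G3_f  100.0%
Acc_f       97.4%

PCA+SVM pipeline variant (stage-1 60.0/82.8, stage-2 100/4.2):
AccE_f      60.0%
AccG1_f      2.5%
AccG2G3_f   82.8%
Acc_f       65.7%
```

Reading: with a perfect stage 1, the cascade's only losses are stage-2
G1 errors (20/24 = 83.3%), giving (31 + 20 + 99)/154 = 97.4% overall;
the SVM variant loses 40% of EG1 spectra already at stage 1, capping its
E and G1 finals at 60% of their stage-2 values.

Training the full cascade on a synthetic cohort
(`python examples/04_train_cascade.py`, a few minutes on one CPU):

```
AccE_f     100.0%
AccG1_f    100.0%
AccG2G3_f  100.0%
Acc_f      100.0%
empirical three-class accuracy: 100.0%
per-class: {'E': 100.0, 'G1': 100.0, 'G2G3': 100.0}
```

The default synthetic cohort is deliberately separable at full band
contrast; `CohortConfig(band_contrast=...)` dials the grade-dependent
biochemistry down to zero to study degradation. Other examples:
`01_simulate_cohort.py` (cohort generation and CSV round-trip),
`02_wavelet_scalogram.py` (CWT → synchrosqueezing → PNG, plus the
round-trip inversion error), `05_cam_saliency.py` (CAM saliency
recovering a planted 960 cm⁻¹ band; prints the salient wavenumber
interval).

A thin CLI wraps the same library: `ramangrade simulate`,
`ramangrade render`, `ramangrade full`, `ramangrade tables --help`.

## Scope

Instrument acquisition settings, baseline/fluorescence removal (the
cascade consumes raw signals on purpose), G2-vs-G3 sub-classification
and pretrained-backbone fine-tuning are out of scope. See
`docs/methods.md` for the model, parameter and simulator details and for
what passing synthetic-cohort tests do and do not demonstrate.
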