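"""Cascade composition and aggregated accuracy accounting.

The two binary stages compose asymmetrically: spectra labeled G2G3 by
stage 1 terminate there; spectra labeled EG1 are rendered to scalogram
images and routed to stage 2 for the E-vs-G1 call.  Per-class accuracies
therefore combine multiplicatively,

    Acc_G2G3^f = Acc_G2G3^1
    Acc_E^f    = Acc_E^2 * Acc_EG1^1
    Acc_G1^f   = Acc_G1^2 * Acc_EG1^1

(products of fractions, reported in %), and the final mean accuracy is the
class-count-weighted mean

    Acc^f = (n_E Acc_E^f + n_G1 Acc_G1^f + n_G2G3 Acc_G2G3^f)
            / (n_E + n_G1 + n_G2G3).

Printed per-class accuracies are reports of integer correct counts over
known class sizes, so the default ``fraction_counts`` mode reconstructs
the nearest-integer counts at the stage level (e.g. 82.8% of 99 -> 82/99)
and combines exact fractions; ``printed_products`` multiplies the rounded
percentages directly, as a sensitivity check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .spectra import SpectraDataset, grade_class

__all__ = [
    "CascadeAccuracyReport",
    "weighted_sampler_weights",
    "per_class_accuracy",
    "aggregate_final_accuracy",
    "run_cascade",
]


@dataclass(frozen=True)
class CascadeAccuracyReport:
    """All stage, final and aggregate accuracies (percent) with class counts.

    The multiplicative identities between stage and final accuracies are
    enforced at construction (to float precision).
    """

    acc_EG1_stage1: float
    acc_G2G3_stage1: float
    acc_E_stage2: float
    acc_G1_stage2: float
    acc_E_final: float
    acc_G1_final: float
    acc_G2G3_final: float
    n_E: int
    n_G1: int
    n_G2G3: int
    acc_final: float

    def __post_init__(self):
        vals = [self.acc_EG1_stage1, self.acc_G2G3_stage1, self.acc_E_stage2,
                self.acc_G1_stage2, self.acc_E_final, self.acc_G1_final,
                self.acc_G2G3_final, self.acc_final]
        if any(not 0.0 <= v <= 100.0 + 1e-9 for v in vals):
            raise ValueError("accuracies must be in [0, 100]")
        if min(self.n_E, self.n_G1, self.n_G2G3) <= 0:
            raise ValueError("class counts must be positive")
        tol = 1e-9
        if abs(self.acc_G2G3_final - self.acc_G2G3_stage1) > tol:
            raise ValueError("G2G3 final accuracy must equal its stage-1 accuracy")
        if abs(self.acc_E_final - self.acc_E_stage2 * self.acc_EG1_stage1 / 100.0) > tol:
            raise ValueError("E final accuracy must be the stage product")
        if abs(self.acc_G1_final - self.acc_G1_stage2 * self.acc_EG1_stage1 / 100.0) > tol:
            raise ValueError("G1 final accuracy must be the stage product")
        n = self.n_E + self.n_G1 + self.n_G2G3
        expected = (self.n_E * self.acc_E_final + self.n_G1 * self.acc_G1_final
                    + self.n_G2G3 * self.acc_G2G3_final) / n
        if abs(self.acc_final - expected) > tol:
            raise ValueError("final accuracy must be the count-weighted mean")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> str:
        """Render as a small text table, one decimal, per-class then mean."""
        rows = [
            ("AccE_f", self.acc_E_final),
            ("AccG1_f", self.acc_G1_final),
            ("AccG2G3_f", self.acc_G2G3_final),
            ("Acc_f", self.acc_final),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v:5.1f}%" for k, v in rows)


def weighted_sampler_weights(labels) -> np.ndarray:
    """Per-sample weights proportional to inverse class frequency.

    Sampling with these weights draws each class with equal probability,
    balancing training batches on imbalanced cohorts.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    freq = dict(zip(classes.tolist(), counts.tolist()))
    return np.array([1.0 / freq[l] for l in labels.tolist()])


def per_class_accuracy(pred, true, classes=None) -> dict:
    """Accuracy per class in percent: correct_c / n_c * 100."""
    pred, true = np.asarray(pred), np.asarray(true)
    if len(pred) != len(true):
        raise ValueError("pred and true must have the same length")
    if classes is None:
        classes = np.unique(true).tolist()
    out = {}
    for c in classes:
        mask = true == c
        if not mask.any():
            raise ValueError(f"class {c!r} absent from the true labels")
        out[c] = float(100.0 * np.mean(pred[mask] == true[mask]))
    return out


def _stage_fraction(acc_percent: float, n: int, rounding: str) -> float:
    if rounding == "fraction_counts":
        return round(acc_percent / 100.0 * n) / n
    if rounding == "printed_products":
        return acc_percent / 100.0
    raise ValueError(f"unknown rounding mode {rounding!r}")


def aggregate_final_accuracy(acc_EG1_stage1: float, acc_G2G3_stage1: float,
                             acc_E_stage2: float, acc_G1_stage2: float,
                             n_E: int, n_G1: int, n_G2G3: int,
                             rounding: str = "fraction_counts") -> CascadeAccuracyReport:
    """Combine stage per-class accuracies into the final cascade report.

    ``fraction_counts`` (default) reconstructs nearest-integer correct
    counts at stage level before multiplying — the arithmetic that printed
    percentages imply; ``printed_products`` multiplies percentages as
    printed.
    """
    for v in (acc_EG1_stage1, acc_G2G3_stage1, acc_E_stage2, acc_G1_stage2):
        if not 0.0 <= v <= 100.0:
            raise ValueError("stage accuracies must be in [0, 100]")
    p_eg1 = _stage_fraction(acc_EG1_stage1, n_E + n_G1, rounding)
    p_g2g3 = _stage_fraction(acc_G2G3_stage1, n_G2G3, rounding)
    p_e2 = _stage_fraction(acc_E_stage2, n_E, rounding)
    p_g12 = _stage_fraction(acc_G1_stage2, n_G1, rounding)
    acc_e_f = 100.0 * p_e2 * p_eg1
    acc_g1_f = 100.0 * p_g12 * p_eg1
    acc_g2g3_f = 100.0 * p_g2g3
    n = n_E + n_G1 + n_G2G3
    acc_f = (n_E * acc_e_f + n_G1 * acc_g1_f + n_G2G3 * acc_g2g3_f) / n
    return CascadeAccuracyReport(
        acc_EG1_stage1=100.0 * p_eg1,
        acc_G2G3_stage1=100.0 * p_g2g3,
        acc_E_stage2=100.0 * p_e2,
        acc_G1_stage2=100.0 * p_g12,
        acc_E_final=acc_e_f,
        acc_G1_final=acc_g1_f,
        acc_G2G3_final=acc_g2g3_f,
        n_E=n_E, n_G1=n_G1, n_G2G3=n_G2G3,
        acc_final=acc_f,
    )


def run_cascade(test: SpectraDataset, stage1_predictor, renderer,
                stage2_predictor) -> np.ndarray:
    """Route test spectra through the two-stage cascade.

    ``stage1_predictor(dataset) -> bool array`` flags spectra as EG1;
    ``renderer(spectrum) -> RGBImage`` produces the scalogram image;
    ``stage2_predictor(images) -> array of "E"/"G1"`` resolves the routed
    spectra.  Returns per-spectrum labels in {E, G1, G2G3}.
    """
    for pred in (stage1_predictor, stage2_predictor):
        if getattr(pred, "trained", True) is False:
            raise ValueError("cascade predictors must be trained")
    is_eg1 = np.asarray(stage1_predictor(test), dtype=bool)
    if len(is_eg1) != len(test):
        raise ValueError("stage-1 predictor returned wrong-length mask")
    labels = np.array(["G2G3"] * len(test), dtype=object)
    routed = np.flatnonzero(is_eg1)
    if len(routed):
        images = [renderer(test[i]) for i in routed]
        stage2_labels = np.asarray(stage2_predictor(images))
        if len(stage2_labels) != len(routed):
            raise ValueError("stage-2 predictor returned wrong-length labels")
        labels[routed] = stage2_labels
    return labels.astype(str)
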