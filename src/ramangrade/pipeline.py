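"""End-to-end orchestration: simulate/load -> normalize -> train stage 1 ->
wavelet-render -> train stage 2 -> evaluate the cascade -> write artifacts.

This is the library behind the command-line entry points; every stochastic
component receives a sub-seed derived from the master seed, so a run is
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cascade as casc
from .simulate import CohortConfig, generate_cohort, split_by_meta
from .spectra import (TASK_E_VS_G1, TASK_EG1_VS_G2G3, SpectraDataset,
                      zscore_normalize)
from .stage1 import TrainConfig1d, build_cnn1d, predict_1d, train_binary_1d
from .stage2 import (Model2d, TransferSpec, build_transfer_model,
                     from_scratch_config, predict_2d, train_2d)
from .tfr import WaveletParams, cwt, save_png, scalogram_to_rgb, synchrosqueeze

log = logging.getLogger("ramangrade")

__all__ = ["RunConfig", "ScalogramRenderer", "run_full_pipeline", "derive_seeds"]


def derive_seeds(master: int, n: int) -> list:
    """n reproducible sub-seeds (each < 2**31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "runs/latest"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    train1d: TrainConfig1d = field(default_factory=lambda: TrainConfig1d(epochs=40))
    train2d_epochs: int = 25
    backbone: str = "resnet_small"
    use_synchrosqueezing: bool = True
    n_sample_pngs: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid"] = np.asarray(self.cohort.grid).tolist()
        d["cohort"]["bands"] = [dataclasses.asdict(b) for b in self.cohort.bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .simulate import BandSpec

        d = dict(d)
        coh = dict(d.pop("cohort", {}))
        if "grid" in coh:
            coh["grid"] = np.asarray(coh["grid"], dtype=float)
        if "bands" in coh:
            coh["bands"] = [BandSpec(**b) for b in coh["bands"]]
        wav = dict(d.pop("wavelet", {}))
        if wav.get("scale_range") is not None:
            wav["scale_range"] = tuple(wav["scale_range"])
        t1 = dict(d.pop("train1d", {}))
        if "betas" in t1:
            t1["betas"] = tuple(t1["betas"])
        return cls(cohort=CohortConfig(**coh), wavelet=WaveletParams(**wav),
                   train1d=TrainConfig1d(**t1), **d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class ScalogramRenderer:
    """Normalized spectrum -> (synchrosqueezed) CWT -> JET RGB image."""

    def __init__(self, params: WaveletParams | None = None,
                 synchrosqueezed: bool = True, out_size: int = 224):
        self.params = WaveletParams() if params is None else params
        self.synchrosqueezed = synchrosqueezed
        self.out_size = out_size

    def __call__(self, spectrum):
        x = spectrum.intensities
        sc = cwt(x, self.params)
        if self.synchrosqueezed:
            sc = synchrosqueeze(sc, x, self.params)
        return scalogram_to_rgb(sc, self.out_size)


class _Stage1Predictor:
    def __init__(self, model):
        self.model = model

    @property
    def trained(self):
        return self.model.trained

    def __call__(self, dataset):
        _, is_pos = predict_1d(self.model, dataset)
        return is_pos


class _Stage2Predictor:
    """Maps model class indices back to grade labels (index 0 = E, 1 = G1)."""

    CLASSES = np.array(["E", "G1"])

    def __init__(self, model: Model2d):
        self.model = model

    @property
    def trained(self):
        return self.model.trained

    def __call__(self, images):
        labels, _ = predict_2d(self.model, images)
        return self.CLASSES[labels]


def run_full_pipeline(config: RunConfig | None = None,
                      dataset: SpectraDataset | None = None) -> dict:
    """Execute the full cascade experiment; returns a result dict.

    With ``dataset=None`` a synthetic cohort is generated from
    ``config.cohort``.  Artifacts (report.json, predictions.csv,
    metrics.csv, sample scalogram PNGs, config.yaml) are written under
    ``config.out_dir``.  Result keys: ``report``
    (:class:`~ramangrade.cascade.CascadeAccuracyReport`, Eq-recombined from
    stage accuracies), ``empirical_three_class_accuracy``, ``stage1_model``,
    ``stage2_model``, ``final_labels``, ``test``.
    """
    config = RunConfig() if config is None else config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, 5)
    log.info("derived sub-seeds: %s", seeds)

    # --- data -------------------------------------------------------------
    if dataset is None:
        log.info("stage: simulate (seed %d)", seeds[0])
        dataset = generate_cohort(config.cohort, seed=seeds[0])
    train, test = split_by_meta(dataset)
    if len(train) == 0 or len(test) == 0:
        raise RuntimeError("simulate: dataset has an empty split")
    log.info("stage: preprocess (%d train / %d test spectra)", len(train), len(test))
    train = train.map(zscore_normalize)
    test = test.map(zscore_normalize)

    # --- stage 1 ----------------------------------------------------------
    log.info("stage: train-1d")
    cfg1 = dataclasses.replace(config.train1d, seed=seeds[1])
    model1 = build_cnn1d(len(dataset.shared_grid), seed=seeds[1])
    if cfg1.epochs > 0:
        history1 = train_binary_1d(model1, train, TASK_EG1_VS_G2G3, cfg1)
    else:
        history1, model1.trained = [], True

    # --- stage 2 ----------------------------------------------------------
    log.info("stage: transform + train-2d")
    renderer = ScalogramRenderer(config.wavelet, config.use_synchrosqueezing)
    eg1_train = train.subset(np.isin(train.labels(), ["E", "G1"]))
    images = [renderer(sp) for sp in eg1_train]
    labels2 = np.array([0 if c == "E" else 1 for c in eg1_train.labels()])
    model2 = build_transfer_model(TransferSpec(backbone=config.backbone),
                                  n_classes=2, seed=seeds[2])
    cfg2 = from_scratch_config(epochs=config.train2d_epochs, seed=seeds[3])
    if cfg2.epochs > 0:
        history2 = train_2d(model2, images, labels2, cfg2)
    else:
        history2, model2.trained = [], True

    # --- cascade evaluation ----------------------------------------------
    log.info("stage: evaluate")
    final_labels = casc.run_cascade(test, _Stage1Predictor(model1), renderer,
                                    _Stage2Predictor(model2))
    true_labels = test.labels()
    per_class = casc.per_class_accuracy(final_labels, true_labels,
                                        ["E", "G1", "G2G3"])
    empirical = float(100.0 * np.mean(final_labels == true_labels))

    # stage-level accuracies on the test split, for the Eq-based report
    s1_true = np.isin(true_labels, ["E", "G1"])
    s1_pred = _Stage1Predictor(model1)(test)
    acc_eg1_s1 = 100.0 * np.mean(s1_pred[s1_true])
    acc_g2g3_s1 = 100.0 * np.mean(~s1_pred[~s1_true])
    eg1_test = test.subset(s1_true)
    s2_labels = _Stage2Predictor(model2)([renderer(sp) for sp in eg1_test])
    s2_true = eg1_test.labels()
    s2_acc = casc.per_class_accuracy(s2_labels, s2_true, ["E", "G1"])
    counts = {c: int(np.sum(true_labels == c)) for c in ("E", "G1", "G2G3")}
    report = casc.aggregate_final_accuracy(
        acc_eg1_s1, acc_g2g3_s1, s2_acc["E"], s2_acc["G1"],
        counts["E"], counts["G1"], counts["G2G3"])

    # --- artifacts ---------------------------------------------------------
    config.to_yaml(out / "config.yaml")
    report.to_json(out / "report.json")
    with open(out / "predictions.csv", "w") as fh:
        fh.write("spectrum_id,true,predicted\n")
        for sp, p in zip(test, final_labels):
            fh.write(f"{sp.spectrum_id},{grade_or_class(sp)},{p}\n")
    with open(out / "metrics.csv", "w") as fh:
        fh.write("stage,epoch,loss\n")
        for e, l in enumerate(history1):
            fh.write(f"stage1,{e},{l!r}\n")
        for e, l in enumerate(history2):
            fh.write(f"stage2,{e},{l!r}\n")
    for i in range(min(config.n_sample_pngs, len(test))):
        save_png(renderer(test[i]), out / f"scalogram_{test[i].spectrum_id}.png")
    with open(out / "summary.json", "w") as fh:
        json.dump({"empirical_three_class_accuracy": empirical,
                   "per_class": per_class, "counts": counts,
                   "seeds": seeds}, fh, indent=2)
    log.info("final three-class accuracy: %.1f%%", empirical)
    return {
        "report": report,
        "empirical_three_class_accuracy": empirical,
        "per_class": per_class,
        "stage1_model": model1,
        "stage2_model": model2,
        "stage1_history": history1,
        "stage2_history": history2,
        "final_labels": final_labels,
        "test": test,
        "renderer": renderer,
    }


def grade_or_class(sp) -> str:
    from .spectra import grade_class

    try:
        return grade_class(sp.grade)
    except ValueError:
        return sp.grade
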