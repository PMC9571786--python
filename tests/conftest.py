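"""Shared fixtures.

The two expensive session fixtures — the full cascade run and the
planted-band stage-2 model — are computed once and shared between the
module tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ramangrade.pipeline import RunConfig, ScalogramRenderer, run_full_pipeline
from ramangrade.simulate import BandSpec, CohortConfig, generate_cohort, split_by_meta
from ramangrade.spectra import zscore_normalize
from ramangrade.stage1 import TrainConfig1d
from ramangrade.stage2 import TransferSpec, build_transfer_model, from_scratch_config, train_2d
from ramangrade.tfr import WaveletParams

SMALL_GRID = np.linspace(200.0, 3400.0, 401)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return SMALL_GRID.copy()


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """Full cascade experiment on the default synthetic cohort.

    Reduced epochs and 32 voices per octave keep the run within a few
    minutes of CPU while leaving wide margins on the learning targets.
    """
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(seed=0, out_dir=str(out),
                    wavelet=WaveletParams(nv=32),
                    train1d=TrainConfig1d(epochs=30),
                    train2d_epochs=20)
    return run_full_pipeline(cfg)


def planted_band_config(contrast: float = 1.0) -> CohortConfig:
    """Cohort whose only class-discriminative feature is the 960 cm^-1 band.

    The planted band is weaker than the shared bands so that per-image
    render normalization stays anchored on class-shared structure and the
    discriminative pixels remain local to the band.
    """
    neutral = {"E": 1.0, "G1": 1.0, "G2G3": 1.0}
    bands = [
        BandSpec(728.0, 12.0, 1.0, dict(neutral), "collagen_728"),
        BandSpec(1206.0, 12.0, 0.8, dict(neutral), "collagen_1206"),
        BandSpec(1660.0, 18.0, 0.6, dict(neutral), "amide_I_1660"),
        BandSpec(2940.0, 30.0, 0.8, dict(neutral), "ch_stretch_2940"),
        BandSpec(960.0, 12.0, 0.6,
                 {"E": 0.05, "G1": 1.0, "G2G3": 0.05}, "hydroxyapatite_960"),
    ]
    return CohortConfig(
        bands=bands,
        baseline_amplitude={"E": 1.5, "G1": 1.5, "G2G3": 1.5},
        band_contrast=contrast,
        train_counts={"E": 20, "G1": 20, "G2G3": 4},
        test_counts={"E": 8, "G1": 8, "G2G3": 4},
    )


def train_e_vs_g1(config: CohortConfig, seed: int = 0, epochs: int = 12,
                  nv: int = 16):
    """Render an E/G1 cohort and train a small stage-2 model on it.

    Returns (model, renderer, train EG1 subset, test EG1 subset).
    """
    ds = generate_cohort(config, seed=seed)
    train, test = split_by_meta(ds)
    train = train.map(zscore_normalize)
    test = test.map(zscore_normalize)
    renderer = ScalogramRenderer(WaveletParams(nv=nv))
    tr_eg1 = train.subset(np.isin(train.labels(), ["E", "G1"]))
    te_eg1 = test.subset(np.isin(test.labels(), ["E", "G1"]))
    images = [renderer(sp) for sp in tr_eg1]
    labels = np.array([0 if c == "E" else 1 for c in tr_eg1.labels()])
    model = build_transfer_model(TransferSpec(), n_classes=2, seed=seed)
    cfg2 = from_scratch_config(epochs=epochs, seed=seed, batch_size=32)
    train_2d(model, images, labels, cfg2)
    return model, renderer, tr_eg1, te_eg1


@pytest.fixture(scope="session")
def planted_band_model():
    """Stage-2 model trained where 960 cm^-1 is the only discriminative band."""
    model, renderer, tr, te = train_e_vs_g1(planted_band_config(), seed=0,
                                            epochs=15)
    return {"model": model, "renderer": renderer, "train": tr, "test": te}
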