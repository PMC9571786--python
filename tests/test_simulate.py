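"""Synthetic cohort generator: band structure, counts, splits, separability."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from ramangrade.simulate import (
    CohortConfig,
    PatientProfile,
    default_band_set,
    generate_cohort,
    split_by_meta,
    split_one_patient_per_class_out,
    synthesize_spectrum,
)
from ramangrade.spectra import zscore_normalize


def band(name):
    return next(b for b in default_band_set() if b.name == name)


class TestDefaultBands:
    def test_collagen_and_chondroitin_degrade_with_grade(self):
        for name in ("collagen_728", "collagen_830", "collagen_1206",
                     "chondroitin_1380"):
            m = band(name).grade_multipliers
            assert m["E"] > m["G1"] > m["G2G3"]

    def test_hydroxyapatite_peaks_at_g1(self):
        m = band("hydroxyapatite_960").grade_multipliers
        assert m["G1"] > m["E"] and m["G1"] > m["G2G3"]

    def test_dna_rna_increases_with_grade(self):
        for name in ("dna_rna_785", "dna_rna_1578"):
            m = band(name).grade_multipliers
            assert m["E"] < m["G1"] < m["G2G3"]


class TestSynthesizeSpectrum:
    def test_all_zero_when_everything_off(self):
        cfg = CohortConfig(bands=[], baseline_amplitude={},
                           rayleigh_amplitude=0.0, noise_sigma=0.0)
        sp = synthesize_spectrum(PatientProfile("P", "E"), cfg,
                                 np.random.default_rng(0))
        np.testing.assert_array_equal(sp.intensities, 0.0)

    def test_single_band_peaks_at_its_center(self):
        from ramangrade.simulate import BandSpec

        cfg = CohortConfig(
            bands=[BandSpec(960.0, 12.0, 1.0, {"E": 1.0, "G1": 1.0, "G2G3": 1.0})],
            baseline_amplitude={}, rayleigh_amplitude=0.0, noise_sigma=0.0)
        sp = synthesize_spectrum(PatientProfile("P", "E"), cfg,
                                 np.random.default_rng(0))
        peak_wn = sp.wavenumbers[np.argmax(sp.intensities)]
        assert abs(peak_wn - 960.0) <= np.diff(sp.wavenumbers).max()

    def test_seeded_determinism(self):
        cfg = CohortConfig()
        prof = PatientProfile("P", "G1", 1.1, 0.5)
        a = synthesize_spectrum(prof, cfg, np.random.default_rng(3))
        b = synthesize_spectrum(prof, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            synthesize_spectrum(PatientProfile("P", "unknown"), CohortConfig(),
                                np.random.default_rng(0))

    def test_zero_variability_makes_same_grade_identical(self):
        cfg = CohortConfig(patient_amp_sigma=0.0, patient_offset_sigma=0.0,
                           noise_sigma=0.0,
                           train_counts={"E": 2, "G1": 2, "G2G3": 2},
                           test_counts={"E": 1, "G1": 1, "G2G3": 1})
        # baseline jitter is a per-draw effect; disable it via zero amplitude
        cfg.baseline_amplitude = {}
        ds = generate_cohort(cfg, seed=0)
        for grade in ("E", "G1"):
            rows = [sp.intensities for sp in ds if sp.grade == grade]
            for r in rows[1:]:
                np.testing.assert_allclose(r, rows[0])


class TestGenerateCohort:
    def test_default_counts_match_study_design(self):
        ds = generate_cohort(seed=0)
        assert len(ds) == 400
        train, test = split_by_meta(ds)
        test_counts = {c: int(np.sum(test.labels() == c))
                       for c in ("E", "G1", "G2G3")}
        train_counts = {c: int(np.sum(train.labels() == c))
                        for c in ("E", "G1", "G2G3")}
        assert test_counts == {"E": 31, "G1": 24, "G2G3": 99}
        assert train_counts == {"E": 69, "G1": 76, "G2G3": 101}

    def test_patients_disjoint_across_splits(self):
        ds = generate_cohort(seed=1)
        train, test = split_by_meta(ds)
        assert not set(train.patient_ids()) & set(test.patient_ids())

    def test_seeded_determinism(self):
        a = generate_cohort(seed=5)
        b = generate_cohort(seed=5)
        np.testing.assert_array_equal(a.intensity_matrix(), b.intensity_matrix())

    def test_small_counts_split_each_patient_one_side(self):
        cfg = CohortConfig(patients_per_class=2,
                           train_counts={"E": 4, "G1": 4, "G2G3": 4},
                           test_counts={"E": 4, "G1": 4, "G2G3": 4})
        ds = generate_cohort(cfg, seed=0)
        train, test = split_by_meta(ds)
        assert not set(train.patient_ids()) & set(test.patient_ids())
        assert len(ds) == 24


class TestPatientSplit:
    def test_held_out_patient_absent_from_train(self):
        ds = generate_cohort(seed=0)
        held = {"E": "P_E_0", "G1": "P_G1_0", "G2G3": "P_G2G3_0"}
        train, test = split_one_patient_per_class_out(ds, held)
        assert "P_E_0" not in set(train.patient_ids())
        assert set(test.patient_ids()) == set(held.values())
        assert len(train) + len(test) == len(ds)

    def test_mismatched_class_rejected(self):
        ds = generate_cohort(seed=0)
        with pytest.raises(ValueError, match="carry"):
            split_one_patient_per_class_out(ds, {"E": "P_G1_0"})

    def test_emptying_a_class_rejected(self):
        cfg = CohortConfig(patients_per_class=2,
                           train_counts={"E": 2, "G1": 2, "G2G3": 2},
                           test_counts={"E": 2, "G1": 2, "G2G3": 2})
        ds = generate_cohort(cfg, seed=0)
        # drop the second E patient so P_E_0 is the only E patient left
        only_one_e = ds.subset(ds.patient_ids() != "P_E_1")
        with pytest.raises(ValueError, match="empties"):
            split_one_patient_per_class_out(only_one_e, {"E": "P_E_0"})


class TestSeparability:
    def test_high_contrast_ceiling_and_zero_contrast_floor(self):
        # ceiling: default contrast is linearly separable across patients
        ds = generate_cohort(CohortConfig(band_contrast=1.0), seed=3)
        tr, te = split_by_meta(ds)
        tr, te = tr.map(zscore_normalize), te.map(zscore_normalize)
        clf = LogisticRegression(max_iter=2000)
        clf.fit(tr.intensity_matrix(), tr.labels())
        acc_high = (clf.predict(te.intensity_matrix()) == te.labels()).mean()
        assert acc_high > 0.95
        # floor: no biochemical contrast, no patient effects -> near prior
        cfg0 = CohortConfig(band_contrast=0.0, patient_amp_sigma=0.0,
                            patient_offset_sigma=0.0)
        ds0 = generate_cohort(cfg0, seed=3)
        tr0, te0 = split_by_meta(ds0)
        tr0, te0 = tr0.map(zscore_normalize), te0.map(zscore_normalize)
        clf0 = LogisticRegression(max_iter=2000)
        clf0.fit(tr0.intensity_matrix(), tr0.labels())
        acc_floor = (clf0.predict(te0.intensity_matrix()) == te0.labels()).mean()
        prior = 99 / 154
        assert acc_floor < 0.8
        assert abs(acc_floor - prior) < 0.2
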