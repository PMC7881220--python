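"""Preprocessing: presence filter, deisotoping, transforms, round trips."""

import warnings

import numpy as np
import pytest

import plaquemap as pm
from plaquemap.msi_data import (
    ISOTOPE_DELTA,
    MzAxis,
    StudyFormatError,
    log_transform,
    normalize_image_per_mz,
    read_study,
    remove_isotopes,
    select_common_peaks,
)
from conftest import make_study


class TestReadStudy:
    def test_round_trip_preserves_spectra(self, small_study, tmp_path):
        spec = pm.PhantomSpec(grid_shape=(32, 32))
        study, _ = pm.generate_study(2, (3, 3), spec, seed=3, n_per_class=1,
                                     out_dir=tmp_path)
        loaded = read_study(tmp_path / "manifest.csv")
        assert len(loaded) == len(study) == 6
        assert np.allclose(loaded.mz.values, study.mz.values, atol=1e-4)
        for s in study.sections:
            l = loaded.section(s.patient_id, s.section_id)
            assert np.allclose(l.intensities, s.intensities, rtol=1e-5, atol=1e-4)

    def test_empty_manifest_warns(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text("patient_id,section_id,imzml\n")
        with pytest.warns(UserWarning, match="empty"):
            study = read_study(path)
        assert len(study) == 0

    def test_corrupt_file_names_the_section(self, tmp_path):
        bad = tmp_path / "bad.imzML"
        bad.write_text("not imzml at all")
        path = tmp_path / "manifest.csv"
        path.write_text(f"patient_id,section_id,imzml\nP09,S03,bad.imzML\n")
        with pytest.raises(StudyFormatError, match="P09/S03"):
            read_study(path)

    def test_hdf5_round_trip(self, tmp_path, small_study):
        study, _ = small_study
        pm.msi_data.save_study(study, tmp_path / "study.h5")
        loaded = pm.msi_data.load_study(tmp_path / "study.h5")
        assert len(loaded) == len(study)
        s, l = study.sections[0], loaded.section(study.sections[0].patient_id,
                                                 study.sections[0].section_id)
        assert np.array_equal(s.intensities, l.intensities)


class TestMzAxis:
    def test_rejects_unsorted_or_out_of_range(self):
        with pytest.raises(ValueError):
            MzAxis(np.array([400.0, 399.0]))
        with pytest.raises(ValueError):
            MzAxis(np.array([100.0, 500.0]))

    def test_index_lookup_within_tolerance(self):
        axis = MzAxis(np.array([400.0, 500.0]), tolerance=0.02)
        assert axis.index_of(400.01) == 0
        with pytest.raises(KeyError):
            axis.index_of(400.5)


class TestSelectCommonPeaks:
    def _study_with_presence(self, n_sections, present_in):
        """Peak 0 nonzero in the first ``present_in`` sections, peak 1 in all."""
        blocks = []
        for i in range(n_sections):
            first = 5.0 if i < present_in else 0.0
            blocks.append([[first, 1.0], [first, 2.0], [first, 1.5], [first, 0.5]])
        return make_study(blocks)

    @pytest.mark.parametrize("present,expected_kept", [(32, True), (31, False)])
    def test_strict_30_percent_threshold_at_study_scale(self, present, expected_kept):
        """106-section scale: 32/106 ≈ 0.302 is kept, 31/106 ≈ 0.292 dropped."""
        study = self._study_with_presence(106, present)
        table = select_common_peaks(study, min_fraction=0.30)
        assert (0 in table.df.index) is expected_kept
        assert 1 in table.df.index                    # present everywhere

    def test_idempotent_and_subset(self, small_study):
        study, _ = small_study
        first = select_common_peaks(study)
        again = select_common_peaks(pm.msi_data.subset_study(study, first),
                                    min_fraction=0.30)
        assert len(again) == len(first)
        assert set(first.mz).issuperset(set(again.mz))

    def test_presence_fraction_bounds(self, small_study):
        study, _ = small_study
        table = select_common_peaks(study, min_fraction=0.0)
        assert ((table.df.presence_fraction >= 0)
                & (table.df.presence_fraction <= 1)).all()


class TestRemoveIsotopes:
    def test_planted_satellite_removed(self):
        """A peak 1.00335 Da up at 0.44× its parent is a first isotopologue."""
        parent, sat = 701.571, 701.571 + ISOTOPE_DELTA
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, size=(8, 1))
        blocks = [np.hstack([base, 0.44 * base]) for _ in range(3)]
        study = make_study(blocks, mz=[parent, sat], grid=(2, 4))
        table = select_common_peaks(study, min_fraction=0.0)
        out = remove_isotopes(table, study)
        assert list(out.mz) == [parent]

    def test_adduct_gap_peaks_both_retained(self):
        """671.580 / 693.562: the 21.982 Da Na−H gap is not an isotope gap."""
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 5, size=(8, 1))
        blocks = [np.hstack([base, 0.3 * base]) for _ in range(3)]
        study = make_study(blocks, mz=[671.580, 693.562], grid=(2, 4))
        table = select_common_peaks(study, min_fraction=0.0)
        out = remove_isotopes(table, study)
        assert len(out) == 2

    def test_no_lighter_partner_never_removed(self):
        rng = np.random.default_rng(2)
        blocks = [rng.uniform(1, 5, size=(8, 3)) for _ in range(2)]
        study = make_study(blocks, mz=[400.0, 450.0, 500.0], grid=(2, 4))
        table = select_common_peaks(study, min_fraction=0.0)
        out = remove_isotopes(table, study)
        assert len(out) == 3

    def test_strong_peak_one_dalton_up_survives(self):
        """A genuine peak above the isotope-ratio ceiling is not deleted."""
        base = np.ones((8, 1)) * 2.0
        blocks = [np.hstack([base, 1.9 * base]) for _ in range(3)]
        study = make_study(blocks, mz=[500.0, 500.0 + ISOTOPE_DELTA], grid=(2, 4))
        table = select_common_peaks(study, min_fraction=0.0)
        assert len(remove_isotopes(table, study)) == 2

    def test_invalid_tolerance(self, small_study):
        study, _ = small_study
        table = select_common_peaks(study)
        with pytest.raises(ValueError):
            remove_isotopes(table, study, tol=0.0)

    def test_phantom_deisotoping_accuracy(self, small_study):
        """≥95% of satellites removed and ≥95% of parent species retained."""
        study, truth = small_study
        table = select_common_peaks(study)
        out = remove_isotopes(table, study)
        parents = np.round(truth.panel.mz, 3)
        sats = np.round(truth.panel.mz + ISOTOPE_DELTA, 3)
        kept = np.round(out.mz, 3)
        assert np.isin(parents, kept).mean() >= 0.95
        assert 1 - np.isin(sats, kept).mean() >= 0.95


class TestTransforms:
    def test_log_transform_closed_forms_and_monotone(self):
        study = make_study([[[0.0, np.e - 1], [2.0, 5.0], [1.0, 0.5], [0.1, 9.0]]])
        logged = log_transform(study)
        X, L = study.sections[0].intensities, logged.sections[0].intensities
        assert L[0, 0] == 0.0
        assert L[0, 1] == pytest.approx(1.0)
        order = np.argsort(X.ravel())
        assert (np.diff(L.ravel()[order]) >= 0).all()
        assert study.scale == "raw" and logged.scale == "log"
        assert X.max() > L.max()                       # raw view untouched

    def test_log_transform_rejects_negative(self):
        study = make_study([[[1.0, 1.0]] * 4])
        study.sections[0].intensities[0, 0] = -1e-9    # corrupt post-hoc
        with pytest.raises(ValueError):
            log_transform(study)

    @pytest.mark.parametrize("case", ["constant", "zero", "hot"])
    def test_normalize_image_per_mz(self, case):
        values = {"constant": np.full(4, 7.0), "zero": np.zeros(4),
                  "hot": np.array([0, 0, 0, 9.0])}[case]
        study = make_study([values[:, None]])
        img = normalize_image_per_mz(study.sections[0], 0)
        at = img[study.sections[0].coords[:, 0], study.sections[0].coords[:, 1]]
        if case == "constant":
            assert np.allclose(at, 1.0)
        elif case == "zero":
            assert np.allclose(img, 0.0)
        else:
            assert at.max() == 1.0 and img.min() == 0.0
        assert img.min() >= 0 and img.max() <= 1
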