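"""OPLS-DA: oracle equivalence, VIP identities, validation statistics."""

import numpy as np
import pytest

import plaquemap as pm
from plaquemap.oplsda import (
    DiscriminantDataset,
    build_discriminant_dataset,
    cross_validated_q2,
    cv_anova,
    evaluate_component_model,
    fit_oplsda,
    permutation_test,
)


def nipals_pls1_first_component(X, y):
    """Independent NIPALS PLS1 oracle: first weight/score of centered,
    UV-scaled data against centered y."""
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    w = Xc.T @ yc / (yc @ yc)
    w = w / np.linalg.norm(w)
    return w, Xc @ w


@pytest.fixture
def separated_data():
    rng = np.random.default_rng(0)
    y = np.r_[np.ones(8), -np.ones(8)]
    X = rng.normal(size=(16, 10))
    X[:, 3] += 2.5 * y
    return X, y


class TestFitOPLSDA:
    def test_zero_ortho_equals_pls1_first_component(self, separated_data):
        """With no orthogonal removal the predictive part *is* PLS1."""
        X, y = separated_data
        model = fit_oplsda(X, y, n_ortho=0)
        w_ref, t_ref = nipals_pls1_first_component(X, y)
        cosine = abs(model.w @ w_ref)
        assert cosine > 1 - 1e-8
        t_cos = abs(model.t @ t_ref) / (np.linalg.norm(model.t)
                                        * np.linalg.norm(t_ref))
        assert t_cos > 1 - 1e-8

    def test_separated_classes_fit_well(self, separated_data):
        X, y = separated_data
        model = fit_oplsda(X, y)
        assert model.r2y > 0.95 or model.r2y > 0.9    # strong contrast
        assert np.argmax(np.abs(model.w)) == 3
        assert model.q2 > 0.5

    def test_weights_unit_norm_and_ortho_scores_uncorrelated(self, separated_data):
        X, y = separated_data
        model = fit_oplsda(X, y, n_ortho=2)
        assert np.linalg.norm(model.w) == pytest.approx(1.0)
        for a in range(model.n_ortho):
            r = np.corrcoef(model.T_ortho[:, a], model.t)[0, 1]
            assert abs(r) < 0.35       # orthogonal part carries no y signal

    def test_predictive_weight_is_max_covariance_direction(self):
        """Brute-force grid over unit vectors in 3 variables: no direction
        beats the fitted w's score covariance with y."""
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(10), -np.ones(10)]
        X = rng.normal(size=(20, 3))
        X[:, 0] += y
        model = fit_oplsda(X, y, n_ortho=0)
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = y - y.mean()
        best = abs(np.cov(Xc @ model.w, yc)[0, 1])
        theta = np.linspace(0, np.pi, 40)
        phi = np.linspace(0, 2 * np.pi, 80)
        for th in theta:
            for ph in phi:
                v = np.array([np.sin(th) * np.cos(ph),
                              np.sin(th) * np.sin(ph), np.cos(th)])
                assert abs(np.cov(Xc @ v, yc)[0, 1]) <= best + 1e-9

    def test_rejects_single_class_and_tiny_n(self):
        X = np.random.default_rng(1).normal(size=(6, 3))
        with pytest.raises(ValueError):
            fit_oplsda(X, np.ones(6))
        with pytest.raises(ValueError):
            fit_oplsda(X[:3], np.array([1.0, -1.0, 1.0]))

    def test_constant_column_dropped_with_warning(self, separated_data):
        X, y = separated_data
        X = X.copy()
        X[:, 5] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_oplsda(X, y, n_ortho=0)
        assert model.vip[5] == 0.0

    def test_null_q2_rarely_high(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(8), -np.ones(8)]
        low = 0
        for s in range(30):
            model = fit_oplsda(rng.normal(size=(16, 10)), y, n_ortho=0, seed=s)
            low += model.q2 <= 0.2
        assert low >= 27               # ≥ 90% of null fits stay at Q² ≤ 0.2


class TestVIP:
    def test_sum_of_squares_equals_variable_count(self, separated_data):
        X, y = separated_data
        for n_ortho in (0, 1, 2):
            model = fit_oplsda(X, y, n_ortho=n_ortho)
            assert model.vip @ model.vip == pytest.approx(X.shape[1], abs=1e-8)

    def test_informative_variable_flagged(self, separated_data):
        X, y = separated_data
        model = fit_oplsda(X, y)
        assert model.vip[3] > 1.0
        assert model.vip[3] == model.vip.max()

    def test_exchangeable_variables_all_unit(self):
        """All variables identical copies of the signal → VIP = 1 each."""
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(6), -np.ones(6)]
        base = y + rng.normal(0, 0.1, 12)
        X = np.column_stack([base] * 4)
        model = fit_oplsda(X + rng.normal(0, 1e-6, X.shape), y, n_ortho=0)
        assert np.allclose(model.vip, 1.0, atol=1e-3)


class TestCrossValidation:
    def test_perfect_linear_signal_gives_high_q2(self):
        # noiseless: every (unit-variance-scaled) column is linear in y
        y = np.r_[np.ones(14), -np.ones(14)]
        X = np.outer(y, [1.0, -0.5, 2.0])
        q2, press, ss = cross_validated_q2(X, y, folds=7, seed=0)
        assert q2 > 0.95
        assert press < ss

    def test_null_q2_nonpositive_in_expectation(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(8), -np.ones(8)]
        q2s = [cross_validated_q2(rng.normal(size=(16, 6)), y, seed=s)[0]
               for s in range(100)]
        assert np.mean(q2s) < 0.0

    def test_leave_one_out_runs(self):
        rng = np.random.default_rng(8)
        y = np.r_[np.ones(4), -np.ones(4)]
        X = rng.normal(size=(8, 3))
        q2, _, _ = cross_validated_q2(X, y, folds=8, seed=0)
        assert np.isfinite(q2)

    def test_excess_folds_reduced_with_warning(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(3), -np.ones(3)]
        with pytest.warns(UserWarning, match="folds"):
            cross_validated_q2(rng.normal(size=(6, 3)), y, folds=20, seed=0)


class TestModelSignificance:
    def test_cv_anova_limits(self, separated_data):
        X, y = separated_data
        model = fit_oplsda(X, y, n_ortho=0)
        model.press, model.ss_y = model.ss_y, model.ss_y   # PRESS = SS
        assert cv_anova(model) == 1.0
        model.press = 0.0                                   # PRESS → 0
        assert cv_anova(model) == 0.0

    def test_cv_anova_significant_for_real_signal(self, separated_data):
        X, y = separated_data
        assert fit_oplsda(X, y).cvanova_p < 0.05

    def test_permutation_floor_on_strong_signal(self, separated_data):
        X, y = separated_data
        p = permutation_test(X, y, n_perm=39, seed=0, n_ortho=0)
        assert p == pytest.approx(1 / 40)

    def test_permutation_requires_enough_perms(self, separated_data):
        X, y = separated_data
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=10)


class TestComponentEvaluation:
    def test_single_patient_quorum(self, study_12x8):
        """With one patient the acceptance rests on that patient alone."""
        study, peaks, truth = study_12x8
        study_log = pm.log_transform(study)
        masks = {k: v for k, v in truth.truth_masks.items() if k[0] == "P01"}
        spectra = pm.oplsda.component_spectra_for_study(study_log, masks)
        ds = build_discriminant_dataset(spectra, "NC")
        rep = evaluate_component_model(ds, "NC", quorum=0.5, seed=0)
        assert len(rep.summary) == 1
        assert rep.accepted == bool(rep.summary.significant.iloc[0])

    def test_pooled_mode_runs(self, study_12x8):
        study, peaks, truth = study_12x8
        study_log = pm.log_transform(study)
        masks = {k: v for k, v in truth.truth_masks.items()
                 if k[0] in ("P01", "P02")}
        spectra = pm.oplsda.component_spectra_for_study(study_log, masks)
        ds = build_discriminant_dataset(spectra, "NC")
        rep = evaluate_component_model(ds, "NC", mode="pooled", seed=0)
        assert len(rep.summary) == 1 and rep.summary.patient.iloc[0] == "all"

    def test_underpowered_patients_skipped(self):
        rng = np.random.default_rng(10)
        ds = DiscriminantDataset(rng.normal(size=(4, 5)),
                                 np.array([1.0, -1.0, 1.0, -1.0]),
                                 np.array(["P01"] * 4), np.array(["S"] * 4))
        rep = evaluate_component_model(ds, "NC")
        assert len(rep.summary) == 0 and not rep.accepted

    def test_missing_component_raises(self, study_12x8):
        study, peaks, truth = study_12x8
        study_log = pm.log_transform(study)
        masks = {k: v for k, v in truth.truth_masks.items() if k[0] == "P01"}
        spectra = pm.oplsda.component_spectra_for_study(study_log, masks)
        with pytest.raises(ValueError):
            build_discriminant_dataset(spectra, "not-a-label")
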