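"""Univariate statistics: exact Wilcoxon, ROC/Youden, paired section means."""

import itertools

import numpy as np
import pytest
from scipy import stats

import plaquemap as pm
from plaquemap.registration import LABEL_CODES
from plaquemap.univariate import (
    confirm_vips,
    paired_means,
    roc_youden,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Full 2ⁿ sign-flip enumeration of the W+ null (n ≤ 12)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats_all = [np.asarray(signs) @ ranks
                 for signs in itertools.product([0, 1], repeat=len(d))]
    stats_all = np.asarray(stats_all)
    cdf = (stats_all <= w_obs + 1e-9).mean()
    sf = (stats_all >= w_obs - 1e-9).mean()
    return w_obs, min(1.0, 2 * min(cdf, sf))


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.statistic == 15
        assert res.p_value == pytest.approx(0.0625)   # 2/2⁵

    def test_symmetric_differences_p_one(self):
        res = wilcoxon_signed_rank(np.array([3.0, -3.0, 1.5, -1.5]))
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = np.round(rng.normal(size=n), 1)           # rounding creates ties
        w_ref, p_ref = wilcoxon_enumeration_oracle(d)
        res = wilcoxon_signed_rank(d)
        assert res.statistic == pytest.approx(w_ref)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(42)
        d = rng.normal(0.3, 1.0, size=15)
        res = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided")
        # scipy reports min(W+, W−); ours is W+ — p-values must agree
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped(self):
        with_zeros = wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, -0.5,
                                                    3.0, 1.5]))
        without = wilcoxon_signed_rank(np.array([1.0, 2.0, -0.5, 3.0, 1.5]))
        assert with_zeros.statistic == without.statistic
        assert with_zeros.n == 5

    def test_underpowered_flagged(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.underpowered and 0 < res.p_value <= 1

    def test_null_rejection_rate_calibrated(self):
        """n=30 null pairs, 400 reps: rejection at 0.05 within [0.03, 0.07]."""
        rng = np.random.default_rng(7)
        reject = 0
        reps = 400
        for _ in range(reps):
            d = rng.normal(size=30)
            reject += wilcoxon_signed_rank(d).p_value <= 0.05
        assert 0.03 <= reject / reps <= 0.07


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden(np.array([5.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.cutoff == pytest.approx(4.0)       # midpoint of (3, 5)

    def test_identical_distributions(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = roc_youden(x, x)
        assert res.auc == pytest.approx(0.5)
        assert res.youden_j == pytest.approx(0.0)

    def test_small_fixture_by_exhaustive_scan(self):
        x_in = np.array([0.3, 0.5, 0.7])
        x_out = np.array([0.2, 0.4])
        res = roc_youden(x_in, x_out)
        uniq = np.unique(np.r_[x_in, x_out])
        best = max(((x_in > c).mean() + (x_out <= c).mean() - 1, -c)
                   for c in (uniq[:-1] + uniq[1:]) / 2)
        assert res.youden_j == pytest.approx(best[0])
        assert res.cutoff == pytest.approx(-best[1])

    @pytest.mark.parametrize("seed", range(20))
    def test_cutoff_matches_exhaustive_scan_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        x_in = rng.normal(1.0, 1.0, size=rng.integers(3, 15))
        x_out = rng.normal(0.0, 1.0, size=rng.integers(3, 15))
        res = roc_youden(x_in, x_out)
        uniq = np.unique(np.r_[x_in, x_out])
        mids = (uniq[:-1] + uniq[1:]) / 2
        js = np.array([(x_in > c).mean() + (x_out <= c).mean() - 1 for c in mids])
        assert res.youden_j == pytest.approx(js.max(), abs=1e-12)
        # lowest cutoff among numerically tied maxima
        assert res.cutoff == pytest.approx(min(mids[js >= js.max() - 1e-9]))

    def test_auc_equals_trapezoidal_integration(self):
        rng = np.random.default_rng(3)
        x_in = rng.normal(0.8, 1.0, 40)
        x_out = rng.normal(0.0, 1.0, 50)
        res = roc_youden(x_in, x_out)
        thresholds = np.r_[np.inf, np.sort(np.unique(np.r_[x_in, x_out]))[::-1]]
        tpr = [(x_in >= t).mean() for t in thresholds] + [1.0]
        fpr = [(x_out >= t).mean() for t in thresholds] + [1.0]
        assert res.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-10)

    def test_auc_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        x_in = rng.normal(0.5, 1.0, 30)
        x_out = rng.normal(0.0, 1.0, 30)
        res = roc_youden(x_in, x_out)
        ref = sk.roc_auc_score(np.r_[np.ones(30), np.zeros(30)],
                               np.r_[x_in, x_out])
        assert res.auc == pytest.approx(ref, abs=1e-12)

    def test_constant_equal_groups(self):
        res = roc_youden(np.full(3, 2.0), np.full(4, 2.0))
        assert res.auc == 0.5 and res.youden_j == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_youden(np.array([]), np.array([1.0]))


class TestPairedMeans:
    def test_uniform_intensity_fold_one(self, noise_free_record):
        section = noise_free_record.section
        uniform = pm.msi_data.SectionImage("P01", "S01", section.coords,
                                           np.full_like(section.intensities, 3.0),
                                           section.grid_shape)
        study = pm.msi_data.Study([uniform], pm.msi_data.MzAxis(
            np.linspace(400, 500, section.intensities.shape[1])))
        pairs = paired_means(study, {("P01", "S01"): noise_free_record.truth_mask},
                             "NC", 0)
        assert np.allclose(pairs.fold_change, 1.0)

    def test_noise_free_phantom_fold_exact(self, noise_free_record, panel):
        section = noise_free_record.section
        study = pm.msi_data.Study([section], pm.msi_data.MzAxis(
            panel.axis_table().mz.to_numpy()))
        j = int(np.nonzero(np.isclose(panel.axis_table().mz,
                                      panel.species_of_class("SM")[0]))[0][0])
        pairs = paired_means(study, {("P01", "S01"): noise_free_record.truth_mask},
                             "NC", j)
        assert pairs.fold_change[0] == pytest.approx(3.0, abs=1e-9)

    def test_absent_label_gives_empty_result(self, noise_free_record, panel):
        section = noise_free_record.section
        study = pm.msi_data.Study([section], pm.msi_data.MzAxis(
            panel.axis_table().mz.to_numpy()))
        labels = noise_free_record.truth_mask.labels.copy()
        labels[labels == LABEL_CODES["calcium"]] = LABEL_CODES["other_tissue"]
        mask = pm.registration.SegmentationMask(labels)
        pairs = paired_means(study, {("P01", "S01"): mask}, "calcium", 0)
        assert len(pairs) == 0

    def test_log_scale_study_rejected(self, small_study):
        study, truth = small_study
        logged = pm.log_transform(study)
        with pytest.raises(ValueError):
            paired_means(logged, dict(truth.truth_masks), "NC", 0)


def test_confirm_vips_requires_nonempty_set(small_study):
    study, truth = small_study
    with pytest.raises(ValueError):
        confirm_vips(study, dict(truth.truth_masks), "NC", np.array([]))
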