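"""Density-threshold classifier: ROC/AUC, optimal threshold, Monte-Carlo
islet subsampling, and the Model/Results surface."""

import math

import numpy as np
import pytest

from isletquant import (
    DonorRecord,
    Group,
    RuleConfig,
    ThresholdRuleModel,
    classify_donor,
    optimal_threshold,
    roc_auc,
    sens_spec_table,
    subsample_density,
    threshold_distribution,
)

from conftest import make_islet


def _donor(donor_id, group, counts, area=0.02):
    islets = [make_islet(donor=donor_id, islet=f"{donor_id}-{j}", area=area, cd3=c)
              for j, c in enumerate(counts)]
    return DonorRecord(donor_id=donor_id, group=group, islets=islets)


def _separable_cohort():
    """ND donors with zero counts, T1D donors far above any threshold."""
    nd = [_donor(f"nd{j}", Group.ND, [0] * 40) for j in range(4)]
    t1d = [_donor(f"t{j}", Group.T1D, [8] * 40) for j in range(4)]
    return nd + t1d


class TestRocAuc:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc([1, 2], [3, 4], ci_boot=0)
        assert auc == 1.0

    def test_identical_lists_give_half(self):
        auc, *_ = roc_auc([1, 2, 3], [1, 2, 3], ci_boot=0)
        assert auc == pytest.approx(0.5)

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            neg = rng.normal(0, 1, int(rng.integers(2, 26)))
            pos = rng.normal(0.5, 1, int(rng.integers(2, 26)))
            # make ties possible
            pos[0] = neg[0]
            auc, *_ = roc_auc(neg, pos, ci_boot=0)
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == wins / (len(pos) * len(neg))

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(23)
        neg = rng.normal(0, 1, 15)
        pos = rng.normal(1, 1, 10)
        auc, *_ = roc_auc(neg, pos, ci_boot=0)
        y = np.r_[np.zeros(15), np.ones(10)]
        assert auc == pytest.approx(roc_auc_score(y, np.r_[neg, pos]), abs=1e-12)

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(31)
        auc, lo, hi = roc_auc(rng.normal(0, 1, 15), rng.normal(1.5, 1, 10),
                              ci_boot=500, seed=0)
        assert lo <= auc <= hi

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestOptimalThreshold:
    def test_separable_midpoint(self):
        thr, j = optimal_threshold([10, 20, 40, 50], [False, False, True, True])
        assert thr == pytest.approx(30.0)
        assert j == pytest.approx(1.0)

    def test_all_equal_scores_degenerate(self):
        thr, j = optimal_threshold([5, 5, 5, 5], [False, False, True, True])
        assert math.isnan(thr)
        assert j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold([1, 2], [True, True])

    def test_matches_brute_force_scan_on_random_donor_sets(self):
        """Random 12-donor score sets: the reported cut equals an
        exhaustive scan over all candidate cut-points."""
        rng = np.random.default_rng(41)
        for _ in range(200):
            scores = np.round(rng.normal(30, 12, 12), 1)
            labels = np.r_[np.zeros(6, bool), np.ones(6, bool)]
            thr, j = optimal_threshold(scores, labels)
            # oracle: scan midpoints and sentinels directly
            u = np.unique(scores)
            cands = np.r_[u[0] - 1, (u[:-1] + u[1:]) / 2, u[-1] + 1]
            pos, neg = scores[labels], scores[~labels]
            js = np.array([(pos >= t).mean() + (neg < t).mean() - 1 for t in cands])
            if js.max() <= 0:
                assert math.isnan(thr)
            else:
                best = cands[js >= js.max() - 1e-12].min()
                assert thr == pytest.approx(best)
                assert j == pytest.approx(js.max())


class TestSubsampling:
    def test_full_sample_equals_pooled_density(self):
        d = _donor("x", Group.T1D, [1, 2, 3, 4], area=0.01)
        rng = np.random.default_rng(0)
        assert subsample_density(d, 10, rng, min_cells=0) == pytest.approx(
            10 / 0.04
        )

    def test_zero_count_donor_always_zero(self):
        d = _donor("x", Group.ND, [0] * 20)
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert subsample_density(d, 5, rng, min_cells=0) == 0.0

    def test_sampling_mean_consistent_with_full_density(self):
        """Equal-area islets: the subsample pooled density is unbiased."""
        rng = np.random.default_rng(7)
        counts = list(rng.poisson(3, 60))
        d = _donor("x", Group.T1D, counts, area=0.02)
        full = sum(counts) / (0.02 * 60)
        draws = [subsample_density(d, 15, rng, min_cells=0) for _ in range(4000)]
        se = np.std(draws) / math.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(full, abs=4 * se + 1e-9)

    def test_no_islets_undefined(self):
        d = DonorRecord(donor_id="x", group=Group.ND, islets=[])
        assert math.isnan(subsample_density(d, 5, np.random.default_rng(0)))


class TestThresholdDistribution:
    def test_degenerate_cohort_collapses_to_single_band(self):
        dist = threshold_distribution(_separable_cohort(), n_grid=(5,),
                                      iterations=50, seed=1, min_cells=0)
        assert dist["threshold"].nunique() == 1
        # all-zero vs all-8 at 0.02 mm2: midpoint of 0 and 400
        assert dist["threshold"].iloc[0] == pytest.approx(200.0)

    def test_width_shrinks_with_more_islets(self, study_cohort):
        dist = threshold_distribution(study_cohort, n_grid=(10, 200),
                                      iterations=300, seed=3)
        sd10 = dist[dist.n_islets == 10]["threshold"].std()
        sd200 = dist[dist.n_islets == 200]["threshold"].std()
        assert sd200 < sd10

    def test_fixed_seed_reproducible(self):
        cohort = _separable_cohort()
        d1 = threshold_distribution(cohort, n_grid=(5, 10), iterations=40,
                                    seed=9, min_cells=0)
        d2 = threshold_distribution(cohort, n_grid=(5, 10), iterations=40,
                                    seed=9, min_cells=0)
        assert d1.equals(d2)

    def test_grid_order_does_not_change_substreams(self):
        cohort = _separable_cohort()
        a = threshold_distribution(cohort, n_grid=(5, 10), iterations=30,
                                   seed=2, min_cells=0)
        b = threshold_distribution(cohort, n_grid=(10, 5), iterations=30,
                                   seed=2, min_cells=0)
        a5 = a[a.n_islets == 5].reset_index(drop=True)
        b5 = b[b.n_islets == 5].reset_index(drop=True)
        assert a5.equals(b5)


class TestSensSpecTable:
    def test_separable_cohort_perfect_with_zero_sd(self):
        table = sens_spec_table(_separable_cohort(), threshold=30.0,
                                n_grid=(5, 10), iterations=100, seed=0, min_cells=0)
        assert (table["sensitivity_mean"] == 1.0).all()
        assert (table["specificity_mean"] == 1.0).all()
        assert (table["sensitivity_sd"] == 0.0).all()
        assert (table["specificity_sd"] == 0.0).all()

    def test_threshold_above_every_score(self):
        table = sens_spec_table(_separable_cohort(), threshold=1e9,
                                n_grid=(5,), iterations=50, seed=0, min_cells=0)
        assert table.loc[0, "sensitivity_mean"] == 0.0
        assert table.loc[0, "specificity_mean"] == 1.0

    def test_raising_threshold_never_helps_sensitivity(self, study_cohort):
        t_lo = sens_spec_table(study_cohort, threshold=20.0, n_grid=(30,),
                               iterations=300, seed=5)
        t_hi = sens_spec_table(study_cohort, threshold=60.0, n_grid=(30,),
                               iterations=300, seed=5)
        assert t_hi.loc[0, "sensitivity_mean"] <= t_lo.loc[0, "sensitivity_mean"]
        assert t_hi.loc[0, "specificity_mean"] >= t_lo.loc[0, "specificity_mean"]

    def test_degenerates_to_full_data_confusion_matrix(self, study_cohort):
        """n >= every donor's islet count and one iteration reproduce the
        deterministic full-data confusion matrix."""
        from isletquant import filter_islets, pooled_density

        n_max = max(len(filter_islets(d.islets, 30)[0]) for d in study_cohort)
        table = sens_spec_table(study_cohort, threshold=30.0, n_grid=(n_max,),
                                iterations=1, seed=0)
        sens = spec = 0
        n_pos = n_neg = 0
        for d in study_cohort:
            if d.group not in (Group.ND, Group.T1D):
                continue
            kept, _ = filter_islets(d.islets, 30)
            dens = pooled_density(kept)
            if d.group is Group.T1D:
                n_pos += 1
                sens += dens >= 30.0
            else:
                n_neg += 1
                spec += dens < 30.0
        assert table.loc[0, "sensitivity_mean"] == pytest.approx(sens / n_pos)
        assert table.loc[0, "specificity_mean"] == pytest.approx(spec / n_neg)
        assert table.loc[0, "sensitivity_sd"] == 0.0


class TestClassifyDonor:
    def test_zero_everywhere_never_t1d_like(self):
        d = _donor("x", Group.ND, [0] * 50)
        frac = classify_donor(d, RuleConfig(iterations=200), min_cells=0)
        assert frac == 0.0

    def test_uniformly_dense_donor_always_t1d_like(self):
        d = _donor("x", Group.T1D, [8] * 50)     # 400 cells/mm2 everywhere
        frac = classify_donor(d, RuleConfig(iterations=200), min_cells=0)
        assert frac == 1.0

    def test_borderline_donor_fraction_strictly_between(self):
        # half the islets at 60 cells/mm2, half empty: a 30-islet subsample
        # with k dense islets has density 2k, crossing 30 at k = 15
        d = _donor("x", Group.AAB2, [3] * 30 + [0] * 30, area=0.05)
        cfg = RuleConfig(iterations=500, seed=4)
        frac = classify_donor(d, cfg, min_cells=0)
        assert 0.0 < frac < 1.0
        assert frac == classify_donor(d, cfg, min_cells=0)  # reproducible

    def test_no_islets_undefined(self):
        d = DonorRecord(donor_id="x", group=Group.AAB2, islets=[])
        assert math.isnan(classify_donor(d, RuleConfig(iterations=10)))


class TestModelResults:
    def test_fit_carries_auc_threshold_and_summary(self, study_cohort):
        model = ThresholdRuleModel(study_cohort)
        res = model.fit(ci_boot=200, seed=0)
        assert 0.9 <= res.auc <= 1.0
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
        assert res.optimal_threshold > 0
        text = res.summary()
        assert "AUC" in text and "threshold" in text.lower()

    def test_both_classes_required(self):
        nd_only = [_donor("a", Group.ND, [0] * 10)]
        with pytest.raises(ValueError):
            ThresholdRuleModel(nd_only)

    def test_classify_returns_fraction_per_donor(self, study_cohort):
        model = ThresholdRuleModel(study_cohort)
        res = model.fit(ci_boot=0)
        aab = [d for d in study_cohort if d.group is Group.AAB2]
        out = res.classify(aab, RuleConfig(iterations=200, seed=1))
        assert len(out) == len(aab)
        assert out["fraction_t1d_like"].between(0, 1).all()

    def test_plot_smoke(self, study_cohort):
        import matplotlib

        matplotlib.use("Agg")
        model = ThresholdRuleModel(study_cohort)
        res = model.fit(ci_boot=0)
        ax = res.plot_roc()
        assert ax.get_xlabel() == "1 - specificity"
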