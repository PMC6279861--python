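import numpy as np
import pandas as pd
import pytest

from nawm_radiomics.errors import InvalidArgumentError
from nawm_radiomics.evaluation import (
    hosmer_lemeshow,
    icc,
    icc_per_feature,
    roc_auc,
)

from .oracles import auc_pair_count


class TestRocAuc:
    def test_perfect_separation(self):
        probs = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        labels = np.repeat([0, 1], 10)
        r = roc_auc(probs, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        probs = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_auc(probs, labels).auc - 0.5) < 0.03

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.random(10), 1)  # induce ties
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(auc_pair_count(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_negation_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)

    def test_delong_and_bootstrap_cis_agree(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.repeat([0, 1], 50)
        d = roc_auc(scores, labels, ci_method="delong")
        b = roc_auc(scores, labels, ci_method="bootstrap", n_boot=2000, seed=7)
        assert abs(d.auc_ci[0] - b.auc_ci[0]) < 0.03
        assert abs(d.auc_ci[1] - b.auc_ci[1]) < 0.03
        assert d.auc_ci[0] <= d.auc <= d.auc_ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_auc([0.1, 0.9], [1, 1])


class TestHosmerLemeshow:
    def test_flat_half_probabilities_balanced_outcome(self):
        probs = np.full(40, 0.5)
        labels = np.tile([0, 1], 20)
        r = hosmer_lemeshow(probs, labels)
        assert r.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_worked_four_group_fixture(self):
        """20 samples, four distinct probability levels; observed/expected
        arithmetic done by hand in the test."""
        probs = np.array([0.1] * 5 + [0.3] * 5 + [0.6] * 5 + [0.8] * 5)
        labels = np.array(
            [0, 0, 0, 0, 1] + [0, 0, 0, 1, 1] + [0, 0, 1, 1, 1] + [0, 1, 1, 1, 1]
        )
        r = hosmer_lemeshow(probs, labels, groups=4)
        expected = sum(
            (o - e) ** 2 / (e * (1 - e / 5))
            for o, e in [(1, 0.5), (2, 1.5), (3, 3.0), (4, 4.0)]
        )
        assert r.statistic == pytest.approx(expected, abs=1e-9)
        assert r.df == 2

    def test_well_calibrated_probabilities_not_rejected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(50):
            probs = rng.uniform(0.05, 0.95, 400)
            labels = (rng.random(400) < probs).astype(int)
            if hosmer_lemeshow(probs, labels).p_value < 0.05:
                rejections += 1
        assert rejections < 10  # ~5% expected

    def test_expected_counts_sum_to_total(self):
        rng = np.random.default_rng(6)
        probs = rng.uniform(0.1, 0.9, 100)
        labels = (rng.random(100) < probs).astype(int)
        r = hosmer_lemeshow(probs, labels)
        assert r.table["n"].sum() == 100
        assert r.table["observed"].sum() == labels.sum()
        assert r.df == len(r.table) - 2


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.random.default_rng(0).normal(size=20)
        r = icc(np.column_stack([x, x]))
        assert r.icc == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(1)
        r = icc(rng.normal(size=(500, 2)))
        assert abs(r.icc) < 0.15

    def test_textbook_fixture_matches_anova_mean_squares(self):
        """6x2 fixture: ICC(2,1) recomputed from the ANOVA decomposition
        by hand."""
        x = np.array(
            [[9.0, 2.0], [6.0, 1.0], [8.0, 4.0], [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]]
        )
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)) / (
            (n - 1) * (k - 1)
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(x).icc == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        subj = rng.normal(0, 2, 30)
        x = np.column_stack([subj + rng.normal(0, 1, 30), subj + rng.normal(0, 1, 30) + 0.5])
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(30), 2),
                "rater": np.tile([0, 1], 30),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        r = icc(x)
        assert r.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        # pingouin prints the CI rounded to 2 decimals
        assert r.ci[0] == pytest.approx(row["CI95"][0], abs=0.011)
        assert r.ci[1] == pytest.approx(row["CI95"][1], abs=0.011)

    def test_zero_between_subject_variance_degenerate(self):
        x = np.ones((10, 2))
        r = icc(x)
        assert r.icc == 0.0 and r.degenerate

    def test_per_feature_range_summary(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(size=(25, 3))
        a = pd.DataFrame(subj, columns=["f1", "f2", "f3"])
        b = a + rng.normal(0, 0.2, size=a.shape)
        series = icc_per_feature(a, b)
        assert set(series.index) == {"f1", "f2", "f3"}
        assert (series > 0.5).all()
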