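"""Agreement statistics vs independent oracles: RMSE/SD, ICC(2,1),
Bland-Altman limits, ROC/AUC/Youden."""

import numpy as np
import pytest

from nervequant.stats import (MeasureSeries, bland_altman, error_summary,
                              icc_absolute, roc_analysis)


class TestErrorSummary:
    def test_identical_series(self):
        v = np.arange(5.0)
        es = error_summary(v, v)
        assert es.rmse == 0 and es.sd == 0 and es.v_bar == 0

    def test_constant_offset(self):
        v = np.arange(5.0)
        es = error_summary(v + 3.0, v)
        assert es.rmse == pytest.approx(3.0) and es.sd == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # V = (1, -1, 2): RMSE = sqrt(6/3) = sqrt(2); SD = sqrt(sum((V-2/3)^2)/2)
        es = error_summary(np.array([1.0, -1.0, 2.0]), np.zeros(3))
        assert es.rmse == pytest.approx(np.sqrt(2))
        v = np.array([1.0, -1.0, 2.0])
        sd_brute = np.sqrt(((v - v.mean()) ** 2).sum() / 2)
        assert es.sd == pytest.approx(sd_brute)
        assert es.sd == pytest.approx(1.5275252316519465)

    def test_rmse_sd_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            a, b = rng.normal(size=n), rng.normal(size=n)
            es = error_summary(a, b)
            assert es.rmse ** 2 == pytest.approx(
                es.v_bar ** 2 + (n - 1) / n * es.sd ** 2, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            error_summary(np.arange(3.0), np.arange(4.0))

    def test_measure_series_container(self):
        s = MeasureSeries(np.arange(4.0), np.arange(4.0) + 1, "total_length_um")
        assert error_summary(s).rmse == pytest.approx(1.0)


def _icc_oracle(y):
    """Two-way ANOVA mean-squares ICC(2,1), written out independently."""
    n, k = y.shape
    grand = y.mean()
    msr = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((y - grand) ** 2).sum() \
        - k * ((y.mean(axis=1) - grand) ** 2).sum() \
        - n * ((y.mean(axis=0) - grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_series_is_excellent(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        icc, band = icc_absolute(v, v)
        assert icc == pytest.approx(1.0)
        assert band == "excellent"

    def test_offset_penalised_by_absolute_agreement(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        icc, _ = icc_absolute(v + 10.0, v)
        assert icc < 0.5  # offset >> subject SD: far from 1 despite r = 1

    def test_matches_pingouin_mixed_model(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a = rng.normal(10, 3, 12)
        b = a + rng.normal(0.5, 1.0, 12)
        icc, _ = icc_absolute(a, b)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["m", "ma"], 12),
            "score": np.column_stack([a, b]).ravel(),
        })
        table = pg.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score")
        # absolute-agreement single-rater row: "ICC2" / "ICC(A,1)" by version
        row = table["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(table.loc[row, "ICC"].iloc[0])
        assert icc == pytest.approx(icc2, abs=1e-10)

    def test_matches_anova_oracle_on_toy_table(self):
        a = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        b = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        icc, _ = icc_absolute(a, b)
        assert icc == pytest.approx(_icc_oracle(np.column_stack([a, b])),
                                    abs=1e-12)

    def test_rater_exchange_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert icc_absolute(a, b)[0] == pytest.approx(icc_absolute(b, a)[0],
                                                      abs=1e-12)

    def test_zero_variance_undefined(self):
        v = np.full(5, 2.0)
        icc, band = icc_absolute(v, v)
        assert np.isnan(icc) and band == "undefined"

    @pytest.mark.parametrize("icc,band", [
        (0.2, "poor"), (0.6, "moderate"), (0.8, "good"), (0.95, "excellent")])
    def test_band_cutoffs(self, icc, band):
        from nervequant.stats import _icc_band

        assert _icc_band(icc) == band


class TestBlandAltman:
    def test_identical_series(self):
        v = np.array([1.0, 2.0, 3.0])
        rep = bland_altman(v, v)
        assert rep.ba_mean_diff == 0
        assert rep.ba_loa_low == rep.ba_loa_high == 0

    def test_hand_computed_limits(self):
        # D = (-2, 0, 2): mean 0, SD 2, LoA = +/- 3.92
        rep = bland_altman(np.array([-2.0, 0.0, 2.0]), np.zeros(3))
        assert rep.ba_mean_diff == pytest.approx(0.0)
        assert rep.ba_loa_high == pytest.approx(3.92)
        assert rep.ba_loa_low == pytest.approx(-3.92)
        assert rep.ci_mean[0] < 0 < rep.ci_mean[1]

    def test_loa_coverage_on_gaussian_differences(self):
        rng = np.random.default_rng(0)
        d = rng.normal(1.0, 2.0, 5000)
        rep = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= rep.ba_loa_low) & (d <= rep.ba_loa_high))
        assert 0.93 <= inside <= 0.97

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="at least 3"):
            bland_altman(np.array([1.0, 2.0]), np.zeros(2))


def _auc_concordance(scores, y):
    """O(n^2) Mann-Whitney concordance with ties counted one half."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        roc = roc_analysis(scores, labels)
        assert roc.auc == 1.0 and roc.youden_j == 1.0
        assert roc.sens_at_cut == 1.0 and roc.spec_at_cut == 1.0

    def test_constant_scores_uninformative(self):
        roc = roc_analysis(np.ones(10), np.array([0, 1] * 5))
        assert roc.auc == pytest.approx(0.5)
        assert roc.youden_j == pytest.approx(0.0)

    def test_auc_equals_concordance_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=20).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]  # both classes guaranteed
        roc = roc_analysis(scores, labels)
        expect = _auc_concordance(scores, labels)
        if expect < 0.5:
            expect = 1 - expect  # analysis auto-orients
        assert roc.auc == pytest.approx(expect, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        labels = (scores + rng.normal(0, 1, 30) > 0).astype(int)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        a1 = roc_analysis(scores, labels).auc
        a2 = roc_analysis(np.exp(scores), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_low_scores_indicate_disease_auto_orientation(self):
        # nerve length is LOWER in neuropathy: flipped orientation recorded
        rng = np.random.default_rng(9)
        healthy = rng.normal(2400, 300, 25)
        neuro = rng.normal(1500, 300, 25)
        scores = np.concatenate([healthy, neuro])
        labels = np.array([0] * 25 + [1] * 25)
        roc = roc_analysis(scores, labels)
        assert roc.auc > 0.9
        assert roc.orientation == -1
        # decision rule: score <= cut -> positive; check it reproduces sens
        called_pos = scores <= roc.optimal_cut
        sens = called_pos[labels == 1].mean()
        assert sens == pytest.approx(roc.sens_at_cut)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis(np.arange(4.0), np.zeros(4, dtype=int))

    def test_string_labels_with_positive_label(self):
        roc = roc_analysis(np.array([1.0, 2.0, 3.0, 4.0]),
                           np.array(["h", "h", "n", "n"]),
                           positive_label="n")
        assert roc.auc == 1.0
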