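"""Aggregation, %DAPT normalization, Z'-factor, plate QC and group statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from myeliscreen import (
    QCError,
    UndefinedScoreError,
    aggregate_condition,
    compare_conditions,
    gaussian_tail_pct,
    percent_of_control,
    plate_qc,
    zprime,
)
from myeliscreen.fiber_morphometrics import FieldScores
from myeliscreen.imaging_io import PlateLayout, WellInfo


def _fs(fiber=10.0, mbp=10.0, n_dapi=100, n_olig2=20, usable=True):
    fm = fiber / mbp if usable else None
    return FieldScores(n_dapi, n_olig2 if usable else 0,
                       mbp if usable else None, fiber if usable else None, fm, usable)


class TestAggregateCondition:
    def test_identical_fields(self):
        s = aggregate_condition([_fs(fiber=10.0)] * 8, "C1", 5.0)
        assert s.fiber_score_mean == 10.0 and s.fiber_score_sem == 0.0
        assert s.n_fields_used == 8

    def test_two_field_sem(self):
        s = aggregate_condition([_fs(fiber=8.0), _fs(fiber=12.0)], "C1", 5.0)
        assert s.fiber_score_mean == 10.0
        assert s.fiber_score_sem == pytest.approx(2.0)

    def test_unusable_fields_excluded(self):
        fields = [_fs(fiber=10.0)] * 5 + [_fs(usable=False)] * 3
        s = aggregate_condition(fields, "C1", 5.0)
        assert s.n_fields_used == 5 and s.fiber_score_mean == 10.0

    def test_all_unusable_flagged(self):
        s = aggregate_condition([_fs(usable=False)] * 4, "C1", 5.0)
        assert s.n_fields_used == 0 and s.fiber_score_mean is None


class TestPercentOfControl:
    @pytest.mark.parametrize("x,expected", [(2.0, 0.0), (6.0, 100.0), (4.0, 50.0)])
    def test_anchors(self, x, expected):
        assert percent_of_control(x, 2.0, 6.0) == pytest.approx(expected)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(UndefinedScoreError):
            percent_of_control(1.0, 3.0, 3.0)

    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-1000.0, 1000.0),
        x=st.floats(-100.0, 100.0),
    )
    def test_invariant_under_positive_affine_transforms(self, a, b, x):
        neg, pos = 3.0, 9.0
        raw = percent_of_control(x, neg, pos)
        mapped = percent_of_control(a * x + b, a * neg + b, a * pos + b)
        assert mapped == pytest.approx(raw, rel=1e-6, abs=1e-6)


class TestZPrime:
    def test_textbook_construction(self):
        """Means 100/0, SDs 10/10 give exactly Z' = 0.4."""
        pos = [90.0, 100.0, 110.0]  # mean 100, sample SD 10
        neg = [-10.0, 0.0, 10.0]  # mean 0, sample SD 10
        assert zprime(pos, neg) == pytest.approx(0.4)

    def test_zero_variance_distinct_means(self):
        assert zprime([5.0, 5.0], [1.0, 1.0]) == 1.0

    def test_equal_means_undefined(self):
        assert zprime([1.0, 3.0], [3.0, 1.0]) == float("-inf")

    def test_monotone_in_group_sd(self):
        base = zprime([95.0, 105.0], [-5.0, 5.0])
        wider = zprime([85.0, 115.0], [-5.0, 5.0])
        assert wider < base


class TestGaussianTail:
    def test_three_sd_tail_value(self):
        assert gaussian_tail_pct(3.0) == pytest.approx(0.13499, abs=1e-4)


def _control_layout():
    wells = {}
    for r in "ABCD":
        wells[f"{r}12"] = WellInfo("positive_control", "DAPT", 1.0)
    for r in "EFGH":
        wells[f"{r}12"] = WellInfo("negative_control", "DMSO", 0.0)
    return PlateLayout("P1", wells)


def _control_scores(dapt_fiber, dmso_fiber, dapt_fm, dmso_fm, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    scores = {}
    for i, r in enumerate("ABCD"):
        scores[f"{r}12"] = [
            _fs(fiber=dapt_fiber * (1 + jitter * rng.standard_normal()),
                mbp=dapt_fiber / dapt_fm) for _ in range(4)
        ]
    for i, r in enumerate("EFGH"):
        scores[f"{r}12"] = [
            _fs(fiber=dmso_fiber * (1 + jitter * rng.standard_normal()),
                mbp=dmso_fiber / dmso_fm) for _ in range(4)
        ]
    return scores


class TestPlateQC:
    def test_healthy_plate_passes_with_ratio(self):
        scores = _control_scores(2000.0, 1000.0, dapt_fm=1.61, dmso_fm=1.0, jitter=0.05, seed=1)
        report = plate_qc(scores, _control_layout())
        assert report.passed
        assert report.dapt_dmso_fiber_mbp == pytest.approx(1.61, rel=0.02)
        assert report.zprime > 0

    def test_narrow_window_fails_with_reason(self):
        scores = _control_scores(2000.0, 1000.0, dapt_fm=1.05, dmso_fm=1.0, jitter=0.02, seed=2)
        report = plate_qc(scores, _control_layout())
        assert not report.passed
        assert any("below acceptance floor" in r for r in report.reasons)

    def test_three_sd_threshold_formula(self):
        scores = _control_scores(2000.0, 1000.0, 1.6, 1.0, jitter=0.1, seed=3)
        report = plate_qc(scores, _control_layout())
        assert report.three_sd_threshold == pytest.approx(
            report.dmso_mean + 3 * report.dmso_sd
        )

    def test_missing_controls_raise(self):
        with pytest.raises(QCError):
            plate_qc({"A12": [_fs()]}, _control_layout())


class TestCompareConditions:
    def test_identical_groups_no_effect(self):
        g = {"DMSO": [1.0, 2.0, 3.0], "A": [1.0, 2.0, 3.0]}
        res = compare_conditions(g, method="ttest")
        anova = res[res["comparison"] == "ANOVA"].iloc[0]
        assert anova["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert anova["p"] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["anova_dunnett", "anova_bonferroni", "ttest"])
    def test_large_separation_detected(self, method):
        rng = np.random.default_rng(12)
        g = {"DMSO": rng.normal(0, 1, 20), "drug": rng.normal(5, 1, 20)}
        res = compare_conditions(g, method=method)
        post = res[res["comparison"] != "ANOVA"]
        assert (post["p"] < 1e-3).all()

    def test_bonferroni_is_scaled_ttest(self):
        rng = np.random.default_rng(3)
        g = {
            "DMSO": rng.normal(0, 1, 10),
            "A": rng.normal(0.5, 1, 10),
            "B": rng.normal(1.0, 1, 10),
        }
        raw = compare_conditions(g, method="ttest")
        adj = compare_conditions(g, method="anova_bonferroni")
        for label in ("A vs DMSO", "B vs DMSO"):
            p_raw = raw.loc[raw["comparison"] == label, "p"].iloc[0]
            p_adj = adj.loc[adj["comparison"] == label, "p"].iloc[0]
            assert p_adj == pytest.approx(min(1.0, p_raw * 2))

    def test_dunnett_matches_independent_oracle(self):
        # expected values computed once with R multcomp::glht (Dunnett contrasts)
        # on this exact data; ANOVA F/p from the same aov fit
        g = {
            "DMSO": [1.2, 2.3, 1.8, 2.9, 2.1],
            "A": [3.1, 4.0, 3.3, 2.8, 3.9],
            "B": [1.9, 2.4, 2.2, 3.0, 2.7],
        }
        res = compare_conditions(g, method="anova_dunnett")
        anova = res[res["comparison"] == "ANOVA"].iloc[0]
        assert anova["statistic"] == pytest.approx(8.7616, rel=1e-3)
        assert anova["p"] == pytest.approx(0.004509, rel=1e-2)
        p = {r["comparison"]: r["p"] for _, r in res.iterrows()}
        # both sides estimate the multivariate-t integral by Monte Carlo,
        # so small p-values agree only to a few percent
        assert p["A vs DMSO"] == pytest.approx(0.002989, rel=0.05)
        assert p["B vs DMSO"] == pytest.approx(0.442513, rel=0.02)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions({"DMSO": [1.0], "A": [1.0, 2.0]})


class TestNullScreenFalsePositives:
    def test_null_conditions_rarely_exceed_three_sd_line(self, null_screen_pct):
        """On a hit-free screen the 3-SD line passes ~0.13% of conditions."""
        pct = null_screen_pct
        half = len(pct) // 2
        thr = pct[:half].mean() + 3.0 * pct[:half].std(ddof=1)
        frac = (pct[half:] > thr).mean()
        assert frac <= 0.005
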