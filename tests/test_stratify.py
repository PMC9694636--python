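import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgspipe import (
    ContingencyTable,
    ScoreVector,
    assign_bmi_band,
    assign_septiles,
    bmi_pgs_grid,
    odds_ratio_wald,
    or_from_wald_ci,
    percentile_ranks,
    top_vs_bottom_or,
)

from conftest import make_cohort


def score_vector(scores):
    scores = np.asarray(scores, dtype=float)
    return ScoreVector(
        sample_ids=np.array([f"S{i}" for i in range(len(scores))], dtype=object),
        scores=scores,
        percentile_rank=percentile_ranks(scores),
    )


class TestOddsRatioWald:
    def test_balanced_table_or_one(self):
        est = odds_ratio_wald(ContingencyTable(10, 10, 10, 10))
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(1.0 / est.ci_high)

    def test_closed_form_example(self):
        # OR = 4, SE_log = sqrt(0.3)
        est = odds_ratio_wald(ContingencyTable(20, 10, 10, 20), alpha=0.05)
        assert est.odds_ratio == pytest.approx(4.0)
        se = np.sqrt(1 / 20 + 1 / 10 + 1 / 10 + 1 / 20)
        z = 1.959963984540054
        assert est.ci_low == pytest.approx(4.0 * np.exp(-z * se), rel=1e-9)
        assert est.ci_high == pytest.approx(4.0 * np.exp(z * se), rel=1e-9)
        assert est.ci_low == pytest.approx(1.367, abs=5e-4)
        assert est.ci_high == pytest.approx(11.70, abs=5e-3)

    def test_zero_cell_correction_flagged(self):
        est = odds_ratio_wald(ContingencyTable(5, 0, 3, 10))
        assert est.zero_cell_corrected
        assert est.odds_ratio == pytest.approx((5.5 * 10.5) / (0.5 * 3.5))

    def test_inestimable_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 5, 5)

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_log_symmetry_invariant(self, a, b, c, d):
        est = odds_ratio_wald(ContingencyTable(a, b, c, d))
        assert np.sqrt(est.ci_low * est.ci_high) == pytest.approx(est.odds_ratio, rel=1e-9)
        assert or_from_wald_ci(est.ci_low, est.ci_high) == pytest.approx(
            est.odds_ratio, rel=1e-9
        )

    @given(
        a=st.integers(1, 100), b=st.integers(1, 100),
        c=st.integers(1, 100), d=st.integers(1, 100),
        k=st.integers(2, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_scaling_cells_fixes_or_and_narrows_ci(self, a, b, c, d, k):
        base = odds_ratio_wald(ContingencyTable(a, b, c, d))
        scaled = odds_ratio_wald(ContingencyTable(k * a, k * b, k * c, k * d))
        assert scaled.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-12)
        assert scaled.ci_high / scaled.ci_low < base.ci_high / base.ci_low

    @given(
        a=st.integers(1, 100), b=st.integers(1, 100),
        c=st.integers(1, 100), d=st.integers(1, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_reciprocal_property(self, a, b, c, d):
        fwd = odds_ratio_wald(ContingencyTable(a, b, c, d))
        rev = odds_ratio_wald(ContingencyTable(c, d, a, b))
        assert fwd.odds_ratio * rev.odds_ratio == pytest.approx(1.0, rel=1e-12)


class TestTopVsBottom:
    def test_direct_two_by_two_evaluation(self):
        # 100 distinct scores; top 25: 10 cases/15 controls; bottom 50: 5 cases/45 controls
        scores = score_vector(np.arange(100, dtype=float))
        labels = np.array(["control"] * 100, dtype=object)
        labels[75:85] = "case"  # 10 cases in the top 25
        case_bottom = [0, 10, 20, 30, 40]
        labels[case_bottom] = "case"
        res = top_vs_bottom_or(scores, labels, top_fraction=0.25)
        assert res.estimate.odds_ratio == pytest.approx(6.0)
        assert res.estimate.cells.a == 10 and res.estimate.cells.d == 45

    def test_null_scores_or_near_one(self):
        rng = np.random.default_rng(40)
        ors = []
        for _ in range(20):
            scores = score_vector(rng.normal(size=10_000))
            labels = np.where(rng.random(10_000) < 0.2, "case", "control")
            res = top_vs_bottom_or(scores, labels, top_fraction=0.25)
            ors.append(res.estimate.odds_ratio)
        assert all(0.6 < o < 1.6 for o in ors)

    def test_half_vs_half_null_symmetry(self):
        rng = np.random.default_rng(41)
        scores = score_vector(rng.normal(size=50_000))
        labels = np.where(rng.random(50_000) < 0.3, "case", "control")
        res = top_vs_bottom_or(scores, labels, top_fraction=0.5, bottom_fraction=0.5)
        assert res.estimate.odds_ratio == pytest.approx(1.0, abs=0.1)

    def test_overlapping_fractions_rejected(self):
        scores = score_vector(np.arange(10, dtype=float))
        with pytest.raises(ValueError):
            top_vs_bottom_or(scores, np.array(["case"] * 10), 0.6, 0.5)

    def test_boolean_labels_accepted(self):
        scores = score_vector(np.arange(40, dtype=float))
        labels = np.array([False, True] * 20)
        res = top_vs_bottom_or(scores, labels, top_fraction=0.25)
        assert res.estimate.cells.a + res.estimate.cells.b == 10


class TestSeptiles:
    def test_fourteen_distinct_scores_two_per_septile(self):
        sept = assign_septiles(score_vector(np.arange(14, dtype=float)))
        assert all((sept == k).sum() == 2 for k in range(1, 8))

    def test_all_tied_scores_share_one_septile(self):
        sept = assign_septiles(score_vector(np.full(21, 3.0)))
        assert (sept == 4).all()  # mid-rank 0.5 -> middle septile

    def test_median_sample_in_septile_four(self):
        scores = score_vector(np.arange(1, 100, dtype=float))
        sept = assign_septiles(scores)
        median_idx = np.argmin(np.abs(scores.percentile_rank - 0.5))
        assert sept[median_idx] == 4

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            assign_septiles(score_vector(np.arange(6, dtype=float)))


class TestBmiBands:
    @pytest.mark.parametrize(
        "bmi,band",
        [(18.5, "low"), (24.0, "low"), (24.999, "low"), (25.0, "medium"),
         (27.5, "medium"), (29.999, "medium"), (30.0, "high"), (45.0, "high")],
    )
    def test_band_boundaries(self, bmi, band):
        assert assign_bmi_band(bmi)[0] == band

    def test_underweight_rejected(self):
        with pytest.raises(ValueError):
            assign_bmi_band(17.0)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            assign_bmi_band(np.nan)


class TestBmiPgsGrid:
    @staticmethod
    def _generative_cohort(seed, bmi_effect, score_effect, n=20_000):
        from scipy.special import expit

        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        bmi = np.clip(27.0 + 4.5 * rng.normal(size=n), 18.5, None)
        eta = -1.8 + score_effect * score + bmi_effect * (bmi - 27.0) / 4.5
        status = np.where(rng.random(n) < expit(eta), "case", "control")
        cohort = make_cohort(status, bmi=bmi)
        return cohort, score_vector(score)

    def test_reference_cell_or_one(self):
        cohort, scores = self._generative_cohort(1, 0.3, 0.3)
        grid = bmi_pgs_grid(cohort, scores)
        ref = [r for r in grid if r.stratum_label == "(BMI medium, septile 4)"]
        assert len(ref) == 1 and ref[0].estimate.odds_ratio == 1.0
        assert len(grid) == 21
        assert len({r.stratum_label for r in grid}) == 21

    def test_bmi_dominance_when_bmi_effect_larger(self):
        cohort, scores = self._generative_cohort(2, bmi_effect=0.7, score_effect=0.25)
        grid = {r.stratum_label: r.estimate.odds_ratio for r in bmi_pgs_grid(cohort, scores)}
        assert grid["(BMI high, septile 7)"] > grid["(BMI low, septile 7)"]
        # the high-BMI band dominates: even its lowest septile outranks
        # every low-BMI septile
        high_band = [grid[f"(BMI high, septile {k})"] for k in range(1, 8)]
        low_band = [grid[f"(BMI low, septile {k})"] for k in range(1, 8)]
        assert min(high_band) > max(low_band)

    def test_no_bmi_effect_bands_agree(self):
        cohort, scores = self._generative_cohort(3, bmi_effect=0.0, score_effect=0.4)
        grid = {r.stratum_label: r.estimate for r in bmi_pgs_grid(cohort, scores)}
        for k in range(1, 8):
            ors = [np.log(grid[f"(BMI {b}, septile {k})"].odds_ratio) for b in ("low", "medium", "high")]
            assert max(ors) - min(ors) < 0.75  # within Monte-Carlo error at cell size ~2000

    def test_empty_cell_fails_with_name(self):
        cohort = make_cohort(
            ["case", "control"] * 7, bmi=[24.0] * 14  # no medium/high BMI at all
        )
        scores = score_vector(np.arange(14, dtype=float))
        with pytest.raises(ValueError, match="medium|septile"):
            bmi_pgs_grid(cohort, scores)


class TestOrFromWaldCi:
    def test_geometric_mean(self):
        assert or_from_wald_ci(2.0, 8.0) == pytest.approx(4.0)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            or_from_wald_ci(3.0, 2.0)
        with pytest.raises(ValueError):
            or_from_wald_ci(-1.0, 2.0)
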