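import itertools

import numpy as np
import pytest
from scipy import stats as sps

from dosemass.errors import StatisticsError
from dosemass.stats import (
    PatientMetrics,
    build_summary,
    paired_delta,
    regression_zero_crossing,
    spearman_correlations,
    wilcoxon_signed_rank,
)


class TestPairedDelta:
    def test_table_style_values(self):
        delta, rel = paired_delta(18.9, 14.4)
        assert delta == pytest.approx(-4.5)
        assert rel == pytest.approx(-23.8095, abs=1e-3)

    def test_dmean_row(self):
        delta, _ = paired_delta(10.0, 8.1)
        assert delta == pytest.approx(-1.9)

    def test_identity(self):
        assert paired_delta(7.7, 7.7) == (0.0, 0.0)

    def test_zero_fb_flags_nan(self):
        delta, rel = paired_delta(0.0, 5.0)
        assert delta == 5.0
        assert np.isnan(rel)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.5, 50, 2)
            d1, r1 = paired_delta(a, b)
            d2, _ = paired_delta(b, a)
            assert d1 == pytest.approx(-d2)


def enumeration_oracle(diffs):
    """Exact two-sided Wilcoxon p by enumerating all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    total = ranks.sum()
    lo = min(w_obs, total - w_obs)
    hi = total - lo
    count = 0
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= lo + 1e-12 or w >= hi - 1e-12:
            count += 1
    return count / 2 ** len(diffs)


class TestWilcoxon:
    def test_all_increasing_exact_p(self):
        pairs = [(1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12)]
        assert wilcoxon_signed_rank(pairs) == pytest.approx(2 / 64)

    def test_balanced_antisymmetric_p_one(self):
        pairs = [(0, 1), (1, 0), (0, 2), (2, 0), (0, 3), (3, 0)]
        assert wilcoxon_signed_rank(pairs) == pytest.approx(1.0)

    def test_all_tied_raises(self):
        with pytest.raises(StatisticsError):
            wilcoxon_signed_rank([(1.0, 1.0)] * 8)

    def test_zeros_dropped(self):
        base = [(1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12)]
        with_zeros = base + [(9.0, 9.0), (4.2, 4.2)]
        assert wilcoxon_signed_rank(with_zeros) == wilcoxon_signed_rank(base)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_matches_full_enumeration(self, n, rng):
        for _ in range(5):
            diffs = rng.normal(size=n)
            diffs[diffs == 0] = 0.5
            pairs = np.column_stack([np.zeros(n), diffs])
            assert wilcoxon_signed_rank(pairs) == pytest.approx(enumeration_oracle(diffs), abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self, rng):
        diffs = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 3.0, 0.5])
        pairs = np.column_stack([np.zeros(len(diffs)), diffs])
        assert wilcoxon_signed_rank(pairs) == pytest.approx(enumeration_oracle(diffs), abs=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        diffs = rng.normal(0.8, 1.0, 40)
        pairs = np.column_stack([np.zeros(40), diffs])
        p = wilcoxon_signed_rank(pairs)
        ref = sps.wilcoxon(diffs, correction=False, mode="approx").pvalue
        assert p == pytest.approx(ref, abs=1e-9)


class TestRegression:
    def test_exact_line(self):
        x = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        r = regression_zero_crossing(x, 2 * x + 4)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(4.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.x_at_y0 == pytest.approx(-2.0)

    def test_constant_y_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        r = regression_zero_crossing(x, np.zeros(4))
        assert r.slope == 0.0
        assert not r.crossing_defined
        assert np.isnan(r.x_at_y0)

    def test_constant_x_raises(self):
        with pytest.raises(StatisticsError):
            regression_zero_crossing(np.ones(5), np.arange(5.0))

    def test_too_few_points_raises(self):
        with pytest.raises(StatisticsError):
            regression_zero_crossing([1.0, 2.0], [1.0, 2.0])

    def test_generative_recovery(self):
        # known line y = 1.1 x + 9.24 (x-intercept -8.4), noise SD 1, n=31
        rng = np.random.default_rng(3)
        x = rng.normal(-20, 8, 31)
        y = 1.1 * x + 9.24 + rng.normal(0, 1, 31)
        r = regression_zero_crossing(x, y)
        assert r.x_at_y0 == pytest.approx(-8.4, abs=1.0)
        assert r.r_squared > 0.9

    def test_replicate_mean_recovery(self):
        recovered = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(-20, 8, 31)
            y = 1.1 * x + 9.24 + rng.normal(0, 1, 31)
            recovered.append(regression_zero_crossing(x, y).x_at_y0)
        assert np.mean(recovered) == pytest.approx(-8.4, abs=0.5)


class TestSpearman:
    def test_monotone_increasing(self):
        t = spearman_correlations({"f": [1, 2, 3, 4, 5]}, {"d": [10, 20, 40, 80, 160]})
        assert t.loc["d", "f"]["r"] == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        t = spearman_correlations({"f": [1, 2, 3, 4, 5]}, {"d": [5, 4, 3, 2, 1]})
        assert t.loc["d", "f"]["r"] == pytest.approx(-1.0)

    def test_hand_computed_rank_formula(self):
        # ranks (1..5) vs (2,1,4,3,5): r = 1 - 6*4/120 = 0.8
        t = spearman_correlations({"f": [1, 2, 3, 4, 5]}, {"d": [2, 1, 4, 3, 5]})
        assert t.loc["d", "f"]["r"] == pytest.approx(0.8)

    def test_constant_column_flagged(self):
        t = spearman_correlations({"f": [1.0] * 5}, {"d": [1, 2, 3, 4, 5]})
        cell = t.loc["d", "f"]
        assert cell["undefined"]
        assert np.isnan(cell["r"])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        t1 = spearman_correlations({"f": x}, {"d": y})
        t2 = spearman_correlations({"f": np.exp(x)}, {"d": y**3})
        assert t1.loc["d", "f"]["r"] == pytest.approx(t2.loc["d", "f"]["r"], abs=1e-12)

    def test_small_n_raises(self):
        with pytest.raises(StatisticsError):
            spearman_correlations({"f": [1, 2, 3]}, {"d": [1, 2, 3]})

    def test_significance_stars(self):
        n = 20
        x = np.arange(n, dtype=float)
        t = spearman_correlations({"f": x}, {"d": x})
        assert t.loc["d", "f"]["stars"] == "**"


def _fake_patient(pid, fb_dmean, dibh_dmean, adverse=False):
    def scalars(dmean):
        return {
            "dmean_dvh_gy": dmean,
            "dmean_dmh_gy": dmean * 0.85,
            "volume_cm3": 1400.0 + 10 * fb_dmean,
            "mass_g": 440.0,
            "mean_density_g_cm3": 0.3,
            "v20_rel_pct": dmean * 1.9,
            "v20_abs_cm3": dmean * 26.0,
            "m20_rel_pct": dmean * 1.5,
            "m20_abs_g": dmean * 6.5,
        }

    return PatientMetrics(
        patient_id=pid,
        dose_metrics={
            "fb": {"left_lung": scalars(fb_dmean), "heart": {"dmean_dvh_gy": 4.0,
                   "v20_rel_pct": 6.0, "v40_rel_pct": 3.5}, "ptv": {"volume_cm3": 950.0}},
            "dibh": {"left_lung": scalars(dibh_dmean), "heart": {"dmean_dvh_gy": 1.7,
                     "v20_rel_pct": 1.2, "v40_rel_pct": 0.4}, "ptv": {"volume_cm3": 940.0}},
        },
        anatomy={"ptv_volume_fb_cm3": 950.0, "delta_lung_volume_pct": 80.0 + fb_dmean},
        adverse=adverse,
    )


class TestBuildSummary:
    def test_two_identical_patients_zero_sd(self):
        patients = [_fake_patient("a", 10.0, 8.0), _fake_patient("b", 10.0, 8.0)]
        result = build_summary(patients)
        row = result.summary.loc["lung_dmean_dvh_gy"]
        assert row["fb_mean"] == pytest.approx(10.0)
        assert row["fb_sd"] == 0.0
        assert row["delta_mean"] == pytest.approx(-2.0)

    def test_single_patient_raises(self):
        with pytest.raises(StatisticsError):
            build_summary([_fake_patient("a", 10.0, 8.0)])

    def test_delta_convention_dibh_minus_fb(self):
        patients = [_fake_patient(str(i), 10.0 + i, 8.0 + i) for i in range(6)]
        result = build_summary(patients)
        assert result.summary.loc["lung_dmean_dvh_gy", "delta_mean"] == pytest.approx(-2.0)
        assert (result.per_patient["lung_dmean_dvh_gy_delta"] < 0).all()

    def test_wilcoxon_p_present_and_small(self):
        rng = np.random.default_rng(0)
        patients = [
            _fake_patient(str(i), 10.0 + rng.normal(0, 1), 8.0 + rng.normal(0, 0.5))
            for i in range(12)
        ]
        result = build_summary(patients)
        assert result.tests["lung_dmean_dvh_gy"] < 0.01

    def test_regressions_emitted(self):
        rng = np.random.default_rng(1)
        patients = [
            _fake_patient(str(i), 10.0 + rng.normal(0, 2), 8.0 + rng.normal(0, 1))
            for i in range(12)
        ]
        result = build_summary(patients)
        assert "dmean_dvh_vs_dmh" in result.regressions
        assert "v20_vs_m20" in result.regressions
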