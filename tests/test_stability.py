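import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rotomics.stability import (
    StabilityConfig,
    aggregate_subgroups,
    compute_stability,
    effect_stratum,
    iqr_with_ci,
    percent_difference,
    spearman_vs_rotation,
)


class TestPercentDifference:
    def test_direct_arithmetic(self):
        assert percent_difference(3.0, 2.0) == pytest.approx(50.0)

    def test_equal_is_exactly_zero(self):
        assert percent_difference(5.0, 5.0) == 0.0

    def test_eps_guard_bounds(self):
        # f0 = 0, eps = 1e-6: denominator is eps, value finite per stated rule
        got = percent_difference(1e-9, 0.0, eps=1e-6)
        assert got == pytest.approx(100.0 * 1e-9 / 1e-6)
        assert np.isfinite(percent_difference(1.0, 0.0))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    def test_antisymmetry_up_to_denominator(self, a, b):
        eps = 1e-9
        fwd = percent_difference(a, b, eps)
        bwd = percent_difference(b, a, eps)
        # antisymmetric after undoing the denominator change
        assert fwd * max(abs(b), eps) == pytest.approx(-bwd * max(abs(a), eps),
                                                       rel=1e-9, abs=1e-6)


class TestIqrWithCi:
    def test_quantile_rule_oracle(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        iqrs, mean, ci = iqr_with_ci({10: vals, 20: vals})
        expect = np.percentile(vals, 75) - np.percentile(vals, 25)  # type-7
        assert iqrs[10] == pytest.approx(expect)
        assert mean == pytest.approx(expect)

    def test_identical_iqrs_degenerate_ci(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0])
        _, mean, ci = iqr_with_ci({10: vals, 20: vals, 30: vals})
        assert ci[0] == pytest.approx(mean) and ci[1] == pytest.approx(mean)

    def test_two_labels_t_closed_form(self):
        a = np.array([0.0, 1.0, 1.0, 2.0])   # IQR 0.5... compute via oracle
        b = np.array([0.0, 2.0, 2.0, 4.0])
        iqrs, mean, ci = iqr_with_ci({10: a, 20: b})
        i1 = np.percentile(a, 75) - np.percentile(a, 25)
        i2 = np.percentile(b, 75) - np.percentile(b, 25)
        m = (i1 + i2) / 2
        sd = np.std([i1, i2], ddof=1)
        half = stats.t.ppf(0.975, 1) * sd / np.sqrt(2)
        assert mean == pytest.approx(m)
        assert ci == (pytest.approx(m - half), pytest.approx(m + half))

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 4"):
            iqr_with_ci({10: np.array([1.0]), 20: np.array([1.0, 2, 3, 4])})


class TestSpearman:
    def test_monotone_gives_one(self):
        # one point per label (no ties in x), |%d| strictly increasing
        pd_by = {lab: np.array([float(lab) * 1.5]) for lab in range(10, 130, 10)}
        cc, p, stratum = spearman_vs_rotation(pd_by)
        assert cc == pytest.approx(1.0)
        assert stratum == "strong"

    def test_null_monte_carlo(self, rng):
        pd_by = {lab: rng.normal(0, 1, 60) for lab in range(10, 90, 10)}
        cc, p, stratum = spearman_vs_rotation(pd_by)
        assert abs(cc) < 0.1
        assert stratum == "trivial"

    def test_constant_convention(self):
        pd_by = {lab: np.full(5, 2.0) for lab in (10, 20, 30)}
        with pytest.warns(UserWarning, match="constant"):
            cc, p, stratum = spearman_vs_rotation(pd_by)
        assert (cc, p, stratum) == (0.0, 1.0, "trivial")

    def test_strata_boundaries(self):
        # printed intervals: lower bound inclusive
        assert effect_stratum(0.09) == "trivial"
        assert effect_stratum(0.1) == "weak"
        assert effect_stratum(0.3) == "moderate"
        assert effect_stratum(-0.3) == "moderate"
        assert effect_stratum(0.7) == "strong"

    def test_magnitude_vs_signed_mode(self, rng):
        # spread grows with label but is sign-symmetric: only |%d| correlates
        pd_by = {lab: rng.normal(0, lab, 200) for lab in range(10, 90, 10)}
        cc_mag, _, _ = spearman_vs_rotation(pd_by, StabilityConfig(use_magnitude=True))
        cc_sgn, _, _ = spearman_vs_rotation(pd_by, StabilityConfig(use_magnitude=False))
        assert cc_mag > 0.3
        assert abs(cc_sgn) < 0.1


def _toy_table(n_pat=6, labels=(0, 10, 20, 30), feature_fn=None):
    rows = []
    rng = np.random.default_rng(0)
    for pid in range(n_pat):
        base = {"A": 10.0 + pid, "B": 5.0}
        for lab in labels:
            for feat, val in base.items():
                v = val if feature_fn is None else feature_fn(feat, val, lab, pid, rng)
                rows.append({"patient_id": f"P{pid}", "rotation_label": lab,
                             "channel": "original", "category": "firstorder",
                             "feature": feat, "value": v})
    return pd.DataFrame(rows)


class TestComputeStability:
    def test_identical_labels_zero_everything(self):
        records, per_label = compute_stability(_toy_table())
        assert np.allclose(records.mean_iqr, 0.0)
        assert not records.significant_nontrivial.any()
        assert set(per_label.rotation_label) == {10, 20, 30}

    def test_trending_feature_flagged(self):
        def fn(feat, val, lab, pid, rng):
            if feat == "A":
                return val * (1 + 0.01 * lab + 0.001 * rng.normal())
            return val + 0.001 * rng.normal()

        df = _toy_table(n_pat=12, labels=tuple(range(0, 90, 10)), feature_fn=fn)
        records, _ = compute_stability(df)
        rec = records.set_index("feature")
        assert rec.loc["A", "significant_nontrivial"]
        assert not rec.loc["B", "significant_nontrivial"]

    def test_vector_spearman_matches_scipy(self, rng):
        from rotomics.stability import _vector_spearman

        x = np.repeat(np.arange(8, dtype=float), 10)
        y = rng.normal(0, 1, size=(5, 80))
        y[0] = x + rng.normal(0, 0.1, 80)
        cc, p = _vector_spearman(stats.rankdata(x), y)
        for i in range(5):
            ref_cc, ref_p = stats.spearmanr(x, y[i])
            assert cc[i] == pytest.approx(ref_cc, abs=1e-12)
            assert p[i] == pytest.approx(ref_p, rel=1e-6)

    def test_missing_reference_label_raises(self):
        df = _toy_table(labels=(10, 20, 30))
        with pytest.raises(ValueError, match="label 0"):
            compute_stability(df)


class TestAggregate:
    def _records(self, n_flagged, n_total=93, channel="wavelet-LLH"):
        rows = []
        for i in range(n_total):
            rows.append({"channel": channel, "category": "glcm",
                         "feature": f"f{i}", "mean_iqr": 1.0,
                         "spearman_cc": 0.5, "spearman_p": 0.001,
                         "stratum": "moderate",
                         "significant_nontrivial": i < n_flagged})
        return pd.DataFrame(rows)

    def test_percentage_arithmetic(self):
        # 50 of 93 features flagged -> 53.76%
        _, _, per_channel = aggregate_subgroups(self._records(50))
        assert per_channel.loc["wavelet-LLH", "pct_significant"] == \
            pytest.approx(100 * 50 / 93, abs=0.01)
        assert per_channel.loc["wavelet-LLH", "pct_significant"] == \
            pytest.approx(53.76, abs=0.01)

    def test_all_stable_zero_pct(self):
        heat_iqr, heat_pct, _ = aggregate_subgroups(self._records(0))
        assert (heat_pct.to_numpy() == 0).all()

    def test_channel_marginal_mean(self):
        rows = [
            {"channel": "original", "category": "glcm", "feature": "a",
             "mean_iqr": 3.0, "spearman_cc": 0, "spearman_p": 1,
             "stratum": "trivial", "significant_nontrivial": False},
            {"channel": "original", "category": "glrlm", "feature": "b",
             "mean_iqr": 5.0, "spearman_cc": 0, "spearman_p": 1,
             "stratum": "trivial", "significant_nontrivial": False},
        ]
        _, _, per_channel = aggregate_subgroups(pd.DataFrame(rows))
        assert per_channel.loc["original", "mean_iqr"] == pytest.approx(4.0)
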