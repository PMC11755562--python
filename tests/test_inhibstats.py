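import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from piakit.assaysim import CONTROL_ID, AssayConfig, PeptideEffect, simulate_panel
from piakit.inhibstats import (InhibitionModel, correlate_descriptors,
                               dunnett_test, max_t_null_sample,
                               rank_and_classify, relative_intensity,
                               significance_stars, t_test_summary)


def make_measurements(values: dict, time_h: float = 3.0) -> pd.DataFrame:
    rows = [(pid, 500.0, time_h, i + 1, v)
            for pid, vals in values.items() for i, v in enumerate(vals)]
    return pd.DataFrame(rows, columns=["peptide_id", "dose", "time_h",
                                       "replicate", "fluorescence_au"])


class TestRelativeIntensity:
    def test_control_normalizes_to_exactly_one(self):
        m = make_measurements({CONTROL_ID: [90.0, 100.0, 110.0],
                               "p": [50.0, 50.0, 50.0]})
        rel = relative_intensity(m)
        assert rel.loc[CONTROL_ID, "rel_mean"] == pytest.approx(1.0)
        assert rel.loc["p", "rel_mean"] == pytest.approx(0.5)

    def test_noise_free_half_rate_recovery(self):
        cfg = AssayConfig(noise_cv=0.0)
        frame = simulate_panel([PeptideEffect("p", d50=500.0)], cfg)
        rel = relative_intensity(frame, ref_time=3.0)
        expected = (1 - math.exp(-1.5)) / (1 - math.exp(-3.0))
        assert rel.loc["p", "rel_mean"] == pytest.approx(expected, abs=1e-12)

    def test_zero_band_flagged(self):
        m = make_measurements({CONTROL_ID: [100.0, 101.0],
                               "dead": [0.0, 0.0]})
        rel = relative_intensity(m)
        assert rel.loc["dead", "rel_mean"] == 0.0
        assert bool(rel.loc["dead", "no_band"])

    def test_missing_control_raises(self):
        m = make_measurements({"p": [1.0, 2.0]})
        with pytest.raises(ValueError, match="control"):
            relative_intensity(m)

    def test_scale_invariance_of_full_fit(self):
        m = make_measurements({CONTROL_ID: [95.0, 100.0, 105.0],
                               "a": [40.0, 42.0, 44.0],
                               "b": [80.0, 85.0, 90.0]})
        r1 = InhibitionModel(m).fit(seed=0).frame
        scaled = m.assign(fluorescence_au=m["fluorescence_au"] * 7.3)
        r2 = InhibitionModel(scaled).fit(seed=0).frame
        pd.testing.assert_frame_equal(r1, r2)


class TestDunnett:
    def test_single_group_reduces_to_t_test(self):
        rng = np.random.default_rng(0)
        group, control = rng.normal(0.4, 1, 6), rng.normal(0, 1, 6)
        res = dunnett_test([group], control, n_draws=400_000, seed=1)
        _, p = stats.ttest_ind(group, control)
        assert res.adjusted_p[0] == pytest.approx(p, abs=0.002)
        assert res.raw_p[0] == pytest.approx(p, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        control = np.array([1.0, 2.0, 3.0])
        res = dunnett_test([control.copy(), control + 1e-15], control,
                           n_draws=10_000, seed=0)
        assert res.adjusted_p[0] > 0.99

    def test_matches_scipy_multivariate_t_integration(self):
        """Independent oracle: scipy evaluates the same many-to-one null by
        multivariate-t integration rather than Monte Carlo."""
        rng = np.random.default_rng(42)
        control = rng.normal(10, 1, 5)
        groups = [rng.normal(10 - 0.8 * i, 1, 5) for i in range(4)]
        mine = dunnett_test(groups, control, n_draws=300_000, seed=7)
        ref = stats.dunnett(*groups, control=control,
                            random_state=np.random.default_rng(1))
        assert mine.adjusted_p == pytest.approx(ref.pvalue, abs=0.005)

    def test_adjusted_monotone_in_statistic_and_above_raw(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(mu, 1, 4) for mu in (0.0, 0.5, 1.0, 2.0)]
        res = dunnett_test(groups, rng.normal(0, 1, 4), seed=2)
        order = np.argsort(np.abs(res.statistics))
        assert (np.diff(res.adjusted_p[order]) <= 1e-12).all()
        assert (res.adjusted_p >= res.raw_p - 1e-12).all()

    def test_more_groups_never_lower_adjusted_p(self):
        rng = np.random.default_rng(9)
        control = rng.normal(0, 1, 5)
        groups = [rng.normal(0.9, 1, 5) for _ in range(4)]
        p2 = dunnett_test(groups[:2], control, n_draws=200_000,
                          seed=5).adjusted_p
        p4 = dunnett_test(groups, control, n_draws=200_000, seed=5).adjusted_p
        assert (p4[:2] >= p2 - 0.003).all()
        assert p4[:2].mean() > p2.mean()

    def test_degenerate_variance_raises(self):
        flat = np.ones(3)
        with pytest.raises(ValueError, match="degenerate"):
            dunnett_test([flat], flat)

    def test_fwer_calibration_small(self):
        """Null 3-group experiments reject any comparison at about the
        nominal 5% family-wise rate."""
        k, n, n_exp = 3, 4, 2000
        null = max_t_null_sample([n] * k, n, n_draws=100_000, seed=0)
        crit = null[int(0.95 * len(null))]
        rng = np.random.default_rng(10)
        rejected = 0
        for _ in range(n_exp):
            data = rng.standard_normal((k + 1, n))
            res = dunnett_test(list(data[1:]), data[0], null_sample=null)
            rejected += (np.abs(res.statistics) > crit).any()
        assert rejected / n_exp == pytest.approx(0.05, abs=0.015)


class TestTTestSummary:
    def test_published_dna_concentration_comparison(self):
        assert t_test_summary(3, 3.297, 0.006, 3, 0.332, 0.003) < 1e-10

    def test_equal_summaries_give_p_one(self):
        assert t_test_summary(4, 1.0, 0.2, 4, 1.0, 0.2) == pytest.approx(1.0)

    def test_against_exhaustive_permutation_oracle(self):
        """On six values the full 20-split permutation null and the pooled-t
        p-value agree about where the evidence stands."""
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 7.0]
        g1 = [1.0, 2.0, 4.0]
        g2 = [v for v in values if v not in g1] + []
        obs = abs(np.mean(g1) - np.mean(g2))
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            a = [values[i] for i in combo]
            b = [values[i] for i in range(6) if i not in combo]
            total += 1
            if abs(np.mean(a) - np.mean(b)) >= obs - 1e-12:
                count += 1
        perm_p = count / total
        t_p = t_test_summary(3, np.mean(g1), np.std(g1, ddof=1),
                             3, np.mean(g2), np.std(g2, ddof=1))
        assert t_p == pytest.approx(perm_p, abs=0.2)
        assert (t_p < 0.5) == (perm_p < 0.5)


class TestRanking:
    def test_threshold_subset_and_rank_order(self):
        frame = pd.DataFrame({"rel_mean": [0.8, 0.1, 0.25, 0.3]},
                             index=pd.Index(["a", "b", "c", "d"],
                                            name="peptide_id"))
        ranked = rank_and_classify(frame, threshold=0.3)
        assert list(ranked.index) == ["b", "c", "d", "a"]
        assert list(ranked["rank"]) == [1, 2, 3, 4]
        # strictly-below rule: 0.3 itself is excluded
        assert set(ranked[ranked.most_inhibitory].index) == {"b", "c"}

    def test_all_above_threshold_gives_empty_subset(self):
        frame = pd.DataFrame({"rel_mean": [0.5, 0.9]},
                             index=pd.Index(["a", "b"], name="peptide_id"))
        ranked = rank_and_classify(frame, threshold=0.3)
        assert not ranked["most_inhibitory"].any()

    def test_ties_break_lexicographically(self):
        frame = pd.DataFrame({"rel_mean": [0.2, 0.2, 0.1]},
                             index=pd.Index(["z", "a", "m"],
                                            name="peptide_id"))
        ranked = rank_and_classify(frame)
        assert list(ranked.index) == ["m", "a", "z"]


class TestCorrelation:
    def _results(self, values, ids=None):
        ids = ids or [f"p{i}" for i in range(len(values))]
        return pd.DataFrame({"rel_mean": values},
                            index=pd.Index(ids, name="peptide_id"))

    def test_perfect_negative_correlation(self):
        res = self._results([0.9, 0.7, 0.5, 0.3])
        desc = pd.DataFrame({"size": [1.0, 2.0, 3.0, 4.0]}, index=res.index)
        out = correlate_descriptors(res, desc, ["size"])
        assert out[0].pearson_r == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        res = self._results([1.0, 2.0, 4.0, 3.0])
        desc = pd.DataFrame({"f": [1.0, 3.0, 2.0, 5.0]}, index=res.index)
        x, y = desc["f"].to_numpy(), res["rel_mean"].to_numpy()
        # textbook formula as the independent route
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        out = correlate_descriptors(res, desc, ["f"])
        assert out[0].pearson_r == pytest.approx(r_manual, abs=1e-12)

    def test_independent_factor_has_near_zero_r(self):
        rng = np.random.default_rng(5)
        n = 4000
        res = self._results(rng.uniform(0, 1, n))
        desc = pd.DataFrame({"noise": rng.uniform(0, 1, n)}, index=res.index)
        out = correlate_descriptors(res, desc, ["noise"])
        assert abs(out[0].pearson_r) < 0.05

    def test_constant_factor_reported_not_fatal(self):
        res = self._results([0.1, 0.2, 0.3, 0.4])
        desc = pd.DataFrame({"flat": [1.0] * 4, "ok": [1.0, 2.0, 3.0, 4.0]},
                            index=res.index)
        out = correlate_descriptors(res, desc, ["flat", "ok"])
        assert out[0].error == "constant factor"
        assert math.isnan(out[0].pearson_r)
        assert out[1].error is None

    def test_exclusion_list_dropped_before_pairing(self):
        res = self._results([0.1, 0.2, 0.3, 10.0],
                            ids=["a", "b", "c", "BP19.5"])
        desc = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=res.index)
        out = correlate_descriptors(res, desc, ["f"], exclude=["BP19.5"])
        assert out[0].n == 3


class TestModelInterface:
    def test_fit_is_deterministic_given_seed(self):
        cfg = AssayConfig(noise_cv=0.05, seed=21)
        frame = simulate_panel([PeptideEffect("a", d50=30.0),
                                PeptideEffect("b", d50=3000.0)], cfg)
        r1 = InhibitionModel(frame).fit(seed=4).frame
        r2 = InhibitionModel(frame).fit(seed=4).frame
        pd.testing.assert_frame_equal(r1, r2)

    def test_summary_and_stars(self):
        cfg = AssayConfig(noise_cv=0.02, seed=8)
        frame = simulate_panel([PeptideEffect("strong", d50=10.0),
                                PeptideEffect("weak", d50=1e8)], cfg)
        results = InhibitionModel(frame).fit(seed=0)
        text = results.summary()
        assert "strong" in text and "rank" in text
        assert results.frame.loc["strong", "stars"] == "**"
        assert results.frame.loc["weak", "stars"] == "ns"
        assert results.most_inhibitory == ["strong"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lack columns"):
            InhibitionModel(pd.DataFrame({"x": [1]}))

    def test_stars_thresholds(self):
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"
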