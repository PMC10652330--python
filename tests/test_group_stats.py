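"""Exact nonparametric inference: Wilcoxon, Kendall tau-b, KS normality."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mtmrs.exchange_kinetics import KineticFit, SubjectResult
from mtmrs.group_stats import (
    PairedSample,
    kendall_tau_b,
    ks_normality,
    run_cohort_analysis,
    wilcoxon_signed_rank,
)


def _paired(diffs):
    pre = np.zeros(len(diffs))
    return PairedSample(tuple(f"s{i}" for i in range(len(diffs))), pre, np.asarray(diffs))


def _brute_force_wilcoxon_p(diffs):
    """Literal 2^n enumeration, independent of the implementation."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.abs(d) > 1e-12]
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_small = min(w_plus, total - w_plus)
    count = 0
    n = len(d)
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_small + 1e-9 or w >= total - w_small - 1e-9:
            count += 1
    return min(count / 2.0**n, 1.0)


class TestWilcoxon:
    def test_seven_positive_differences(self):
        """All-positive n=7 differences: Z = -2.366, exact p = 2/128."""
        result = wilcoxon_signed_rank(_paired([0.1, 0.05, 0.2, 0.15, 0.3, 0.07, 0.12]))
        assert result.z == pytest.approx(-2.366, abs=5e-4)
        assert result.p_two_tailed == pytest.approx(2 / 128)
        assert round(result.p_two_tailed, 3) == 0.016
        assert result.method == "exact"

    def test_six_positive_differences(self):
        result = wilcoxon_signed_rank(_paired([1, 2, 3, 4, 5, 6]))
        assert result.p_two_tailed == pytest.approx(2 / 64)
        assert result.z == pytest.approx(-2.201, abs=5e-4)

    def test_perfect_antisymmetry(self):
        result = wilcoxon_signed_rank(_paired([0.4, -0.4]))
        assert result.z == pytest.approx(0.0, abs=1e-12)
        assert result.p_two_tailed == 1.0

    def test_zero_differences_dropped_then_error(self):
        sample = _paired([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(sample)
        kept = wilcoxon_signed_rank(_paired([0.0, 0.1, -0.2, 0.3]))
        assert kept.n_effective == 3

    def test_asymptotic_z_closed_form_all_positive(self):
        for n in range(4, 12):
            result = wilcoxon_signed_rank(_paired(list(range(1, n + 1))))
            expected = -(n * (n + 1) / 4.0) / math.sqrt(
                n * (n + 1) * (2 * n + 1) / 24.0
            )
            assert result.z == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_exact_p(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = rng.normal(0.1, 1.0, 9)
            ours = wilcoxon_signed_rank(_paired(d), method="exact")
            ref = sps.wilcoxon(d, method="exact", alternative="two-sided")
            assert ours.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.lists(
            st.integers(-6, 6).filter(lambda v: v != 0), min_size=3, max_size=10
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_brute_force_enumeration(self, diffs):
        result = wilcoxon_signed_rank(_paired(diffs), method="exact")
        assert result.p_two_tailed == pytest.approx(
            _brute_force_wilcoxon_p(diffs), rel=1e-12
        )


class TestKendall:
    def test_perfect_orders(self):
        x = [1, 2, 3, 4, 5]
        up = kendall_tau_b(x, [2, 4, 5, 7, 9])
        down = kendall_tau_b(x, [9, 7, 5, 4, 2])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_tie_corrected_value_matches_pair_count_oracle(self):
        x = np.array([1, 2, 2, 3])
        y = np.array([1, 3, 2, 4])
        res = kendall_tau_b(x, y)
        # brute force: concordant/discordant over all pairs
        conc = disc = tx = ty = 0
        for i in range(3):
            for j in range(i + 1, 4):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        denom = math.sqrt((6 - tx) * (6 - ty))
        assert res.statistic == pytest.approx((conc - disc) / denom)
        ref = sps.kendalltau(x, y, variant="b")
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_antisymmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=7), rng.normal(size=7)
        a = kendall_tau_b(x, y).statistic
        b = kendall_tau_b(x, -y).statistic
        assert a == pytest.approx(-b)
        assert -1.0 <= a <= 1.0

    def test_exact_p_matches_scipy_untied(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        ours = kendall_tau_b(x, y, method="exact")
        ref = sps.kendalltau(x, y, method="exact")
        assert ours.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])


class TestKsNormality:
    def test_normal_quantiles_give_small_d_large_p(self):
        x = sps.norm.ppf((np.arange(1, 41) - 0.5) / 40)
        res = ks_normality(x, n_replicates=400, seed=1)
        assert res.statistic < 0.06
        assert res.p_two_tailed > 0.5

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for seed in range(10):
            x = np.concatenate([rng.normal(-3, 0.4, 50), rng.normal(3, 0.4, 50)])
            res = ks_normality(x, n_replicates=500, seed=seed)
            rejections += res.p_two_tailed < 0.01
        assert rejections >= 9

    def test_null_p_roughly_uniform(self):
        """p-values under the null are uniform: KS test on the p sample."""
        rng = np.random.default_rng(7)
        pvals = [
            ks_normality(rng.standard_normal(12), n_replicates=200, seed=s).p_two_tailed
            for s in range(60)
        ]
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0, 1.0])


def _subject(sid, session, kf_pi, kf_pcr=0.3):
    mk = lambda m, v: KineticFit(metabolite=m, kf=v, t1=3.1, t1_mode="fixed", s0=1.0)
    return SubjectResult(
        subject_id=sid, session=session,
        kf_pi=mk("Pi_i", kf_pi), kf_pcr=mk("PCr", kf_pcr),
    )


class TestCohortAnalysis:
    def _results(self, pre, post):
        out = []
        for i, (a, b) in enumerate(zip(pre, post)):
            out.append(_subject(f"s{i}", "pre", a))
            out.append(_subject(f"s{i}", "post", b))
        return out

    def test_all_positive_cohort_reproduces_reference_statistics(self):
        pre = [0.15, 0.18, 0.2, 0.22, 0.19, 0.25, 0.17]
        post = [p + d for p, d in zip(pre, [0.1, 0.08, 0.12, 0.05, 0.11, 0.07, 0.09])]
        report = run_cohort_analysis(self._results(pre, post))
        t = report.tests["Pi_i"]
        assert t.z == pytest.approx(-2.366, abs=5e-4)
        assert round(t.p_two_tailed, 3) == 0.016
        assert report.n_increased["Pi_i"] == 7

    def test_identical_sessions_reported_as_no_change(self):
        pre = [0.2, 0.21, 0.22]
        report = run_cohort_analysis(self._results(pre, pre))
        assert isinstance(report.tests["Pi_i"], str)
        assert "no change" in report.tests["Pi_i"]

    def test_one_decrease_counted(self):
        pre = [0.2, 0.2, 0.2, 0.2]
        post = [0.3, 0.3, 0.3, 0.1]
        report = run_cohort_analysis(self._results(pre, post))
        assert report.n_increased["Pi_i"] == 3

    def test_kendall_age_correlation_included(self):
        pre = [0.15, 0.2, 0.25, 0.2, 0.18]
        post = [0.25, 0.28, 0.33, 0.31, 0.3]
        ages = {f"s{i}": a for i, a in enumerate([61, 65, 70, 77, 83])}
        report = run_cohort_analysis(self._results(pre, post), ages=ages)
        assert report.kendall_age is not None
        assert -1.0 <= report.kendall_age.statistic <= 1.0

    def test_unpaired_subjects_excluded(self):
        results = self._results([0.2, 0.25], [0.3, 0.35])
        results.append(_subject("lonely", "pre", 0.2))
        with pytest.warns(UserWarning, match="lonely"):
            report = run_cohort_analysis(results)
        assert report.n_pairs == 2
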