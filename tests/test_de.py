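import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hdcn.containers import ExpressionMatrix
from hdcn.de import (
    call_degs,
    combine_pvalues,
    hypergeometric_overrep,
    overlap_summary,
    permutation_pvalue,
)
from hdcn.deconvolution import estimate_proportions, fit_reference
from hdcn.simulate import simulate_expression_cohort


def enumerate_permutation_p(x, y, statistic_fn):
    """Exact two-sided permutation tail probability by full enumeration."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    s_obs = abs(statistic_fn(np.asarray(x), np.asarray(y)))
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        s = abs(statistic_fn(pooled[mask], pooled[~mask]))
        hits += s >= s_obs
        total += 1
    return hits / total


class TestPermutationPvalue:
    def test_identical_groups_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert permutation_pvalue(x, x, "median_diff", seed=0) == 1.0

    @pytest.mark.parametrize("statistic", ["t", "rank_sum", "median_diff"])
    def test_sampled_p_converges_to_enumerated_p(self, statistic):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        fns = {
            "t": lambda a, b: stats.ttest_ind(a, b, equal_var=False).statistic,
            "rank_sum": lambda a, b: stats.rankdata(np.concatenate([a, b]))[
                : len(a)
            ].sum()
            - len(a) * (len(a) + len(b) + 1) / 2,
            "median_diff": lambda a, b: np.median(a) - np.median(b),
        }
        q = enumerate_permutation_p(x, y, fns[statistic])
        p = permutation_pvalue(x, y, statistic, n_perm=4000, seed=1)
        assert abs(p - q) < 0.03

    def test_p_values_live_on_the_add_one_grid(self):
        rng = np.random.default_rng(3)
        n_perm = 50
        for _ in range(10):
            p = permutation_pvalue(
                rng.standard_normal(6),
                rng.standard_normal(7),
                "t",
                n_perm=n_perm,
                seed=int(rng.integers(1000)),
            )
            k = p * (1 + n_perm)
            assert abs(k - round(k)) < 1e-9
            assert 1 / (1 + n_perm) <= p <= 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1.0, 2.0], [1.0, 2.0, 3.0], "t")


class TestCombinePvalues:
    def test_all_ones_combine_to_one(self):
        assert combine_pvalues(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_matches_chi_square_closed_form(self):
        # survival of chi^2 with 6 df: exp(-x/2) * (1 + x/2 + (x/2)^2 / 2)
        for ps in [(0.05, 0.05, 0.05), (0.5, 0.1, 0.9), (0.001, 0.8, 0.3)]:
            x = -2 * sum(math.log(p) for p in ps)
            expected = math.exp(-x / 2) * (1 + x / 2 + (x / 2) ** 2 / 2)
            assert combine_pvalues(*ps) == pytest.approx(expected, abs=1e-12)

    def test_known_value_for_three_0p05(self):
        # X = -6 ln 0.05 ~= 17.97; exact chi^2_6 upper tail is 0.0062965
        assert combine_pvalues(0.05, 0.05, 0.05) == pytest.approx(
            0.0062965, abs=1e-6
        )

    def test_monotone_in_each_argument(self):
        base = combine_pvalues(0.2, 0.3, 0.4)
        assert combine_pvalues(0.25, 0.3, 0.4) > base
        assert combine_pvalues(0.2, 0.35, 0.4) > base
        assert combine_pvalues(0.2, 0.3, 0.45) > base

    def test_zero_input_clamped(self):
        assert 0 < combine_pvalues(0.0, 0.5, 0.5) < 1


class TestCallDegs:
    def test_constant_gene_called_none(self, small_cohort):
        m, _ = small_cohort
        mixed = m.subset(samples=m.mixed_samples)
        ref = m.subset(samples=m.reference_samples)
        table = call_degs(mixed, ref, n_perm=100, seed=0)
        assert set(table["call"]) <= {"up", "down", "none"}
        assert ((table.loc[table["call"] == "up", "log2_fc"]) > np.log2(1.25)).all()
        assert ((table.loc[table["call"] == "down", "log2_fc"]) < -np.log2(1.25)).all()

    def test_gene_id_mismatch_is_error(self, small_cohort):
        m, _ = small_cohort
        mixed = m.subset(genes=m.gene_ids[:10], samples=m.mixed_samples)
        ref = m.subset(genes=m.gene_ids[10:20], samples=m.reference_samples)
        with pytest.raises(ValueError, match="gene ids"):
            call_degs(mixed, ref)

    def test_planted_up_deg_called_up_after_deconvolution(self):
        m, truth = simulate_expression_cohort(
            n_genes=300, n_mixed=40, n_reference=40, n_deg=60, seed=11
        )
        result = estimate_proportions(m, m.gene_ids, fit_reference(m, m.gene_ids))
        ref = m.subset(m.gene_ids, m.reference_samples)
        table = call_degs(result.purified, ref, n_perm=300, seed=11)
        up_truth = [g for g, e in truth.deg_genes.items() if e > 0]
        frac_up = (table.loc[up_truth, "call"] == "up").mean()
        assert frac_up >= 0.9

    def test_recovery_sensitivity_and_false_positive_rate(self):
        m, truth = simulate_expression_cohort(
            n_genes=500, n_mixed=40, n_reference=40, n_deg=50,
            pi_range=(0.0, 0.0), seed=7,
        )
        table = call_degs(
            m.subset(samples=m.mixed_samples),
            m.subset(samples=m.reference_samples),
            n_perm=500,
            seed=7,
        )
        called = set(table.index[table["call"] != "none"])
        planted = set(truth.deg_genes)
        assert len(called & planted) / len(planted) >= 0.8
        assert len(called - planted) / (500 - len(planted)) <= 0.02

    def test_gene_order_does_not_change_per_gene_pvalues(self, small_cohort):
        m, _ = small_cohort
        genes = m.gene_ids[:30]
        mixed = m.subset(genes, m.mixed_samples)
        ref = m.subset(genes, m.reference_samples)
        t1 = call_degs(mixed, ref, n_perm=100, seed=5)
        rev = list(reversed(genes))
        t2 = call_degs(
            m.subset(rev, m.mixed_samples),
            m.subset(rev, m.reference_samples),
            n_perm=100,
            seed=5,
        )
        assert (t1.loc[genes, "p_combined"] == t2.loc[genes, "p_combined"]).all()


class TestOverlapSummary:
    def test_paper_style_percentages(self):
        up = {f"u{i}" for i in range(80)}
        down = {f"d{i}" for i in range(757)}
        reference = {f"u{i}" for i in range(66)} | {f"d{i}" for i in range(501)}
        summary = overlap_summary(up, down, reference)
        assert summary.loc["up", "percent"] == 82.5
        assert summary.loc["down", "percent"] == 66.2

    def test_no_overlap_is_zero_percent(self):
        summary = overlap_summary({"a", "b"}, set(), {"x"})
        assert summary.loc["up", "percent"] == 0.0

    def test_empty_direction_reports_nan_not_zero(self):
        summary = overlap_summary(set(), {"a"}, {"a"})
        assert np.isnan(summary.loc["up", "percent"])
        assert summary.loc["down", "percent"] == 100.0


class TestHypergeometricOverrep:
    def test_certain_event_has_p_one(self):
        assert hypergeometric_overrep(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_pmf_summation(self):
        def pmf(k, N, K, n):
            return (
                math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            )

        expected = sum(pmf(k, 20, 5, 5) for k in range(3, 6))
        assert hypergeometric_overrep(3, 5, 5, 20) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_k(self):
        ps = [hypergeometric_overrep(k, 10, 10, 50) for k in range(0, 8)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overrep(6, 5, 5, 20)
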