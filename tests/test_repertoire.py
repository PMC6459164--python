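import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hdcn.containers import ClonotypeTable
from hdcn.repertoire import (
    alpha_diversity,
    beta_diversity,
    collapse_reads,
    filter_in_frame,
    group_permutation_test,
    select_top_k,
    vj_matrix,
)


def _table(rows):
    return ClonotypeTable(
        pd.DataFrame(rows, columns=list(ClonotypeTable.COLUMNS))
    )


class TestCollapse:
    def test_duplicate_junctions_merge_with_count_sum(self):
        t = _table(
            [("s1", "V1", "J1", "TGTGCC", 2)] * 2
            + [("s1", "V1", "J1", "TGTGCC", 1)]
        )
        out = collapse_reads(t)
        assert len(out) == 1
        assert out.records["count"].iloc[0] == 5

    def test_unique_input_unchanged(self):
        t = _table(
            [("s1", "V1", "J1", "TGTGCC", 2), ("s2", "V1", "J1", "TGTGCC", 3)]
        )
        assert len(collapse_reads(t)) == 2

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2"]),
                st.sampled_from(["AAA", "AAC", "TGT", "GGGACC"]),
                st.integers(1, 9),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_collapse_is_idempotent(self, rows):
        t = _table([(s, "V1", "J1", j, c) for s, j, c in rows])
        once = collapse_reads(t)
        twice = collapse_reads(once)
        pd.testing.assert_frame_equal(
            once.records.reset_index(drop=True),
            twice.records.reset_index(drop=True),
        )


class TestTopK:
    def test_small_sample_kept_whole(self):
        t = _table(
            [
                ("s1", "V1", "J1", "AAA", 3),
                ("s1", "V1", "J1", "AAC", 2),
                ("s1", "V1", "J2", "TGT", 1),
            ]
        )
        assert len(select_top_k(t, 10000)) == 3

    def test_ties_break_lexicographically(self):
        t = _table(
            [
                ("s1", "V1", "J1", "TTT", 9),
                ("s1", "V1", "J1", "CCC", 5),
                ("s1", "V1", "J1", "AAA", 5),
                ("s1", "V1", "J1", "GGG", 1),
            ]
        )
        kept = select_top_k(t, 2).records["junction_nt"].tolist()
        assert kept == ["TTT", "AAA"]

    def test_per_sample_cap_property(self):
        import itertools

        rng = np.random.default_rng(5)
        kmers = ["".join(k) for k in itertools.product("ACGT", repeat=3)]
        rows = [
            (f"s{rng.integers(3)}", "V1", "J1", kmers[i], int(rng.integers(1, 9)))
            for i in range(60)
        ]
        out = select_top_k(collapse_reads(_table(rows)), 5)
        assert out.records.groupby("sample_id").size().max() <= 5


class TestInFrame:
    @pytest.mark.parametrize(
        "junction,kept",
        [
            ("TGTGCC", True),  # two clean codons
            ("TGTTAAGCC", False),  # TAA stop in frame 0
            ("TGTGC", False),  # length not divisible by 3
            ("TAGTGT", False),  # leading stop
            ("GTAAGC", True),  # TAA straddles codons, frame 0 is GTA AGC
        ],
    )
    def test_frame_rules(self, junction, kept):
        t = _table([("s1", "V1", "J1", junction, 1)])
        assert (len(filter_in_frame(t)) == 1) is kept

    def test_n_containing_sequences_dropped(self):
        t = _table(
            [("s1", "V1", "J1", "TGTGNC", 1), ("s1", "V1", "J1", "TGTGCC", 1)]
        )
        assert filter_in_frame(t).records["junction_nt"].tolist() == ["TGTGCC"]


class TestDiversity:
    def test_uniform_counts_give_log_richness(self):
        vj = pd.DataFrame(
            [[5, 5, 5, 5]],
            index=["s1"],
            columns=pd.MultiIndex.from_product([["V1", "V2"], ["J1", "J2"]]),
        )
        assert alpha_diversity(vj)["s1"] == pytest.approx(math.log(4))

    def test_single_combination_has_zero_entropy(self):
        vj = pd.DataFrame(
            [[7, 0]],
            index=["s1"],
            columns=pd.MultiIndex.from_product([["V1"], ["J1", "J2"]]),
        )
        assert alpha_diversity(vj)["s1"] == 0.0

    def test_matches_direct_summation(self, rng):
        counts = rng.integers(1, 50, size=(1, 20))
        vj = pd.DataFrame(counts, index=["s1"])
        p = counts[0] / counts.sum()
        assert alpha_diversity(vj)["s1"] == pytest.approx(-(p * np.log(p)).sum())

    def test_alpha_invariant_to_column_order(self, rng):
        counts = rng.integers(0, 30, size=(3, 12))
        counts[:, 0] += 1
        vj = pd.DataFrame(counts, index=["a", "b", "c"])
        perm = rng.permutation(12)
        assert np.allclose(
            alpha_diversity(vj), alpha_diversity(vj.iloc[:, perm])
        )

    def test_zero_count_sample_is_error(self):
        vj = pd.DataFrame([[0, 0], [1, 2]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            alpha_diversity(vj)


class TestBetaDiversity:
    def test_identical_and_disjoint_limits(self):
        vj = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
            index=["a", "b", "c"],
        )
        beta = beta_diversity(vj)
        assert beta["total"].loc["a", "b"] == 0.0
        assert beta["total"].loc["a", "c"] == 1.0
        assert beta["turnover"].loc["a", "c"] == 1.0
        assert beta["nestedness"].loc["a", "c"] == 0.0

    def test_hand_computed_partition(self):
        # a=2 shared, b=1 unique to s1, c=3 unique to s2
        vj = pd.DataFrame(
            [[1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 1, 1]], index=["s1", "s2"]
        )
        beta = beta_diversity(vj)
        assert beta["total"].loc["s1", "s2"] == pytest.approx(0.5)
        assert beta["turnover"].loc["s1", "s2"] == pytest.approx(1 / 3)
        assert beta["nestedness"].loc["s1", "s2"] == pytest.approx(1 / 6)

    def test_partition_identity_on_random_tables(self, rng):
        counts = (rng.random((6, 15)) < 0.4) * rng.integers(1, 9, (6, 15))
        counts[:, 0] += 1
        beta = beta_diversity(pd.DataFrame(counts))
        total = beta["total"].to_numpy()
        assert np.allclose(
            total, beta["turnover"].to_numpy() + beta["nestedness"].to_numpy(),
            atol=1e-12,
        )
        assert np.allclose(np.diag(total), 0.0)
        for key in beta:
            arr = beta[key].to_numpy()
            assert ((arr >= -1e-12) & (arr <= 1 + 1e-12)).all()


class TestGroupPermutationTest:
    def test_identical_groups_give_p_one(self):
        values = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        p = group_permutation_test(values, labels, "alpha_mean_diff", seed=0)
        assert p == 1.0

    def test_power_on_concentration_contrast(self, repertoire_sim):
        table, groups, _ = repertoire_sim
        vj = vj_matrix(filter_in_frame(collapse_reads(table)))
        alpha = alpha_diversity(vj)
        labels = groups.loc[vj.index]
        p = group_permutation_test(
            alpha, labels, "alpha_mean_diff", n_perm=500, seed=1
        )
        assert p <= 0.05
        beta = beta_diversity(vj)
        p_beta = group_permutation_test(
            beta["total"], labels, "beta_within_group_mean_diff",
            n_perm=300, seed=1,
        )
        assert p_beta <= 0.05

    def test_single_group_rejected(self):
        values = pd.Series([1.0, 2.0], index=["a", "b"])
        labels = pd.Series(["g1", "g1"], index=["a", "b"])
        with pytest.raises(ValueError):
            group_permutation_test(values, labels, "alpha_mean_diff")
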