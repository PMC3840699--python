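import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trflpkit.diversity import (
    OTUTable,
    cluster_otus,
    diversity_summary,
    incidence_summary,
    pdistance,
    rank_abundance,
    rarefaction_curve,
)


class TestPDistance:
    def test_identical(self):
        assert pdistance("ACGT", "ACGT") == 0.0

    def test_one_difference(self):
        assert pdistance("ACGT", "ACGA") == 0.25

    def test_gap_column_excluded(self):
        assert pdistance("AC-T", "ACGT") == 0.0

    def test_ambiguity_excluded(self):
        # N column dropped from the denominator
        assert pdistance("ACNT", "ACGA") == pytest.approx(1 / 3)

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            pdistance("ACGT", "ACG")

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError):
            pdistance("--", "AC")


def brute_force_cluster(dist, cutoff, linkage="average"):
    """Exhaustive agglomeration oracle, coded independently with plain
    python lists and itertools."""
    clusters = [[i] for i in range(len(dist))]

    def cdist(a, b):
        vals = [dist[i][j] for i, j in itertools.product(a, b)]
        if linkage == "average":
            return sum(vals) / len(vals)
        return min(vals) if linkage == "nearest" else max(vals)

    while len(clusters) > 1:
        pairs = []
        for a, b in itertools.combinations(sorted(clusters, key=min), 2):
            pairs.append((cdist(a, b), min(a), min(b), a, b))
        d, _, _, a, b = min(pairs)
        if d > cutoff:
            break
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(sorted(a + b))
    labels = [0] * len(dist)
    for lbl, c in enumerate(sorted(clusters, key=min)):
        for i in c:
            labels[i] = lbl
    return labels


class TestClusterOtus:
    def test_all_identical_one_otu(self):
        dist = np.zeros((4, 4))
        assert len(set(cluster_otus(dist))) == 1

    def test_two_far_sequences(self):
        dist = np.array([[0.0, 0.05], [0.05, 0.0]])
        assert len(set(cluster_otus(dist))) == 2

    def test_hand_agglomeration_three_sequences(self):
        # d(A,B)=0.01 merges; {A,B} vs C averages 0.05 > cutoff -> 2 OTUs
        dist = np.array(
            [[0.0, 0.01, 0.05], [0.01, 0.0, 0.05], [0.05, 0.05, 0.0]]
        )
        labels = cluster_otus(dist, cutoff=0.02)
        assert labels[0] == labels[1] != labels[2]

    def test_cutoff_inclusive(self):
        dist = np.array([[0.0, 0.02], [0.02, 0.0]])
        assert len(set(cluster_otus(dist, cutoff=0.02))) == 1

    def test_cutoff_zero_splits_distinct(self, rng):
        n = 6
        d = rng.uniform(0.01, 0.5, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        assert len(set(cluster_otus(d, cutoff=0.0))) == n

    def test_cutoff_one_merges_all(self, rng):
        n = 6
        d = rng.uniform(0.0, 0.9, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        assert len(set(cluster_otus(d, cutoff=1.0))) == 1

    def test_otu_count_non_increasing_in_cutoff(self, rng):
        n = 6
        d = rng.uniform(0, 0.2, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        counts = [
            len(set(cluster_otus(d, cutoff=c)))
            for c in np.linspace(0, 0.2, 21)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("linkage", ["average", "nearest", "furthest"])
    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_oracle(self, seed, linkage):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        d = rng.uniform(0, 0.1, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        cutoff = float(rng.uniform(0, 0.1))
        expected = brute_force_cluster(d.tolist(), cutoff, linkage)
        actual = cluster_otus(d, cutoff=cutoff, linkage=linkage)
        assert actual.tolist() == expected


class TestDiversitySummary:
    def test_single_otu(self):
        ds = diversity_summary([42])
        assert ds.shannon == 0.0
        assert ds.margalef == 0.0

    def test_uniform_four_otus(self):
        ds = diversity_summary([10, 10, 10, 10])
        assert ds.shannon == pytest.approx(math.log(4))

    def test_chao1_bias_corrected(self):
        # n1=2, n2=0 -> chao1 = 3 + 2*1/(2*1) = 4.0
        ds = diversity_summary([5, 1, 1])
        assert ds.chao1 == pytest.approx(4.0)

    def test_margalef_formula(self):
        counts = [50, 30, 20, 10, 5]
        ds = diversity_summary(counts)
        assert ds.margalef == pytest.approx((5 - 1) / math.log(115))

    def test_relative_abundance_input_gates_richness(self):
        ds = diversity_summary([0.2, 0.8])
        assert ds.margalef is None and ds.chao1 is None
        assert ds.shannon == pytest.approx(-(0.2 * math.log(0.2) + 0.8 * math.log(0.8)))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diversity_summary([0, 0])

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_chao1_lower_bound_and_equality(self, counts):
        ds = diversity_summary(counts)
        n1 = sum(1 for c in counts if c == 1)
        assert ds.chao1 >= ds.s_obs
        assert (ds.chao1 == ds.s_obs) == (n1 <= 1)

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_shannon_maximal_iff_uniform(self, counts):
        ds = diversity_summary(counts)
        s = len(counts)
        if len(set(counts)) == 1:
            assert ds.shannon == pytest.approx(math.log(s))
        else:
            assert ds.shannon < math.log(s) + 1e-12

    def test_shannon_relabeling_invariant(self, rng):
        counts = rng.integers(1, 100, size=12)
        a = diversity_summary(counts).shannon
        b = diversity_summary(rng.permutation(counts)).shannon
        assert a == pytest.approx(b)


class TestRarefaction:
    def test_full_sample_recovers_sobs(self):
        df = rarefaction_curve([4, 3, 2, 1], [10])
        assert df["expected_S"].iloc[0] == pytest.approx(4.0)

    def test_zero_subsample(self):
        df = rarefaction_curve([4, 3], [0])
        assert df["expected_S"].iloc[0] == 0.0

    def test_direct_combinatorial_case(self):
        # counts (2,1), n=1: E[S] = 2/3 + 1/3 = 1
        df = rarefaction_curve([2, 1], [1])
        assert df["expected_S"].iloc[0] == pytest.approx(1.0)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve([2, 1], [4])

    def test_matches_enumeration_oracle(self):
        """Exhaustive enumeration of all subsets for a tiny community."""
        counts = [3, 2, 1]
        individuals = [0, 0, 0, 1, 1, 2]
        n = 3
        richness = [
            len(set(combo))
            for combo in itertools.combinations(individuals, n)
        ]
        expected = np.mean(richness)
        df = rarefaction_curve(counts, [n])
        assert df["expected_S"].iloc[0] == pytest.approx(expected)

    def test_monotone_and_concave(self, rng):
        counts = rng.integers(1, 20, size=8)
        sizes = range(0, int(counts.sum()) + 1)
        vals = rarefaction_curve(counts, list(sizes))["expected_S"].to_numpy()
        d1 = np.diff(vals)
        assert (d1 >= -1e-9).all()
        assert (np.diff(d1) <= 1e-9).all()


class TestIncidenceSummary:
    @staticmethod
    def make_matrix(n_total, n_ubiquitous, n_unique, n_groups=4):
        """Samples x OTUs presence matrix with exact sharing counts."""
        samples = [f"s{g}" for g in range(n_groups)]
        groups = {f"s{g}": f"g{g}" for g in range(n_groups)}
        mat = np.zeros((n_groups, n_total))
        mat[:, :n_ubiquitous] = 1.0
        for i in range(n_unique):
            mat[i % n_groups, n_ubiquitous + i] = 1.0
        for i in range(n_total - n_ubiquitous - n_unique):
            j = n_ubiquitous + n_unique + i
            mat[i % n_groups, j] = 1.0
            mat[(i + 1) % n_groups, j] = 1.0
        df = pd.DataFrame(mat, index=samples,
                          columns=[f"otu{i}" for i in range(n_total)])
        return df, groups

    def test_paper_counts_give_18_and_22_percent(self):
        df, groups = self.make_matrix(116, 21, 25)
        inc = incidence_summary(df, groups)
        assert inc.n_ubiquitous == 21 and inc.pct_ubiquitous == 18
        assert inc.n_unique == 25 and inc.pct_unique == 22

    def test_single_group_degenerate(self):
        df = pd.DataFrame([[1.0, 0.0, 2.0]], index=["s1"],
                          columns=["a", "b", "c"])
        inc = incidence_summary(df, {"s1": "g"})
        assert inc.n_total == 2
        assert inc.n_ubiquitous == inc.n_unique == 2

    def test_prevalence_fraction(self):
        df, groups = self.make_matrix(10, 10, 0)
        inc = incidence_summary(df, groups, prevalence_threshold=0.70)
        assert inc.n_prevalent == 10  # ubiquitous here means all samples
        df2, groups2 = self.make_matrix(10, 0, 10)
        inc2 = incidence_summary(df2, groups2, prevalence_threshold=0.70)
        assert inc2.n_prevalent == 0

    def test_unassigned_sample_rejected(self):
        df, groups = self.make_matrix(5, 5, 0)
        groups.pop("s0")
        with pytest.raises(ValueError):
            incidence_summary(df, groups)

    def test_rounding_half_away_from_zero(self):
        # 1 of 8 = 12.5% -> 13
        df, groups = self.make_matrix(8, 1, 0, n_groups=4)
        inc = incidence_summary(df, groups)
        assert inc.pct_ubiquitous == 13

    def test_otu_table_input(self):
        table = OTUTable(
            otu_ids=["a", "b"], sample_ids=["s1", "s2"],
            counts=np.array([[3, 0], [1, 2]]),
        )
        inc = incidence_summary(table, {"s1": "g1", "s2": "g2"})
        assert inc.n_total == 2
        assert inc.n_ubiquitous == 1  # b occurs in both groups
        assert inc.n_unique == 1  # a only in g1


class TestRankAbundance:
    def test_sort_and_normalize(self):
        assert rank_abundance([10, 30, 60]).tolist() == pytest.approx([0.6, 0.3, 0.1])

    def test_single(self):
        assert rank_abundance([7]).tolist() == [1.0]

    def test_uniform(self):
        assert rank_abundance([2, 2, 2, 2]).tolist() == pytest.approx([0.25] * 4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rank_abundance([0.0, 0.0])


class TestOTUTable:
    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            OTUTable(["a"], ["s"], np.array([[0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            OTUTable(["a"], ["s"], np.array([[-1]]))

    def test_roundtrip_frame(self):
        t = OTUTable(["a", "b"], ["s1"], np.array([[1], [2]]))
        assert OTUTable.from_frame(t.to_frame()).counts.tolist() == [[1], [2]]
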