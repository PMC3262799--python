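import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mircornet.io import FoldChangeTable, FormatError
from mircornet.validation import (
    over_representation,
    overlap_stats,
    replicated_pairs,
    validate_against_knockout,
)
from oracles import hypergeom_tail


def _sets(n_a, n_b, n_common):
    common = {f"c{i}" for i in range(n_common)}
    a = common | {f"a{i}" for i in range(n_a - n_common)}
    b = common | {f"b{i}" for i in range(n_b - n_common)}
    return a, b


class TestOverlapStats:
    @pytest.mark.parametrize(
        ("n_a", "n_b", "n_common", "expected"),
        [
            (749, 672, 416, 0.41),  # cross-cohort specific genes
            (35, 54, 24, 0.37),     # cross-cohort specific miRNAs
            (6, 21, 4, 0.17),       # miRNAs with significant target overlap
        ],
    )
    def test_published_jaccard_examples(self, n_a, n_b, n_common, expected):
        a, b = _sets(n_a, n_b, n_common)
        ov = overlap_stats(a, b, universe_size=20000)
        assert round(ov.jaccard, 2) == expected
        assert ov.n_common == n_common

    def test_identical_sets(self):
        a = {"x", "y", "z"}
        ov = overlap_stats(a, a, universe_size=100)
        assert ov.jaccard == 1.0
        assert ov.hypergeom_p == pytest.approx(
            hypergeom_tail(100, 3, 3, 3), rel=1e-9
        )

    def test_universe_too_small(self):
        with pytest.raises(FormatError):
            overlap_stats({"a", "b"}, {"c"}, universe_size=2)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30), max_size=15),
        b=st.sets(st.integers(0, 30), max_size=15),
    )
    def test_symmetry(self, a, b):
        ov1 = overlap_stats(a, b, universe_size=31)
        ov2 = overlap_stats(b, a, universe_size=31)
        assert ov1.jaccard == ov2.jaccard
        assert ov1.n_common == ov2.n_common


class TestReplicatedPairs:
    def test_disjoint_and_subset(self):
        a = {("m1", "g1"), ("m2", "g2")}
        b = {("m3", "g3")}
        assert replicated_pairs(a, b) == set()
        c = {("m1", "g1"), ("m3", "g3")}
        inter = replicated_pairs(a, c)
        assert inter <= a and inter <= c
        assert inter == {("m1", "g1")}


class TestKnockoutValidation:
    def _fc_table(self, values):
        return FoldChangeTable(
            pd.DataFrame({"gene": [f"g{i}" for i in range(len(values))],
                          "linear_fc": values})
        )

    def test_published_fraction_example(self):
        """11 responders out of 66 measurable candidates -> 16.7%."""
        values = [1.6] * 4 + [1.4] * 7 + [1.0] * 55 + [1.2] * 100
        fc = self._fc_table(values)
        candidates = {f"g{i}" for i in range(66)}
        background = {f"g{i}" for i in range(166)}
        res = validate_against_knockout(candidates, fc, background, seed=0)
        assert round(100 * res.observed_fraction, 1) == 16.7
        assert res.counts_above[1.3] == 11
        assert res.counts_above[1.5] == 4
        assert res.counts_above[1.5] <= res.counts_above[1.3]

    def test_candidates_equal_background_p_one(self):
        fc = self._fc_table([1.6, 1.4, 1.0, 1.1])
        genes = {"g0", "g1", "g2", "g3"}
        res = validate_against_knockout(genes, fc, genes, n_permutations=200, seed=1)
        assert res.permutation_p == pytest.approx(1.0)

    def test_enriched_candidates_significant(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([np.full(20, 1.8), rng.uniform(0.7, 1.1, 180)])
        fc = self._fc_table(values)
        candidates = {f"g{i}" for i in range(20)}  # exactly the responders
        background = {f"g{i}" for i in range(200)}
        res = validate_against_knockout(candidates, fc, background, seed=3)
        assert res.permutation_p <= 0.01
        res_mean = validate_against_knockout(
            candidates, fc, background, seed=3, statistic="mean_fc"
        )
        assert res_mean.permutation_p <= 0.01

    def test_missing_fc_dropped_with_warning(self):
        fc = self._fc_table([1.6, 1.0])
        with pytest.warns(UserWarning, match="dropped"):
            res = validate_against_knockout(
                {"g0", "g1", "gX"}, fc, {"g0", "g1", "gX"}, n_permutations=50, seed=0
            )
        assert res.n_dropped_no_fc == 1

    def test_permutation_matches_enumeration_on_small_background(self):
        """Exact tail of the fraction statistic by enumerating all draws."""
        values = [1.6, 1.5, 1.4, 1.0, 1.0, 0.9, 1.1, 1.35, 0.8, 1.2]
        fc = self._fc_table(values)
        background = {f"g{i}" for i in range(10)}
        candidates = {"g0", "g1", "g7"}  # 3 of 4 responders
        res = validate_against_knockout(
            candidates, fc, background, n_permutations=20000, seed=4
        )
        above = [v > 1.3 for v in values]
        k = len(candidates)
        draws = list(itertools.combinations(range(10), k))
        exact = sum(
            1 for d in draws if sum(above[i] for i in d) / k >= res.observed_fraction
        ) / len(draws)
        assert res.permutation_p == pytest.approx(exact, abs=0.02)


class TestOverRepresentation:
    def test_term_equal_universe_p_one(self):
        uni = {f"g{i}" for i in range(20)}
        out = over_representation({"g0", "g1"}, {"all": uni}, uni)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_planted_term_ranks_first(self):
        uni = {f"g{i}" for i in range(50)}
        query = {f"g{i}" for i in range(8)}
        annotation = {
            "hit": set(query),
            "broad": {f"g{i}" for i in range(40)},
            "miss": {f"g{i}" for i in range(40, 50)},
        }
        out = over_representation(query, annotation, uni)
        assert out.loc[0, "term"] == "hit"

    def test_matches_hand_computed_tails(self):
        uni = {f"g{i}" for i in range(12)}
        query = {"g0", "g1", "g2", "g3"}
        annotation = {
            "t1": {"g0", "g1", "g5"},
            "t2": {"g4", "g5", "g6", "g7"},
            "t3": {"g0", "g1", "g2", "g8"},
        }
        out = over_representation(query, annotation, uni).set_index("term")
        for term, genes in annotation.items():
            k = len(query & genes)
            expect = hypergeom_tail(12, len(genes), len(query), k)
            assert out.loc[term, "p"] == pytest.approx(expect, rel=1e-9)

    def test_empty_term_skipped(self):
        uni = {"g0", "g1"}
        with pytest.warns(UserWarning, match="empty"):
            out = over_representation({"g0"}, {"empty": set(), "ok": {"g1"}}, uni)
        assert list(out["term"]) == ["ok"]
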