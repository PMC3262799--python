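import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mircornet import qc
from mircornet._stats import bh_adjust, oneway_anova_from_stats, two_sample_t_from_stats
from mircornet.io import ExpressionMatrix, FormatError, SampleMetadata
from mircornet.specificity import (
    SpecificityParams,
    call_specificity,
    summarize_calls,
)
from oracles import brute_force_specificity


def _matrix_meta(values, cell_types, platform="mirna"):
    n_rep = values.shape[1] // len(cell_types)
    sample_ids, meta_rows = [], []
    for ct in cell_types:
        for r in range(n_rep):
            sid = f"{ct}_r{r}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "cell_type": ct, "donor_pool": f"{ct}{r}",
                 "cohort": "A", "scan_batch": "b"}
            )
    df = pd.DataFrame(values, index=[f"t{i}" for i in range(values.shape[0])],
                      columns=sample_ids)
    return ExpressionMatrix(df, platform), SampleMetadata(pd.DataFrame(meta_rows))


class TestVectorizedStats:
    """The summary-statistic formulas must agree with scipy on raw samples."""

    def test_anova_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(0, 3), 1, size=rng.integers(3, 8))
                      for _ in range(4)]
            expect = stats.f_oneway(*groups).pvalue
            got = oneway_anova_from_stats(
                np.array([[g.mean() for g in groups]]),
                np.array([[g.var(ddof=1) for g in groups]]),
                np.array([[len(g) for g in groups]]),
            )[0]
            assert got == pytest.approx(expect, rel=1e-10)

    @pytest.mark.parametrize("equal_var", [False, True])
    def test_t_matches_scipy(self, equal_var):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 9))
            b = rng.normal(0.5, 2, size=rng.integers(3, 9))
            expect = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
            got = two_sample_t_from_stats(
                a.mean(), a.var(ddof=1), len(a),
                b.mean(), b.var(ddof=1), len(b),
                equal_var=equal_var,
            )
            assert float(got) == pytest.approx(expect, rel=1e-10)

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestRuleOrder:
    def test_all_means_equal_no_call(self, toy_scheme):
        m, meta = _matrix_meta(np.full((3, 9), 9.0), toy_scheme.cell_types)
        assert call_specificity(m, meta, toy_scheme) == []

    def test_heterogeneous_top_pair_rejected_at_k2(self, toy_scheme):
        """Two high cell types that differ 4-fold between themselves fail the
        within-top-group homogeneity gate; the k=1 call wins instead."""
        rng = np.random.default_rng(5)
        base = np.concatenate([
            np.full(4, 13.0),  # cA: highest
            np.full(4, 11.0),  # cB: 4-fold below cA but 16-fold above cC
            np.full(4, 7.0),   # cC
        ])
        vals = np.vstack([base + rng.normal(0, 0.05, size=12) for _ in range(3)])
        m, meta = _matrix_meta(vals, toy_scheme.cell_types)
        calls = call_specificity(
            m, meta, toy_scheme, SpecificityParams(min_fold_change_linear=4.0)
        )
        assert calls, "expected k=1 calls"
        for c in [c for c in calls if c.direction == "up"]:
            assert c.k == 1
            assert c.specific_cell_types == ("cA",)

    def test_planted_cohort_recovery(self, cohort, scheme):
        truth = cohort.truth.specific_transcripts
        ok = tot = 0
        for matrix in (cohort.mirna, cohort.mrna):
            det = qc.detection_filter(matrix, cohort.metadata, scheme)
            calls = call_specificity(
                matrix.subset_transcripts(det.kept_transcripts), cohort.metadata, scheme
            )
            by_key = {(c.transcript, c.direction): c for c in calls}
            for r in truth[truth.platform == matrix.platform].itertuples():
                tot += 1
                c = by_key.get((r.transcript, r.direction))
                if c and c.k == r.k and set(c.specific_cell_types) == set(r.cell_types):
                    ok += 1
        assert ok / tot >= 0.9

    def test_monotone_in_fold_change_gate(self, cohort, scheme):
        det = qc.detection_filter(cohort.mrna, cohort.metadata, scheme)
        matrix = cohort.mrna.subset_transcripts(det.kept_transcripts)
        n_calls = []
        for fc in (1.0, 2.0, 4.0, 8.0, 32.0):
            params = SpecificityParams(min_fold_change_linear=fc)
            n_calls.append(len(call_specificity(matrix, cohort.metadata, scheme, params)))
        assert n_calls == sorted(n_calls, reverse=True)

    def test_duplicate_sample_keeps_rankings(self, cohort, scheme):
        matrix = cohort.mirna
        dup = matrix.data.copy()
        src = matrix.sample_ids[0]
        dup["dup_sample"] = dup[src]
        meta2 = cohort.metadata.data.copy()
        row = meta2[meta2.sample_id == src].iloc[0].to_dict()
        row["sample_id"] = "dup_sample"
        meta2 = pd.concat([meta2, pd.DataFrame([row])], ignore_index=True)
        m2 = ExpressionMatrix(dup, "mirna")
        means1 = qc.cell_type_means(matrix, cohort.metadata, scheme)
        means2 = qc.cell_type_means(m2, SampleMetadata(meta2), scheme)
        # a single duplicate can reorder noise-level ties; the separated part
        # of the ranking — the specific top-k set — must be unchanged
        truth = cohort.truth.specific_transcripts
        sub = truth[(truth.platform == "mirna") & (truth.direction == "up")]
        for r in sub.itertuples():
            for means in (means1, means2):
                row = means.loc[r.transcript]
                top = set(row.sort_values(ascending=False).index[: r.k])
                assert top == set(r.cell_types)

    def test_cell_type_with_one_sample_rejected(self, toy_scheme):
        vals = np.random.default_rng(0).normal(8, 1, size=(2, 7))
        sample_ids = [f"s{i}" for i in range(7)]
        cts = ["cA"] * 3 + ["cB"] * 3 + ["cC"]  # cC has a single sample
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": sample_ids, "cell_type": cts,
            "donor_pool": sample_ids, "cohort": "A", "scan_batch": "b",
        }))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=["t0", "t1"], columns=sample_ids), "mirna"
        )
        with pytest.raises(FormatError, match="cC"):
            call_specificity(m, meta, toy_scheme)


class TestBruteForceEquivalence:
    """On small instances the vectorized classifier must match an exhaustive
    naive evaluation of the rule hierarchy."""

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_oracle(self, toy_scheme, seed):
        rng = np.random.default_rng(seed)
        n_t = int(rng.integers(2, 5))
        # draw means from separated levels so boundary tests are exercised
        means = rng.choice([6.0, 7.5, 9.0, 12.0], size=(n_t, 3))
        vals = np.repeat(means, 4, axis=1) + rng.normal(0, 0.4, size=(n_t, 12))
        m, meta = _matrix_meta(vals, toy_scheme.cell_types)
        params = SpecificityParams(min_fold_change_linear=1.0)
        got = {
            (c.transcript, c.direction, c.k, c.specific_cell_types)
            for c in call_specificity(m, meta, toy_scheme, params)
        }
        expect = brute_force_specificity(m, meta, toy_scheme, params)
        assert got == expect


class TestSummaries:
    def test_empty_calls_zero_table(self):
        out = summarize_calls([])
        assert out["by_k"]["total"].sum() == 0
        assert out["by_cell_type"].empty

    def test_totals_conserved(self, cohort, scheme):
        det = qc.detection_filter(cohort.mirna, cohort.metadata, scheme)
        calls = call_specificity(
            cohort.mirna.subset_transcripts(det.kept_transcripts),
            cohort.metadata, scheme,
        )
        by_k = summarize_calls(calls)["by_k"]
        body = by_k[by_k["k"] != "Total"]
        total = by_k[by_k["k"] == "Total"]
        assert total["total"].sum() == body["total"].sum() == len(calls)
        assert (body["up"] + body["down"] == body["total"]).all()
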