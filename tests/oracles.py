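"""Independent brute-force oracles used by the test suite.

These deliberately take the naive route — per-transcript loops over raw
sample groups with scipy/statsmodels calls — so that they share no code with
the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mircornet.io import CellTypeScheme, ExpressionMatrix, SampleMetadata
from mircornet.specificity import SpecificityParams


def brute_force_specificity(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    scheme: CellTypeScheme,
    params: SpecificityParams,
) -> set[tuple[str, str, int, tuple[str, ...]]]:
    """Exhaustive per-transcript evaluation of the specificity rules.

    Returns the set of (transcript, direction, k, specific cell types).
    """
    ct_of = meta.cell_type_of()
    cts = sorted(scheme.cell_types)
    groups = {
        ct: [
            j
            for j, s in enumerate(matrix.sample_ids)
            if scheme.analysis_label(ct_of[s]) == ct
        ]
        for ct in cts
    }
    vals = matrix.values
    transcripts = matrix.transcript_ids
    n_t = len(transcripts)

    def samples(i: int, ct: str) -> np.ndarray:
        return vals[i, groups[ct]]

    # overall gate: one-way ANOVA across all groups, BH across transcripts
    if params.require_overall_anova:
        p_overall = []
        for i in range(n_t):
            groups_i = [samples(i, ct) for ct in cts]
            p = stats.f_oneway(*groups_i).pvalue
            p_overall.append(1.0 if np.isnan(p) else p)
        gate = multipletests(p_overall, method="fdr_bh")[1] < params.alpha
    else:
        gate = np.ones(n_t, dtype=bool)

    max_k = min(params.max_k, len(cts) - 1)
    found: set[tuple[str, str, int, tuple[str, ...]]] = set()
    for direction in ("up", "down"):
        # ranking with lexical tie-break (cts is lexically sorted)
        rankings = []
        for i in range(n_t):
            means = [np.mean(samples(i, ct)) for ct in cts]
            key = sorted(
                range(len(cts)),
                key=lambda j: (-means[j] if direction == "up" else means[j], j),
            )
            rankings.append([cts[j] for j in key])

        # raw boundary p per (transcript, k), BH per k over gated transcripts
        adj = {}
        for k in range(1, max_k + 1):
            raw = []
            for i in range(n_t):
                a = samples(i, rankings[i][k - 1])
                b = samples(i, rankings[i][k])
                p = stats.ttest_ind(a, b, equal_var=params.boundary_equal_var).pvalue
                raw.append(1.0 if np.isnan(p) else p)
            p_adj = np.full(n_t, np.nan)
            idx = np.flatnonzero(gate)
            if len(idx):
                p_adj[idx] = multipletests(np.asarray(raw)[idx], method="fdr_bh")[1]
            adj[k] = p_adj

        for i in range(n_t):
            if not gate[i]:
                continue
            for k in range(1, max_k + 1):
                top = rankings[i][:k]
                rest = rankings[i][k:]
                m_k = np.mean(samples(i, rankings[i][k - 1]))
                m_next = np.mean(samples(i, rankings[i][k]))
                if direction == "up":
                    detected = all(
                        np.mean(samples(i, ct)) >= params.detection_threshold for ct in top
                    )
                    fc = 2.0 ** (m_k - m_next)
                else:
                    detected = all(
                        np.mean(samples(i, ct)) >= params.detection_threshold for ct in rest
                    )
                    fc = 2.0 ** (m_next - m_k)
                if not detected or fc < params.min_fold_change_linear:
                    continue
                if np.isnan(adj[k][i]) or adj[k][i] >= params.alpha:
                    continue
                if k >= 2 and params.require_top_homogeneity:
                    p_hom = stats.f_oneway(*[samples(i, ct) for ct in top]).pvalue
                    if np.isnan(p_hom):
                        p_hom = 1.0
                    if p_hom < params.alpha:
                        continue
                found.add((transcripts[i], direction, k, tuple(sorted(top))))
                break
    return found


def brute_force_collapse(
    regulators: list[tuple[str, list[tuple[str, int, int]]]],
) -> tuple[list[str], list[list[str]]]:
    """Naive transitive-closure grouping of seed-similar regulators."""
    def overlap(a, b):
        return a[0] == b[0] and max(a[1], b[1]) < min(a[2], b[2])

    def similar(sa, sb):
        fwd = all(any(overlap(x, y) for y in sb) for x in sa)
        rev = all(any(overlap(y, x) for x in sa) for y in sb)
        return bool(sa) and bool(sb) and fwd and rev

    names = [m for m, _ in regulators]
    sites = {m: s for m, s in regulators}
    parent = {m: m for m in names}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if similar(sites[a], sites[b]):
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for m in names:
        comps.setdefault(find(m), []).append(m)
    kept = sorted(min(v) for v in comps.values())
    groups = sorted(sorted(v) for v in comps.values() if len(v) > 1)
    return kept, groups


def hypergeom_tail(universe: int, n_marked: int, n_drawn: int, at_least: int) -> float:
    """Exact P[X >= at_least] for X ~ Hypergeom, by direct summation."""
    from math import comb

    total = comb(universe, n_drawn)
    hi = min(n_marked, n_drawn)
    return sum(
        comb(n_marked, x) * comb(universe - n_marked, n_drawn - x) for x in range(at_least, hi + 1)
    ) / total
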