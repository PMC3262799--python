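"""Calling transcripts specifically up- or down-regulated in 1-3 cell types.

For each transcript the analysis cell types are ranked by mean log2
expression.  A transcript is called *up-specific to the top k cell types*
(k = 1, 2, 3, smallest k wins) when

(a) every one of the top-k cell types is expressed above the detection floor,
(b) expression differences *within* the top-k group are insignificant
    (one-way ANOVA, unadjusted p >= alpha; vacuous for k = 1),
(c) the boundary comparison between the k-th and (k+1)-th ranked cell types
    is significant after Benjamini-Hochberg adjustment across transcripts
    (the adjusted value is reported as ``boundary_p_adj``), and
(d) the linear fold change across that boundary, ``2**(mean_k - mean_{k+1})``,
    reaches the platform's fold gate (4-fold for mRNA; disabled for miRNA,
    where few transcripts show marked fold differentials).

Down-specific calls mirror the procedure on ascending ranks, with the
detection requirement applied to all *non*-specific cell types instead.
An optional overall one-way ANOVA across all cell types (BH-adjusted across
transcripts) gates entry into the hierarchy.

The boundary test defaults to a Welch two-sample t between the samples of the
two boundary cell types (a pooled-variance variant is available); BH
adjustment is applied within each (direction, k) family of boundary tests,
over the transcripts that passed the overall gate.  Ties in mean expression
are broken by lexical cell-type order, making the ranking deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, oneway_anova_from_stats, two_sample_t_from_stats
from .io import CellTypeScheme, ExpressionMatrix, FormatError, SampleMetadata
from .qc import DETECTION_THRESHOLD

__all__ = [
    "SpecificityParams",
    "SpecificityCall",
    "call_specificity",
    "calls_to_frame",
    "summarize_calls",
]


@dataclass(frozen=True)
class SpecificityParams:
    """Tunable thresholds of the specificity classifier."""

    alpha: float = 0.05
    min_fold_change_linear: float = 1.0
    detection_threshold: float = DETECTION_THRESHOLD
    max_k: int = 3
    require_overall_anova: bool = True
    require_top_homogeneity: bool = True
    boundary_equal_var: bool = False  # False -> Welch t

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold_change_linear < 1.0:
            raise ValueError("min_fold_change_linear must be >= 1")
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")

    @classmethod
    def for_platform(cls, platform: str, **overrides) -> "SpecificityParams":
        """Platform defaults: a 4-fold gate for mRNA, none for miRNA."""
        fc = 4.0 if platform == "mrna" else 1.0
        overrides.setdefault("min_fold_change_linear", fc)
        return cls(**overrides)


@dataclass
class SpecificityCall:
    """One transcript's cell-type specificity classification.

    ``boundary_fold_change`` is the linear ratio between the k-th and
    (k+1)-th ranked cell types; ``boundary_p_adj`` its BH-adjusted p-value.
    """

    transcript: str
    platform: str
    direction: str  # "up" | "down"
    k: int
    specific_cell_types: tuple[str, ...]
    boundary_fold_change: float
    boundary_p: float
    boundary_p_adj: float
    cell_type_means: dict[str, float] = field(default_factory=dict)


def _group_stats(
    matrix: ExpressionMatrix, meta: SampleMetadata, scheme: CellTypeScheme
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-analysis-cell-type means/vars/counts, columns in lexical order."""
    meta.require_cover(matrix.sample_ids)
    ct_of = meta.cell_type_of()
    labels = np.asarray(
        [scheme.analysis_label(ct_of[s]) for s in matrix.sample_ids]
    )
    cts = sorted(scheme.cell_types)
    vals = matrix.values
    means, varis, counts = [], [], []
    for ct in cts:
        sel = labels == ct
        n = int(sel.sum())
        if n < 2:
            raise FormatError(
                f"cell type {ct!r} has {n} sample(s); >=2 required for variance"
            )
        sub = vals[:, sel]
        means.append(sub.mean(axis=1))
        varis.append(sub.var(axis=1, ddof=1))
        counts.append(n)
    return cts, np.column_stack(means), np.column_stack(varis), np.asarray(counts, float)


def call_specificity(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    scheme: CellTypeScheme,
    params: SpecificityParams | None = None,
) -> list[SpecificityCall]:
    """Classify every transcript's cell-type specificity.

    Returns at most one up and one down call per transcript (smallest k wins
    within each direction).  See the module docstring for the rule order.
    """
    if params is None:
        params = SpecificityParams.for_platform(matrix.platform)
    cts, means, varis, counts = _group_stats(matrix, meta, scheme)
    n_t, g = means.shape
    if g < 2:
        raise FormatError("specificity calling needs >=2 analysis cell types")
    max_k = min(params.max_k, g - 1)

    if params.require_overall_anova:
        counts_b = np.broadcast_to(counts, means.shape)
        p_overall = oneway_anova_from_stats(means, varis, counts_b)
        gate = bh_adjust(p_overall) < params.alpha
    else:
        gate = np.ones(n_t, dtype=bool)

    calls: list[SpecificityCall] = []
    for direction in ("up", "down"):
        # stable argsort breaks mean ties by lexical cell-type order
        order = np.argsort(-means if direction == "up" else means, axis=1, kind="stable")
        r_means = np.take_along_axis(means, order, axis=1)
        r_vars = np.take_along_axis(varis, order, axis=1)
        r_counts = counts[order]

        chosen = np.full(n_t, -1, dtype=int)
        chosen_p = np.full(n_t, np.nan)
        chosen_p_adj = np.full(n_t, np.nan)
        chosen_fc = np.full(n_t, np.nan)
        for k in range(1, max_k + 1):
            p_raw = two_sample_t_from_stats(
                r_means[:, k - 1], r_vars[:, k - 1], r_counts[:, k - 1],
                r_means[:, k], r_vars[:, k], r_counts[:, k],
                equal_var=params.boundary_equal_var,
            )
            p_adj = np.full(n_t, np.nan)
            if gate.any():
                p_adj[gate] = bh_adjust(p_raw[gate])
            if direction == "up":
                detected = r_means[:, :k].min(axis=1) >= params.detection_threshold
                log_fc = r_means[:, k - 1] - r_means[:, k]
            else:
                detected = r_means[:, k:].min(axis=1) >= params.detection_threshold
                log_fc = r_means[:, k] - r_means[:, k - 1]
            fc = np.exp2(log_fc)
            ok = gate & detected & (fc >= params.min_fold_change_linear)
            ok &= np.where(np.isnan(p_adj), False, p_adj < params.alpha)
            if k >= 2 and params.require_top_homogeneity:
                p_hom = oneway_anova_from_stats(
                    r_means[:, :k], r_vars[:, :k], r_counts[:, :k]
                )
                ok &= p_hom >= params.alpha
            new = ok & (chosen < 0)
            chosen[new] = k
            chosen_p[new] = p_raw[new]
            chosen_p_adj[new] = p_adj[new]
            chosen_fc[new] = fc[new]

        cts_arr = np.asarray(cts)
        for i in np.flatnonzero(chosen > 0):
            k = int(chosen[i])
            spec = tuple(sorted(cts_arr[order[i, :k]]))
            calls.append(
                SpecificityCall(
                    transcript=matrix.transcript_ids[i],
                    platform=matrix.platform,
                    direction=direction,
                    k=k,
                    specific_cell_types=spec,
                    boundary_fold_change=float(chosen_fc[i]),
                    boundary_p=float(chosen_p[i]),
                    boundary_p_adj=float(chosen_p_adj[i]),
                    cell_type_means={ct: float(means[i, j]) for j, ct in enumerate(cts)},
                )
            )
    calls.sort(key=lambda c: (c.transcript, c.direction))
    return calls


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    """Flat table of calls: one row per call, Table-1-like columns."""
    rows = []
    for c in calls:
        rows.append(
            {
                "transcript": c.transcript,
                "platform": c.platform,
                "direction": c.direction,
                "k": c.k,
                "specific_cell_types": ";".join(c.specific_cell_types),
                "fold_change": round(c.boundary_fold_change, 2),
                "p_raw": c.boundary_p,
                "p_adj": c.boundary_p_adj,
                "log2_expression": ";".join(
                    f"{c.cell_type_means[ct]:.2f}" for ct in c.specific_cell_types
                ),
            }
        )
    cols = [
        "transcript", "platform", "direction", "k", "specific_cell_types",
        "fold_change", "p_raw", "p_adj", "log2_expression",
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_calls(calls: list[SpecificityCall]) -> dict[str, pd.DataFrame]:
    """Contingency summaries of a call list.

    ``by_k``: up/down/total counts per (platform, k), with a Total row per
    platform.  ``by_cell_type``: up/down counts of single-cell-type (k=1)
    calls per cell type and platform.
    """
    platforms = sorted({c.platform for c in calls}) or ["mirna", "mrna"]
    k_rows = []
    for plat in platforms:
        sub = [c for c in calls if c.platform == plat]
        for k in (1, 2, 3):
            up = sum(1 for c in sub if c.k == k and c.direction == "up")
            down = sum(1 for c in sub if c.k == k and c.direction == "down")
            k_rows.append(
                {"platform": plat, "k": str(k), "up": up, "down": down, "total": up + down}
            )
        tot_up = sum(r["up"] for r in k_rows if r["platform"] == plat)
        tot_down = sum(r["down"] for r in k_rows if r["platform"] == plat)
        k_rows.append(
            {"platform": plat, "k": "Total", "up": tot_up, "down": tot_down,
             "total": tot_up + tot_down}
        )
    by_k = pd.DataFrame(k_rows, columns=["platform", "k", "up", "down", "total"])

    ct_counter: Counter[tuple[str, str, str]] = Counter()
    for c in calls:
        if c.k == 1:
            ct_counter[(c.platform, c.specific_cell_types[0], c.direction)] += 1
    ct_rows = []
    for plat in platforms:
        cell_types = sorted({ct for (p, ct, _), _ in ct_counter.items() if p == plat})
        for ct in cell_types:
            ct_rows.append(
                {
                    "platform": plat,
                    "cell_type": ct,
                    "up": ct_counter.get((plat, ct, "up"), 0),
                    "down": ct_counter.get((plat, ct, "down"), 0),
                }
            )
    by_ct = pd.DataFrame(ct_rows, columns=["platform", "cell_type", "up", "down"])
    return {"by_k": by_k, "by_cell_type": by_ct}
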