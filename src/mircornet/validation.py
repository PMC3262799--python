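"""Cross-cohort agreement statistics, knockout fold-change validation and a
generic over-representation test.

Cross-cohort agreement between two transcript or pair sets is summarized by
the Jaccard coefficient |A∩B| / |A∪B| together with a hypergeometric
upper-tail p-value for the observed overlap given a stated universe size
(the universe must be supplied; it is not inferable from the sets).

Knockout validation asks whether candidate target genes respond to removal
of their regulator more often than same-sized random draws from the
predicted-target background: the statistic is the fraction of candidates
with linear fold change above the primary threshold (default 1.3, with a
secondary 1.5 bin reported), and its permutation p-value uses add-one
smoothing over same-size background draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import FoldChangeTable, FormatError

__all__ = [
    "OverlapStats",
    "KnockoutValidation",
    "overlap_stats",
    "replicated_pairs",
    "validate_against_knockout",
    "over_representation",
]


@dataclass
class OverlapStats:
    n_a: int
    n_b: int
    n_common: int
    jaccard: float
    hypergeom_p: float
    universe_size: int


def overlap_stats(set_a: set, set_b: set, universe_size: int) -> OverlapStats:
    """Jaccard coefficient and hypergeometric overlap p for two sets.

    ``hypergeom_p`` is the upper-tail probability of observing at least the
    realized overlap when |A| items are marked in a universe of
    ``universe_size`` and |B| are drawn without replacement.
    """
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if universe_size < len(union):
        raise FormatError(
            f"universe size {universe_size} smaller than union {len(union)}"
        )
    n_common = len(set_a & set_b)
    jaccard = n_common / len(union) if union else 0.0
    p = float(
        stats.hypergeom.sf(n_common - 1, universe_size, len(set_a), len(set_b))
    )
    return OverlapStats(
        n_a=len(set_a),
        n_b=len(set_b),
        n_common=n_common,
        jaccard=jaccard,
        hypergeom_p=p,
        universe_size=universe_size,
    )


def replicated_pairs(
    pairs_a: set[tuple[str, str]], pairs_b: set[tuple[str, str]]
) -> set[tuple[str, str]]:
    """miRNA->gene pairs present in both cohorts (exact intersection)."""
    return set(pairs_a) & set(pairs_b)


@dataclass
class KnockoutValidation:
    """Outcome of the knockout fold-change validation."""

    candidate_genes: list[str]
    background_genes: list[str]
    fc_thresholds: tuple[float, ...]
    counts_above: dict[float, int]
    observed_fraction: float  # fraction of candidates above the primary threshold
    permutation_p: float
    n_permutations: int
    seed: int | None
    n_dropped_no_fc: int


def validate_against_knockout(
    candidates: set[str],
    fc: FoldChangeTable,
    background: set[str],
    thresholds: tuple[float, ...] = (1.3, 1.5),
    n_permutations: int = 1000,
    seed: int | None = None,
    statistic: str = "fraction",
) -> KnockoutValidation:
    """Compare candidate targets' knockout response against random
    same-sized draws from the predicted-target background.

    Genes without fold-change data are dropped with a warning (e.g. targets
    lacking a homolog in the knockout organism).  The test statistic is the
    fraction of candidates above the primary (smallest) threshold, or with
    ``statistic="mean_fc"`` the candidates' mean linear fold change; the
    permutation p is the add-one-smoothed fraction of draws whose statistic
    reaches the observed one.
    """
    if statistic not in ("fraction", "mean_fc"):
        raise ValueError(f"unknown statistic {statistic!r}")
    fc_map = fc.as_series()
    candidates = set(candidates)
    background = set(background)
    if not candidates <= background:
        raise FormatError("candidates must be a subset of the background")
    bg = sorted(background & set(fc_map.index))
    cand = sorted(candidates & set(fc_map.index))
    n_dropped = len(candidates) - len(cand)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} candidate gene(s) lack fold-change data and were dropped",
            stacklevel=2,
        )
    if not cand:
        raise FormatError("no candidate genes with fold-change data")
    thresholds = tuple(sorted(thresholds))
    cand_fc = fc_map[cand].to_numpy()
    counts = {t: int(np.count_nonzero(cand_fc > t)) for t in thresholds}
    primary = thresholds[0]
    observed = counts[primary] / len(cand)

    bg_fc = fc_map[bg].to_numpy()
    rng = np.random.default_rng(seed)
    k = len(cand)
    hits = 0
    per_gene = (bg_fc > primary).astype(float) if statistic == "fraction" else bg_fc
    observed_stat = observed if statistic == "fraction" else float(cand_fc.mean())
    for _ in range(n_permutations):
        draw = rng.choice(len(bg), size=k, replace=False)
        if per_gene[draw].mean() >= observed_stat:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return KnockoutValidation(
        candidate_genes=cand,
        background_genes=bg,
        fc_thresholds=thresholds,
        counts_above=counts,
        observed_fraction=observed,
        permutation_p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        n_dropped_no_fc=n_dropped,
    )


def over_representation(
    gene_set: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` in each annotation
    term, BH-adjusted across terms.

    Terms with an empty gene set are skipped with a warning.  Input sets must
    be subsets of the universe.
    """
    universe = set(universe)
    gene_set = set(gene_set) & universe
    if not set().union(*annotation.values(), gene_set) <= universe:
        raise FormatError("annotation terms or query extend beyond the universe")
    rows = []
    for term, genes in annotation.items():
        genes = set(genes)
        if not genes:
            warnings.warn(f"term {term!r} has an empty gene set; skipped", stacklevel=2)
            continue
        k = len(gene_set & genes)
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(genes), len(gene_set))
        )
        rows.append({"term": term, "n_term": len(genes), "n_overlap": k, "p": p})
    df = pd.DataFrame(rows, columns=["term", "n_term", "n_overlap", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "term"]).reset_index(drop=True)
    else:
        df["p_adj"] = []
    return df
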