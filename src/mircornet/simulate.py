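"""Synthetic cohort generator with planted cell-type-specific transcripts and
planted miRNA->mRNA repression couplings.

The generator emulates the structure of a sorted-immune-cell profiling study:
eight analysis cell types in two hematopoietic lineages (myeloid: neutrophils,
eosinophils, monocytes, mDC; lymphoid: T, B, NK, pDC), a handful of replicate
donor pools per type, RMA-like log2 signal with a detection floor, transcripts
specifically up- or down-regulated in 1, 2 or 3 cell types (3-type patterns
are lineage-coherent), and target genes whose cell-type profile is depressed
in proportion to their regulator miRNA's standardized profile.  A prediction
table carries all true couplings plus expression-independent decoys, and a
truth table records everything planted so downstream stages can be scored.

Noise is Gaussian on the log2 scale, the standard behaviour of RMA-normalized
signal.  Donor pooling chemistry, probe-level artifacts and batch effects are
not simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    LYMPHOID,
    MYELOID,
    CellTypeScheme,
    ExpressionMatrix,
    SampleMetadata,
    TargetPredictionTable,
)

__all__ = ["SimulationConfig", "TruthTables", "CohortData", "simulate_cohort", "simulate_second_cohort"]


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


DEFAULT_CELL_TYPES = MYELOID + LYMPHOID


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Counts in ``n_up_per_k`` / ``n_down_per_k`` are per platform and indexed
    by k-1 (number of specific cell types).  ``coupling_beta`` is the log2
    depression of a target gene's cell-type mean per unit of its regulator's
    standardized cell-type profile.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_pools_per_type: int = 5
    n_mirna: int = 60
    n_mrna: int = 300
    background_mean: float = 5.0
    background_fraction: float = 0.2
    expressed_mean_range: tuple[float, float] = (8.0, 12.0)
    noise_sd: float = 0.5
    specificity_shift: float = 3.0
    n_up_per_k: tuple[int, int, int] = (10, 5, 5)
    n_down_per_k: tuple[int, int, int] = (4, 2, 2)
    coupling_beta: float = 1.0
    n_true_links_per_mirna: int = 5
    n_decoy_predictions_per_mirna: int = 5
    n_decoy_only_mirnas: int = 5
    n_hub_genes: int = 4
    n_regulators_per_hub: int = 3
    cohort: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if any(c < 0 for c in self.n_up_per_k + self.n_down_per_k):
            raise ConfigError("planted counts must be >= 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ConfigError("background_fraction must be in [0, 1)")
        if self.n_pools_per_type < 2:
            raise ConfigError("need >=2 pools per cell type for variance estimates")
        if len(self.cell_types) == 0:
            raise ConfigError("cell_types must be non-empty")
        unknown = set(self.cell_types) - set(DEFAULT_CELL_TYPES)
        if unknown:
            raise ConfigError(f"unknown cell type(s): {sorted(unknown)}")
        layout = _role_layout(self)
        if layout.mirna_flat_start > self.n_mirna:
            raise ConfigError(
                "n_mirna too small for requested specific + decoy-only transcripts"
            )
        if layout.mrna_flat_start > self.n_mrna:
            raise ConfigError(
                "n_mrna too small for requested specific + coupled transcripts"
            )
        n_flat_mrna = self.n_mrna - layout.mrna_flat_start
        n_bg = int(self.background_fraction * n_flat_mrna)
        if self.n_decoy_predictions_per_mirna > n_flat_mrna - n_bg:
            raise ConfigError("not enough uncoupled expressed genes for decoys")
        # lineage-coherent k=3 patterns need >=3 types in some lineage
        if self.n_up_per_k[2] or self.n_down_per_k[2]:
            if not any(
                sum(ct in lin for ct in self.cell_types) >= 3
                for lin in (MYELOID, LYMPHOID)
            ):
                raise ConfigError("k=3 patterns need >=3 cell types in one lineage")

    def scheme(self) -> CellTypeScheme:
        full = CellTypeScheme.immune_default()
        return full.restrict(self.cell_types)


@dataclass
class TruthTables:
    """Ground truth of everything planted by the generator."""

    specific_transcripts: pd.DataFrame  # transcript, platform, direction, k, cell_types
    true_links: set[tuple[str, str]]
    decoy_links: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.true_links & self.decoy_links:
            raise ConfigError("true and decoy links overlap")

    def specific_mirnas(self) -> set[str]:
        df = self.specific_transcripts
        return set(df.loc[df["platform"] == "mirna", "transcript"])


class CohortData(NamedTuple):
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    metadata: SampleMetadata
    predictions: TargetPredictionTable
    truth: TruthTables


@dataclass(frozen=True)
class _Layout:
    """Deterministic index blocks for transcript roles (independent of RNG)."""

    mirna_up_blocks: tuple[tuple[int, int], ...]  # per k: [start, stop)
    mirna_down_blocks: tuple[tuple[int, int], ...]
    mirna_decoy_only: tuple[int, int]
    mirna_flat_start: int
    mrna_up_blocks: tuple[tuple[int, int], ...]
    mrna_down_blocks: tuple[tuple[int, int], ...]
    mrna_coupled: tuple[int, int]
    mrna_hubs: tuple[int, int]
    mrna_flat_start: int


def _blocks(start: int, counts: tuple[int, int, int]) -> tuple[tuple[tuple[int, int], ...], int]:
    out = []
    for c in counts:
        out.append((start, start + c))
        start += c
    return tuple(out), start


def _role_layout(config: SimulationConfig) -> _Layout:
    up_mi, pos = _blocks(0, config.n_up_per_k)
    down_mi, pos = _blocks(pos, config.n_down_per_k)
    decoy_only = (pos, pos + config.n_decoy_only_mirnas)
    mirna_flat_start = decoy_only[1]

    up_m, pos = _blocks(0, config.n_up_per_k)
    down_m, pos = _blocks(pos, config.n_down_per_k)
    n_coupled = sum(config.n_up_per_k) * config.n_true_links_per_mirna
    coupled = (pos, pos + n_coupled)
    hubs = (coupled[1], coupled[1] + config.n_hub_genes)
    return _Layout(
        mirna_up_blocks=up_mi,
        mirna_down_blocks=down_mi,
        mirna_decoy_only=decoy_only,
        mirna_flat_start=mirna_flat_start,
        mrna_up_blocks=up_m,
        mrna_down_blocks=down_m,
        mrna_coupled=coupled,
        mrna_hubs=hubs,
        mrna_flat_start=hubs[1],
    )


def _mirna_names(n: int) -> list[str]:
    return [f"miR-sim-{i:03d}" for i in range(1, n + 1)]


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def _draw_specific_types(
    rng: np.random.Generator, k: int, cell_types: tuple[str, ...]
) -> tuple[str, ...]:
    """Choose k specific cell types; k=3 patterns stay within one lineage."""
    if k < 3:
        idx = rng.choice(len(cell_types), size=k, replace=False)
        return tuple(sorted(cell_types[i] for i in idx))
    lineages = [
        [ct for ct in cell_types if ct in lin]
        for lin in (MYELOID, LYMPHOID)
    ]
    lineages = [lin for lin in lineages if len(lin) >= 3]
    lin = lineages[int(rng.integers(len(lineages)))]
    idx = rng.choice(len(lin), size=3, replace=False)
    return tuple(sorted(lin[i] for i in idx))


def _plant_specifics(
    rng: np.random.Generator,
    names: list[str],
    blocks_up: tuple[tuple[int, int], ...],
    blocks_down: tuple[tuple[int, int], ...],
    platform: str,
    cell_types: tuple[str, ...],
) -> list[dict]:
    rows = []
    for direction, blocks in (("up", blocks_up), ("down", blocks_down)):
        for k, (start, stop) in enumerate(blocks, start=1):
            for i in range(start, stop):
                rows.append(
                    {
                        "transcript": names[i],
                        "platform": platform,
                        "direction": direction,
                        "k": k,
                        "cell_types": _draw_specific_types(rng, k, cell_types),
                    }
                )
    return rows


def _mean_matrix(
    rng: np.random.Generator,
    n: int,
    cell_types: tuple[str, ...],
    config: SimulationConfig,
    spec_rows: list[dict],
    names: list[str],
    flat_start: int,
) -> np.ndarray:
    """Per-transcript, per-cell-type planted means (before coupling)."""
    lo, hi = config.expressed_mean_range
    base = rng.uniform(lo, hi, size=n)
    means = np.tile(base[:, None], (1, len(cell_types)))
    ct_index = {ct: j for j, ct in enumerate(cell_types)}
    name_index = {t: i for i, t in enumerate(names)}
    for row in spec_rows:
        i = name_index[row["transcript"]]
        sign = 1.0 if row["direction"] == "up" else -1.0
        for ct in row["cell_types"]:
            means[i, ct_index[ct]] = base[i] + sign * config.specificity_shift
    # trailing fraction of the flat block sits at background level
    n_flat = n - flat_start
    n_bg = int(config.background_fraction * n_flat)
    if n_bg > 0:
        means[n - n_bg :, :] = config.background_mean
    return means


def _standardized_profile(profile: np.ndarray) -> np.ndarray:
    sd = profile.std(ddof=1)
    if sd == 0:
        return np.zeros_like(profile)
    return (profile - profile.mean()) / sd


def _sample_values(
    rng: np.random.Generator,
    means: np.ndarray,
    sample_ct_idx: np.ndarray,
    noise_sd: float,
) -> np.ndarray:
    base = means[:, sample_ct_idx]
    return base + rng.normal(0.0, noise_sd, size=base.shape)


def _make_metadata(config: SimulationConfig) -> SampleMetadata:
    rows = []
    for ct in config.cell_types:
        for p in range(1, config.n_pools_per_type + 1):
            rows.append(
                {
                    "sample_id": f"{config.cohort}_{ct}_p{p}",
                    "cell_type": ct,
                    "donor_pool": f"{ct}_pool{p}",
                    "cohort": config.cohort,
                    "scan_batch": "batch1",
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


def _build_predictions(
    true_links: set[tuple[str, str]], decoy_links: set[tuple[str, str]]
) -> TargetPredictionTable:
    """Deterministic prediction table from link sets.

    Each regulator of a gene receives a distinct, non-overlapping synthetic
    seed interval on that gene's own coordinate system, so the table is
    identical however the links were produced (true or decoy, cohort A or B).
    """
    by_gene: dict[str, list[str]] = {}
    for m, g in sorted(true_links | decoy_links):
        by_gene.setdefault(g, []).append(m)
    rows = []
    for gene in sorted(by_gene):
        for j, mirna in enumerate(sorted(by_gene[gene])):
            start = 100 + 50 * j
            rows.append(
                {
                    "mirna_family": mirna,
                    "gene": gene,
                    "site_chrom": gene,
                    "site_start": start,
                    "site_end": start + 7,
                    "sources": frozenset({"targetscan", "mirdb"}),
                }
            )
    cols = ["mirna_family", "gene", "site_chrom", "site_start", "site_end", "sources"]
    return TargetPredictionTable(pd.DataFrame(rows, columns=cols))


def _lineage_of(cell_types: tuple[str, ...]) -> str | None:
    if cell_types and all(ct in MYELOID for ct in cell_types):
        return "myeloid"
    if cell_types and all(ct in LYMPHOID for ct in cell_types):
        return "lymphoid"
    return None


def _plan_links(
    rng: np.random.Generator,
    config: SimulationConfig,
    layout: _Layout,
    mirna_names: list[str],
    gene_names: list[str],
    mi_spec_rows: list[dict],
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Assign coupled target genes (disjoint per miRNA), lineage-coherent hub
    genes co-targeted by several miRNAs, and decoy predictions."""
    up_mirnas = [
        mirna_names[i]
        for start, stop in layout.mirna_up_blocks
        for i in range(start, stop)
    ]
    coupled_genes = gene_names[layout.mrna_coupled[0] : layout.mrna_coupled[1]]
    true_links: set[tuple[str, str]] = set()
    pos = 0
    for m in up_mirnas:
        for g in coupled_genes[pos : pos + config.n_true_links_per_mirna]:
            true_links.add((m, g))
        pos += config.n_true_links_per_mirna

    # hub genes: co-targeted by same-lineage miRNAs with broad (large-k)
    # lineage coverage, so that every regulator's profile tracks the hub's
    pools: dict[str, list[str]] = {"myeloid": [], "lymphoid": []}
    up_rows = sorted(
        (r for r in mi_spec_rows if r["direction"] == "up"),
        key=lambda r: (-r["k"], r["transcript"]),
    )
    for r in up_rows:
        lin = _lineage_of(r["cell_types"])
        if lin is not None:
            pools[lin].append(r["transcript"])
    hub_genes = gene_names[layout.mrna_hubs[0] : layout.mrna_hubs[1]]
    for i, gene in enumerate(hub_genes):
        lin = "myeloid" if i % 2 == 0 else "lymphoid"
        pool = pools[lin] if len(pools[lin]) >= 2 else pools["myeloid" if lin == "lymphoid" else "lymphoid"]
        if len(pool) < 2:
            continue
        for m in pool[: config.n_regulators_per_hub]:
            true_links.add((m, gene))

    n_flat = config.n_mrna - layout.mrna_flat_start
    n_bg = int(config.background_fraction * n_flat)
    flat_genes = gene_names[layout.mrna_flat_start : config.n_mrna - n_bg]
    down_mirnas = [
        mirna_names[i]
        for start, stop in layout.mirna_down_blocks
        for i in range(start, stop)
    ]
    decoy_only = [
        mirna_names[i]
        for i in range(layout.mirna_decoy_only[0], layout.mirna_decoy_only[1])
    ]
    decoy_links: set[tuple[str, str]] = set()
    for m in up_mirnas + down_mirnas + decoy_only:
        idx = rng.choice(len(flat_genes), size=config.n_decoy_predictions_per_mirna, replace=False)
        for i in idx:
            decoy_links.add((m, flat_genes[i]))
    return true_links, decoy_links


def _generate(config: SimulationConfig, truth: TruthTables | None) -> CohortData:
    rng = np.random.default_rng(config.seed)
    layout = _role_layout(config)
    mirnas = _mirna_names(config.n_mirna)
    genes = _gene_names(config.n_mrna)

    if truth is None:
        spec_rows = _plant_specifics(
            rng, mirnas, layout.mirna_up_blocks, layout.mirna_down_blocks,
            "mirna", config.cell_types,
        ) + _plant_specifics(
            rng, genes, layout.mrna_up_blocks, layout.mrna_down_blocks,
            "mrna", config.cell_types,
        )
        true_links, decoy_links = _plan_links(
            rng, config, layout, mirnas, genes,
            [r for r in spec_rows if r["platform"] == "mirna"],
        )
    else:
        # replay the planted truth, restricted to this cohort's cell types
        spec_rows = []
        for r in truth.specific_transcripts.itertuples():
            kept = tuple(ct for ct in r.cell_types if ct in config.cell_types)
            spec_rows.append(
                {
                    "transcript": r.transcript,
                    "platform": r.platform,
                    "direction": r.direction,
                    "k": r.k,
                    "cell_types": kept,
                }
            )
        true_links, decoy_links = truth.true_links, truth.decoy_links

    mi_rows = [r for r in spec_rows if r["platform"] == "mirna"]
    m_rows = [r for r in spec_rows if r["platform"] == "mrna"]
    mi_means = _mean_matrix(
        rng, config.n_mirna, config.cell_types, config, mi_rows, mirnas,
        layout.mirna_flat_start,
    )
    m_means = _mean_matrix(
        rng, config.n_mrna, config.cell_types, config, m_rows, genes,
        layout.mrna_flat_start,
    )

    # couple each target gene to the mean standardized cell-type profile of
    # its regulator(s); single-regulator genes reduce to one z profile
    mi_index = {t: i for i, t in enumerate(mirnas)}
    g_index = {t: i for i, t in enumerate(genes)}
    regs_by_gene: dict[str, list[str]] = {}
    for m, g in sorted(true_links):
        regs_by_gene.setdefault(g, []).append(m)
    for g, regs in regs_by_gene.items():
        z = np.mean(
            [_standardized_profile(mi_means[mi_index[m]]) for m in regs], axis=0
        )
        m_means[g_index[g]] = m_means[g_index[g]] - config.coupling_beta * z

    metadata = _make_metadata(config)
    ct_pos = {ct: j for j, ct in enumerate(config.cell_types)}
    sample_ct_idx = np.array(
        [ct_pos[ct] for ct in metadata.data["cell_type"]], dtype=int
    )
    mi_vals = _sample_values(rng, mi_means, sample_ct_idx, config.noise_sd)
    m_vals = _sample_values(rng, m_means, sample_ct_idx, config.noise_sd)

    sample_ids = metadata.sample_ids
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mi_vals, index=mirnas, columns=sample_ids), "mirna"
    )
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(m_vals, index=genes, columns=sample_ids), "mrna"
    )
    predictions = _build_predictions(true_links, decoy_links)
    out_truth = truth if truth is not None else TruthTables(
        specific_transcripts=pd.DataFrame(
            spec_rows, columns=["transcript", "platform", "direction", "k", "cell_types"]
        ),
        true_links=true_links,
        decoy_links=decoy_links,
    )
    return CohortData(mirna_matrix, mrna_matrix, metadata, predictions, out_truth)


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate a full synthetic cohort plus its ground-truth tables.

    Deterministic under a fixed ``config.seed``: running twice yields
    byte-identical outputs.
    """
    return _generate(config, truth=None)


def simulate_second_cohort(
    truth: TruthTables,
    config: SimulationConfig,
    cell_types: tuple[str, ...] | None = None,
) -> CohortData:
    """Generate an independent replication cohort sharing the planted truth.

    Fresh base means, pools and noise are drawn under ``config.seed``; the
    identity of specific transcripts and of true/decoy couplings is carried
    over from ``truth``.  By default the dendritic-cell subsets (mDC, pDC)
    are dropped, mirroring a replication panel restricted to the more
    accessible cell types; planted patterns whose cell types are absent here
    simply lose their shift.
    """
    if cell_types is None:
        cell_types = tuple(ct for ct in config.cell_types if ct not in ("mDC", "pDC"))
    if len(cell_types) == 0:
        raise ConfigError("second cohort shares no cell types with the first")
    cfg = dataclasses.replace(config, cell_types=tuple(cell_types))
    return _generate(cfg, truth=truth)
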