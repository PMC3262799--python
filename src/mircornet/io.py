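"""Typed containers and TSV readers/writers for the pipeline's inputs and outputs.

All expression values are log2-scale RMA-style signal throughout; linear fold
changes are always ``2 ** (delta log2)``.  Genomic intervals for predicted
seed sites use the 0-based half-open convention (BED-compatible).
Transcript and gene identifiers are opaque strings; no symbol remapping is
performed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleMetadata",
    "CellTypeScheme",
    "TargetPredictionTable",
    "FoldChangeTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_prediction_table",
    "write_prediction_table",
    "filter_confirmed_predictions",
    "write_sites_bed",
    "read_fold_change_table",
    "write_fold_change_table",
]

PLATFORMS = ("mirna", "mrna")

#: Databases that may vouch for a predicted miRNA target site.
PREDICTION_SOURCES = frozenset(
    {"targetscan", "miranda", "mirdb", "mir2disease", "tarbase"}
)

METADATA_COLUMNS = ("sample_id", "cell_type", "donor_pool", "cohort", "scan_batch")


class FormatError(ValueError):
    """Raised when an input file or in-memory table violates its contract."""


def _find_duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """A transcripts-by-samples matrix of log2 expression values.

    Parameters
    ----------
    data
        DataFrame indexed by transcript id with one column per sample id.
        Values are log2-scale signal; no missing entries allowed.
    platform
        Either ``"mirna"`` or ``"mrna"``.
    """

    data: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise FormatError(f"unknown platform {self.platform!r}")
        dup_t = _find_duplicates(self.data.index)
        if dup_t:
            raise FormatError(f"duplicate transcript id(s): {', '.join(dup_t)}")
        dup_s = _find_duplicates(self.data.columns)
        if dup_s:
            raise FormatError(f"duplicate sample id(s): {', '.join(dup_s)}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression value: {exc}") from exc
        if self.data.isna().any().any():
            bad = self.data.isna().stack()
            t, s = bad[bad].index[0]
            raise FormatError(f"missing value at transcript {t!r}, sample {s!r}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_transcripts(self, transcripts: Iterable[str]) -> "ExpressionMatrix":
        keep = [t for t in transcripts]
        missing = set(keep) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown transcript(s): {sorted(missing)}")
        return ExpressionMatrix(self.data.loc[keep].copy(), self.platform)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in samples]
        missing = set(keep) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample(s): {sorted(missing)}")
        return ExpressionMatrix(self.data[keep].copy(), self.platform)


@dataclass
class SampleMetadata:
    """Per-sample annotations: cell type, donor pool, cohort and scan batch."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing column(s): {', '.join(missing)}")
        self.data = self.data[list(METADATA_COLUMNS)].astype(str).reset_index(drop=True)
        dups = _find_duplicates(self.data["sample_id"])
        if dups:
            raise FormatError(f"duplicate sample_id(s) in metadata: {', '.join(dups)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def cell_type_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["cell_type"]))

    def donor_pool_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["donor_pool"]))

    def require_cover(self, sample_ids: Iterable[str]) -> None:
        """Check every given sample id has exactly one metadata row."""
        missing = set(sample_ids) - set(self.data["sample_id"])
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)}")

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = set(sample_ids)
        return SampleMetadata(self.data[self.data["sample_id"].isin(keep)].copy())


# Analysis groups of the immune-cell panel.  CD4+ and CD8+ T cells are merged
# into a single "T" group; too few transcripts distinguish resting CD4 from CD8.
MYELOID = ("Neutrophils", "Eosinophils", "Monocytes", "mDC")
LYMPHOID = ("T", "B", "NK", "pDC")


@dataclass(frozen=True)
class CellTypeScheme:
    """Mapping from raw sample labels to analysis cell-type groups and lineages.

    ``merge_map`` must be total over the raw labels that appear in metadata and
    ``lineage_map`` total over the analysis labels.
    """

    cell_types: tuple[str, ...]
    merge_map: Mapping[str, str] = field(default_factory=dict)
    lineage_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dups = _find_duplicates(self.cell_types)
        if dups:
            raise FormatError(f"duplicate analysis cell type(s): {dups}")
        bad = set(self.merge_map.values()) - set(self.cell_types)
        if bad:
            raise FormatError(f"merge_map targets outside cell_types: {sorted(bad)}")
        missing = set(self.cell_types) - set(self.lineage_map)
        if missing:
            raise FormatError(f"lineage_map not total; missing: {sorted(missing)}")

    @classmethod
    def immune_default(cls) -> "CellTypeScheme":
        """The eight-group blood panel with CD4/CD8 merged into T cells."""
        cell_types = MYELOID + LYMPHOID
        merge = {ct: ct for ct in cell_types}
        merge.update({"CD4": "T", "CD8": "T"})
        lineage = {ct: "myeloid" for ct in MYELOID}
        lineage.update({ct: "lymphoid" for ct in LYMPHOID})
        return cls(cell_types=cell_types, merge_map=merge, lineage_map=lineage)

    def analysis_label(self, raw: str) -> str:
        try:
            return self.merge_map[raw]
        except KeyError as exc:
            raise FormatError(f"raw cell-type label {raw!r} not in merge_map") from exc

    def restrict(self, keep: Iterable[str]) -> "CellTypeScheme":
        """Scheme restricted to a subset of analysis cell types (order kept)."""
        keep_set = set(keep)
        unknown = keep_set - set(self.cell_types)
        if unknown:
            raise FormatError(f"unknown analysis cell type(s): {sorted(unknown)}")
        cts = tuple(ct for ct in self.cell_types if ct in keep_set)
        merge = {r: a for r, a in self.merge_map.items() if a in keep_set}
        lin = {a: l for a, l in self.lineage_map.items() if a in keep_set}
        return CellTypeScheme(cts, merge, lin)


PREDICTION_COLUMNS = ("mirna_family", "gene", "site_chrom", "site_start", "site_end", "sources")


@dataclass
class TargetPredictionTable:
    """Predicted miRNA seed sites: (miRNA family, gene, interval, source databases).

    Intervals are 0-based half-open on an arbitrary per-gene or genomic
    coordinate system; rows are unique on the full site key.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PREDICTION_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"prediction table missing column(s): {missing}")
        df = self.data[list(PREDICTION_COLUMNS)].reset_index(drop=True).copy()
        df["site_start"] = df["site_start"].astype(int)
        df["site_end"] = df["site_end"].astype(int)
        bad = df["site_start"] >= df["site_end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"site_start >= site_end at row {i} "
                f"({df.at[i, 'mirna_family']} -> {df.at[i, 'gene']})"
            )
        df["sources"] = df["sources"].map(lambda s: frozenset(s))
        unknown = set().union(*df["sources"]) - PREDICTION_SOURCES if len(df) else set()
        if unknown:
            raise FormatError(f"unknown prediction source(s): {sorted(unknown)}")
        key_cols = ["mirna_family", "gene", "site_chrom", "site_start", "site_end"]
        if df.duplicated(key_cols).any():
            row = df[df.duplicated(key_cols)].iloc[0]
            raise FormatError(
                f"duplicate prediction row: {row['mirna_family']} -> {row['gene']} "
                f"{row['site_chrom']}:{row['site_start']}-{row['site_end']}"
            )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.data["mirna_family"].unique())

    def genes_for(self, mirna: str) -> set[str]:
        return set(self.data.loc[self.data["mirna_family"] == mirna, "gene"])

    def sites_for(self, mirna: str, gene: str) -> list[tuple[str, int, int]]:
        sel = self.data[(self.data["mirna_family"] == mirna) & (self.data["gene"] == gene)]
        return [
            (r.site_chrom, int(r.site_start), int(r.site_end))
            for r in sel.itertuples()
        ]


@dataclass
class FoldChangeTable:
    """Linear fold changes (treatment/control) per gene, e.g. from a knockout."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("gene", "linear_fc"):
            if c not in self.data.columns:
                raise FormatError(f"fold-change table missing column {c!r}")
        df = self.data[["gene", "linear_fc"]].reset_index(drop=True).copy()
        df["linear_fc"] = df["linear_fc"].astype(float)
        if (df["linear_fc"] <= 0).any():
            g = df.loc[df["linear_fc"] <= 0, "gene"].iloc[0]
            raise FormatError(f"non-positive fold change for gene {g!r}")
        dups = _find_duplicates(df["gene"])
        if dups:
            raise FormatError(f"duplicate gene(s) in fold-change table: {dups}")
        self.data = df

    def as_series(self) -> pd.Series:
        return self.data.set_index("gene")["linear_fc"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, platform: str) -> ExpressionMatrix:
    """Read a transcripts-by-samples TSV (header = sample ids, col 0 = transcripts).

    Rejects duplicate identifiers and non-numeric cells, naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup_t = _find_duplicates(df.index)
    if dup_t:
        raise FormatError(f"{path}: duplicate transcript id(s): {', '.join(dup_t)}")
    dup_s = _find_duplicates(df.columns)
    if dup_s:
        raise FormatError(f"{path}: duplicate sample id(s): {', '.join(dup_s)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        stacked = bad.stack()
        t, s = stacked[stacked].index[0]
        raise FormatError(f"{path}: non-numeric value at transcript {t!r}, sample {s!r}")
    return ExpressionMatrix(numeric, platform)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.6f", index_label="transcript_id")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_prediction_table(path: str | Path) -> TargetPredictionTable:
    """Read a prediction TSV with semicolon-separated ``sources``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    df["sources"] = df["sources"].map(
        lambda s: frozenset(x for x in str(s).split(";") if x)
    )
    return TargetPredictionTable(df)


def write_prediction_table(table: TargetPredictionTable, path: str | Path) -> None:
    df = table.data.copy()
    df["sources"] = df["sources"].map(lambda s: ";".join(sorted(s)))
    df.to_csv(path, sep="\t", index=False)


def filter_confirmed_predictions(table: TargetPredictionTable) -> TargetPredictionTable:
    """Keep seed-match predictions confirmed by at least one other database.

    A row survives when ``targetscan`` is among its sources and at least one
    further database (computational or experimental) agrees.  Row order is
    preserved.
    """
    mask = table.data["sources"].map(lambda s: "targetscan" in s and len(s) >= 2)
    return TargetPredictionTable(table.data[mask].reset_index(drop=True))


def write_sites_bed(table: TargetPredictionTable, path: str | Path) -> None:
    """Export seed-site intervals as BED6 (name = mirna_family|gene)."""
    with open(path, "w") as fh:
        for r in table.data.itertuples():
            name = f"{r.mirna_family}|{r.gene}"
            fh.write(
                f"{r.site_chrom}\t{r.site_start}\t{r.site_end}\t{name}\t0\t+\n"
            )


def read_fold_change_table(path: str | Path) -> FoldChangeTable:
    return FoldChangeTable(pd.read_csv(path, sep="\t"))


def write_fold_change_table(table: FoldChangeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6f")
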