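"""Pre-inference quality control: detection filtering, PCA outlier flagging
and cell-type profile standardization.

The detection rule follows the microarray convention for RMA-scale data: a
transcript is considered expressed when its mean log2 signal reaches the
detection floor (default 7.0) in at least one analysis cell type.  The
comparison is inclusive (``>=``) so the boundary behaves deterministically;
the threshold is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import CellTypeScheme, ExpressionMatrix, FormatError, SampleMetadata

__all__ = [
    "DetectionFilterResult",
    "OutlierReport",
    "ZProfiles",
    "cell_type_means",
    "detection_filter",
    "flag_outliers_pca",
    "ztransform_frame",
    "ztransform_profiles",
    "DETECTION_THRESHOLD",
]

#: Default detection floor on mean log2 signal.
DETECTION_THRESHOLD = 7.0


def cell_type_means(
    matrix: ExpressionMatrix, meta: SampleMetadata, scheme: CellTypeScheme
) -> pd.DataFrame:
    """Per-transcript mean log2 expression in each analysis cell type.

    Raw metadata labels are mapped through the scheme's merge map (e.g. CD4
    and CD8 samples pooled into the T group).  Columns follow the scheme's
    cell-type order; cell types with no samples raise.
    """
    meta.require_cover(matrix.sample_ids)
    ct_of = meta.cell_type_of()
    labels = [scheme.analysis_label(ct_of[s]) for s in matrix.sample_ids]
    cols: dict[str, np.ndarray] = {}
    vals = matrix.values
    lab_arr = np.asarray(labels)
    for ct in scheme.cell_types:
        sel = lab_arr == ct
        if not sel.any():
            raise FormatError(f"no samples for analysis cell type {ct!r}")
        cols[ct] = vals[:, sel].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.transcript_ids)


@dataclass
class DetectionFilterResult:
    """Transcripts passing the detection floor, with the per-cell-type means
    the decision was based on."""

    kept_transcripts: list[str]
    threshold: float
    basis: pd.DataFrame  # transcripts x analysis cell types, mean log2
    n_total: int

    @property
    def n_kept(self) -> int:
        return len(self.kept_transcripts)


def detection_filter(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    scheme: CellTypeScheme,
    threshold: float = DETECTION_THRESHOLD,
) -> DetectionFilterResult:
    """Keep transcripts whose mean log2 signal is >= ``threshold`` in at least
    one analysis cell type."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise FormatError("empty expression matrix")
    basis = cell_type_means(matrix, meta, scheme)
    kept = basis.index[(basis >= threshold).any(axis=1)].tolist()
    return DetectionFilterResult(
        kept_transcripts=kept,
        threshold=threshold,
        basis=basis,
        n_total=matrix.shape[0],
    )


@dataclass
class OutlierReport:
    """Samples flagged as outliers on the first two principal components.

    Flagging is advisory: callers decide whether to drop the samples.
    """

    scores: pd.DataFrame  # samples x (PC1, PC2)
    flagged_samples: list[str]
    k_sd: float


def flag_outliers_pca(matrix: ExpressionMatrix, k_sd: float = 3.0) -> OutlierReport:
    """Flag samples whose PC1 or PC2 score exceeds ``k_sd`` standard deviations.

    Transcripts are centered, samples are projected onto the first two
    principal components of the sample-by-transcript matrix, and a sample is
    flagged when the absolute score on either component exceeds ``k_sd`` times
    that component's score SD (ddof=1).
    """
    n_samples = matrix.shape[1]
    if n_samples < 3:
        raise FormatError(f"PCA outlier flagging needs >=3 samples, got {n_samples}")
    x = matrix.values.T  # samples x transcripts
    x = x - x.mean(axis=0, keepdims=True)
    n_comp = min(2, n_samples - 1, x.shape[1])
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    if n_comp < 2:  # degenerate; pad so the report shape is stable
        scores = np.hstack([scores, np.zeros((n_samples, 2 - n_comp))])
    df = pd.DataFrame(scores[:, :2], index=matrix.sample_ids, columns=["PC1", "PC2"])
    flagged: list[str] = []
    if math.isfinite(k_sd):
        sd = df.std(axis=0, ddof=1).replace(0.0, np.inf)
        mask = (df.abs() > k_sd * sd).any(axis=1)
        flagged = df.index[mask].tolist()
    return OutlierReport(scores=df, flagged_samples=flagged, k_sd=k_sd)


@dataclass
class ZProfiles:
    """Row-standardized profiles: zero mean, unit variance (ddof=1) per row.

    ``degenerate`` marks rows that were constant before standardization; such
    rows are all-zero and must be excluded from correlation analysis.
    """

    values: pd.DataFrame
    degenerate: pd.Series

    @property
    def axis_labels(self) -> list[str]:
        return list(self.values.columns)


def ztransform_frame(frame: pd.DataFrame) -> ZProfiles:
    """Standardize each row of a profile matrix to zero mean / unit variance."""
    vals = frame.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (vals - mean) / safe_sd
    z[degenerate, :] = 0.0
    return ZProfiles(
        values=pd.DataFrame(z, index=frame.index, columns=frame.columns),
        degenerate=pd.Series(degenerate, index=frame.index),
    )


def ztransform_profiles(
    matrix: ExpressionMatrix, meta: SampleMetadata, scheme: CellTypeScheme
) -> ZProfiles:
    """Per-cell-type mean profiles standardized across cell types.

    Requires at least two analysis cell types.  Constant profiles map to
    all-zero rows flagged as degenerate.
    """
    if len(scheme.cell_types) < 2:
        raise FormatError("profile standardization needs >=2 analysis cell types")
    return ztransform_frame(cell_type_means(matrix, meta, scheme))
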