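"""Pairwise miRNA-mRNA Pearson correlation and permutation FDR calibration
of the negative-correlation cutoff.

Profiles may be built on two bases:

``matched_samples`` (pipeline default)
    Each transcript's profile is its log2 value across samples, with miRNA
    and mRNA samples paired by (analysis cell type, donor pool) — both
    platforms are assayed on the same pools.  With ~40 points the null
    distribution of r is tight enough for a 1% permutation FDR cutoff to
    exist at realistic signal fractions.
``cell_type_means``
    Each transcript's profile is its vector of per-cell-type means (one
    point per analysis group).

Either way profiles are standardized to zero mean and unit variance before
correlating; Pearson r then reduces to a scaled dot product.

The cutoff is calibrated by randomizing the profile axis: in each permutation
round one shared random permutation is applied to the entire mRNA profile
matrix (preserving gene-gene correlation structure, hence an honest null) and
all pair correlations are recomputed.  For each candidate cutoff c the FDR is
estimated as the mean permuted count of pairs below c divided by the observed
count (floored at 1), and the chosen cutoff is the most lenient candidate
with estimated FDR at or under the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellTypeScheme, ExpressionMatrix, FormatError, SampleMetadata
from .qc import ZProfiles, ztransform_frame, ztransform_profiles

__all__ = [
    "CorrelationTable",
    "CutoffResult",
    "correlate_pairs",
    "calibrate_cutoff",
    "matched_sample_profiles",
    "build_profiles",
    "DEFAULT_CUTOFF_GRID",
]

#: Candidate cutoffs scanned during calibration, most lenient first.
DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(-0.05, -1.0, -0.05), 2))


@dataclass
class CorrelationTable:
    """All pairwise Pearson correlations between two profile sets.

    ``r`` has shape (n_mirna, n_mrna); entries involving a degenerate
    (constant) profile are NaN and excluded downstream.
    """

    mirna_ids: list[str]
    mrna_ids: list[str]
    r: np.ndarray
    profile_basis: str

    def to_frame(self) -> pd.DataFrame:
        """Long-form (mirna, mrna, r) table, NaN rows dropped."""
        mi = np.repeat(self.mirna_ids, len(self.mrna_ids))
        mr = np.tile(self.mrna_ids, len(self.mirna_ids))
        df = pd.DataFrame({"mirna": mi, "mrna": mr, "r": self.r.ravel()})
        return df.dropna(subset=["r"]).reset_index(drop=True)

    def r_for(self, mirna: str) -> pd.Series:
        i = self.mirna_ids.index(mirna)
        return pd.Series(self.r[i], index=self.mrna_ids, name=mirna)


def _check_axes(mirna_z: ZProfiles, mrna_z: ZProfiles) -> int:
    if mirna_z.axis_labels != mrna_z.axis_labels:
        raise FormatError(
            "miRNA and mRNA profiles are on different axes: "
            f"{mirna_z.axis_labels[:3]}... vs {mrna_z.axis_labels[:3]}..."
        )
    n = len(mirna_z.axis_labels)
    if n < 4:
        raise FormatError(f"need >=4 profile points, got {n}")
    return n


def correlate_pairs(
    mirna_z: ZProfiles, mrna_z: ZProfiles, profile_basis: str = "cell_type_means"
) -> CorrelationTable:
    """Pearson r for every miRNA x mRNA profile pair.

    Profiles must already be standardized (``ztransform_*``) and share the
    same ordered axis; r is then ``Zm @ Zg.T / (n - 1)``.
    """
    n = _check_axes(mirna_z, mrna_z)
    zm = mirna_z.values.to_numpy()
    zg = mrna_z.values.to_numpy()
    r = zm @ zg.T / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    r[mirna_z.degenerate.to_numpy(), :] = np.nan
    r[:, mrna_z.degenerate.to_numpy()] = np.nan
    return CorrelationTable(
        mirna_ids=list(mirna_z.values.index),
        mrna_ids=list(mrna_z.values.index),
        r=r,
        profile_basis=profile_basis,
    )


@dataclass
class CutoffResult:
    """Permutation-calibrated negative correlation cutoff.

    ``cutoff`` is None when no candidate achieves the target FDR; the full
    ``fdr_curve`` (candidate, observed count, mean null count, estimated FDR)
    is always reported so the caller can decide.
    """

    cutoff: float | None
    target_fdr: float
    n_permutations: int
    fdr_curve: pd.DataFrame
    seed: int | None


def calibrate_cutoff(
    mirna_z: ZProfiles,
    mrna_z: ZProfiles,
    target_fdr: float = 0.01,
    n_permutations: int = 100,
    grid: tuple[float, ...] = DEFAULT_CUTOFF_GRID,
    seed: int | None = None,
) -> CutoffResult:
    """Choose the most lenient negative cutoff with permutation FDR <= target.

    One shared random permutation of the profile axis is applied to the whole
    mRNA matrix per round.  Deterministic under ``seed``.
    """
    n = _check_axes(mirna_z, mrna_z)
    obs = correlate_pairs(mirna_z, mrna_z).r
    obs_flat = obs[np.isfinite(obs)]
    grid_arr = np.sort(np.asarray(grid))  # ascending: most negative first
    # counts of r < c via a sorted scan; 'left' side gives strict <
    obs_sorted = np.sort(obs_flat)
    obs_counts = np.searchsorted(obs_sorted, grid_arr, side="left").astype(float)

    rng = np.random.default_rng(seed)
    zm = mirna_z.values.to_numpy()
    zg = mrna_z.values.to_numpy()
    good_m = ~mirna_z.degenerate.to_numpy()
    good_g = ~mrna_z.degenerate.to_numpy()
    null_counts = np.zeros_like(grid_arr, dtype=float)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = zm[good_m] @ zg[good_g][:, perm].T / (n - 1)
        perm_sorted = np.sort(r_perm.ravel())
        null_counts += np.searchsorted(perm_sorted, grid_arr, side="left")
    null_counts /= n_permutations

    fdr = null_counts / np.maximum(1.0, obs_counts)
    curve = pd.DataFrame(
        {
            "cutoff": grid_arr,
            "n_observed": obs_counts.astype(int),
            "mean_null": null_counts,
            "fdr": fdr,
        }
    ).sort_values("cutoff", ascending=False).reset_index(drop=True)
    passing = curve[curve["fdr"] <= target_fdr]
    cutoff = float(passing["cutoff"].iloc[0]) if len(passing) else None
    return CutoffResult(
        cutoff=cutoff,
        target_fdr=target_fdr,
        n_permutations=n_permutations,
        fdr_curve=curve,
        seed=seed,
    )


def matched_sample_profiles(
    mirna: ExpressionMatrix,
    mirna_meta: SampleMetadata,
    mrna: ExpressionMatrix,
    mrna_meta: SampleMetadata,
    scheme: CellTypeScheme,
) -> tuple[ZProfiles, ZProfiles]:
    """Standardized sample-level profiles with both platforms' samples paired
    by (analysis cell type, donor pool).

    Only pools assayed on both platforms are kept; columns are relabelled to
    the shared ``celltype|pool`` key, sorted, so the two outputs share an
    identical ordered axis.
    """
    def keys(meta: SampleMetadata, matrix: ExpressionMatrix) -> dict[str, str]:
        meta.require_cover(matrix.sample_ids)
        ct = meta.cell_type_of()
        pool = meta.donor_pool_of()
        return {
            f"{scheme.analysis_label(ct[s])}|{pool[s]}": s for s in matrix.sample_ids
        }

    k1 = keys(mirna_meta, mirna)
    k2 = keys(mrna_meta, mrna)
    shared = sorted(set(k1) & set(k2))
    if len(shared) < 4:
        raise FormatError(
            f"only {len(shared)} matched (cell type, pool) samples; >=4 required"
        )
    f1 = mirna.data[[k1[k] for k in shared]].copy()
    f1.columns = shared
    f2 = mrna.data[[k2[k] for k in shared]].copy()
    f2.columns = shared
    return ztransform_frame(f1), ztransform_frame(f2)


def build_profiles(
    mirna: ExpressionMatrix,
    mirna_meta: SampleMetadata,
    mrna: ExpressionMatrix,
    mrna_meta: SampleMetadata,
    scheme: CellTypeScheme,
    basis: str = "matched_samples",
) -> tuple[ZProfiles, ZProfiles]:
    """Build the standardized profile pair for a chosen basis."""
    if basis == "matched_samples":
        return matched_sample_profiles(mirna, mirna_meta, mrna, mrna_meta, scheme)
    if basis == "cell_type_means":
        return (
            ztransform_profiles(mirna, mirna_meta, scheme),
            ztransform_profiles(mrna, mrna_meta, scheme),
        )
    raise ValueError(f"unknown profile basis {basis!r}")
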