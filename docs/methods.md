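# Methods

`mircornet` infers miRNA→mRNA repression relationships from paired miRNA and
mRNA expression profiles of sorted immune cell subsets.  The chain is:
detection filtering → cell-type specificity calling → pairwise
anti-correlation with a permutation-calibrated cutoff → predicted-target
overlap enrichment → cross-cohort replication → bipartite network assembly.
This note records the model, the defaults and why, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Data model

Expression values are RMA-style log2 signal throughout; linear fold changes
are always `2**(Δlog2)`.  Samples are replicate donor pools annotated with a
cell type, pool, cohort and scan batch.  Raw cell-type labels map through a
merge map to eight analysis groups in two hematopoietic lineages — myeloid
(neutrophils, eosinophils, monocytes, mDC) and lymphoid (T, B, NK, pDC) —
with CD4+ and CD8+ samples pooled into a single T group: too few transcripts
distinguish resting CD4 from CD8 cells for them to be useful as separate
classes.  Predicted seed sites are 0-based half-open intervals (the BED
convention; a BED writer is provided).  Transcript and gene identifiers are
opaque strings; probe curation against current genome annotation is consumed
as a pre-filtered input, never computed here.

## Detection filter

A transcript is *expressed* when its mean log2 signal reaches the detection
floor (default 7.0) in at least one analysis cell type.  The rule operates on
per-cell-type means rather than single samples — single-sample excursions at
this scale are noise — and the comparison is inclusive (`>=`) so the boundary
is deterministic.  The filter is idempotent.  PCA outlier flagging
(|PC1/PC2 score| > 3 SD) is advisory: it reports, the analyst decides.

## Specificity classifier

For each transcript the analysis cell types are ranked by mean expression
(descending for up-calls, ascending for down-calls; ties broken by lexical
cell-type order for determinism).  A transcript is called specific to the top
k cell types (k = 1, 2, 3; smallest k wins) when:

1. an optional overall one-way ANOVA across all cell types passes
   BH-adjusted p < α (adjusted across transcripts; default on, α = 0.05);
2. every top-k cell type is expressed above the detection floor (for
   down-calls: every *non*-specific cell type is);
3. expression within the top-k group is homogeneous (one-way ANOVA,
   unadjusted p ≥ α; vacuous at k = 1);
4. the boundary comparison between the k-th and (k+1)-th ranked cell types
   is significant: a Welch two-sample t-test on the two groups' samples,
   BH-adjusted within each (direction, k) family across the transcripts that
   passed the overall gate; and
5. the boundary linear fold change reaches the platform gate — 4-fold for
   mRNA, disabled (1-fold) for miRNA, where fold differentials are
   characteristically modest.

The boundary test is the minimal two-group reading of a "significance of
this comparison" contrast; a pooled-variance variant is available
(`boundary_equal_var=True`).  The within-top-group homogeneity gate is
applied to both platforms for symmetry and can be switched off.  All group
statistics are computed vectorized from per-group summaries; unit tests pin
them to `scipy.stats.f_oneway` / `ttest_ind`, and small-instance calls are
pinned to an exhaustive brute-force evaluation of the rule hierarchy.

Degenerate inputs: zero within-group variance yields p = 1 when group means
are equal and p = 0 otherwise (the limiting behaviour); constant profiles
are flagged and excluded from correlation.

## Correlation and cutoff calibration

Profiles are standardized to zero mean and unit variance (ddof = 1) and all
miRNA × mRNA Pearson correlations computed as a scaled dot product.  Two
profile bases exist:

- **matched_samples** (pipeline default): each transcript's values across
  samples, with the two platforms' samples paired by (cell type, donor
  pool).  With ~40 points the null sd of r is ≈ 0.16, so a stringent
  negative cutoff can reach a 1% false discovery rate.
- **cell_type_means**: the 8-point vector of per-cell-type means.  With only
  8 points the null tail is heavy (P[r < −0.55] ≈ 8%), which makes a 1% FDR
  cutoff arithmetically unattainable at any realistic signal fraction; this
  basis is retained for profile visualization and for the specificity-level
  anti-correlation diagnostics, not for cutoff calibration.

The cutoff is calibrated by label permutation: in each of 100 rounds one
shared random permutation of the profile axis is applied to the whole mRNA
matrix (preserving gene–gene correlation, hence an honest null) and all pair
correlations recomputed.  For each candidate c on a grid (−0.05 … −0.95,
step 0.05) the FDR estimate is the mean permuted count of pairs below c over
the observed count (denominator floored at 1); the chosen cutoff is the most
lenient candidate with estimated FDR ≤ the 1% target.  When no candidate
qualifies the result reports an undefined cutoff plus the full FDR curve and
downstream stages select nothing.  On default synthetic cohorts the chosen
cutoff is typically −0.55 to −0.6.

## Overlap enrichment

Per miRNA m: N(m) = profiled genes with r(m,·) below the cutoff, T(m) =
confirmed predicted targets within the profiled universe (a prediction is
*confirmed* when the seed-match source is corroborated by at least one other
computational or experimental database).  The null fixes |T(m)| and
randomizes target identities: each of 100 permutations draws a uniform gene
set of size |T(m)| from the universe and records its overlap with N(m) —
exactly hypergeometric sampling, which the tests exploit as a closed-form
oracle.  Empirical p-values use add-one smoothing, are BH-adjusted across
miRNAs, and tiered at 1% / 5%.  BH on the per-miRNA permutation p-values was
chosen as the most defensible concrete multiple-testing scheme for this
design; the hypergeometric equivalence keeps it auditable.

## Replication, knockout validation, over-representation

Cross-cohort agreement is the Jaccard coefficient |A∩B| / |A∪B| plus a
hypergeometric upper-tail p for the overlap; the universe size is a required
argument because it cannot be inferred from the sets.  Replicated pairs are
the exact intersection of the two cohorts' (miRNA, gene) pair sets.

Knockout validation takes candidate targets, a predicted-target background
and a linear fold-change table (homolog mapping is an input, not computed);
genes without fold-change data are dropped with a warning.  The statistic is
the fraction of candidates above the primary threshold (default bins 1.3 and
1.5; a mean-fold-change statistic is available), compared against 1000
same-size random background draws with an add-one-smoothed permutation p.
On backgrounds small enough to enumerate, the permutation p matches the
exact tail of the draw distribution.

A generic hypergeometric over-representation test (BH across terms) covers
functional enrichment against user-supplied term→gene-set tables; no live
annotation database is queried.

## Network assembly

Input edges are replicated pairs whose miRNA carries a specificity call
(taken from the cohort with more miRNA calls).  Per gene, *seed-similar*
regulators — every site of each overlapping a site of the other — are
collapsed to the lexically smallest member, so a gene's degree counts only
independent site evidence; partial overlap keeps both regulators, and every
collapse is reported.  Genes with fewer than `min_degree` (default 2)
regulators after collapse are removed.  miRNA nodes carry their specific
cell types and lineage; genes are ranked as hubs by in-degree (ties
lexical).  Exports: SIF (`mirna represses gene`) and GraphML; both
round-trip their topology.

## Synthetic cohorts

The generator emulates the sorted-immune-cell study design: 8 cell types × 5
replicate pools, Gaussian log2 noise (sd 0.5, matching RMA-scale behaviour),
expressed base means uniform on [8, 12] with a 20% background block at log2
5, specificity shifts of ±3 log2 (≈ 8-fold) planted in 1/2/3 cell types
(3-type patterns lineage-coherent), and default planted counts of (10, 5, 5)
up and (4, 2, 2) down transcripts per platform.  Each up-specific miRNA
represses 5 dedicated target genes: the gene's per-cell-type mean is its base
minus `coupling_beta` (default 1.0) times the regulator's standardized
cell-type profile, noise added per sample.  Four hub genes are co-targeted
by 3 same-lineage miRNAs (coupled to the mean of their standardized
profiles), giving the network stage multi-regulator structure.  The
prediction table carries all true couplings plus 5 expression-independent
decoys per miRNA — the seed-match false positives the anti-correlation
filter exists to remove — with disjoint synthetic site intervals, and 5
further decoy-only miRNAs carry predictions but no coupling.  A second
cohort replays the same planted truth with fresh pools and noise and, by
default, without the dendritic-cell subsets, mimicking a replication panel
of the more accessible cell types.

What passing tests show: the classifier recovers planted patterns (≈ 97%
over 100 seeds) at near-zero null call rate, the cutoff machinery controls
the null discovery rate, enrichment separates coupled from decoy-only
miRNAs, and ~85–90% of planted couplings replicate across cohorts.  What
they do not show: robustness to probe-level artifacts, batch/scan-date
confounding, donor-pool chemistry, non-Gaussian heavy tails, or indirect
(non-causal) anti-correlation — none of which the generator simulates.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline derives per-stage
seeds as `(seed * 100 + stage_offset) mod 2**31`, so stages re-run
identically in isolation and a full run is byte-reproducible.  Default test
and acceptance problem sizes (60 miRNAs × 300 genes × 40 samples; 100
permutations; 25–100 simulation seeds) were chosen so the statistical
assertions have comfortable Monte-Carlo margins while a full suite run
completes in well under a minute on one CPU.

## Known limitations

- The specificity p-values are conditional on the data-driven ranking; like
  the original rank-and-test design they are screening statistics, not
  inferential guarantees.
- The permutation null for the cutoff destroys *all* miRNA–mRNA matching,
  so genuine but unplanted anti-correlation (e.g. an up-specific miRNA and
  an independently down-specific gene in the same cell type) counts as
  discovery, not as error; the FDR is with respect to label exchangeability.
- Family-level collapsing of miRNA probes is consumed as an optional input
  mapping, never computed.
- GO-style enrichment requires the caller to supply term definitions.
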