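# mircornet

Cell-type-specific miRNA/mRNA expression calling and anti-correlation-based
regulatory network inference for sorted immune cell profiles.

## The problem

Blood is a mixture of cell populations with sharply distinct transcriptomes,
and miRNAs — ~21-nt RNAs that repress target mRNAs through 3′UTR seed-site
binding — are among the regulators that establish those identities.  Given
paired miRNA and mRNA expression matrices from sorted immune cell subsets
(neutrophils, eosinophils, monocytes, mDC, T, B, NK, pDC; RMA-normalized
log2 signal, replicate donor pools per type), `mircornet` answers three
questions:

1. **Which transcripts are specific to 1, 2 or 3 cell types?**  A
   hierarchical rank-and-test classifier ranks cell types by mean
   expression and calls a transcript specific to the top *k* types when the
   top group is internally homogeneous (ANOVA p ≥ α), the boundary to the
   (k+1)-th type is significant (Welch t, Benjamini–Hochberg adjusted
   p\* < α) and, for mRNA, at least 4-fold; down-regulation is called
   symmetrically on ascending ranks.  Expression must clear a detection
   floor of log2 signal 7.
2. **Which predicted miRNA targets are actually repressed?**  All miRNA ×
   mRNA Pearson correlations are computed on standardized profiles, and a
   negative cutoff is calibrated so that the permutation-null discovery
   rate is ≤ 1% (100 label permutations).  Per miRNA, a fixed-size
   randomization test (equivalent to hypergeometric sampling) asks whether
   its confirmed seed-match predictions are over-represented among its
   anti-correlated genes.
3. **What does the regulatory program look like?**  Pairs that replicate
   across two independent cohorts, for cell-type-specific miRNAs, are
   assembled into a bipartite miRNA→gene network; regulators with fully
   overlapping seed sites are collapsed so multi-miRNA "hub" genes reflect
   independent evidence, and hubs are ranked by in-degree.

Validation utilities cover cross-cohort agreement (Jaccard coefficient with
hypergeometric overlap p), response of candidate targets in knockout
fold-change data against randomized predicted-target draws, and a generic
over-representation test.  A synthetic-data module generates cohorts with
planted ground truth — specific transcripts, true couplings, decoy
predictions — so every stage is testable without any external download.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from mircornet import (
    SimulationConfig, simulate_cohort, detection_filter, call_specificity,
    build_profiles, calibrate_cutoff, correlate_pairs, test_overlap,
    filter_confirmed_predictions, summarize_calls,
)

config = SimulationConfig(seed=1)        # 8 cell types x 5 pools, planted truth
cohort = simulate_cohort(config)
scheme = config.scheme()

kept = detection_filter(cohort.mirna, cohort.metadata, scheme)
print(f"expressed miRNAs: {kept.n_kept}/{kept.n_total}")

calls = call_specificity(
    cohort.mirna.subset_transcripts(kept.kept_transcripts),
    cohort.metadata, scheme,
)
print(summarize_calls(calls)["by_k"].to_string(index=False))

zm, zg = build_profiles(cohort.mirna, cohort.metadata,
                        cohort.mrna, cohort.metadata, scheme)
cutoff = calibrate_cutoff(zm, zg, target_fdr=0.01, seed=1)
print(f"calibrated cutoff: {cutoff.cutoff}")

corr = correlate_pairs(zm, zg)
predictions = filter_confirmed_predictions(cohort.predictions)
results = test_overlap(corr, cutoff.cutoff, predictions,
                       cohort.mrna.transcript_ids, seed=1)
significant = [r.mirna for r in results if r.significant_at is not None]
print(f"miRNAs with significant target overlap: {len(significant)}")
```

Output:

```
expressed miRNAs: 55/60
platform     k  up  down  total
   mirna     1  10     4     14
   mirna     2   5     2      7
   mirna     3   5     2      7
   mirna Total  20     8     28
calibrated cutoff: -0.55
miRNAs with significant target overlap: 20
```

All 28 planted specific miRNAs are recalled at their planted k; the
permutation-calibrated cutoff lands at −0.55 (with ~40 matched samples the
null sd of r is ≈ 0.16, so −0.55 is where the 1% FDR target is met); and
exactly the 20 miRNAs with planted couplings — none of the decoy-only ones —
show significant target overlap.

The same stages are available from the shell:

```sh
mircornet simulate --seed 1 --outdir sim/
mircornet specificity --expression sim/mirna.tsv --metadata sim/metadata.tsv \
    --platform mirna --out calls.tsv
mircornet run-all --seed 1 --outdir run/     # full two-cohort pipeline
```

`run-all` simulates two cohorts sharing one planted truth (the second
without dendritic cells), runs QC → specificity → correlation → enrichment
per cohort, intersects the pairs, builds the network, and writes a
`manifest.json` whose checksums are byte-identical across reruns with the
same seed.

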