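"""End-to-end orchestration: qc -> specificity -> correlation -> enrichment
-> replication -> network, with deterministic seeding and a run manifest.

A single global seed fans out to per-stage seeds through a fixed derivation
(``stage_seed = (seed * 100 + stage_offset) mod 2**31``), so each stage can be
re-run in isolation and identical config + seed yields byte-identical outputs.

Two input modes are supported: *synthetic* (two simulated cohorts sharing a
planted truth) and *files* (TSV inputs for one or two cohorts).  Outputs are
TSV/JSON/SIF/GraphML files in the output directory plus a ``manifest.json``
recording the seed, per-stage counts and the SHA-256 checksum of every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import correlation as corr_mod
from . import enrichment as enr_mod
from . import network as net_mod
from . import qc as qc_mod
from . import specificity as spec_mod
from . import validation as val_mod
from .io import (
    CellTypeScheme,
    read_expression_matrix,
    read_prediction_table,
    read_sample_metadata,
    filter_confirmed_predictions,
    write_expression_matrix,
    write_prediction_table,
    write_sample_metadata,
)
from .simulate import CohortData, SimulationConfig, simulate_cohort, simulate_second_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

_STAGE_OFFSETS = {
    "simulate_a": 11,
    "simulate_b": 12,
    "correlation_a": 31,
    "correlation_b": 32,
    "enrichment_a": 41,
    "enrichment_b": 42,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable, < 2**31)."""
    return (seed * 100 + _STAGE_OFFSETS[stage]) % (2**31)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    When ``simulation`` is set the two cohorts are generated; otherwise the
    ``*_path`` fields must point at existing TSV inputs (cohort B optional).
    """

    seed: int = 0
    outdir: str = "pipeline_out"
    simulation: SimulationConfig | None = None
    # file-mode inputs (cohort A; cohort B optional)
    mirna_path: str | None = None
    mrna_path: str | None = None
    metadata_path: str | None = None
    predictions_path: str | None = None
    mirna_b_path: str | None = None
    mrna_b_path: str | None = None
    metadata_b_path: str | None = None
    # analysis parameters
    detection_threshold: float = qc_mod.DETECTION_THRESHOLD
    alpha: float = 0.05
    profile_basis: str = "matched_samples"
    target_fdr: float = 0.01
    corr_permutations: int = 100
    enrich_permutations: int = 100
    min_degree: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("cell_types", "n_up_per_k", "n_down_per_k", "expressed_mean_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def input_paths(self) -> list[str]:
        return [
            p
            for p in (
                self.mirna_path, self.mrna_path, self.metadata_path,
                self.predictions_path, self.mirna_b_path, self.mrna_b_path,
                self.metadata_b_path,
            )
            if p is not None
        ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyze_cohort(
    label: str,
    data: CohortData,
    scheme: CellTypeScheme,
    config: PipelineConfig,
    outdir: Path,
    counts: dict,
    outputs: list[Path],
) -> dict:
    """QC, specificity, correlation and enrichment for one cohort."""
    # qc
    det_mi = qc_mod.detection_filter(data.mirna, data.metadata, scheme, config.detection_threshold)
    det_m = qc_mod.detection_filter(data.mrna, data.metadata, scheme, config.detection_threshold)
    mirna = data.mirna.subset_transcripts(det_mi.kept_transcripts)
    mrna = data.mrna.subset_transcripts(det_m.kept_transcripts)
    counts[f"{label}.detected_mirna"] = det_mi.n_kept
    counts[f"{label}.detected_mrna"] = det_m.n_kept

    # specificity
    calls = []
    for matrix in (mirna, mrna):
        params = spec_mod.SpecificityParams.for_platform(
            matrix.platform,
            alpha=config.alpha,
            detection_threshold=config.detection_threshold,
        )
        calls.extend(spec_mod.call_specificity(matrix, data.metadata, scheme, params))
    frame = spec_mod.calls_to_frame(calls)
    p = outdir / f"specificity_{label}.tsv"
    frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)
    counts[f"{label}.specificity_calls"] = len(calls)

    # correlation + cutoff
    zm, zg = corr_mod.build_profiles(
        mirna, data.metadata, mrna, data.metadata, scheme, basis=config.profile_basis
    )
    corr = corr_mod.correlate_pairs(zm, zg, profile_basis=config.profile_basis)
    cut = corr_mod.calibrate_cutoff(
        zm, zg,
        target_fdr=config.target_fdr,
        n_permutations=config.corr_permutations,
        seed=stage_seed(config.seed, f"correlation_{label}"),
    )
    p = outdir / f"cutoff_curve_{label}.tsv"
    cut.fdr_curve.to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)
    counts[f"{label}.cutoff"] = cut.cutoff

    # enrichment
    predictions = filter_confirmed_predictions(data.predictions)
    universe = mrna.transcript_ids
    if cut.cutoff is None:
        results = []
        pairs: set[tuple[str, str]] = set()
    else:
        results = enr_mod.test_overlap(
            corr, cut.cutoff, predictions, universe,
            n_permutations=config.enrich_permutations,
            seed=stage_seed(config.seed, f"enrichment_{label}"),
        )
        pairs = set()
        for res in results:
            if res.significant_at is not None:
                tl = enr_mod.negcorr_target_list(corr, cut.cutoff, predictions, res.mirna)
                pairs.update((res.mirna, g) for g in tl["gene"])
    p = outdir / f"enrichment_{label}.tsv"
    enr_mod.results_to_frame(results).to_csv(p, sep="\t", index=False, float_format="%.6g")
    outputs.append(p)
    counts[f"{label}.significant_mirnas"] = sum(
        1 for r in results if r.significant_at is not None
    )
    counts[f"{label}.pairs"] = len(pairs)
    return {"calls": calls, "corr": corr, "cutoff": cut, "pairs": pairs,
            "predictions": predictions}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise PipelineError(f"stage inputs: missing file(s): {missing}")
    if config.simulation is None and not config.mirna_path:
        raise PipelineError("stage inputs: neither simulation nor input files configured")

    counts: dict = {}
    outputs: list[Path] = []

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulation is not None:
            sim_a = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, "simulate_a"), cohort="A"
            )
            cohort_a = simulate_cohort(sim_a)
            sim_b = dataclasses.replace(
                sim_a, seed=stage_seed(config.seed, "simulate_b"), cohort="B"
            )
            cohort_b = simulate_second_cohort(cohort_a.truth, sim_b)
            for label, data in (("a", cohort_a), ("b", cohort_b)):
                for name, mat in (("mirna", data.mirna), ("mrna", data.mrna)):
                    p = outdir / f"{name}_{label}.tsv"
                    write_expression_matrix(mat, p)
                    outputs.append(p)
                p = outdir / f"metadata_{label}.tsv"
                write_sample_metadata(data.metadata, p)
                outputs.append(p)
            p = outdir / "predictions.tsv"
            write_prediction_table(cohort_a.predictions, p)
            outputs.append(p)
        else:
            mirna = read_expression_matrix(config.mirna_path, "mirna")
            mrna = read_expression_matrix(config.mrna_path, "mrna")
            meta = read_sample_metadata(config.metadata_path)
            preds = read_prediction_table(config.predictions_path)
            cohort_a = CohortData(mirna, mrna, meta, preds, None)
            cohort_b = None
            if config.mirna_b_path:
                cohort_b = CohortData(
                    read_expression_matrix(config.mirna_b_path, "mirna"),
                    read_expression_matrix(config.mrna_b_path, "mrna"),
                    read_sample_metadata(config.metadata_b_path),
                    preds,
                    None,
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage inputs: {exc}") from exc

    full_scheme = CellTypeScheme.immune_default()

    def scheme_for(data: CohortData) -> CellTypeScheme:
        cts = {
            full_scheme.analysis_label(ct) for ct in data.metadata.data["cell_type"]
        }
        return full_scheme.restrict([c for c in full_scheme.cell_types if c in cts])

    results = {}
    for label, data in (("a", cohort_a), ("b", cohort_b)):
        if data is None:
            continue
        try:
            results[label] = _analyze_cohort(
                label, data, scheme_for(data), config, outdir, counts, outputs
            )
        except Exception as exc:
            raise PipelineError(f"stage analyze_{label}: {exc}") from exc

    # ---- stage: replication -------------------------------------------
    try:
        if "b" in results:
            replicated = val_mod.replicated_pairs(
                results["a"]["pairs"], results["b"]["pairs"]
            )
            sig_a = {r for (r, _) in results["a"]["pairs"]}
            sig_b = {r for (r, _) in results["b"]["pairs"]}
            n_mirna_universe = len(cohort_a.mirna.transcript_ids)
            if sig_a or sig_b:
                ov = val_mod.overlap_stats(sig_a, sig_b, n_mirna_universe)
                counts["replication.jaccard_significant_mirnas"] = round(ov.jaccard, 4)
            counts["replication.pairs"] = len(replicated)
        else:
            replicated = {(m, g) for (m, g) in results["a"]["pairs"]}
        rep_rows = sorted(replicated)
        p = outdir / "replicated_pairs.tsv"
        with open(p, "w") as fh:
            fh.write("mirna\tgene\n")
            for m, g in rep_rows:
                fh.write(f"{m}\t{g}\n")
        outputs.append(p)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage replication: {exc}") from exc

    # ---- stage: network ------------------------------------------------
    try:
        # annotate with the cohort that yielded more miRNA calls
        calls_source = "a"
        if "b" in results:
            n_a = sum(1 for c in results["a"]["calls"] if c.platform == "mirna")
            n_b = sum(1 for c in results["b"]["calls"] if c.platform == "mirna")
            calls_source = "b" if n_b >= n_a else "a"
        corr_a = results["a"]["corr"]
        cut_a = results["a"]["cutoff"].cutoff
        edges = []
        for m, g in sorted(replicated):
            r = corr_a.r_for(m).get(g, float("nan"))
            edges.append((m, g, float(r)))
        net = net_mod.build_network(
            edges,
            results[calls_source]["calls"],
            results["a"]["predictions"],
            min_degree=config.min_degree,
            scheme=full_scheme,
        )
        for fmt, suffix in (("sif", "sif"), ("graphml", "graphml")):
            p = outdir / f"network.{suffix}"
            net_mod.export_network(net, p, fmt=fmt)
            outputs.append(p)
        counts["network.genes"] = len(net.genes)
        counts["network.mirnas"] = len(net.mirnas)
        counts["network.edges"] = len(net.edges)
        hubs = net_mod.rank_hubs(net)
        counts["network.top_hub"] = list(hubs[0]) if hubs else None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage network: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "profile_basis": config.profile_basis,
        "counts": counts,
        "outputs": sorted(str(p.name) for p in outputs),
        "checksums": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
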