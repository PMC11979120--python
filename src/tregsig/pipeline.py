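"""End-to-end orchestration: simulate/load -> thymic DE -> signature ->
private genes -> trajectory -> enrichment, with a reproducible run manifest.

A single global seed fans out to per-stage seeds through a fixed
``SeedSequence`` spawn order (stage 0 = simulation, stage 1 = GSEA), so
stages stay reproducible in isolation and the whole run is byte-identical
for identical inputs, configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import de, enrichment, signature as sigmod, simulate as simmod, trajectory as trajmod
from .io import (
    CountMatrix,
    GeneSetCollection,
    PipelineConfig,
    file_digest,
    write_results,
)

log = logging.getLogger("tregsig")

THYMIC_CONTRAST = "thymus.Treg - thymus.Tconv"


def _stage_seeds(seed: int, n: int = 2) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str]
    counts: dict[str, int]
    recovery: dict[str, float]
    file_digests: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclasses.dataclass
class PipelineResult:
    manifest: RunManifest
    thymic: de.ContrastAnalysis
    signature: sigmod.ExpressionSignature
    private: sigmod.PrivateGeneSet
    contrasts: trajmod.CompartmentContrasts
    classification: trajmod.TrajectoryClassification
    heatmap: trajmod.HeatmapMatrix
    gsea: pd.DataFrame | None
    ora: pd.DataFrame | None
    truth: pd.DataFrame | None


def _jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def recovery_metrics(result: PipelineResult, truth: pd.DataFrame) -> dict[str, float]:
    """Planted-class recovery of a run against the simulator's truth table."""
    up_true = set(truth.index[truth["signature_class"] == simmod.SIGNATURE_UP])
    down_true = set(truth.index[truth["signature_class"] == simmod.SIGNATURE_DOWN])
    up_called = set(result.signature.up_genes)
    down_called = set(result.signature.down_genes)
    called = up_called | down_called
    true_deg = up_true | down_true
    tp = len((up_called & up_true) | (down_called & down_true))
    sens = tp / len(true_deg) if true_deg else float("nan")
    prec = tp / len(called) if called else float("nan")

    private_true = set(truth.index[truth["is_private"]])
    enriched_true = set(truth.index[truth["thymus_enriched"]])
    analyzed = list(result.classification.table.index)
    cells_called = result.classification.table["cell"]
    cells_true = truth.loc[analyzed, "trajectory_class"]
    cell_acc = float((cells_called == cells_true).mean()) if analyzed else float("nan")

    ref_planted = float(truth.loc[result.private.reference_gene, "planted_log2cpm.thymus.Tconv"])
    return {
        "deg_sensitivity": sens,
        "deg_precision": prec,
        "jaccard_up": _jaccard(up_called, up_true),
        "jaccard_down": _jaccard(down_called, down_true),
        "jaccard_private": _jaccard(result.private.members, private_true),
        "jaccard_thymus_enriched": _jaccard(result.classification.thymus_enriched, enriched_true),
        "trajectory_cell_accuracy": cell_acc,
        "threshold_estimate": result.private.threshold_log2cpm,
        "threshold_planted": ref_planted,
    }


def run_pipeline(
    config: PipelineConfig,
    cm: CountMatrix | None = None,
    sim_params: simmod.SimulationParams | None = None,
    gene_sets: GeneSetCollection | None = None,
    tf_list: Iterable[str] | None = None,
    out_dir: str | Path | None = None,
    input_digests: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every stage on real counts or a freshly simulated experiment.

    Exactly one of ``cm`` (a loaded count matrix) or ``sim_params`` must be
    given.  When simulating, the simulation seed is derived from
    ``config.seed`` unless ``sim_params.seed`` was set explicitly (non-zero).
    Writes stage TSVs and ``manifest.json`` into ``out_dir`` when given.
    """
    if (cm is None) == (sim_params is None):
        raise ValueError("provide exactly one of cm or sim_params")
    sim_seed, gsea_seed = _stage_seeds(config.seed)

    truth = None
    if sim_params is not None:
        if sim_params.seed == 0:
            sim_params = dataclasses.replace(sim_params, seed=sim_seed)
        cm, truth = simmod.simulate_experiment(sim_params)
        log.info("simulated %d genes x %d libraries (seed %d)",
                 cm.n_genes, cm.n_samples, sim_params.seed)

    # --- stage 1: thymic contrast -------------------------------------
    thymic_ids = cm.samples.index[cm.samples["compartment"] == "thymus"]
    cm_thymus = cm.subset_samples(thymic_ids)
    thymic = de.run_contrasts(
        cm_thymus,
        contrasts={"thymic": THYMIC_CONTRAST},
        min_cpm=config.filter_min_cpm,
        max_low_libraries=config.filter_max_low_libraries,
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
        adjust_method=config.adjust_method,
        keep_genes=(config.reference_gene,),
    )
    result = thymic.results["thymic"]
    log.info("thymic analysis: %d/%d genes pass the %.3g-CPM filter",
             thymic.filtered.n_genes, cm.n_genes, config.filter_min_cpm)

    # --- stage 2: signature and private genes -------------------------
    sig = sigmod.build_signature(result, source_contrast=THYMIC_CONTRAST)
    log.info("signature: %d up, %d down DEGs (|log2FC| >= %g, %s-adjusted p < %g)",
             sig.n_up, sig.n_down, config.lfc_threshold, config.adjust_method, config.alpha)
    opposing = list(cm_thymus.samples.index[cm_thymus.samples["lineage"] == "Tconv"])
    threshold = sigmod.private_threshold(
        thymic.log2cpm, config.reference_gene, opposing, statistic=config.private_statistic
    )
    private = sigmod.extract_private_genes(
        sig, thymic.log2cpm, opposing, threshold,
        reference_gene=config.reference_gene, inclusive=config.private_inclusive,
    )
    log.info("private genes: %d of %d up DEGs at or below the %s threshold (%.3f log2-CPM)",
             len(private.members), sig.n_up, config.reference_gene, threshold)

    # --- stage 3: trajectory ------------------------------------------
    contrasts = trajmod.harmonize_and_contrast(cm, private, config)
    log.info("trajectory: %d private genes analyzed, %d dropped by the joint filter",
             len(contrasts.analyzed), len(contrasts.dropped))
    classification = trajmod.classify_trajectory(contrasts)
    treg_ids = contrasts.samples.index[contrasts.samples["lineage"] == "Treg"]
    analyzed = contrasts.analyzed
    if len(analyzed) >= 2:
        heatmap = trajmod.cluster_heatmap_matrix(
            contrasts.log2cpm.loc[analyzed, treg_ids], contrasts.samples.loc[treg_ids]
        )
    else:
        heatmap = trajmod.HeatmapMatrix(
            matrix=contrasts.log2cpm.loc[analyzed, treg_ids],
            leaf_order=list(analyzed),
            first_split=pd.Series(0, index=pd.Index(analyzed), dtype=int),
        )

    # --- stage 4: enrichment ------------------------------------------
    gsea = ora = None
    if gene_sets is not None and len(gene_sets):
        ranked = enrichment.rank_by_log2fc(result)
        gsea = enrichment.gsea_permutation(
            ranked, gene_sets, nperm=config.gsea_nperm, seed=gsea_seed
        )
        if private.members:
            ora = enrichment.ora_collection(
                set(private.members), gene_sets, set(result.index),
                alpha=config.alpha, include_all=True,
            )

    tf_overlap = None
    if tf_list is not None:
        tf_overlap = sigmod.annotate_overlap(sig, tf_list, label="transcription_factors")
        log.info("TF overlap: %d up, %d down", tf_overlap["n_up"], tf_overlap["n_down"])

    counts = {
        "n_genes": int(cm.n_genes),
        "n_samples": int(cm.n_samples),
        "n_filtered_thymic": int(thymic.filtered.n_genes),
        "n_degs": sig.n_up + sig.n_down,
        "n_up": sig.n_up,
        "n_down": sig.n_down,
        "n_private": len(private.members),
        "n_analyzed": len(contrasts.analyzed),
        "n_dropped_by_joint_filter": len(contrasts.dropped),
        "n_thymus_enriched": len(classification.thymus_enriched),
    }

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=_version(),
        input_digests=dict(input_digests or {}),
        counts=counts,
        recovery={},
        file_digests={},
    )
    res = PipelineResult(
        manifest=manifest,
        thymic=thymic,
        signature=sig,
        private=private,
        contrasts=contrasts,
        classification=classification,
        heatmap=heatmap,
        gsea=gsea,
        ora=ora,
        truth=truth,
    )
    if truth is not None:
        manifest.recovery = recovery_metrics(res, truth)

    if out_dir is not None:
        _write_outputs(res, Path(out_dir), tf_overlap)
    return res


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("tregsig")
    except Exception:  # pragma: no cover
        return "unknown"


def _write_outputs(res: PipelineResult, out_dir: Path, tf_overlap: dict | None) -> None:
    tables: dict[str, pd.DataFrame] = {
        "de_results": res.thymic.results["thymic"],
        "signature": sigmod.signature_table(res.thymic.results["thymic"], res.signature),
        "private_genes": pd.DataFrame(
            {
                "opposing_mean_log2cpm": res.private.opposing_mean,
                "threshold_log2cpm": res.private.threshold_log2cpm,
            },
            index=pd.Index(res.private.members, name="gene_id"),
        ),
        "trajectory_classes": res.classification.table,
        "heatmap_matrix": res.heatmap.matrix,
    }
    if res.gsea is not None:
        tables["gsea"] = res.gsea
    if res.ora is not None:
        tables["ora"] = res.ora
    if res.truth is not None:
        tables["truth"] = res.truth
    written = write_results(tables, out_dir)
    order_path = out_dir / "cluster_order.txt"
    order_path.write_text("\n".join(res.heatmap.leaf_order) + "\n", encoding="utf-8")
    written["cluster_order"] = order_path
    enriched_path = out_dir / "thymus_enriched.txt"
    enriched_path.write_text(
        "\n".join(res.classification.thymus_enriched) + "\n", encoding="utf-8"
    )
    written["thymus_enriched"] = enriched_path
    if tf_overlap is not None:
        tf_path = out_dir / "tf_overlap.json"
        tf_path.write_text(json.dumps(tf_overlap, indent=2, sort_keys=True), encoding="utf-8")
        written["tf_overlap"] = tf_path
    res.manifest.file_digests = {
        name: file_digest(path) for name, path in sorted(written.items())
    }
    (out_dir / "manifest.json").write_text(res.manifest.to_json() + "\n", encoding="utf-8")
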