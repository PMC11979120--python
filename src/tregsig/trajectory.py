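"""Thymus -> naive -> memory trajectory analysis of the private genes.

All 18 libraries are harmonized in one joint analysis (single filter, TMM
and precision-weight pass), the within-Treg compartment contrasts are
computed, and each private gene is assigned a cell of the 3x3 grid of
(thymus->naive, naive->memory) statuses.

Orientation convention: every transition contrast is *later minus earlier*
(naive - thymus, memory - naive, memory - thymus), so ``log2fc < 0`` and
status ``down`` mean expression decreases across that transition, i.e. was
higher in the earlier compartment.  "Down upon egress" is therefore C1 =
down.  The thymus-enriched aggregate is C1 down with C2 stable or down,
plus the down-then-up genes whose mean thymic expression exceeds their mean
memory expression (an expression-level tiebreak; the thymus-vs-memory
contrast C3 is computed and reported for transparency but does not drive
the tiebreak).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from . import de
from .io import CountMatrix, PipelineConfig, TregsigError
from .signature import PrivateGeneSet

C1 = "thymus_to_naive"
C2 = "naive_to_memory"
C3 = "thymus_to_memory"

_CONTRASTS = {
    C1: "naive.Treg - thymus.Treg",
    C2: "memory.Treg - naive.Treg",
    C3: "memory.Treg - thymus.Treg",
}

THYMUS_ENRICHED_CELLS = ("down_stable", "down_down")


@dataclasses.dataclass
class CompartmentContrasts:
    """Per-gene transition statistics for the private genes.

    ``tables`` maps contrast name (thymus_to_naive, naive_to_memory,
    thymus_to_memory) to a result frame over the analyzed genes.
    ``analyzed`` are the private genes surviving the joint filter;
    ``dropped`` the ones it removed.
    """

    tables: dict[str, pd.DataFrame]
    analyzed: list[str]
    dropped: list[str]
    log2cpm: pd.DataFrame  # joint TMM-normalized log2-CPM, all filtered genes
    samples: pd.DataFrame


@dataclasses.dataclass
class TrajectoryClassification:
    table: pd.DataFrame  # per analyzed gene: statuses, cell, tiebreak, enriched
    cells: dict[str, list[str]]  # cell label -> member genes
    thymus_enriched: list[str]
    aggregates: dict[str, list[str]]


def harmonize_and_contrast(
    cm_all: CountMatrix,
    private: PrivateGeneSet,
    config: PipelineConfig,
) -> CompartmentContrasts:
    """Joint 18-library analysis and Treg-lineage transition contrasts.

    All six population groups must be present with at least two samples
    each.  A single filter/TMM/weighting pass over all libraries feeds the
    joint group-means fit; the three Treg transition contrasts are then
    tested.  Only private genes surviving the joint filter are reported;
    by default their p-values are adjusted within the private family
    (``config.trajectory_adjust_scope = "genome"`` adjusts across all
    filtered genes instead).
    """
    groups = cm_all.group_labels()
    expected = [f"{c}.{l}" for c in ("thymus", "naive", "memory") for l in ("Treg", "Tconv")]
    for g in expected:
        if (groups == g).sum() < 2:
            raise TregsigError(f"population group {g!r} is missing or has < 2 samples")

    analysis = de.run_contrasts(
        cm_all,
        contrasts=_CONTRASTS,
        min_cpm=config.filter_min_cpm,
        max_low_libraries=config.filter_max_low_libraries,
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
        adjust_method=config.adjust_method,
        keep_genes=(config.reference_gene,),
    )
    surviving = [g for g in private.members if g in analysis.filtered.gene_ids]
    dropped = [g for g in private.members if g not in analysis.filtered.gene_ids]

    tables: dict[str, pd.DataFrame] = {}
    for name, res in analysis.results.items():
        if config.trajectory_adjust_scope == "private":
            sub = res.loc[surviving].copy()
            sub["p_adj"] = de.adjust_pvalues(sub["p_raw"].to_numpy(), config.adjust_method)
            sub = de.call_degs(sub, lfc_threshold=config.lfc_threshold, alpha=config.alpha)
        else:
            sub = res.loc[surviving].copy()
        tables[name] = sub

    return CompartmentContrasts(
        tables=tables,
        analyzed=surviving,
        dropped=dropped,
        log2cpm=analysis.log2cpm,
        samples=analysis.filtered.samples,
    )


def classify_trajectory(contrasts: CompartmentContrasts) -> TrajectoryClassification:
    """Assign each analyzed gene its (C1-status, C2-status) grid cell.

    Down-then-up genes get the thymus-vs-memory expression tiebreak; the
    aggregates (thymus_enriched, periphery_up, memory_up) are assembled from
    the grid.  The nine cells partition the analyzed genes.
    """
    genes = contrasts.analyzed
    c1 = contrasts.tables[C1].loc[genes, "status"]
    c2 = contrasts.tables[C2].loc[genes, "status"]
    cell = c1.str.cat(c2, sep="_")

    samples = contrasts.samples
    thy_ids = samples.index[(samples["compartment"] == "thymus") & (samples["lineage"] == "Treg")]
    mem_ids = samples.index[(samples["compartment"] == "memory") & (samples["lineage"] == "Treg")]
    if len(genes):
        thy_mean = contrasts.log2cpm.loc[genes, thy_ids].mean(axis=1)
        mem_mean = contrasts.log2cpm.loc[genes, mem_ids].mean(axis=1)
        thymus_gt_memory = thy_mean > mem_mean
    else:
        thy_mean = mem_mean = thymus_gt_memory = pd.Series(dtype=float)

    enriched = cell.isin(THYMUS_ENRICHED_CELLS) | ((cell == "down_up") & thymus_gt_memory)

    table = pd.DataFrame(
        {
            "c1_status": c1,
            "c2_status": c2,
            "cell": cell,
            "log2fc_thymus_to_naive": contrasts.tables[C1].loc[genes, "log2fc"],
            "log2fc_naive_to_memory": contrasts.tables[C2].loc[genes, "log2fc"],
            "log2fc_thymus_to_memory": contrasts.tables[C3].loc[genes, "log2fc"],
            "p_adj_thymus_to_naive": contrasts.tables[C1].loc[genes, "p_adj"],
            "p_adj_naive_to_memory": contrasts.tables[C2].loc[genes, "p_adj"],
            "mean_log2cpm_thymus": thy_mean,
            "mean_log2cpm_memory": mem_mean,
            "thymus_gt_memory": thymus_gt_memory,
            "thymus_enriched": enriched,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    cells = {
        label: sorted(table.index[table["cell"] == label])
        for label in sorted(table["cell"].unique())
    }
    aggregates = {
        "thymus_enriched": sorted(table.index[table["thymus_enriched"]]),
        "periphery_up": sorted(table.index[table["cell"] == "up_stable"]),
        "memory_up": sorted(table.index[table["cell"] == "stable_up"]),
    }
    return TrajectoryClassification(
        table=table,
        cells=cells,
        thymus_enriched=aggregates["thymus_enriched"],
        aggregates=aggregates,
    )


@dataclasses.dataclass
class HeatmapMatrix:
    matrix: pd.DataFrame  # row-scaled, rows in dendrogram order
    leaf_order: list[str]
    first_split: pd.Series  # cluster id (1 or 2; 0 for zero-variance rows)


def cluster_heatmap_matrix(
    log2cpm: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> HeatmapMatrix:
    """Row-scaled expression matrix with average-linkage gene ordering.

    Rows are z-scored across samples (zero-variance rows become all zeros
    and are placed last, in gene-id order, outside the dendrogram), then
    clustered with Euclidean distance and average linkage.  The two
    first-level cluster memberships are returned alongside the leaf order.
    """
    if log2cpm.shape[0] < 2:
        raise TregsigError("clustering needs at least 2 genes")
    x = log2cpm.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (x - mean) / sd
    z[flat] = 0.0

    genes = log2cpm.index
    live = np.flatnonzero(~flat)
    if live.size >= 2:
        link = sch.linkage(z[live], method="average", metric="euclidean")
        order = live[sch.leaves_list(link)]
        split = sch.fcluster(link, t=2, criterion="maxclust")
        first_split = pd.Series(0, index=genes, dtype=int)
        first_split.iloc[live] = split
    elif live.size == 1:
        order = live
        first_split = pd.Series(0, index=genes, dtype=int)
        first_split.iloc[live] = 1
    else:
        order = np.array([], dtype=int)
        first_split = pd.Series(0, index=genes, dtype=int)

    flat_order = sorted(genes[flat])
    leaf_order = list(genes[order]) + flat_order
    matrix = pd.DataFrame(z, index=genes, columns=log2cpm.columns).loc[leaf_order]
    return HeatmapMatrix(matrix=matrix, leaf_order=leaf_order, first_split=first_split)
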