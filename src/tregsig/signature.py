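"""The thymic Treg expression signature and the reference-gene "private" rule.

The signature is simply the up/down DEG partition of the thymic
Treg-vs-Tconv contrast, ordered by effect size.  The private-gene rule
operationalizes a sorting-strategy argument: because conventional cells
were sorted on negligible CD25 protein, the transcript level of the CD25
gene (IL2RA) in those cells is a ceiling for "effectively absent"
expression, and an up-regulated gene whose mean expression in the opposing
population falls at or below that ceiling is called private.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .de import STATUS_DOWN, STATUS_UP
from .io import TregsigError


@dataclasses.dataclass
class ExpressionSignature:
    """Up and down DEG lists ordered by effect size."""

    up_genes: list[str]  # descending log2fc
    down_genes: list[str]  # ascending log2fc
    source_contrast: str = ""

    @property
    def n_up(self) -> int:
        return len(self.up_genes)

    @property
    def n_down(self) -> int:
        return len(self.down_genes)


@dataclasses.dataclass
class PrivateGeneSet:
    threshold_log2cpm: float
    reference_gene: str
    members: list[str]  # signature (effect-size) order
    opposing_mean: pd.Series  # per-member mean log2-CPM in the opposing samples


def build_signature(result: pd.DataFrame, source_contrast: str = "") -> ExpressionSignature:
    """Split a DEG-called contrast result into the up/down signature."""
    if "status" not in result.columns:
        raise TregsigError("build_signature requires a DEG-called result (column 'status')")
    up = result[result["status"] == STATUS_UP]
    down = result[result["status"] == STATUS_DOWN]
    up = up.sort_values("log2fc", ascending=False, kind="stable")
    down = down.sort_values("log2fc", ascending=True, kind="stable")
    return ExpressionSignature(
        up_genes=list(up.index),
        down_genes=list(down.index),
        source_contrast=source_contrast,
    )


def private_threshold(
    log2cpm: pd.DataFrame,
    reference_gene: str,
    opposing_samples: Sequence[str],
    statistic: str = "mean",
) -> float:
    """Reference-gene expression level in the opposing population.

    Returns the mean (or median) normalized log2-CPM of ``reference_gene``
    across ``opposing_samples``.  The reference gene must have survived
    filtering; exempt it via the filter's ``keep_genes`` if necessary.
    """
    if len(opposing_samples) == 0:
        raise TregsigError("opposing_samples must be non-empty")
    if reference_gene not in log2cpm.index:
        raise TregsigError(
            f"reference gene {reference_gene!r} is not in the expression matrix; "
            "whitelist it from low-expression filtering (keep_genes)"
        )
    vals = log2cpm.loc[reference_gene, list(opposing_samples)]
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "median":
        return float(vals.median())
    raise ValueError(f"unknown statistic {statistic!r}")


def extract_private_genes(
    signature: ExpressionSignature,
    log2cpm: pd.DataFrame,
    opposing_samples: Sequence[str],
    threshold: float,
    reference_gene: str = "",
    inclusive: bool = True,
) -> PrivateGeneSet:
    """Up-DEGs whose opposing-population mean falls below the threshold.

    Membership is monotone in the threshold.  The reference gene itself is
    excluded.  With ``inclusive=True`` (default) genes exactly at the
    threshold count as private.
    """
    up = [g for g in signature.up_genes if g != reference_gene]
    if up:
        means = log2cpm.loc[up, list(opposing_samples)].mean(axis=1)
    else:
        means = pd.Series(dtype=float)
    if inclusive:
        mask = means <= threshold
    else:
        mask = means < threshold
    members = [g for g in up if mask.get(g, False)]
    return PrivateGeneSet(
        threshold_log2cpm=float(threshold),
        reference_gene=reference_gene,
        members=members,
        opposing_mean=means[members],
    )


def annotate_overlap(
    signature: ExpressionSignature,
    gene_list: Iterable[str],
    label: str = "",
) -> dict:
    """Overlap of an annotation list (e.g. transcription factors) with the signature."""
    listed = set(gene_list)
    up = [g for g in signature.up_genes if g in listed]
    down = [g for g in signature.down_genes if g in listed]
    return {
        "label": label,
        "n_up": len(up),
        "n_down": len(down),
        "up_members": up,
        "down_members": down,
    }


def signature_table(result: pd.DataFrame, signature: ExpressionSignature) -> pd.DataFrame:
    """Tabular form of the signature for writing (direction + statistics)."""
    genes = signature.up_genes + signature.down_genes
    table = result.loc[genes, ["log2fc", "moderated_t", "p_raw", "p_adj", "status"]].copy()
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    return table
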