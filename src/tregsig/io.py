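"""Readers and writers for count matrices, gene sets, gene lists and configuration.

The on-disk formats are deliberately plain: tab-separated UTF-8 text with a
``.`` decimal separator and no quoting, the standard GMT format for gene-set
collections, one-gene-per-line text files for gene lists, and YAML for the
pipeline configuration.  Gene identifiers are opaque strings throughout; no
identifier conversion is performed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

COMPARTMENTS = ("thymus", "naive", "memory")
LINEAGES = ("Treg", "Tconv")

METADATA_COLUMNS = ("sample_id", "donor_id", "compartment", "lineage")

#: significant digits used when writing floating-point results; chosen so a
#: write/read round-trip reproduces values to 12 significant digits.
FLOAT_FORMAT = "%.12g"


class TregsigError(Exception):
    """Base class for errors raised by this package."""


class ParseError(TregsigError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows (index = gene ids) and
        samples in columns (columns = sample ids).
    samples
        Per-sample metadata indexed by ``sample_id`` with columns
        ``donor_id``, ``compartment`` (thymus/naive/memory) and ``lineage``
        (Treg/Tconv), in the same order as the count columns.
    library_sizes
        Per-sample sequencing depth.  Defaults to the column sums.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise ParseError(f"duplicate gene id {dup!r} in count matrix")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals), atol=0, rtol=0):
                raise ParseError("count matrix contains non-integer values")
            counts = counts.astype(np.int64)
            self.counts = counts
            vals = counts.to_numpy()
        if (vals < 0).any():
            raise ParseError("count matrix contains negative values")
        if list(counts.columns) != list(self.samples.index):
            raise ParseError("count columns and sample metadata are not aligned")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        for col in ("donor_id", "compartment", "lineage"):
            if col not in self.samples.columns:
                raise ParseError(f"sample metadata is missing column {col!r}")
        bad = set(self.samples["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ParseError(f"unknown compartment token(s): {sorted(bad)}")
        bad = set(self.samples["lineage"]) - set(LINEAGES)
        if bad:
            raise ParseError(f"unknown lineage token(s): {sorted(bad)}")
        if self.library_sizes is None:
            self.library_sizes = counts.sum(axis=0).astype(np.int64)
        self.library_sizes = self.library_sizes.reindex(counts.columns)
        if (self.library_sizes <= 0).any():
            zero = self.library_sizes.index[self.library_sizes <= 0][0]
            raise ParseError(f"sample {zero!r} has non-positive library size")

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_labels(self) -> pd.Series:
        """Per-sample population label ``"<compartment>.<lineage>"``."""
        return self.samples["compartment"] + "." + self.samples["lineage"]

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(
            counts=self.counts[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            library_sizes=self.library_sizes[ids].copy(),
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        ids = list(gene_ids)
        return CountMatrix(
            counts=self.counts.loc[ids].copy(),
            samples=self.samples.copy(),
            library_sizes=self.library_sizes.copy(),
        )


def read_count_matrix(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample TSV count matrix and its sample metadata TSV.

    The counts file must have a header row of sample ids and a first column
    of gene ids.  The metadata file must have columns ``sample_id``,
    ``donor_id``, ``compartment`` and ``lineage``.  Samples are returned in
    metadata order; count columns not listed in the metadata are dropped.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ParseError(f"metadata file is missing column(s) {missing_cols}")
    meta = meta.set_index("sample_id")
    absent = [s for s in meta.index if s not in counts.columns]
    if absent:
        raise ParseError(
            f"sample(s) {absent} listed in metadata but absent from the count matrix header"
        )
    counts = counts[list(meta.index)]
    return CountMatrix(counts=counts, samples=meta)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and gene lists
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets, e.g. an MSigDB Hallmark-style collection."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``set_name<TAB>description<TAB>member1<TAB>...``.

    Members are deduplicated and empty member fields dropped.  A line with
    fewer than three tab-separated fields raises :class:`ParseError` naming
    the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name=name, description=desc, members=members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line; blank lines ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per named table into ``out_dir``.

    Column order is preserved as given (deterministic); rows with a ``p_adj``
    column are sorted by adjusted p then gene id so ties break
    lexicographically.  Returns the mapping table name -> written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise PermissionError(out_dir)
    except OSError as exc:
        raise TregsigError(f"output directory {out_dir} is not writable: {exc}") from exc
    written: dict[str, Path] = {}
    for name, table in tables.items():
        table = table.copy()
        if "p_adj" in table.columns:
            order = np.lexsort((table.index.astype(str), table["p_adj"].to_numpy()))
            table = table.iloc[order]
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")
        written[name] = path
    return written


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file (used in run manifests)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and switches shared across the analysis stages.

    ``adjust_method`` selects the multiple-testing correction applied before
    DEG calling: ``"bh"`` (Benjamini-Hochberg, controls the FDR that the DEG
    rule thresholds; default) or ``"holm"`` (step-down FWER control).
    ``trajectory_adjust_scope`` selects whether trajectory-contrast p-values
    are adjusted within the tested private-gene family (``"private"``,
    default) or across all filtered genes (``"genome"``).
    """

    filter_min_cpm: float = 1.0
    filter_max_low_libraries: int = 2
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    adjust_method: str = "bh"
    reference_gene: str = "IL2RA"
    gsea_nperm: int = 10_000
    seed: int = 0
    private_statistic: str = "mean"  # or "median"
    private_inclusive: bool = True  # boundary genes at the threshold count
    trajectory_adjust_scope: str = "private"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.adjust_method not in ("holm", "bh"):
            raise ValueError(f"adjust_method must be 'holm' or 'bh', got {self.adjust_method!r}")
        if self.gsea_nperm < 100:
            raise ValueError("gsea_nperm must be >= 100")
        if self.private_statistic not in ("mean", "median"):
            raise ValueError("private_statistic must be 'mean' or 'median'")
        if self.trajectory_adjust_scope not in ("private", "genome"):
            raise ValueError("trajectory_adjust_scope must be 'private' or 'genome'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
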