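"""Core data model and I/O: community tables, trees, metadata, distance matrices.

The community table is the substrate of every downstream analysis: a
taxon x sample matrix of sequence counts (or relative abundances), as
produced by an amplicon denoising pipeline. This module provides readers
for the plain-text formats such tables travel in (TSV/CSV, JSON-flavour
BIOM), the rooted phylogeny the phylogenetic null models consume, and the
sample-to-group metadata, plus the standard preprocessing steps: rarefaction
to a common depth, the low-occurrence/low-abundance filter applied before
null-model analysis, top-k abundance restriction for network construction,
and conversion to relative abundances.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("ecoassembly")

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "DistanceMatrix",
    "read_community_table",
    "read_biom_table",
    "read_tree",
    "read_metadata",
    "write_community_table",
    "rarefy",
    "filter_low_occurrence",
    "top_abundant_taxa",
    "relative_abundance",
]


@dataclass
class CommunityTable:
    """Taxon x sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame with taxa as the index and samples as columns. All values
        must be non-negative and identifiers unique.
    mode
        ``"counts"`` for raw read counts, ``"proportions"`` when every
        sample column sums to 1.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ValueError(f"mode must be 'counts' or 'proportions', got {self.mode!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate taxon identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(values))
            raise ValueError(f"non-numeric cell at {tuple(bad[0])}")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at taxon {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.mode == "proportions":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                j = int(np.argmax(np.abs(sums - 1.0)))
                raise ValueError(
                    f"proportions column {cols[j]!r} sums to {sums[j]}, expected 1"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_samples(self, sample_ids: list[str]) -> "CommunityTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return CommunityTable(self.data[sample_ids].copy(), mode=self.mode)

    def select_taxa(self, taxon_ids: list[str]) -> "CommunityTable":
        missing = [t for t in taxon_ids if t not in self.data.index]
        if missing:
            raise KeyError(f"unknown taxon(s): {missing}")
        return CommunityTable(self.data.loc[taxon_ids].copy(), mode=self.mode)


@dataclass
class SampleMetadata:
    """Mapping from sample identifier to group label, plus optional covariates."""

    groups: pd.Series  # index: sample_id, values: group label
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            dup = self.groups.index[self.groups.index.duplicated()][0]
            raise ValueError(f"duplicate sample identifier in metadata: {dup!r}")

    def group_of(self, sample_id: str) -> str:
        return str(self.groups.loc[sample_id])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.groups))

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise KeyError(f"unknown group: {group!r}")
        return list(self.groups.index[self.groups == group])

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return self.groups.loc[sample_ids].to_numpy()


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample matrix of pairwise values.

    Used for Bray-Curtis and also for the signed null-model deviations
    (beta-NTI, Raup-Crick), which share the shape but are not metrics;
    entries may be NaN where a null distribution was degenerate.
    """

    ids: list[str]
    values: np.ndarray
    metric: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate sample identifiers")
        finite = ~np.isnan(self.values)
        sym = np.abs(np.where(finite & finite.T, self.values - self.values.T, 0.0))
        if np.nanmax(sym, initial=0.0) > 1e-12:
            raise ValueError("matrix is not symmetric to 1e-12")
        if np.nanmax(np.abs(np.diag(self.values)), initial=0.0) > 1e-12:
            raise ValueError("diagonal is not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def pairs(self):
        """Yield (id_i, id_j, value) over unordered pairs, i < j in index order."""
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.ids[i], self.ids[j], float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Readers / writers


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_community_table(
    path: str | Path,
    orientation: str = "taxa-as-rows",
    sep: str | None = None,
) -> CommunityTable:
    """Read a TSV/CSV abundance table into a :class:`CommunityTable`.

    Parameters
    ----------
    orientation
        ``"taxa-as-rows"`` (default) or ``"samples-as-rows"``; the result is
        always normalised to taxon x sample.
    sep
        Field separator; sniffed from the file when ``None``.
    """
    if orientation not in ("taxa-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate identifier in {path.name}: {dup!r}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path.name} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if orientation == "samples-as-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityTable(df, mode="counts")


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    df = table.data
    if table.mode == "counts" and np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_biom_table(path: str | Path) -> CommunityTable:
    """Read a JSON-flavour BIOM file (dense or sparse) into a CommunityTable."""
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return CommunityTable(pd.DataFrame(mat, index=taxa, columns=samples), mode="counts")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tree tip labels are not unique")
    return tree


def read_metadata(path: str | Path, sep: str | None = None) -> SampleMetadata:
    """Read sample metadata: TSV with header ``sample_id<TAB>group`` (+ extras)."""
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if "group" not in df.columns:
        raise ValueError(f"metadata {path.name} lacks a 'group' column")
    covars = df.drop(columns=["group"])
    return SampleMetadata(df["group"], covars if covars.shape[1] else None)


# ---------------------------------------------------------------------------
# Preprocessing operations


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample without replacement to exactly `depth` reads.

    Samples whose total count is below `depth` are dropped (and logged).
    Counts must be integers: rarefaction draws individual reads.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    if table.mode != "counts":
        raise ValueError("rarefy requires a counts-mode table")
    counts = table.values
    if not np.allclose(counts % 1, 0):
        raise ValueError("rarefy requires integer counts")
    counts = counts.astype(np.int64)
    rng = np.random.default_rng(seed)
    kept_cols: list[str] = []
    out_cols: list[np.ndarray] = []
    for j, sample in enumerate(table.sample_ids):
        total = int(counts[:, j].sum())
        if total < depth:
            logger.warning(
                "rarefy: dropping sample %r (total %d < depth %d)", sample, total, depth
            )
            continue
        out_cols.append(rng.multivariate_hypergeometric(counts[:, j], depth))
        kept_cols.append(sample)
    if not kept_cols:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    df = pd.DataFrame(
        np.column_stack(out_cols), index=table.taxon_ids, columns=kept_cols
    )
    return CommunityTable(df, mode="counts")


def filter_low_occurrence(table: CommunityTable) -> CommunityTable:
    """Drop low-occurrence and low-abundance taxa before null-model analysis.

    Retains taxa with prevalence >= 50% of samples AND total count >= the
    number of samples. Exactly-50% prevalence is retained (only taxa with
    prevalence strictly below the threshold are excluded).
    """
    if table.mode != "counts":
        raise ValueError("filter_low_occurrence requires a counts-mode table")
    counts = table.values
    n_samples = table.n_samples
    prevalence = (counts > 0).sum(axis=1) / n_samples
    totals = counts.sum(axis=1)
    keep = (prevalence >= 0.5) & (totals >= n_samples)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_low_occurrence: removed %d of %d taxa", dropped, table.n_taxa)
    return CommunityTable(table.data.loc[keep].copy(), mode="counts")


def top_abundant_taxa(table: CommunityTable, k: int = 400) -> CommunityTable:
    """Keep the k taxa with the highest total count across all samples.

    Ties are broken lexicographically on the taxon identifier so the
    selection is deterministic across runs and platforms.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= table.n_taxa:
        if k > table.n_taxa:
            logger.warning(
                "top_abundant_taxa: k=%d exceeds %d taxa; keeping all", k, table.n_taxa
            )
        return CommunityTable(table.data.copy(), mode=table.mode)
    totals = table.data.sum(axis=1)
    order = sorted(table.taxon_ids, key=lambda t: (-totals[t], t))
    kept = set(order[:k])
    keep_mask = [t in kept for t in table.taxon_ids]
    return CommunityTable(table.data.loc[keep_mask].copy(), mode=table.mode)


def relative_abundance(table: CommunityTable) -> CommunityTable:
    """Convert counts to per-sample proportions (columns sum to 1)."""
    if table.mode == "proportions":
        return CommunityTable(table.data.copy(), mode="proportions")
    sums = table.values.sum(axis=0)
    if np.any(sums == 0):
        j = int(np.argmax(sums == 0))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero total abundance")
    return CommunityTable(table.data / sums, mode="proportions")
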