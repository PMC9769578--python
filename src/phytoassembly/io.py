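"""Readers, writers, validation and rarefaction for ASV community data.

The three on-disk artefacts of a study are a taxa x samples integer count
table (TSV), a rooted newick phylogeny with branch lengths over the same
taxa, and a per-sample metadata table (CSV, ISO-8601 dates) carrying the
environmental variables. Everything downstream (alpha structure, turnover
nulls, signal tests) consumes the in-memory types defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "Phylogeny",
    "ValidationReport",
    "CommunityTableError",
    "TreeError",
    "UnsupportedFormatError",
    "read_community_table",
    "write_community_table",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "validate_consistency",
    "rarefy",
]


class CommunityTableError(ValueError):
    """Malformed or invariant-violating community table."""


class TreeError(ValueError):
    """Malformed or invariant-violating phylogeny."""


class UnsupportedFormatError(ValueError):
    """Requested file format is not supported by this build."""


# ---------------------------------------------------------------------------
# CommunityTable
# ---------------------------------------------------------------------------


class CommunityTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    taxon_ids, sample_ids
        Unique string identifiers for rows and columns.
    counts
        Integer array of shape ``(n_taxa, n_samples)``, all entries >= 0.
    rarefied
        Set once every column sums to the same depth (enforced).
    """

    def __init__(
        self,
        taxon_ids: Sequence[str],
        sample_ids: Sequence[str],
        counts: np.ndarray,
        rarefied: bool = False,
    ) -> None:
        taxon_ids = [str(t) for t in taxon_ids]
        sample_ids = [str(s) for s in sample_ids]
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape != (len(taxon_ids), len(sample_ids)):
            raise CommunityTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxon_ids)} taxa x {len(sample_ids)} samples"
            )
        if len(set(taxon_ids)) != len(taxon_ids):
            dup = sorted({t for t in taxon_ids if taxon_ids.count(t) > 1})
            raise CommunityTableError(f"duplicate taxon ids: {dup}")
        if len(set(sample_ids)) != len(sample_ids):
            dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise CommunityTableError(f"duplicate sample ids: {dup}")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise CommunityTableError("counts must be integers")
        bad = np.argwhere(counts < 0)
        if bad.size:
            i, j = bad[0]
            raise CommunityTableError(
                f"negative count at taxon {taxon_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        counts = counts.astype(np.int64)
        if rarefied:
            sums = counts.sum(axis=0)
            if len(sums) and not np.all(sums == sums[0]):
                raise CommunityTableError(
                    "rarefied flag requires equal column sums, got "
                    f"{sums.min()}..{sums.max()}"
                )
        self.taxon_ids = taxon_ids
        self.sample_ids = sample_ids
        self.counts = counts
        self.rarefied = rarefied

    # -- basic views -------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.taxon_ids, name="taxon_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rarefied: bool = False) -> "CommunityTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(), rarefied=rarefied)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def sorted(self) -> "CommunityTable":
        """Canonical copy: taxa and samples in lexicographic order.

        Permutation null models are run on the sorted table so that results
        do not depend on input file ordering.
        """
        ti = np.argsort(self.taxon_ids)
        si = np.argsort(self.sample_ids)
        return CommunityTable(
            [self.taxon_ids[i] for i in ti],
            [self.sample_ids[j] for j in si],
            self.counts[np.ix_(ti, si)],
            rarefied=self.rarefied,
        )

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.counts.sum(axis=1) > 0
        dropped = [t for t, k in zip(self.taxon_ids, keep) if not k]
        if dropped:
            logger.info("dropping %d all-zero taxa: %s", len(dropped), dropped[:10])
        return CommunityTable(
            [t for t, k in zip(self.taxon_ids, keep) if k],
            self.sample_ids,
            self.counts[keep],
            rarefied=self.rarefied,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:  # pragma: no cover
        tag = ", rarefied" if self.rarefied else ""
        return f"<CommunityTable {self.n_taxa} taxa x {self.n_samples} samples{tag}>"


def read_community_table(path: str | Path, format: str = "tsv") -> CommunityTable:
    """Read a taxa x samples count table.

    TSV layout: first column is the taxon id (header ``taxon_id`` or
    anything else), remaining columns one per sample; cells are
    non-negative integers. Input row/column order is preserved.
    """
    path = Path(path)
    if format == "biom":
        raise UnsupportedFormatError(
            "BIOM input is not supported in this build; convert to TSV "
            "(e.g. `biom convert --to-tsv`) first"
        )
    if format != "tsv":
        raise UnsupportedFormatError(f"unknown community table format {format!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.size == 0:
        raise CommunityTableError(f"{path}: no sample columns found")
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            row = raw.index[np.argmax(bad.to_numpy())]
            raise CommunityTableError(
                f"{path}: malformed numeric cell at taxon {row!r}, sample {col!r}"
            )
        vals = converted.to_numpy()
        if np.any(vals != np.floor(vals)):
            row = raw.index[int(np.argmax(vals != np.floor(vals)))]
            raise CommunityTableError(
                f"{path}: non-integer count at taxon {row!r}, sample {col!r}"
            )
        if np.any(vals < 0):
            row = raw.index[int(np.argmax(vals < 0))]
            raise CommunityTableError(
                f"{path}: negative count at taxon {row!r}, sample {col!r}"
            )
        counts[:, j] = vals.astype(np.int64)
    sums = counts.sum(axis=0)
    rarefied = len(sums) > 1 and bool(np.all(sums == sums[0]))
    return CommunityTable(list(raw.index), list(raw.columns), counts,
                          rarefied=rarefied)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    """Write a TSV that :func:`read_community_table` reads back bit-exactly."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted phylogeny with branch lengths; tips are the analysis taxa.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    invariants the phylogenetic metrics rely on: unique tip labels, every
    branch length present and non-negative, rooted topology (a root with
    three or more children is treated as unrooted and rejected).
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dup = sorted({t for t in labels if labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        if len(labels) < 2:
            raise TreeError("tree must have at least 2 tips")
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            raise TreeError(
                "tree looks unrooted (root has more than two children); "
                "root it before use"
            )
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue
            if edge.length is None:
                raise TreeError("tree has a branch without a length")
            if edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
        tree.is_rooted = True
        self.tree = tree
        self.tip_labels = sorted(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Patristic (cophenetic) distance matrix over tips.

        Rows/columns in lexicographic tip order; ``d(i,j)`` is the sum of
        branch lengths on the tree path between tips i and j.
        """
        # d(i,j) = depth_i + depth_j - 2*depth(LCA); postorder accumulation
        # of tip sets visits every LCA of a tip pair exactly once
        depth: dict[dendropy.Node, float] = {self.tree.seed_node: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        order = {lab: i for i, lab in enumerate(self.tip_labels)}
        tipdepth = np.zeros(self.n_tips)
        for leaf in self.tree.leaf_node_iter():
            tipdepth[order[leaf.taxon.label]] = depth[leaf]
        d = np.zeros((self.n_tips, self.n_tips))
        tipsets: dict[dendropy.Node, np.ndarray] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = np.array([order[node.taxon.label]])
                continue
            children = [tipsets.pop(c) for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia, jb = children[a], children[b]
                    block = (
                        tipdepth[ia][:, None] + tipdepth[jb][None, :]
                        - 2.0 * depth[node]
                    )
                    d[np.ix_(ia, jb)] = block
                    d[np.ix_(jb, ia)] = block.T
            tipsets[node] = np.concatenate(children)
        return pd.DataFrame(d, index=self.tip_labels, columns=self.tip_labels)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, L={self.total_branch_length():.4g}>"


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        msg = str(exc)
        if "Multiple occurrences" in msg or "duplicate" in msg.lower():
            raise TreeError(f"duplicate tip label in {path}: {msg}") from exc
        raise TreeError(f"failed to parse newick {path}: {msg}") from exc
    return Phylogeny(tree)


def write_tree(phy: Phylogeny, path: str | Path) -> None:
    """Write newick preserving branch lengths to full precision."""
    phy.tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        real_value_format_specifier=".17g",
    )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

#: canonical environmental variable names (units in docs/methods.md)
ENV_VARIABLES = [
    "temperature", "salinity", "par", "no2no3", "sioh4", "po4",
    "chla", "wind_stress", "rainfall", "env",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata CSV.

    Requires columns ``sample_id``, ``date`` (ISO-8601) and ``station``;
    every other numeric column is treated as an environmental variable.
    A ``month`` column (1-12) is derived from the date.
    """
    md = pd.read_csv(path)
    for col in ("sample_id", "date", "station"):
        if col not in md.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        dup = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    md["date"] = pd.to_datetime(md["date"], format="ISO8601")
    md["month"] = md["date"].dt.month
    n_missing = int(md.select_dtypes("number").isna().sum().sum())
    if n_missing:
        logger.warning("metadata has %d missing environmental values", n_missing)
    return md.set_index("sample_id", drop=False)


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    out = md.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.drop(columns=["month"], errors="ignore").to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Consistency validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Cross-checks between table, tree and metadata before analysis."""

    shared_taxa: int
    taxa_missing_from_tree: list[str] = field(default_factory=list)
    samples_missing_metadata: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.taxa_missing_from_tree and not self.samples_missing_metadata


def validate_consistency(
    table: CommunityTable,
    tree: Phylogeny | None = None,
    metadata: pd.DataFrame | None = None,
) -> ValidationReport:
    """Report taxa absent from the tree and samples without metadata.

    Report-only: the pipeline refuses to run phylogenetic stages when
    ``is_valid`` is false, but this function never raises.
    """
    tips = set(tree.tip_labels) if tree is not None else set(table.taxon_ids)
    missing_taxa = sorted(set(table.taxon_ids) - tips)
    if metadata is None:
        missing_samples = list(table.sample_ids)
    else:
        have = set(metadata["sample_id"].astype(str))
        missing_samples = sorted(set(table.sample_ids) - have)
    shared = len(set(table.taxon_ids) & tips)
    return ValidationReport(
        shared_taxa=shared,
        taxa_missing_from_tree=missing_taxa,
        samples_missing_metadata=missing_samples,
    )


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample is an independent multivariate-hypergeometric draw from
    its observed reads (classical rarefaction). Samples with fewer than
    ``depth`` reads are dropped and logged; taxa left with all-zero rows
    are dropped and logged. Deterministic for a given (table, depth, seed).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    totals = table.counts.sum(axis=0)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info(
            "rarefy: dropping %d samples with fewer than %d reads: %s",
            len(dropped), depth, dropped,
        )
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    cols = []
    kept_ids = []
    for j, sample in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        col = table.counts[:, j]
        if totals[j] == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
        kept_ids.append(sample)
    out = CommunityTable(
        table.taxon_ids, kept_ids, np.column_stack(cols), rarefied=True
    )
    return out.drop_empty_taxa()
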