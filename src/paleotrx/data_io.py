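"""Expression tables, binary character matrices, and trees.

Core containers and readers/writers for the three data artifacts the
pipeline moves between stages:

* :class:`ExpressionMatrix` — gene × sample TPM values, missing entries
  allowed (a gene may be unannotated in a species).
* :class:`BinaryMatrix` — taxa × gene character states in ``{0, 1, ?}``
  obtained by thresholding TPM values.
* :class:`PhyloTree` — a phylogeny with branch lengths and (optionally
  labeled) internal nodes, backed by :mod:`dendropy`.

Binary encoding follows the expressed/not-expressed rule: TPM at or above
the threshold (default 2.0) codes state 1, below codes state 0, and a gene
without data in a species codes missing ``?``.  A measured TPM of 0.0 is
state 0, *not* missing: absence of annotation and absence of expression
are distinct observations.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

#: Integer code used for a missing ('?') character state.
MISSING = -1

_STATE_CHARS = {0: "0", 1: "1", MISSING: "?"}
_CHAR_STATES = {"0": 0, "1": 1, "?": MISSING}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene × sample expression table in TPM units.

    ``values`` is a float array of shape (n_genes, n_samples); missing
    entries (gene not annotated in that species) are NaN.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids")
        present = ~np.isnan(self.values)
        if np.any(self.values[present] < 0):
            raise DataError("negative expression values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class BinaryMatrix:
    """Taxa × genes binary character matrix with states {0, 1, ?}.

    ``states`` is an int8 array of shape (n_taxa, n_genes); missing states
    are stored as :data:`MISSING` (-1).
    """

    taxa: list[str]
    gene_ids: list[str]
    states: np.ndarray
    threshold_used: float | None = None
    tree: "PhyloTree | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.gene_ids)):
            raise DataError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.gene_ids)} genes"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise DataError("duplicate taxa")
        bad = ~np.isin(self.states, (0, 1, MISSING))
        if bad.any():
            raise DataError(f"invalid state codes: {np.unique(self.states[bad])}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def row_strings(self) -> list[str]:
        return ["".join(_STATE_CHARS[int(s)] for s in row) for row in self.states]

    def subset_taxa(self, taxa: Sequence[str]) -> "BinaryMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return BinaryMatrix(
            taxa=list(taxa),
            gene_ids=list(self.gene_ids),
            states=self.states[idx],
            threshold_used=self.threshold_used,
        )


class PhyloTree:
    """A phylogenetic tree with branch lengths and internal labels.

    Thin wrapper over :class:`dendropy.Tree` that enforces unique tip
    labels and exposes the operations the pipeline needs (copying,
    re-rooting-safe traversal, bipartition sets, Newick round-trips).
    """

    def __init__(self, tree: dendropy.Tree):
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate tip labels in tree")
        self._tree = tree

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            raise DataError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic structure ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def internal_labels(self) -> list[str]:
        return [
            node.label
            for node in self._tree.preorder_internal_node_iter()
            if node.label is not None
        ]

    def label_internal_nodes(self, prefix: str = "Node") -> None:
        """Assign stable labels ``<prefix><k>`` (preorder numbering) to any
        unlabeled internal node."""
        used = set(self.internal_labels()) | set(self.tip_labels)
        k = 1
        for node in self._tree.preorder_internal_node_iter():
            if node.label is None:
                while f"{prefix}{k}" in used:
                    k += 1
                node.label = f"{prefix}{k}"
                used.add(node.label)

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter() if e.head_node.parent_node
        )

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side frozenset of
        tip labels (ties broken lexicographically)."""
        tips = frozenset(self.tip_labels)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            other = tips - below
            if len(below) < 2 or len(other) < 2:
                continue
            if len(below) < len(other) or (
                len(below) == len(other) and sorted(below) < sorted(other)
            ):
                out.add(below)
            else:
                out.add(other)
        return out

    def rf_distance(self, other: "PhyloTree") -> int:
        """Unweighted Robinson–Foulds distance (symmetric difference of
        non-trivial bipartition sets)."""
        if set(self.tip_labels) != set(other.tip_labels):
            raise DataError("trees have different tip sets")
        return len(self.bipartitions() ^ other.bipartitions())

    # -- serialization -----------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}g",
        )
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.n_tips} tips)"


# ---------------------------------------------------------------------------
# encoding and filtering


def encode_binary(expr: ExpressionMatrix, threshold: float = 2.0) -> BinaryMatrix:
    """Discretize TPM values into binary expressed/not-expressed states.

    A gene is coded 1 (expressed) in a sample when its TPM is >= the
    threshold, 0 when below it, and ``?`` when the value is missing.  The
    comparison is on the exact stored value; no rounding is applied.

    Parameters
    ----------
    expr:
        Gene × sample TPM table.
    threshold:
        Expression cutoff in TPM units (default 2.0); must be positive.

    Returns
    -------
    BinaryMatrix
        Taxa × genes states; note the transpose relative to ``expr``
        (samples become taxa rows).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise DataError("empty expression matrix")
    vals = expr.values
    states = np.where(np.isnan(vals), MISSING, (vals >= threshold).astype(np.int8))
    return BinaryMatrix(
        taxa=list(expr.sample_ids),
        gene_ids=list(expr.gene_ids),
        states=states.T.astype(np.int8),
        threshold_used=threshold,
    )


def filter_columns(
    bm: BinaryMatrix,
    drop_missing: bool = True,
    drop_invariant: bool = True,
) -> tuple[BinaryMatrix, dict[str, int]]:
    """Remove gene columns with missing data and/or invariant states.

    This is the preprocessing applied before clustering: columns containing
    any ``?`` and columns that are constant across taxa (all 0 or all 1)
    carry no clustering information and are dropped.

    Returns the filtered matrix plus a report dict with the number of
    columns removed by each rule (a column failing both rules is counted
    under both keys).
    """
    if bm.n_genes == 0 or bm.n_taxa == 0:
        raise DataError("empty binary matrix")
    has_missing = (bm.states == MISSING).any(axis=0)
    # invariance judged on observed (non-missing) states
    any0 = (bm.states == 0).any(axis=0)
    any1 = (bm.states == 1).any(axis=0)
    invariant = ~(any0 & any1)
    keep = np.ones(bm.n_genes, dtype=bool)
    report = {"removed_missing": 0, "removed_invariant": 0}
    if drop_missing:
        keep &= ~has_missing
        report["removed_missing"] = int(has_missing.sum())
    if drop_invariant:
        keep &= ~invariant
        report["removed_invariant"] = int(invariant.sum())
    if not keep.any():
        raise DataError(
            "all columns removed by filtering "
            f"(missing: {report['removed_missing']}, invariant: {report['removed_invariant']})"
        )
    out = BinaryMatrix(
        taxa=list(bm.taxa),
        gene_ids=[g for g, k in zip(bm.gene_ids, keep) if k],
        states=bm.states[:, keep],
        threshold_used=bm.threshold_used,
    )
    return out, report


# ---------------------------------------------------------------------------
# expression TSV

def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression table: first column gene id, one column per
    taxon, header row required; empty cells are missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns")
    vals = df.apply(pd.to_numeric, errors="coerce")
    # distinguish a truly empty cell (missing) from a non-numeric token
    bad = vals.isna() & df.notna() & (df.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise DataError(f"non-numeric expression value at gene {df.index[g]}, sample {df.columns[s]}")
    return ExpressionMatrix.from_frame(vals)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# character matrices: NEXUS / PHYLIP / TSV


def write_matrix(
    bm: BinaryMatrix,
    path: str | Path,
    fmt: str = "nexus",
    tree: PhyloTree | None = None,
) -> None:
    """Write a binary character matrix.

    ``nexus`` writes a standard-datatype CHARACTERS block with
    ``SYMBOLS="01" MISSING=?``, a CHARLABELS block carrying gene names, and
    a TREES block if a tree is supplied (or attached to the matrix).
    ``phylip`` writes relaxed (whitespace-delimited) PHYLIP; ``tsv`` writes
    taxa as rows and genes as columns.
    """
    path = Path(path)
    tree = tree if tree is not None else bm.tree
    if fmt == "nexus":
        path.write_text(_format_nexus(bm, tree))
    elif fmt == "phylip":
        rows = bm.row_strings()
        with path.open("w") as fh:
            fh.write(f"{bm.n_taxa} {bm.n_genes}\n")
            for taxon, row in zip(bm.taxa, rows):
                fh.write(f"{_safe_label(taxon)}  {row}\n")
    elif fmt == "tsv":
        df = pd.DataFrame(
            [[_STATE_CHARS[int(s)] for s in row] for row in bm.states],
            index=bm.taxa,
            columns=bm.gene_ids,
        )
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown matrix format: {fmt}")


def read_matrix(path: str | Path, fmt: str | None = None) -> BinaryMatrix:
    """Read a binary character matrix from NEXUS, PHYLIP or TSV.

    The format is inferred from the extension when not given.  A NEXUS
    TREES block, if present, is attached to the returned matrix as
    ``.tree``; CHARLABELS provide gene ids (genes are otherwise named
    ``g1..gN``).
    """
    path = Path(path)
    if fmt is None:
        fmt = {
            ".nex": "nexus",
            ".nexus": "nexus",
            ".phy": "phylip",
            ".phylip": "phylip",
            ".tsv": "tsv",
        }.get(path.suffix.lower(), "nexus")
    if fmt == "nexus":
        return _read_nexus(path)
    if fmt == "phylip":
        return _read_phylip(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        states = np.array(
            [[_parse_state(str(v), path) for v in row] for row in df.to_numpy()],
            dtype=np.int8,
        )
        return BinaryMatrix(
            taxa=[str(t) for t in df.index],
            gene_ids=[str(g) for g in df.columns],
            states=states,
        )
    raise ValueError(f"unknown matrix format: {fmt}")


def _parse_state(tok: str, path) -> int:
    tok = tok.strip()
    if tok not in _CHAR_STATES:
        raise DataError(f"{path}: unknown character state {tok!r}")
    return _CHAR_STATES[tok]


def _safe_label(label: str) -> str:
    return label.replace(" ", "_")


def _format_nexus(bm: BinaryMatrix, tree: PhyloTree | None) -> str:
    out = io.StringIO()
    out.write("#NEXUS\n\n")
    out.write("BEGIN TAXA;\n")
    out.write(f"    DIMENSIONS NTAX={bm.n_taxa};\n")
    out.write("    TAXLABELS\n")
    for t in bm.taxa:
        out.write(f"        {_safe_label(t)}\n")
    out.write("    ;\nEND;\n\n")
    out.write("BEGIN CHARACTERS;\n")
    out.write(f"    DIMENSIONS NCHAR={bm.n_genes};\n")
    out.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
    out.write("    CHARLABELS\n        ")
    out.write(" ".join(_safe_label(g) for g in bm.gene_ids))
    out.write("\n    ;\n")
    out.write("    MATRIX\n")
    width = max(len(_safe_label(t)) for t in bm.taxa) + 2
    for taxon, row in zip(bm.taxa, bm.row_strings()):
        out.write(f"        {_safe_label(taxon):<{width}}{row}\n")
    out.write("    ;\nEND;\n")
    if tree is not None:
        out.write("\nBEGIN TREES;\n")
        out.write(f"    TREE phylogeny = {tree.to_newick()}\n")
        out.write("END;\n")
    return out.getvalue()


_CHARLABELS_RE = re.compile(r"CHARLABELS\s+(.*?);", re.IGNORECASE | re.DOTALL)


def _read_nexus(path: Path) -> BinaryMatrix:
    text = Path(path).read_text()
    try:
        ds = dendropy.DataSet.get(data=text, schema="nexus", preserve_underscores=True)
    except dendropy.utility.error.DataParseError as exc:
        raise DataError(f"{path}: invalid NEXUS: {exc}") from exc
    if not ds.char_matrices:
        raise DataError(f"{path}: no CHARACTERS block")
    cm = ds.char_matrices[0]
    taxa = [t.label for t in cm.taxon_namespace if t in cm]
    rows = []
    for t in cm.taxon_namespace:
        if t not in cm:
            continue
        row = []
        for cell in cm[t]:
            row.append(_parse_state(str(cell), path))
        rows.append(row)
    states = np.asarray(rows, dtype=np.int8)
    n_genes = states.shape[1] if states.size else 0
    m = _CHARLABELS_RE.search(text)
    if m:
        gene_ids = m.group(1).split()
        if len(gene_ids) != n_genes:
            raise DataError(
                f"{path}: {len(gene_ids)} CHARLABELS for {n_genes} characters"
            )
    else:
        gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    tree = None
    for tl in ds.tree_lists:
        if len(tl):
            tree = PhyloTree(tl[0])
            break
    return BinaryMatrix(taxa=taxa, gene_ids=gene_ids, states=states, tree=tree)


def _read_phylip(path: Path) -> BinaryMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty file")
    header = lines[0].split()
    if len(header) != 2 or not all(h.isdigit() for h in header):
        raise DataError(f"{path}: malformed PHYLIP header {lines[0]!r}")
    ntax, nchar = int(header[0]), int(header[1])
    body = lines[1:]
    if len(body) != ntax:
        raise DataError(f"{path}: header declares {ntax} taxa but found {len(body)} rows")
    taxa, rows = [], []
    for ln in body:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise DataError(f"{path}: malformed PHYLIP row {ln!r}")
        name, seq = parts
        seq = seq.replace(" ", "").replace("\t", "")
        if len(seq) != nchar:
            raise DataError(
                f"{path}: taxon {name} has {len(seq)} characters, header declares {nchar}"
            )
        taxa.append(name)
        rows.append([_parse_state(c, path) for c in seq])
    return BinaryMatrix(
        taxa=taxa,
        gene_ids=[f"g{i + 1}" for i in range(nchar)],
        states=np.asarray(rows, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# trees


def read_tree(path: str | Path) -> PhyloTree:
    """Read a Newick tree file (internal node labels preserved)."""
    return PhyloTree.from_newick(Path(path).read_text())


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
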