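"""Readers and writers for the external formats the pipeline touches.

Counts come in as CSV/TSV (genes as rows, cells as columns, header row) or as
a MatrixMarket triplet (``base.mtx`` plus ``base.genes.txt`` / ``base.cells.txt``
sidecar files). Gene sets are GMT, protein-interaction networks are 3-column
TSV edge lists. All result tables elsewhere in the package are written as TSV
with a header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionTable",
    "GeneSetCollection",
    "EdgeList",
    "read_counts",
    "write_counts",
    "read_gmt",
    "read_edge_list",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionTable:
    """Genes x cells raw read-count matrix: the pipeline's universal currency.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    cell_ids : list of str
        Unique cell identifiers, one per matrix column.
    counts : ndarray of shape (n_genes, n_cells)
        Non-negative read counts.
    is_spikein : bool ndarray of shape (n_genes,)
        True for synthetic spike-in rows (e.g. ERCC controls); these are
        used only for technical-noise estimation, never in downstream
        biology.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    is_spikein: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        self.counts = np.asarray(self.counts, dtype=float)
        if self.is_spikein is None:
            self.is_spikein = np.zeros(len(self.gene_ids), dtype=bool)
        self.is_spikein = np.asarray(self.is_spikein, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} gene ids / {len(self.cell_ids)} cell ids"
            )
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise FormatError(f"duplicate {kind} ids: {sorted(dupes)}")
        if not np.isfinite(self.counts).all():
            bad = np.argwhere(~np.isfinite(self.counts))[0]
            raise FormatError(f"non-numeric entry at gene row {bad[0]}, cell column {bad[1]}")
        if (self.counts < 0).any():
            g, c = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
            )
        if self.is_spikein.shape != (n_genes,):
            raise FormatError("spike-in flags do not align with gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_genes(self, keep: Sequence[int] | np.ndarray) -> "ExpressionTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionTable(
            [self.gene_ids[i] for i in keep],
            self.cell_ids,
            self.counts[keep, :],
            self.is_spikein[keep],
        )

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "ExpressionTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionTable(
            self.gene_ids,
            [self.cell_ids[i] for i in keep],
            self.counts[:, keep],
            self.is_spikein,
        )

    def biological(self) -> "ExpressionTable":
        """Return the table without spike-in rows."""
        return self.subset_genes(~self.is_spikein)

    def spikeins(self) -> "ExpressionTable":
        return self.subset_genes(self.is_spikein)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a free-text description."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class EdgeList:
    """Undirected weighted interaction network as (gene_a, gene_b, weight) records.

    At most one record per unordered pair; no self-loops; weights in [0, 1].
    """

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen = set()
        for a, b, w in self.edges:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            if not 0.0 <= w <= 1.0:
                raise FormatError(f"edge weight {w} outside [0, 1] for ({a!r}, {b!r})")
            key = frozenset((a, b))
            if key in seen:
                raise FormatError(f"duplicate edge ({a!r}, {b!r})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for a, b, _ in self.edges:
            for n in (a, b):
                if n not in seen:
                    seen.add(n)
                    out.append(n)
        return out


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(
    path: str | Path,
    spikein_prefix: str = "ERCC-",
    delimiter: str | None = None,
) -> ExpressionTable:
    """Read a genes x cells count matrix.

    ``path`` is either a delimited text file (genes as rows, cells as columns,
    header row of cell ids; delimiter sniffed from the extension unless given)
    or a ``.mtx`` MatrixMarket file accompanied by ``<base>.genes.txt`` and
    ``<base>.cells.txt`` name files. Genes whose id starts with
    ``spikein_prefix`` are flagged as spike-ins.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        base = path.with_suffix("")
        genes = Path(f"{base}.genes.txt").read_text().split()
        cells = Path(f"{base}.cells.txt").read_text().split()
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        counts = np.asarray(mat, dtype=float)
        gene_ids, cell_ids = genes, cells
    else:
        sep = delimiter or _sniff_delimiter(path)
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
        dupes = _duplicates(gene_ids) | _duplicates(cell_ids)
        if dupes:
            raise FormatError(f"duplicate ids in {path.name}: {sorted(dupes)}")
        try:
            counts = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric entry in {path.name}: {exc}") from exc
    spike = np.array([g.startswith(spikein_prefix) for g in gene_ids])
    return ExpressionTable(gene_ids, cell_ids, counts, spike)


def write_counts(table: ExpressionTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a count table; integer-valued matrices round-trip exactly."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    mat = table.counts
    if np.allclose(mat, np.round(mat)):
        mat = mat.astype(np.int64)
    pd.DataFrame(mat, index=table.gene_ids, columns=table.cell_ids).to_csv(path, sep=sep)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then member genes, tab-separated."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            # de-duplicate members, preserving first occurrence
            sets[name] = (desc, list(dict.fromkeys(g for g in genes if g)))
    return GeneSetCollection(sets)


def read_edge_list(path: str | Path, min_weight: float = 0.0) -> EdgeList:
    """Read a TSV edge list (gene_a, gene_b, weight) into an undirected network.

    Edges below ``min_weight`` are dropped; duplicate and reversed-duplicate
    records are merged keeping the maximum weight; self-loops are dropped with
    a warning.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 3:
        raise FormatError("edge list needs 3 columns: gene_a, gene_b, weight")
    best: dict[frozenset, tuple[str, str, float]] = {}
    for a, b, w in df.iloc[:, :3].itertuples(index=False):
        a, b, w = str(a), str(b), float(w)
        if not 0.0 <= w <= 1.0:
            raise FormatError(f"edge weight {w} outside [0, 1] for ({a!r}, {b!r})")
        if a == b:
            logger.warning("dropping self-loop on %r", a)
            continue
        key = frozenset((a, b))
        if key not in best or w > best[key][2]:
            best[key] = (a, b, w)
    edges = [e for e in best.values() if e[2] >= min_weight]
    return EdgeList(edges)


def write_edge_list(net: EdgeList, path: str | Path) -> None:
    pd.DataFrame(net.edges, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line, de-duplicated in order."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return list(dict.fromkeys(genes))
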