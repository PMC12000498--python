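"""Core domain types and on-disk formats.

Everything the pipeline consumes or emits is plain text: counts are
featureCounts-style TSV (first column ``gene_id``, optional annotation
columns ignored by name), sample sheets are CSV, trees are two-column
edge-list TSV or newick, gene sets are GMT. Result tables are TSV with a
``#``-prefixed comment header carrying the parameters that produced them,
so runs are diff-able.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, StructureError

#: featureCounts annotation columns silently dropped from count tables.
ANNOTATION_COLUMNS = frozenset({"Chr", "Start", "End", "Strand", "Length"})

VALID_ASSAYS = ("IP", "INPUT")
VALID_CONDITIONS = ("WT", "KO", "NA")


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers (opaque strings), one per row.
    sample_ids
        Unique sample identifiers, one per column.
    counts
        ``(n_genes, n_samples)`` array of nonnegative integers.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = self.counts != np.floor(self.counts)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise FormatError(
                    f"non-integer count {self.counts[i, j]!r} at gene "
                    f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count {self.counts[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (self.gene_ids == other.gene_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


def read_counts(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a featureCounts-style TSV count table.

    The first column is taken as the gene id; annotation columns
    (Chr/Start/End/Strand/Length) are dropped by name; remaining columns
    must be nonnegative integers.
    """
    if dialect != "tsv":
        raise FormatError(f"unsupported counts dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: count table needs a gene column and >=1 sample column")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    data = df.drop(columns=[gene_col])
    data = data.drop(columns=[c for c in data.columns if c in ANNOTATION_COLUMNS])
    sample_ids = list(data.columns)
    try:
        values = data.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count value ({exc})") from exc
    # CountMatrix.__post_init__ reports the offending cell for negatives /
    # fractional values and duplicated ids.
    return CountMatrix(gene_ids, sample_ids, values)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ("sample_id", "population", "assay", "condition", "replicate")


@dataclass
class SampleSheet:
    """Per-sample metadata: population, assay (IP/INPUT), condition, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing required column(s): {', '.join(missing)}")
        t = self.table.loc[:, list(SAMPLE_SHEET_COLUMNS)].copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["population"] = t["population"].astype(str)
        t["assay"] = t["assay"].astype(str).str.upper()
        t["condition"] = t["condition"].astype(str).str.upper()
        bad = ~t["assay"].isin(VALID_ASSAYS)
        if bad.any():
            raise FormatError(
                f"invalid assay value {t.loc[bad, 'assay'].iloc[0]!r}; "
                f"expected one of {VALID_ASSAYS}"
            )
        badc = ~t["condition"].isin(VALID_CONDITIONS)
        if badc.any():
            raise FormatError(
                f"invalid condition value {t.loc[badc, 'condition'].iloc[0]!r}; "
                f"expected one of {VALID_CONDITIONS}"
            )
        t["replicate"] = pd.to_numeric(t["replicate"], errors="raise").astype(int)
        if (t["replicate"] < 1).any():
            raise FormatError("replicate numbers must be positive integers")
        _check_unique(t["sample_id"].tolist(), "sample id")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def samples_for(self, population: str | None = None, assay: str | None = None,
                    condition: str | None = None) -> list[str]:
        """Sample ids in a (population, assay, condition) stratum; None = any."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if population is not None:
            mask &= t["population"] == population
        if assay is not None:
            mask &= t["assay"] == assay.upper()
        if condition is not None:
            mask &= t["condition"] == condition.upper()
        return t.loc[mask, "sample_id"].tolist()

    def validate_against(self, cm: CountMatrix) -> None:
        sheet = set(self.sample_ids)
        matrix = set(cm.sample_ids)
        if sheet != matrix:
            missing = sorted(matrix - sheet)
            extra = sorted(sheet - matrix)
            raise FormatError(
                f"sample sheet / count matrix mismatch: missing from sheet "
                f"{missing}, absent from matrix {extra}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSheet):
            return NotImplemented
        return self.table.equals(other.table)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the CSV sample sheet; categorical fields are case-normalized."""
    return SampleSheet(pd.read_csv(path, dtype=str, comment="#"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HierarchyTree
# ---------------------------------------------------------------------------

@dataclass
class HierarchyTree:
    """Rooted developmental hierarchy: one root, every non-root one parent."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    parent: dict[str, str] = field(init=False)
    root: str = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        self.edges = [(str(p), str(c)) for p, c in self.edges]
        _check_unique(self.nodes, "tree node")
        node_set = set(self.nodes)
        parent: dict[str, str] = {}
        for p, c in self.edges:
            if p not in node_set or c not in node_set:
                raise StructureError(f"edge ({p!r}, {c!r}) references unknown node")
            if c in parent:
                raise StructureError(f"node {c!r} has two parents")
            parent[c] = p
        roots = [n for n in self.nodes if n not in parent]
        if len(roots) != 1:
            raise StructureError(
                f"tree must have exactly one root, found {len(roots)}: {sorted(roots)}"
            )
        # cycle check: walk up from every node, must terminate at the root
        for n in self.nodes:
            seen = {n}
            cur = n
            while cur in parent:
                cur = parent[cur]
                if cur in seen:
                    raise StructureError(f"cycle detected through node {cur!r}")
                seen.add(cur)
        self.parent = parent
        self.root = roots[0]

    def ancestors(self, node: str) -> list[str]:
        """Ancestors of ``node`` from immediate parent up to the root."""
        if node not in set(self.nodes):
            raise StructureError(f"unknown node {node!r}")
        out: list[str] = []
        cur = node
        while cur in self.parent:
            cur = self.parent[cur]
            out.append(cur)
        return out

    def children(self, node: str) -> list[str]:
        return [c for p, c in self.edges if p == node]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HierarchyTree):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and set(self.edges) == set(other.edges)


def read_tree(path: str | Path, format: str = "edge_list") -> HierarchyTree:
    """Read a rooted tree from a two-column parent/child TSV or newick."""
    if format == "edge_list":
        edges: list[tuple[str, str]] = []
        for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 tab-separated columns")
            edges.append((parts[0], parts[1]))
        if not edges:
            raise FormatError(f"{path}: empty edge list")
        nodes = list(dict.fromkeys([n for e in edges for n in e]))
        return HierarchyTree(nodes, edges)
    if format == "newick":
        return _tree_from_newick(Path(path).read_text())
    raise FormatError(f"unknown tree format {format!r}")


def _tree_from_newick(text: str) -> HierarchyTree:
    import dendropy

    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises a zoo of error types
        raise FormatError(f"could not parse newick tree: {exc}") from exc
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []

    def label(nd) -> str:
        if nd.taxon is not None and nd.taxon.label:
            return str(nd.taxon.label)
        if nd.label:
            return str(nd.label)
        raise FormatError("newick tree contains an unlabeled node")

    for nd in dtree.preorder_node_iter():
        nodes.append(label(nd))
        if nd.parent_node is not None:
            edges.append((label(nd.parent_node), label(nd)))
    return HierarchyTree(nodes, edges)


def write_tree(tree: HierarchyTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p, c in tree.edges:
            fh.write(f"{p}\t{c}\n")


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{line_no}: GMT line needs name, description, >=1 member")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if name in sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        sets[name] = set(members)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Commented result tables (design decision: diff-able TSV outputs)
# ---------------------------------------------------------------------------

def write_result_table(df: pd.DataFrame, path: str | Path,
                       params: Mapping[str, object] | None = None,
                       index: bool = False) -> None:
    """Write a TSV result table with a '#' comment header echoing params."""
    buf = _io.StringIO()
    if params:
        for key in params:
            buf.write(f"# {key}={params[key]}\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def read_result_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
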