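"""Readers and writers for the annotation resources the analyses consume.

Five resource kinds are supported, all as plain text:

* gene constraint (gnomAD-style TSV with pLI and LOEUF columns),
* gene x tissue median-TPM expression (wide TSV, or GCT with its two
  extra header lines),
* undirected protein-protein interaction edge lists (2-column TSV),
* gene-set collections (GMT), and
* gene -> disease maps (2-column TSV, one association per line).

Every loader normalizes symbols through :func:`plgenes.symbols.normalize_symbol`
with the same optional alias map, so downstream joins are exact string
joins. Missing metric values are kept as ``None`` and never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .symbols import normalize_symbol

logger = logging.getLogger(__name__)


class ResourceError(ValueError):
    """A resource file violates its format contract."""


# ---------------------------------------------------------------------------
# Gene constraint (pLI / LOEUF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneConstraint:
    """Per-gene loss-of-function constraint metrics.

    ``pli`` is the probability of intolerance to heterozygous pLoF (near 1
    for haploinsufficient genes); ``loeuf`` is the observed/expected pLoF
    upper-bound fraction (lower = more constrained). Either may be None
    when the source row lacks the value.
    """

    gene: str
    pli: float | None
    loeuf: float | None

    def __post_init__(self) -> None:
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ResourceError(f"{self.gene}: pLI {self.pli} outside [0, 1]")
        if self.loeuf is not None and self.loeuf < 0.0:
            raise ResourceError(f"{self.gene}: negative LOEUF {self.loeuf}")


ConstraintMap = dict[str, GeneConstraint]


def _parse_metric(token: str, what: str, where: str) -> float | None:
    token = token.strip()
    if token in {"", "NA", "NaN", "nan", "."}:
        return None
    try:
        value = float(token)
    except ValueError:
        raise ResourceError(f"{where}: non-numeric {what}: {token!r}") from None
    return None if math.isnan(value) else value


def load_constraint(
    path: str | Path,
    gene_col: str = "gene",
    pli_col: str = "pLI",
    loeuf_col: str = "LOEUF",
    alias_map: Mapping[str, str] | None = None,
) -> ConstraintMap:
    """Read a constraint TSV into a symbol -> :class:`GeneConstraint` map.

    Duplicate symbols are resolved by keeping the row with the lowest
    LOEUF (rows without LOEUF lose); each resolution is logged.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (gene_col, pli_col, loeuf_col):
        if col not in table.columns:
            raise ResourceError(f"{path}: missing column {col!r}")
    out: ConstraintMap = {}
    rows = zip(table[gene_col], table[pli_col], table[loeuf_col])
    for idx, (gene_raw, pli_raw, loeuf_raw) in enumerate(rows, start=2):
        where = f"{path}: row {idx}"
        gene = normalize_symbol(gene_raw, alias_map)
        entry = GeneConstraint(
            gene=gene,
            pli=_parse_metric(pli_raw, "pLI", where),
            loeuf=_parse_metric(loeuf_raw, "LOEUF", where),
        )
        if gene in out:
            keep, drop = sorted(
                (out[gene], entry),
                key=lambda c: math.inf if c.loeuf is None else c.loeuf,
            )
            logger.info(
                "constraint: duplicate rows for %s, keeping LOEUF=%s", gene, keep.loeuf
            )
            entry = keep
        out[gene] = entry
    return out


def write_constraint(constraint: ConstraintMap, path: str | Path) -> None:
    rows = [
        {
            "gene": c.gene,
            "pLI": "" if c.pli is None else f"{c.pli:.4f}",
            "LOEUF": "" if c.loeuf is None else f"{c.loeuf:.4f}",
        }
        for c in sorted(constraint.values(), key=lambda c: c.gene)
    ]
    pd.DataFrame(rows, columns=["gene", "pLI", "LOEUF"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionProfile:
    """Median TPM of one gene across tissues, in fixed tissue order."""

    gene: str
    tpm_by_tissue: tuple[tuple[str, float], ...]

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(v for _, v in self.tpm_by_tissue)

    @property
    def median_tpm(self) -> float:
        values = sorted(self.values)
        mid = len(values) // 2
        if len(values) % 2:
            return values[mid]
        return 0.5 * (values[mid - 1] + values[mid])


class ExpressionMatrix:
    """Gene x tissue median-TPM matrix backed by a pandas DataFrame.

    Rows are genes (normalized symbols), columns are tissues in file
    order. Values are non-negative TPM.
    """

    def __init__(self, table: pd.DataFrame):
        if table.shape[1] == 0:
            raise ResourceError("expression matrix must have at least one tissue")
        if (table.values < 0).any():
            raise ResourceError("expression matrix holds negative TPM values")
        self._table = table.astype(float)

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def genes(self) -> list[str]:
        return list(self._table.index)

    @property
    def tissues(self) -> list[str]:
        return list(self._table.columns)

    def __contains__(self, gene: str) -> bool:
        return gene in self._table.index

    def __len__(self) -> int:
        return len(self._table)

    def profile(self, gene: str) -> ExpressionProfile:
        row = self._table.loc[gene]
        return ExpressionProfile(
            gene=gene, tpm_by_tissue=tuple(zip(self._table.columns, row.tolist()))
        )

    def profiles(self) -> Iterator[ExpressionProfile]:
        for gene in self._table.index:
            yield self.profile(gene)

    def median_tpm(self) -> pd.Series:
        """Per-gene median across tissues."""
        return self._table.median(axis=1)

    def breadth(self, tpm_threshold: float = 10.0) -> pd.Series:
        """Per-gene count of tissues with TPM >= threshold (inclusive)."""
        return (self._table >= tpm_threshold).sum(axis=1)


def load_expression_matrix(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a wide expression table (plain TSV, or GCT with ``#1.2`` magic).

    GCT files carry two extra header lines and a Description column; both
    encodings of the same data load to identical matrices. Ragged rows
    raise :class:`ResourceError`.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    is_gct = first.startswith("#1.2") or path.suffix.lower() == ".gct"
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            skiprows=2 if is_gct else 0,
            index_col=0,
            on_bad_lines="error",
        )
    except pd.errors.ParserError as exc:
        raise ResourceError(f"{path}: ragged or malformed table: {exc}") from None
    if is_gct and table.columns[:1].tolist() == ["Description"]:
        table = table.drop(columns="Description")
    if table.isna().any().any():
        raise ResourceError(f"{path}: ragged table (missing values after parsing)")
    table.index = [normalize_symbol(g, alias_map) for g in table.index]
    return ExpressionMatrix(table)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, gct: bool = False
) -> None:
    """Write the matrix as plain TSV or as a 2-header GCT (TPM to 3 dp)."""
    table = matrix.table.round(3)
    if gct:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{table.shape[0]}\t{table.shape[1]}\n")
            out = table.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.3f")
    else:
        table.to_csv(path, sep="\t", index_label="gene", float_format="%.3f")


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

class InteractionNetwork:
    """Undirected protein-protein interaction network (no self-loops)."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        graph = nx.Graph()
        n_self = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            graph.add_edge(a, b)
        if n_self:
            logger.info("network: dropped %d self-loop(s)", n_self)
        self._graph = graph

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self._graph.has_edge(a, b)

    def neighbors(self, gene: str) -> frozenset[str]:
        if gene not in self._graph:
            return frozenset()
        return frozenset(self._graph.neighbors(gene))

    def edges(self) -> Iterator[tuple[str, str]]:
        for a, b in self._graph.edges:
            yield tuple(sorted((a, b)))  # type: ignore[misc]


def load_network(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> InteractionNetwork:
    """Read a 2-column TSV edge list; duplicates and orientation collapse."""
    edges: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ResourceError(f"{path}: line {lineno}: expected 2 columns")
            edges.append(
                (normalize_symbol(parts[0], alias_map), normalize_symbol(parts[1], alias_map))
            )
    return InteractionNetwork(edges)


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and disease map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetCollection:
    """Named collection of gene sets (e.g. GO_BP, MSigDB_C2)."""

    name: str
    sets: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, members in self.sets.items():
            if not members:
                raise ResourceError(f"{self.name}: gene set {set_name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def subset(self, set_names: Iterable[str]) -> "GeneSetCollection":
        names = list(set_names)
        return GeneSetCollection(
            name=self.name, sets={n: self.sets[n] for n in names}
        )


def load_gmt(
    path: str | Path,
    name: str | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> GeneSetCollection:
    """Read a GMT file (set name, description, then member symbols)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ResourceError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and >=1 member (got {len(fields)} fields)"
                )
            sets[fields[0]] = frozenset(
                normalize_symbol(g, alias_map) for g in fields[2:] if g.strip()
            )
    return GeneSetCollection(name=name or Path(path).stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[set_name]))
            fh.write(f"{set_name}\tna\t{members}\n")


DiseaseMap = dict[str, frozenset[str]]


def load_disease_map(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> DiseaseMap:
    """Read a 2-column gene -> disease-id TSV (one association per line).

    Genes absent from the map simply have no known disease association.
    A header line whose first field is ``gene`` is skipped.
    """
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ResourceError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0].strip().lower() == "gene":
                continue
            gene = normalize_symbol(parts[0], alias_map)
            out.setdefault(gene, set()).add(parts[1].strip())
    return {gene: frozenset(ids) for gene, ids in out.items()}


def write_disease_map(disease_map: DiseaseMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdisease_id\n")
        for gene in sorted(disease_map):
            for disease in sorted(disease_map[gene]):
                fh.write(f"{gene}\t{disease}\n")
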