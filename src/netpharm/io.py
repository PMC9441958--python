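"""Readers and writers for the tabular formats the pipeline consumes.

All gene symbols are normalised the same way by every reader: whitespace
stripped and upper-cased. Downstream modules only ever see the in-memory
types defined here, never raw files.

Formats
-------
* edge table   — TSV ``source  target  [weight]``, no header by default
* gene scores  — TSV ``gene  score``
* C-T table    — TSV ``component  target_gene``
* property table — TSV ``component  MW  logP  HBD  HBA  caco2`` (``NA`` for
  missing values)
* GMT          — MSigDB convention: ``term  description  gene ...``
* network export — SIF / GraphML / edge-TSV
* reports      — JSON with sorted keys, plus TSV summaries
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import ParseError, UsageError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "EdgeTable",
    "GeneScoreTable",
    "ComponentTargetTable",
    "GeneSetCollection",
    "PropertyRecord",
    "PropertyTable",
    "read_edge_table",
    "read_gene_scores",
    "read_component_targets",
    "read_gmt",
    "read_property_table",
    "write_network",
    "write_report",
]


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


def _data_lines(path, header: bool):
    """Yield (lineno, stripped line) skipping blanks; optionally skip one header line."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            yield lineno, line


def _split(line: str) -> list[str]:
    # Tab-delimited by convention; fall back to any whitespace so that
    # hand-written space-separated toy files also load.
    fields = [f for f in line.split("\t") if f.strip()]
    if len(fields) <= 1:
        fields = line.split()
    return [f.strip() for f in fields]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EdgeTable:
    """Undirected weighted edge list (self-loops already removed)."""

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    n_self_loops_dropped: int = 0

    def node_set(self) -> set[str]:
        out: set[str] = set()
        for u, v, _ in self.edges:
            out.add(u)
            out.add(v)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneScoreTable:
    """Gene symbol -> relevance score (dimensionless, >= 0)."""

    scores: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.scores.get(gene, default)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores

    def mean(self) -> float:
        if not self.scores:
            raise ValidationError("cannot take the mean of an empty score table")
        return sum(self.scores.values()) / len(self.scores)


@dataclass
class ComponentTargetTable:
    """Component id -> set of target gene symbols (deduplicated)."""

    targets: dict[str, set[str]] = field(default_factory=dict)

    def components(self) -> list[str]:
        return sorted(self.targets)

    def all_targets(self) -> set[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return out

    def n_pairs(self) -> int:
        return sum(len(g) for g in self.targets.values())

    def __len__(self) -> int:
        return len(self.targets)

    def restrict(self, components: Iterable[str]) -> "ComponentTargetTable":
        keep = set(components)
        return ComponentTargetTable(
            {c: set(g) for c, g in self.targets.items() if c in keep}
        )


@dataclass
class GeneSetCollection:
    """Term id -> (description, member gene set)."""

    sets: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def members(self, term: str) -> set[str]:
        return self.sets[term][1]

    def terms(self) -> list[str]:
        return sorted(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PropertyRecord:
    """Physicochemical descriptors of one component; None marks a missing value."""

    component: str
    mw: float | None = None  # molecular weight, g/mol
    logp: float | None = None  # octanol/water partition, dimensionless
    hbd: float | None = None  # H-bond donors, count
    hba: float | None = None  # H-bond acceptors, count
    caco2: float | None = None  # log10 cm/s permeability surrogate


@dataclass
class PropertyTable:
    records: dict[str, PropertyRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, component: str) -> PropertyRecord:
        return self.records[component]

    def __contains__(self, component: str) -> bool:
        return component in self.records


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_edge_table(path, has_weight_column: bool | None = None, header: bool = False) -> EdgeTable:
    """Load a TSV edge list, dropping self-loops (count is logged).

    ``has_weight_column=None`` auto-detects a third numeric column;
    ``True`` requires one; ``False`` ignores any and assigns weight 1.0.
    """
    edges: list[tuple[str, str, float]] = []
    dropped = 0
    for lineno, line in _data_lines(path, header):
        fields = _split(line)
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected >= 2 columns, got {len(fields)}")
        u, v = _norm_gene(fields[0]), _norm_gene(fields[1])
        weight = 1.0
        want_weight = has_weight_column if has_weight_column is not None else len(fields) >= 3
        if want_weight:
            if len(fields) < 3:
                raise ParseError(path, lineno, "weight column required but missing")
            try:
                weight = float(fields[2])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric weight {fields[2]!r}") from None
            if not math.isfinite(weight) or weight < 0:
                raise ParseError(path, lineno, f"weight must be finite and >= 0, got {weight}")
        if u == v:
            dropped += 1
            continue
        edges.append((u, v, weight))
    if dropped:
        log.info("read_edge_table(%s): dropped %d self-loop row(s)", path, dropped)
    return EdgeTable(edges=edges, n_self_loops_dropped=dropped)


def read_gene_scores(path, header: bool = False) -> GeneScoreTable:
    """Load gene relevance scores; duplicate genes collapse to the maximum."""
    scores: dict[str, float] = {}
    n_dup = 0
    for lineno, line in _data_lines(path, header):
        fields = _split(line)
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        gene = _norm_gene(fields[0])
        try:
            score = float(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric score {fields[1]!r}") from None
        if not math.isfinite(score) or score < 0:
            raise ValidationError(f"{path}:{lineno}: score must be finite and >= 0, got {score}")
        if gene in scores:
            n_dup += 1
            scores[gene] = max(scores[gene], score)
        else:
            scores[gene] = score
    if n_dup:
        log.info("read_gene_scores(%s): collapsed %d duplicate row(s) to max", path, n_dup)
    if not scores:
        log.warning("read_gene_scores(%s): file has no data rows", path)
    return GeneScoreTable(scores=scores)


def read_component_targets(path, header: bool = False) -> ComponentTargetTable:
    """Load component->target pairs; pairs deduplicated, genes normalised."""
    targets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path, header):
        fields = _split(line)
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(fields)}")
        comp = fields[0].strip()
        gene = _norm_gene(fields[1])
        if not comp or not gene:
            log.warning("read_component_targets(%s): skipping blank field at line %d", path, lineno)
            continue
        targets.setdefault(comp, set()).add(gene)
    empty = [c for c, g in targets.items() if not g]
    for c in empty:
        log.warning("read_component_targets(%s): component %s has no valid targets", path, c)
        del targets[c]
    if not targets:
        log.warning("read_component_targets(%s): file has no data rows", path)
    return ComponentTargetTable(targets=targets)


def read_gmt(path) -> GeneSetCollection:
    """Load a GMT gene-set collection (term, description, members...)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"GMT line needs >= 3 tab-separated fields, got {len(fields)}")
            term, desc = fields[0].strip(), fields[1].strip()
            genes = {_norm_gene(g) for g in fields[2:] if g.strip()}
            if not genes:
                raise ParseError(path, lineno, f"gene set {term!r} is empty")
            sets[term] = (desc, genes)
    return GeneSetCollection(sets=sets)


def read_property_table(path, header: bool = False) -> PropertyTable:
    """Load the component physicochemical table; 'NA'/'' mark missing values."""
    records: dict[str, PropertyRecord] = {}
    names = ("mw", "logp", "hbd", "hba", "caco2")
    for lineno, line in _data_lines(path, header):
        fields = line.split("\t")
        if len(fields) < 6:
            fields = line.split()
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected 6 columns, got {len(fields)}")
        comp = fields[0].strip()
        values: dict[str, float | None] = {}
        for name, tok in zip(names, fields[1:6]):
            tok = tok.strip()
            if tok in ("", "NA", "NaN", "nan", "."):
                values[name] = None
                continue
            try:
                x = float(tok)
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric {name} value {tok!r}") from None
            if not math.isfinite(x):
                raise ParseError(path, lineno, f"{name} must be finite, got {x}")
            values[name] = x
        records[comp] = PropertyRecord(component=comp, **values)
    return PropertyTable(records=records)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_network(network, path, format: str = "tsv") -> None:
    """Write a network as SIF, GraphML or edge-TSV.

    SIF lines are ``source<TAB>relation<TAB>target`` with the relation token
    taken from the edge's type attribute (``ct`` or ``ppi``). Edge-TSV
    round-trips through :func:`read_edge_table`.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    if graph.number_of_nodes() == 0:
        raise ValidationError("refusing to write an empty network")
    fmt = format.lower()
    path = Path(path)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                rel = data.get("etype", "ppi")
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif fmt == "graphml":
        export = nx.Graph()
        for n, data in graph.nodes(data=True):
            attrs = {}
            if "roles" in data:
                attrs["roles"] = ",".join(sorted(data["roles"]))
            if data.get("score") is not None:
                attrs["score"] = float(data["score"])
            export.add_node(n, **attrs)
        for u, v, data in graph.edges(data=True):
            export.add_edge(u, v, weight=float(data.get("weight", 1.0)),
                            etype=data.get("etype", "ppi"))
        nx.write_graphml(export, path)
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{float(data.get('weight', 1.0)):g}\n")
    else:
        raise UsageError(f"unknown network format {format!r}; use sif, graphml or tsv")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_report(obj, path) -> None:
    """Serialise a result object as deterministic JSON (sorted keys).

    Enrichment-result lists additionally get a TSV summary next to the JSON
    file (same stem, ``.tsv`` suffix), sorted by adjusted q then term id.
    """
    path = Path(path)
    payload = _jsonable(obj)
    try:
        text = json.dumps(payload, sort_keys=True, indent=2, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"object is not serialisable: {exc}") from exc
    path.write_text(text + "\n", encoding="utf-8")

    if isinstance(obj, list) and obj and hasattr(obj[0], "term"):
        tsv = path.with_suffix(".tsv")
        rows = sorted(obj, key=lambda r: (r.q, r.term))
        with open(tsv, "w", encoding="utf-8") as fh:
            fh.write("term\toverlap\tset_size\tquery_size\tuniverse_size\tp\tq\n")
            for r in rows:
                fh.write(
                    f"{r.term}\t{r.overlap}\t{r.set_size}\t{r.query_size}\t"
                    f"{r.universe_size}\t{r.p:.6g}\t{r.q:.6g}\n"
                )
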