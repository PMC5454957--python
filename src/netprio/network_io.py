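"""Readers, writers and validated containers for the toolkit's three inputs.

The network input follows the STRING ``protein.links`` dialect: one
whitespace-separated record ``protein1 protein2 combined_score`` per line,
every interaction listed in both directions, scores being integer combined
confidence scores between 150 and 999.  Seed genes arrive one identifier per
line; term-to-gene annotations arrive in GMT.

The in-memory containers are deliberately thin: :class:`WeightedNetwork`
wraps an undirected :class:`networkx.Graph` (each unordered pair stored once,
symmetric weight), and :class:`TransitionModel` holds the column-stochastic
transition matrix the random walker multiplies by.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

#: STRING combined scores live on this closed integer interval.
SCORE_MIN = 150
SCORE_MAX = 999


class ParseError(ValueError):
    """An input file violates its format (reported with a line number)."""


class DataError(ValueError):
    """An input file parses but its content is internally inconsistent."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class WeightedNetwork:
    """Undirected gene/protein network with integer interaction scores.

    Parameters
    ----------
    graph
        Undirected graph; every edge carries an integer ``score`` attribute
        in ``[SCORE_MIN, SCORE_MAX]``.  No self-loops, no isolated nodes.
    n_directed_records
        Number of directed input records the network was parsed from (STRING
        lists each interaction twice).  Zero for networks built in memory.
    """

    graph: nx.Graph
    n_directed_records: int = 0

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "WeightedNetwork":
        g = nx.Graph()
        for u, v, s in edges:
            g.add_edge(u, v, score=int(s))
        net = cls(graph=g)
        net.validate()
        return net

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def score(self, u: str, v: str) -> int:
        return self.graph[u][v]["score"]

    def neighbors(self, node: str) -> Iterator[str]:
        return iter(self.graph[node])

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Edges in canonical orientation (lexicographically smaller ID first)."""
        for u, v, d in self.graph.edges(data="score"):
            yield (u, v, d) if u < v else (v, u, d)

    def node_ordering(self) -> list[str]:
        """Canonical (sorted) node ordering shared by all vector code."""
        return sorted(self.graph)

    def validate(self) -> None:
        for u, v, s in self.graph.edges(data="score"):
            if u == v:
                raise DataError(f"self-loop on node {u!r}")
            if not (SCORE_MIN <= s <= SCORE_MAX):
                raise DataError(
                    f"edge {u!r}-{v!r} score {s} outside [{SCORE_MIN}, {SCORE_MAX}]"
                )
        for n in self.graph:
            if self.graph.degree(n) == 0:
                raise DataError(f"isolated node {n!r}")


@dataclass
class TransitionModel:
    """Column-stochastic transition matrix over a fixed node ordering.

    ``matrix[i, j] = S(i, j) / sum_k S(k, j)``: the probability that a walker
    sitting on node ``j`` steps to neighbor ``i``.  Every column sums to one
    (the network has no isolated nodes, so no dangling columns exist).
    """

    nodes: list[str]
    matrix: sparse.csr_array
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {n: i for i, n in enumerate(self.nodes)}


@dataclass
class SeedSet:
    """Validated seed genes: ``ids`` are in the network, file order kept."""

    ids: list[str]
    dropped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class AnnotationMap:
    """Term -> gene-set mapping (GO terms and KEGG pathways on one axis)."""

    term_genes: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return list(self.term_genes)

    def __len__(self) -> int:
        return len(self.term_genes)

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# parsing


def parse_string_links(stream: Iterable[str], organism_code: str = "9606") -> WeightedNetwork:
    """Parse a STRING-style links file, keeping one organism's interactome.

    Only lines where *both* protein IDs start with ``organism_code + "."``
    are kept; the organism prefix is retained in node IDs.  STRING lists each
    interaction in both directions: the two directed records collapse to one
    undirected edge, and disagreeing duplicate scores raise :class:`DataError`
    rather than being averaged.  Self-interaction records are dropped with a
    warning.  An optional header line starting with ``protein1`` is skipped.
    """
    if not organism_code:
        raise ValueError("organism_code must be non-empty")
    prefix = organism_code + "."
    g = nx.Graph()
    n_records = 0
    n_self = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if lineno == 1 and fields[0] == "protein1":
            continue
        if len(fields) != 3:
            raise ParseError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        a, b, raw = fields
        if not (a.startswith(prefix) and b.startswith(prefix)):
            continue
        try:
            s = int(raw)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer score {raw!r}") from exc
        if not (SCORE_MIN <= s <= SCORE_MAX):
            raise ParseError(
                f"line {lineno}: score {s} outside [{SCORE_MIN}, {SCORE_MAX}]"
            )
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            prev = g[a][b]["score"]
            if prev != s:
                raise DataError(
                    f"line {lineno}: conflicting scores for pair {a!r}-{b!r}: "
                    f"{prev} vs {s}"
                )
        else:
            g.add_edge(a, b, score=s)
        n_records += 1
    if n_self:
        logger.warning("dropped %d self-interaction record(s)", n_self)
    net = WeightedNetwork(graph=g, n_directed_records=n_records)
    net.validate()
    logger.info(
        "parsed %d directed records -> %d nodes, %d undirected edges",
        n_records, net.n_nodes, net.n_edges,
    )
    return net


def write_string_links(net: WeightedNetwork, stream: IO[str]) -> None:
    """Write one ``protein1 protein2 combined_score`` line per undirected edge."""
    stream.write("protein1 protein2 combined_score\n")
    for u, v, s in sorted(net.edges()):
        stream.write(f"{u} {v} {s}\n")


def load_seeds(stream: Iterable[str], net: WeightedNetwork) -> SeedSet:
    """Load a one-ID-per-line seed file, keeping only IDs present in the network.

    ``#`` comment lines and blank lines are ignored; duplicates keep their
    first occurrence.  IDs absent from the network go to ``dropped`` with a
    warning; zero retained IDs is fatal.
    """
    ids: list[str] = []
    dropped: list[str] = []
    seen: set[str] = set()
    for line in stream:
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            continue
        seen.add(token)
        if token in net:
            ids.append(token)
        else:
            dropped.append(token)
    if dropped:
        logger.warning("%d seed ID(s) absent from the network: %s",
                       len(dropped), ", ".join(dropped[:5]))
    if not ids:
        raise DataError("no seed ID is present in the network")
    return SeedSet(ids=ids, dropped=dropped)


def load_annotations(stream: Iterable[str]) -> AnnotationMap:
    """Parse GMT lines (``term<TAB>description<TAB>gene...``) into a map.

    Duplicate genes within a term are deduplicated; a repeated term ID is an
    error; a line with fewer than three fields is a parse error.
    """
    term_genes: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: GMT line needs >=3 tab-separated fields")
        term, desc, *genes = fields
        if term in term_genes:
            raise DataError(f"line {lineno}: duplicate term ID {term!r}")
        gene_set = frozenset(x for x in genes if x)
        if not gene_set:
            raise ParseError(f"line {lineno}: term {term!r} annotates no gene")
        term_genes[term] = gene_set
        descriptions[term] = desc
    return AnnotationMap(term_genes=term_genes, descriptions=descriptions)


def write_annotations(ann: AnnotationMap, stream: IO[str]) -> None:
    for term, genes in ann.term_genes.items():
        desc = ann.descriptions.get(term, "")
        stream.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# transition model


def column_normalize(net: WeightedNetwork) -> TransitionModel:
    """Build the column-stochastic transition matrix A with A[i,j] = S(i,j)/deg_w(j).

    ``deg_w(j)`` is node j's weighted degree; entries are zero where no edge
    exists.  Every column sums to one because the network contains no
    isolated nodes.
    """
    if net.n_nodes == 0:
        raise DataError("cannot normalize an empty network")
    nodes = net.node_ordering()
    w = nx.to_scipy_sparse_array(
        net.graph, nodelist=nodes, weight="score", dtype=float, format="csc"
    )
    colsum = np.asarray(w.sum(axis=0)).ravel()
    inv = sparse.dia_array((1.0 / colsum[np.newaxis, :], [0]), shape=w.shape)
    a = (w @ inv.tocsc()).tocsr()
    return TransitionModel(nodes=nodes, matrix=a)


def strip_prefix(node_id: str, organism_code: str = "9606") -> str:
    """Display helper: drop the leading ``<organism>.`` from a STRING ID."""
    prefix = organism_code + "."
    return node_id[len(prefix):] if node_id.startswith(prefix) else node_id
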