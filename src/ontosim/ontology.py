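"""Ontology data model and graph primitives.

An ontology is a rooted directed acyclic graph whose nodes are *terms* and
whose edges point from a child term to its more general parent (``is_a`` /
``part_of``).  Items of the annotation domain (diseases, proteins, ...) are
annotated to the most specific terms possible and, by the
annotation-propagation rule, implicitly to every ancestor of those terms.

The graph is stored child->parent; traversals that need the opposite
orientation (e.g. a root-to-leaf topological order) use a reversed *view*
rather than mutating the graph.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

from .errors import (
    EmptyCorpusError,
    MalformedOntologyError,
    MissingTermError,
)

TermID = str

#: Root inserted when an OBO file contains several top-level terms, so that
#: every ontology handled downstream is single-rooted.  It carries p = 1 and
#: therefore IC = 0.
VIRTUAL_ROOT: TermID = "VIRTUAL:ROOT"

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


class Ontology:
    """A rooted DAG of terms with child->parent edges.

    Parameters
    ----------
    graph:
        Directed graph with one node per term and edges pointing from child
        to parent.  Edge data may carry a ``relation`` attribute.
    alt_ids:
        Optional mapping from alternative (merged) identifiers to primary
        term identifiers, applied by :meth:`canonical`.
    """

    def __init__(self, graph: nx.DiGraph, alt_ids: Mapping[TermID, TermID] | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise MalformedOntologyError(f"ontology graph contains a cycle: {cycle}")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise MalformedOntologyError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        self._graph = graph
        self.root: TermID = roots[0]
        self._alt_ids = dict(alt_ids or {})
        self._anc_cache: dict[TermID, frozenset[TermID]] = {}
        self._desc_cache: dict[TermID, frozenset[TermID]] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[TermID, TermID]],
        extra_terms: Iterable[TermID] = (),
    ) -> "Ontology":
        """Build an ontology from (child, parent) pairs; handy for fixtures."""
        g = nx.DiGraph()
        g.add_nodes_from(extra_terms)
        for child, parent in edges:
            g.add_edge(child, parent, relation="is_a")
        return cls(g)

    # -- basic accessors ---------------------------------------------------

    @property
    def terms(self) -> frozenset[TermID]:
        return frozenset(self._graph.nodes)

    @property
    def n_terms(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, term: TermID) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def canonical(self, term: TermID) -> TermID:
        """Map an alt_id to its primary identifier (identity otherwise)."""
        return self._alt_ids.get(term, term)

    def _require(self, term: TermID) -> None:
        if term not in self._graph:
            raise MissingTermError(f"unknown term: {term!r}")

    def parents(self, term: TermID) -> tuple[TermID, ...]:
        """Direct parents of a term, sorted for determinism."""
        self._require(term)
        return tuple(sorted(self._graph.successors(term)))

    def children(self, term: TermID) -> tuple[TermID, ...]:
        self._require(term)
        return tuple(sorted(self._graph.predecessors(term)))

    # -- traversal ---------------------------------------------------------

    def ancestors(self, term: TermID) -> frozenset[TermID]:
        """All terms reachable via parent edges, including ``term`` itself.

        Each ancestor is counted once regardless of how many paths lead
        to it.
        """
        self._require(term)
        cached = self._anc_cache.get(term)
        if cached is None:
            # child->parent edges make graph-descendants the ontological
            # ancestors
            cached = frozenset(nx.descendants(self._graph, term)) | {term}
            self._anc_cache[term] = cached
        return cached

    def descendants(self, term: TermID) -> frozenset[TermID]:
        """All terms that reach ``term`` via parent edges, including itself."""
        self._require(term)
        cached = self._desc_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term)) | {term}
            self._desc_cache[term] = cached
        return cached

    def implicit_closure(self, terms: Iterable[TermID]) -> frozenset[TermID]:
        """Union of the ancestor sets of ``terms`` (the implicit annotation
        set induced by the annotation-propagation rule)."""
        out: set[TermID] = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)

    def topological_order(self) -> list[TermID]:
        """Terms ordered from the root toward the leaves.

        Every term appears after all of its ancestors.  Lexicographic
        tie-breaking makes the order deterministic.
        """
        return list(nx.lexicographical_topological_sort(self._graph.reverse(copy=False)))

    def leaves(self) -> list[TermID]:
        """Terms without children."""
        return sorted(n for n in self._graph.nodes if self._graph.in_degree(n) == 0)

    def iter_edges(self) -> Iterable[tuple[TermID, TermID, str]]:
        """(child, parent, relation) triples."""
        for c, p, d in self._graph.edges(data=True):
            yield c, p, d.get("relation", "is_a")


def _scan_live_term_ids(text: str) -> frozenset[TermID]:
    """Ids of non-obsolete ``[Term]`` stanzas (used to detect dangling
    parent references, which obonet materialises silently)."""
    live: set[TermID] = set()
    cur: TermID | None = None
    obsolete = False
    in_term = False

    def flush():
        if in_term and cur is not None and not obsolete:
            live.add(cur)

    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            cur, obsolete = None, False
        elif in_term and line.startswith("id:") and cur is None:
            cur = line[3:].split("!")[0].strip()
        elif in_term and line.startswith("is_obsolete:"):
            obsolete = line[12:].strip().lower().startswith("true")
    flush()
    return frozenset(live)


def parse_obo(
    source: TextIO | str,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    One node is created per non-obsolete ``[Term]`` stanza; one edge per
    ``is_a`` line and per ``relationship: R`` line whose relation ``R`` is in
    ``relations``.  ``alt_id`` lines are collected into the canonical-id map.
    If the file has several top-level terms a synthetic root
    (:data:`VIRTUAL_ROOT`) is inserted above them.
    """
    relations = frozenset(relations)
    if isinstance(source, str):
        text = source
    else:
        text = source.read()
    live = _scan_live_term_ids(text)
    multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)

    g = nx.DiGraph()
    alt_ids: dict[TermID, TermID] = {}
    for node, data in multigraph.nodes(data=True):
        if node not in live:
            # obonet materialises referenced-but-undeclared parents as bare
            # nodes; treat them as dangling references
            raise MissingTermError(f"reference to undeclared or obsolete term {node!r}")
        g.add_node(node)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in relations:
            continue
        g.add_edge(child, parent, relation=rel)

    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) > 1:
        for r in roots:
            g.add_edge(r, VIRTUAL_ROOT, relation="is_a")
    return Ontology(g, alt_ids=alt_ids)


@dataclass(frozen=True)
class AnnotationCorpus:
    """Explicit annotations: item id -> set of term ids.

    The propagated (implicit) annotation set of an item is obtained with
    :meth:`Ontology.implicit_closure`.
    """

    items: Mapping[str, frozenset[TermID]] = field(default_factory=dict)

    def __post_init__(self):
        for item, terms in self.items.items():
            if not terms:
                raise EmptyCorpusError(f"item {item!r} has no annotations")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items.items())


def parse_annotations(
    source: TextIO | str,
    dialect: str = "tsv",
    ontology: Ontology | None = None,
    on_unknown: str = "error",
) -> AnnotationCorpus:
    """Parse an annotation file into an :class:`AnnotationCorpus`.

    Parameters
    ----------
    source:
        Text stream or string.  ``tsv`` dialect: two tab-separated columns
        ``item_id<TAB>term_id``, ``#`` comment lines allowed.  ``gaf``
        dialect: GAF 2.x, using column 2 (item) and column 5 (term);
        rows carrying a ``NOT`` qualifier (column 4) are dropped.
    ontology:
        When given, term ids are canonicalised through alt_id mapping and
        checked for membership.
    on_unknown:
        ``"error"`` (default) raises on a term absent from the ontology;
        ``"skip"`` drops the row.
    """
    if dialect not in ("tsv", "gaf"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if on_unknown not in ("error", "skip"):
        raise ValueError(f"on_unknown must be 'error' or 'skip', got {on_unknown!r}")
    if isinstance(source, str):
        source = io.StringIO(source)

    items: dict[str, set[TermID]] = {}
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        fields = line.split("\t")
        if dialect == "tsv":
            if len(fields) < 2:
                raise ValueError(f"expected 2 tab-separated columns, got: {line!r}")
            item, term = fields[0].strip(), fields[1].strip()
        else:  # gaf
            if len(fields) < 5:
                raise ValueError(f"GAF row with fewer than 5 columns: {line!r}")
            if "NOT" in fields[3].split("|"):
                continue
            item, term = fields[1], fields[4]
        if ontology is not None:
            term = ontology.canonical(term)
            if term not in ontology:
                if on_unknown == "error":
                    raise MissingTermError(
                        f"annotation of {item!r} uses unknown term {term!r}"
                    )
                continue
        items.setdefault(item, set()).add(term)

    return AnnotationCorpus({k: frozenset(v) for k, v in items.items()})
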