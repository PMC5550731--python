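"""Term ontology handling: OBO parsing, the term DAG, and annotation propagation.

The ontology is a directed acyclic graph of terms connected by typed edges
(``is_a``, ``part_of``, ``regulates``), mirroring the biological-process
branch of the Gene Ontology.  Gene annotations obey the true-path rule: a
gene annotated to a term is implicitly annotated to every ancestor reachable
through ``is_a`` and ``part_of`` edges.  ``regulates`` edges are kept for
traversal and display but do not transmit annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Edge kinds recognised in the term DAG.
RELATIONS = ("is_a", "part_of", "regulates")

#: Edge kinds along which annotations propagate (true-path rule).
PROPAGATING_RELATIONS = ("is_a", "part_of")


class OntologyStructureError(ValueError):
    """Raised for structural defects: cycles, dangling parents, bad relations."""


class EmptyInputError(ValueError):
    """Raised when an input file yields no usable records."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    Parameters
    ----------
    id : str
        Opaque, case-sensitive identifier (e.g. ``"GO:0007399"``).
    name : str
        Human-readable label.
    parents : tuple of (str, str)
        ``(parent_id, relation)`` pairs; relation is one of
        ``is_a``, ``part_of``, ``regulates``.
    """

    id: str
    name: str = ""
    parents: tuple[tuple[str, str], ...] = ()


class Ontology:
    """A DAG of :class:`Term` objects with typed edges.

    Internally backed by a :class:`networkx.MultiDiGraph` whose edges run
    child -> parent with the relation as the edge key.
    """

    def __init__(self, terms: Iterable[Term]):
        graph = nx.MultiDiGraph()
        terms = list(terms)
        for t in terms:
            if t.id in graph and "name" in graph.nodes[t.id]:
                raise OntologyStructureError(f"duplicate term id {t.id!r}")
            graph.add_node(t.id, name=t.name)
        for t in terms:
            for parent_id, relation in t.parents:
                if relation not in RELATIONS:
                    raise OntologyStructureError(
                        f"term {t.id!r}: unknown relation {relation!r}"
                    )
                if parent_id not in graph:
                    raise OntologyStructureError(
                        f"term {t.id!r} references unknown parent {parent_id!r}"
                    )
                graph.add_edge(t.id, parent_id, key=relation)
        _check_acyclic(graph)
        self._graph = graph
        self._terms = {t.id: t for t in terms}

    # -- basic container protocol ------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def __getitem__(self, term_id: str) -> Term:
        return self._terms[term_id]

    @property
    def graph(self) -> nx.MultiDiGraph:
        """The underlying child->parent multigraph (read-only by convention)."""
        return self._graph

    @property
    def roots(self) -> set[str]:
        """Term ids with no parents of any relation kind."""
        return {n for n in self._graph if self._graph.out_degree(n) == 0}

    def name(self, term_id: str) -> str:
        return self._terms[term_id].name

    def ancestors(
        self, term_id: str, relations: Iterable[str] = PROPAGATING_RELATIONS
    ) -> set[str]:
        """Transitive ancestors of *term_id* reachable via *relations*.

        Excludes the term itself.  Raises :class:`KeyError` for unknown ids.
        """
        if term_id not in self._terms:
            raise KeyError(f"unknown term id {term_id!r}")
        wanted = frozenset(relations)
        for r in wanted:
            if r not in RELATIONS:
                raise OntologyStructureError(f"unknown relation {r!r}")
        out: set[str] = set()
        stack = [term_id]
        while stack:
            node = stack.pop()
            for _, parent, rel in self._graph.out_edges(node, keys=True):
                if rel in wanted and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def descendants(
        self, term_id: str, relations: Iterable[str] = PROPAGATING_RELATIONS
    ) -> set[str]:
        """Transitive descendants of *term_id* via *relations* (term excluded)."""
        if term_id not in self._terms:
            raise KeyError(f"unknown term id {term_id!r}")
        wanted = frozenset(relations)
        out: set[str] = set()
        stack = [term_id]
        while stack:
            node = stack.pop()
            for child, _, rel in self._graph.in_edges(node, keys=True):
                if rel in wanted and child not in out:
                    out.add(child)
                    stack.append(child)
        return out


def _check_acyclic(graph: nx.MultiDiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        u, v = cycle[0][0], cycle[0][1]
        raise OntologyStructureError(
            f"ontology contains a cycle (e.g. edge {u!r} -> {v!r})"
        )


def parse_obo(path: str | Path) -> Ontology:
    """Parse an OBO flat file (``[Term]`` stanza subset) into an :class:`Ontology`.

    Obsolete terms are dropped; unknown stanza keys and ``alt_id`` lines are
    ignored.  A parent referenced by ``is_a``/``relationship`` that has no
    stanza of its own, or any cycle among the typed edges, raises
    :class:`OntologyStructureError`.
    """
    graph = obonet.read_obo(str(path))
    # obonet materialises referenced-but-undeclared parents as bare nodes.
    dangling = [n for n, d in graph.nodes(data=True) if "name" not in d]
    if dangling:
        raise OntologyStructureError(
            f"{len(dangling)} referenced term(s) have no stanza, "
            f"e.g. {sorted(dangling)[0]!r}"
        )
    terms = []
    for node, data in graph.nodes(data=True):
        parents = []
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel not in RELATIONS:
                continue  # e.g. has_part or other typedefs outside our subset
            parents.append((parent, rel))
        terms.append(Term(id=node, name=data.get("name", ""), parents=tuple(parents)))
    return Ontology(terms)


@dataclass
class AnnotationTable:
    """Gene -> term annotations with the background-universe size.

    The universe size ``n_background`` is the number of distinct annotated
    genes — the N of the Fisher contingency table.  ``propagated`` records
    whether the true-path closure has been applied.
    """

    annotations: dict[str, frozenset[str]]
    propagated: bool = False
    _n_background: int | None = field(default=None, repr=False)

    @property
    def n_background(self) -> int:
        if self._n_background is not None:
            return self._n_background
        return len(self.annotations)

    @n_background.setter
    def n_background(self, value: int) -> None:
        self._n_background = int(value)

    @property
    def genes(self) -> set[str]:
        return set(self.annotations)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())

    def term_counts(self) -> dict[str, int]:
        """Number of annotated genes per term (the K column of the ORA)."""
        counts: dict[str, int] = {}
        for terms in self.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        return counts


def parse_annotations(path: str | Path, onto: Ontology) -> AnnotationTable:
    """Read a two-column gene/term TSV into an unpropagated annotation table.

    Lines starting with ``#`` are skipped; an optional header row
    (``gene_id<TAB>term_id``) is recognised and dropped.  Rows referencing a
    term absent from *onto* are discarded and counted in a logged warning.
    """
    annotations: dict[str, set[str]] = {}
    n_dropped = 0
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            gene, term = parts[0].strip(), parts[1].strip()
            if (gene, term) == ("gene_id", "term_id"):
                continue
            n_rows += 1
            if term not in onto:
                n_dropped += 1
                continue
            annotations.setdefault(gene, set()).add(term)
    if n_rows == 0:
        raise EmptyInputError(f"no parseable annotation rows in {path}")
    if n_dropped:
        logger.warning(
            "dropped %d annotation row(s) referencing unknown terms", n_dropped
        )
    if not annotations:
        raise EmptyInputError(
            f"all {n_rows} annotation rows referenced unknown terms in {path}"
        )
    return AnnotationTable(
        annotations={g: frozenset(ts) for g, ts in annotations.items()},
        propagated=False,
    )


def propagate(table: AnnotationTable, onto: Ontology) -> AnnotationTable:
    """Apply the true-path closure over ``is_a``/``part_of`` edges.

    Idempotent and monotone: the output annotation set of every gene is a
    superset of its input set, and the universe size is unchanged.
    """
    # Memoised per-term closure keeps this linear in distinct annotated terms.
    closure: dict[str, frozenset[str]] = {}

    def closed(term: str) -> frozenset[str]:
        got = closure.get(term)
        if got is None:
            got = frozenset({term} | onto.ancestors(term, PROPAGATING_RELATIONS))
            closure[term] = got
        return got

    new_annotations = {
        gene: frozenset().union(*(closed(t) for t in terms)) if terms else frozenset()
        for gene, terms in table.annotations.items()
    }
    out = AnnotationTable(annotations=new_annotations, propagated=True)
    out.n_background = table.n_background
    return out


def annotation_table_from_mapping(
    mapping: Mapping[str, Iterable[str]], n_background: int | None = None
) -> AnnotationTable:
    """Build an unpropagated table directly from a gene->terms mapping."""
    table = AnnotationTable(
        annotations={g: frozenset(ts) for g, ts in mapping.items()}
    )
    if n_background is not None:
        table.n_background = n_background
    return table
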