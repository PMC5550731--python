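"""Functional abstraction: reduce a significant-term DAG to headline "functional areas".

A large set of enriched terms eludes direct interpretation.  This module
compresses it into a handful of headline terms chosen by a deterministic
greedy weighted set cover: at each step the candidate term maximising

    (number of newly covered significant terms) x information_content(term)

is promoted to a headline, where the information content of a term is
``-log2(K/N)`` bits (its annotation "surprisal" in the background).  A
headline covers itself and every significant descendant reachable through
``is_a``/``part_of`` edges.  Chosen headlines are pairwise non-redundant:
ancestors and descendants of a headline leave the candidate pool.  The
greedy loop stops once the requested coverage fraction is reached or the
headline budget is exhausted; anything still uncovered is reported as the
residual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .enrichment import ORAResult
from .ontology import AnnotationTable, Ontology, PROPAGATING_RELATIONS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunctionalArea:
    """One headline term with the significant terms it subsumes."""

    term_id: str
    name: str
    covered_terms: frozenset[str]
    n_genes: int
    information: float  # bits


@dataclass(frozen=True)
class HeadlineSet:
    """Ordered greedy selection of functional areas plus the uncovered residual."""

    areas: tuple[FunctionalArea, ...]
    residual: frozenset[str]

    @property
    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for a in self.areas:
            out |= a.covered_terms
        return frozenset(out)

    def coverage(self, n_significant: int) -> float:
        return len(self.covered) / n_significant if n_significant else 0.0


def information_content(term_id: str, table: AnnotationTable) -> float:
    """Annotation surprisal ``-log2(K/N)`` of a term, in bits.

    K is the number of background genes annotated to the term and N the
    universe size; a term annotating every gene carries 0 bits.
    """
    K = table.term_counts().get(term_id, 0)
    return _information(K, table.n_background, term_id)


def _information(K: int, N: int, term_id: str) -> float:
    if K <= 0:
        raise ValueError(f"term {term_id!r} has no background annotation (K = 0)")
    return -math.log2(K / N)


def area_gene_counts(
    area_term: str, query_genes: Iterable[str], table: AnnotationTable
) -> int:
    """Distinct query genes annotated (after propagation) to *area_term*."""
    return sum(1 for g in set(query_genes) if area_term in table.terms_of(g))


def select_functional_areas(
    sig_dag: nx.DiGraph,
    results: Sequence[ORAResult],
    table: AnnotationTable,
    onto: Ontology,
    query_genes: Iterable[str] = (),
    max_headlines: int = 10,
    min_cover: float = 0.95,
) -> HeadlineSet:
    """Greedy selection of headline terms covering the significant DAG.

    Ties in the greedy score are broken by higher information content, then
    lexicographic term id, making the selection fully deterministic.  If
    *min_cover* cannot be reached within *max_headlines*, the best-effort
    set is returned with a warning.
    """
    if sig_dag.number_of_nodes() == 0:
        raise ValueError("significant DAG is empty")
    significant = set(sig_dag.nodes)
    by_term = {r.term_id: r for r in results}
    query = set(query_genes)

    # Headline candidates are the significant terms themselves; each covers
    # itself plus significant descendants via propagating relations.
    cover_sets = {
        t: (onto.descendants(t, PROPAGATING_RELATIONS) & significant) | {t}
        for t in significant
    }
    info = {
        t: _information(by_term[t].K, by_term[t].N, t) if t in by_term else 0.0
        for t in significant
    }

    areas: list[FunctionalArea] = []
    covered: set[str] = set()
    pool = set(significant)
    target = min_cover * len(significant)
    while pool and len(areas) < max_headlines and len(covered) < target:
        def score(t: str) -> tuple[float, float, str]:
            gain = len(cover_sets[t] - covered)
            # sort key: maximise gain*info, then info; term id ascending
            return (-gain * info[t], -info[t], t)

        best = min(pool, key=score)
        gain = len(cover_sets[best] - covered)
        if gain == 0 or info[best] * gain == 0.0:
            break
        areas.append(
            FunctionalArea(
                term_id=best,
                name=onto.name(best),
                covered_terms=frozenset(cover_sets[best]),
                n_genes=area_gene_counts(best, query, table),
                information=info[best],
            )
        )
        covered |= cover_sets[best]
        # non-redundancy: drop the headline and its relatives from the pool
        relatives = (
            {best}
            | (onto.ancestors(best, PROPAGATING_RELATIONS) & pool)
            | (onto.descendants(best, PROPAGATING_RELATIONS) & pool)
        )
        pool -= relatives
    if len(covered) < target:
        logger.warning(
            "coverage target %.2f not reached: covered %d of %d terms with %d headlines",
            min_cover,
            len(covered),
            len(significant),
            len(areas),
        )
    return HeadlineSet(
        areas=tuple(areas), residual=frozenset(significant - covered)
    )
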