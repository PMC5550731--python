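"""Over-representation analysis (ORA) of a gene set against an annotated background.

For every term with at least one background annotation, the overlap between
the query set and the term's annotated genes is scored with a one-sided
(upper-tail) Fisher's exact test on the 2x2 table

    =================  ============  ==============
    .                  in term       not in term
    =================  ============  ==============
    query gene         k             n - k
    background gene    K - k         N - K - n + k
    =================  ============  ==============

i.e. ``p_raw = P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Raw p-values
are corrected by Benjamini-Hochberg FDR or Bonferroni, and terms with
``p_adj <= t_p`` are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import (
    AnnotationTable,
    Ontology,
    RELATIONS,
    Term,
)

import logging

logger = logging.getLogger(__name__)

CORRECTIONS = ("fdr_bh", "bonferroni")


class EmptyOverlapError(ValueError):
    """No query gene is present in the annotation background."""


@dataclass(frozen=True)
class ORAConfig:
    """Threshold and correction method for an ORA run.

    ``t_p`` is compared inclusively: a term is significant when
    ``p_adj <= t_p``.
    """

    t_p: float = 0.05
    correction: str = "fdr_bh"

    def __post_init__(self):
        if not (0.0 < self.t_p <= 1.0):
            raise ValueError(f"t_p must be in (0, 1], got {self.t_p}")
        if self.correction not in CORRECTIONS:
            raise ValueError(
                f"correction must be one of {CORRECTIONS}, got {self.correction!r}"
            )


@dataclass(frozen=True)
class ORAResult:
    """Per-term contingency counts and (corrected) significance."""

    term_id: str
    k: int  # query genes annotated to the term
    n: int  # query-set size (after background intersection)
    K: int  # background genes annotated to the term
    N: int  # background-universe size
    p_raw: float
    p_adj: float
    significant: bool


def fisher_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts term-annotated genes in a size-``n`` draw without
    replacement from ``N`` genes of which ``K`` are annotated.  Equivalent to
    the one-sided Fisher's exact test for over-representation.
    """
    if not (0 <= k <= min(n, K) and k <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid contingency bounds: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); hypergeom(M=N, n=K, N=n) in scipy's parametrisation
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def adjust_p(p_values: Sequence[float], correction: str = "fdr_bh") -> list[float]:
    """Multiple-testing adjustment, order-preserving under the input indexing.

    ``fdr_bh`` applies the Benjamini-Hochberg step-up rule; ``bonferroni``
    returns ``min(1, m*p)``.  An empty input yields an empty list.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method=correction)[1].tolist()


def run_ora(
    query_genes: Iterable[str],
    table: AnnotationTable,
    onto: Ontology,
    cfg: ORAConfig = ORAConfig(),
) -> list[ORAResult]:
    """Score every term with K >= 1 for over-representation in *query_genes*.

    Query genes absent from the background are dropped with a warning before
    testing, so N stays consistent with the annotation table.  Results are
    sorted by ascending raw p, ties broken by term id.
    """
    if not table.propagated:
        raise ValueError("annotation table must be propagated before ORA")
    query = set(query_genes)
    known = query & table.genes
    missing = query - known
    if missing:
        logger.warning(
            "%d of %d query genes absent from the annotation background",
            len(missing),
            len(query),
        )
    if not known:
        raise EmptyOverlapError("no query gene found in the annotation background")

    N = table.n_background
    n = len(known)
    K_counts = table.term_counts()
    k_counts: dict[str, int] = {}
    for g in known:
        for t in table.terms_of(g):
            k_counts[t] = k_counts.get(t, 0) + 1

    term_ids = sorted(t for t, K in K_counts.items() if K >= 1 and t in onto)
    p_raw = [
        fisher_upper_tail(k_counts.get(t, 0), n, K_counts[t], N) for t in term_ids
    ]
    p_adj = adjust_p(p_raw, cfg.correction)
    results = [
        ORAResult(
            term_id=t,
            k=k_counts.get(t, 0),
            n=n,
            K=K_counts[t],
            N=N,
            p_raw=pr,
            p_adj=pa,
            significant=pa <= cfg.t_p,
        )
        for t, pr, pa in zip(term_ids, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def significant_subdag(results: Sequence[ORAResult], onto: Ontology) -> nx.DiGraph:
    """Restrict the term DAG to significant terms, transitively reduced.

    The returned graph has an edge ``s -> t`` when ``t`` is an ancestor of
    ``s`` (over any relation kind) and no other significant term lies
    strictly between them.  With zero significant terms an empty graph is
    returned with a logged warning.
    """
    sig = {r.term_id for r in results if r.significant}
    g = nx.DiGraph()
    if not sig:
        logger.warning("no significant terms; returning an empty DAG")
        return g
    g.add_nodes_from(sig)
    for node in sig:
        g.nodes[node]["name"] = onto.name(node)
    anc = {s: onto.ancestors(s, RELATIONS) & sig for s in sig}
    for s in sig:
        for t in anc[s]:
            # t is "directly above" s if no significant term sits strictly between
            if not any(t in anc[mid] for mid in anc[s] if mid != t):
                g.add_edge(s, t)
    return g
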