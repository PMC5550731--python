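"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from procpharm import (
    Ontology,
    Term,
    annotation_table_from_mapping,
    propagate,
)


def hypergeom_upper_tail_bruteforce(k: int, n: int, K: int, N: int) -> float:
    """Exhaustive hypergeometric sum P(X >= k) — the independent oracle."""
    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    ) / total


def bh_stepup_bruteforce(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.fixture
def diamond_ontology():
    """a -> b -> d and a -> c -> d (is_a), with e regulated by d."""
    return Ontology(
        [
            Term("d", "top"),
            Term("b", "left", (("d", "is_a"),)),
            Term("c", "right", (("d", "part_of"),)),
            Term("a", "bottom", (("b", "is_a"), ("c", "is_a"))),
            Term("e", "regulator", (("d", "regulates"),)),
        ]
    )


@pytest.fixture
def small_annotated():
    """A 12-term chain-and-branch ontology with a 100-gene background.

    Genes g000..g009 are all annotated to the planted term ``t_planted``;
    every gene also carries one of ten background terms.
    """
    terms = [Term("root", "root")]
    for i in range(10):
        terms.append(Term(f"t{i}", f"background {i}", (("root", "is_a"),)))
    terms.append(Term("t_planted", "planted", (("root", "is_a"),)))
    onto = Ontology(terms)
    mapping = {}
    for g in range(100):
        gene = f"g{g:03d}"
        mapping[gene] = {f"t{g % 10}"}
        if g < 10:
            mapping[gene].add("t_planted")
    table = propagate(annotation_table_from_mapping(mapping), onto)
    return onto, table


def random_layered_dag(rng: np.random.Generator, n_terms: int = 20):
    """Random layered ontology for closure property tests."""
    n_layers = int(rng.integers(2, 5))
    sizes = rng.multinomial(n_terms - n_layers, [1 / n_layers] * n_layers) + 1
    terms, layers = [], []
    idx = 0
    for li, size in enumerate(sizes):
        layer = []
        for _ in range(size):
            name = f"n{idx}"
            idx += 1
            if li == 0:
                terms.append(Term(name, name))
            else:
                prev = layers[li - 1]
                k = int(rng.integers(1, min(2, len(prev)) + 1))
                parents = rng.choice(prev, size=k, replace=False)
                rels = rng.choice(["is_a", "part_of", "regulates"], size=k, p=[0.6, 0.25, 0.15])
                terms.append(Term(name, name, tuple(zip(parents.tolist(), rels.tolist()))))
            layer.append(name)
        layers.append(layer)
    return Ontology(terms)
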