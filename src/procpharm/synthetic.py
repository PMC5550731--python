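"""Synthetic ontologies, annotations and drug-target tables with a planted signal.

The generator emulates the statistical situation the repurposing analysis
assumes: a trait gene set shares a handful of enriched biological processes
with a subset of drugs.  Concretely it emits

* a layered random term DAG (acyclic by construction),
* a gene/term annotation TSV (unpropagated — the pipeline's closure code is
  exercised on it),
* a drug/target TSV in which *planted* drugs draw their targets from a pool
  of signal genes, and
* a trait gene list.

Signal genes and trait genes are annotated to each of the planted process
terms with probability ``signal_strength``; the remaining druggable genes
with probability ``background_noise``.  Every artifact gets its own RNG
stream derived from the master seed, so files are byte-identical per seed
and stable under partial regeneration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np


class SyntheticSpecError(ValueError):
    """The requested generator parameters are infeasible or inconsistent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    The defaults encode the reference study condition: a 150-term DAG of
    depth 5 over 400 genes, 300 multi-target drugs of which 30 are planted
    on 8 planted processes, signal 0.9 against background noise 0.05.
    ``n_target_pool`` genes are druggable; ``n_signal_genes`` of them form
    the pool from which planted drugs draw their targets.
    """

    n_terms: int = 150
    dag_depth: int = 5
    branching: float = 3.0
    n_genes: int = 400
    annotation_density: float = 0.03
    n_drugs: int = 300
    targets_per_drug: tuple[int, int] = (10, 12)
    n_trait_genes: int = 16
    n_planted_processes: int = 8
    n_planted_drugs: int = 30
    signal_strength: float = 0.9
    background_noise: float = 0.05
    n_target_pool: int = 80
    n_signal_genes: int = 40
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.background_noise <= self.signal_strength <= 1.0):
            raise SyntheticSpecError(
                "need 0 <= background_noise <= signal_strength <= 1"
            )
        if self.dag_depth < 1 or self.n_terms < self.dag_depth + 1:
            raise SyntheticSpecError("n_terms must exceed dag_depth")
        if self.branching <= 0:
            raise SyntheticSpecError("branching must be positive")
        lo, hi = self.targets_per_drug
        if not (1 <= lo <= hi <= self.n_signal_genes):
            raise SyntheticSpecError(
                "targets_per_drug range must fit within the signal-gene pool"
            )
        if self.n_planted_drugs > self.n_drugs:
            raise SyntheticSpecError("planted drugs exceed total drugs")
        if self.n_signal_genes > self.n_target_pool:
            raise SyntheticSpecError("signal genes exceed the target pool")
        if self.n_target_pool + self.n_trait_genes > self.n_genes:
            raise SyntheticSpecError(
                "target pool plus trait genes exceed the gene universe"
            )
        last_layer = self._layer_sizes()[-1]
        if self.n_planted_processes > last_layer:
            raise SyntheticSpecError(
                f"cannot plant {self.n_planted_processes} processes in a "
                f"deepest layer of {last_layer} terms"
            )

    def _layer_sizes(self) -> list[int]:
        """Geometric layer profile summing to n_terms, one root layer of 1."""
        weights = np.power(self.branching, np.arange(self.dag_depth + 1))
        sizes = np.maximum(1, np.round(weights * self.n_terms / weights.sum()))
        sizes = sizes.astype(int)
        sizes[0] = 1
        # adjust the deepest layer so the total is exact
        sizes[-1] += self.n_terms - int(sizes.sum())
        if sizes[-1] < 1:
            raise SyntheticSpecError("branching profile incompatible with n_terms")
        return sizes.tolist()


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: process term ids, drug ids, trait gene ids.

    ``drug_classes`` records the target-repertoire classes the drugs were
    generated in (the planted drugs form class 0); permuting which class is
    called "planted" is the exchangeable null for recovery scores.
    """

    planted_processes: tuple[str, ...]
    planted_drugs: tuple[str, ...]
    trait_genes: tuple[str, ...]
    drug_classes: tuple[tuple[str, ...], ...] = ()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_processes=tuple(d["planted_processes"]),
            planted_drugs=tuple(d["planted_drugs"]),
            trait_genes=tuple(d["trait_genes"]),
            drug_classes=tuple(tuple(c) for c in d.get("drug_classes", ())),
        )


class RecoveryScore(NamedTuple):
    """Recall/precision of a candidate list against the planted drugs."""

    recall: float
    precision: float
    empty_candidates: bool = False


_RELATION_CHOICES = ("is_a", "part_of", "regulates")
_RELATION_PROBS = (0.7, 0.2, 0.1)


def _term_id(i: int) -> str:
    return f"ST:{i:06d}"


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _drug_id(i: int) -> str:
    return f"D{i:04d}"


def generate(spec: SyntheticSpec, out_dir: str | Path) -> GroundTruth:
    """Write the four pipeline inputs plus ``ground_truth.json`` to *out_dir*.

    Files: ``ontology.obo``, ``annotations.tsv``, ``drug_targets.tsv``,
    ``trait_genes.txt``.  Deterministic per ``spec.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(spec.seed)
    onto_ss, roles_ss, ann_ss, drug_ss = master.spawn(4)

    # --- ontology: layered random DAG -------------------------------------
    rng = np.random.default_rng(onto_ss)
    layer_sizes = spec._layer_sizes()
    layers: list[list[str]] = []
    idx = 0
    for size in layer_sizes:
        layers.append([_term_id(i) for i in range(idx, idx + size)])
        idx += size
    parent_edges: dict[str, list[tuple[str, str]]] = {t: [] for t in layers[0]}
    for depth in range(1, len(layers)):
        prev = layers[depth - 1]
        for term in layers[depth]:
            n_parents = int(rng.integers(1, 3)) if len(prev) > 1 else 1
            chosen = rng.choice(len(prev), size=min(n_parents, len(prev)), replace=False)
            edges = []
            for j, pi in enumerate(np.sort(chosen)):
                # first parent always propagates annotations upward
                rel = (
                    "is_a"
                    if j == 0
                    else str(rng.choice(_RELATION_CHOICES, p=_RELATION_PROBS))
                )
                edges.append((prev[int(pi)], rel))
            parent_edges[term] = edges

    obo_lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for depth, layer in enumerate(layers):
        for term in layer:
            obo_lines.append("[Term]")
            obo_lines.append(f"id: {term}")
            obo_lines.append(f"name: synthetic process {term} (layer {depth})")
            for parent, rel in parent_edges[term]:
                if rel == "is_a":
                    obo_lines.append(f"is_a: {parent}")
                else:
                    obo_lines.append(f"relationship: {rel} {parent}")
            obo_lines.append("")
    (out / "ontology.obo").write_text("\n".join(obo_lines))

    # --- role assignment: pools, trait genes, planted entities ------------
    rng = np.random.default_rng(roles_ss)
    genes = [_gene_id(i) for i in range(spec.n_genes)]
    perm = rng.permutation(spec.n_genes)
    target_pool = [genes[i] for i in perm[: spec.n_target_pool]]
    signal_genes = list(
        rng.choice(target_pool, size=spec.n_signal_genes, replace=False)
    )
    non_pool = [genes[i] for i in perm[spec.n_target_pool:]]
    trait_genes = non_pool[: spec.n_trait_genes]
    deepest = layers[-1]
    planted_processes = list(
        rng.choice(deepest, size=spec.n_planted_processes, replace=False)
    )
    drug_ids = [_drug_id(i) for i in range(spec.n_drugs)]
    planted_drugs = list(
        rng.choice(drug_ids, size=spec.n_planted_drugs, replace=False)
    )

    # --- annotations -------------------------------------------------------
    rng = np.random.default_rng(ann_ss)
    non_root_terms = [t for layer in layers[1:] for t in layer]
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    mean_ann = max(spec.annotation_density * spec.n_terms, 0.5)
    for g in genes:
        n_ann = max(1, int(rng.poisson(mean_ann)))
        n_ann = min(n_ann, len(non_root_terms))
        chosen = rng.choice(len(non_root_terms), size=n_ann, replace=False)
        annotations[g].update(non_root_terms[int(i)] for i in chosen)
    signal_set = set(signal_genes)
    noise_pool = [g for g in target_pool if g not in signal_set]
    for p in planted_processes:
        for g in signal_genes + trait_genes:
            if rng.random() < spec.signal_strength:
                annotations[g].add(p)
        for g in noise_pool:
            if rng.random() < spec.background_noise:
                annotations[g].add(p)

    ann_lines = ["# synthetic gene/term annotations", "gene_id\tterm_id"]
    for g in genes:
        for t in sorted(annotations[g]):
            ann_lines.append(f"{g}\t{t}")
    (out / "annotations.tsv").write_text("\n".join(ann_lines) + "\n")

    # --- drugs -------------------------------------------------------------
    rng = np.random.default_rng(drug_ss)
    lo, hi = spec.targets_per_drug
    planted_set = set(planted_drugs)
    drug_lines = ["# synthetic drug/target table", "drug_id\tdrug_name\tgene_id"]
    # Drugs fall into classes sharing a target repertoire of the same size
    # as the signal pool; the planted drugs form one class whose repertoire
    # IS the signal pool.  With signal == noise every class is statistically
    # identical, so the planted label carries no information (exchangeable
    # negative control).
    n_classes = max(spec.n_drugs // max(spec.n_planted_drugs, 1), 1)
    class_pools = [signal_genes]
    for _ in range(n_classes - 1):
        sub = rng.choice(len(target_pool), size=spec.n_signal_genes, replace=False)
        class_pools.append([target_pool[int(i)] for i in np.sort(sub)])
    non_planted = [d for d in drug_ids if d not in planted_set]
    drug_class = {d: 0 for d in planted_set}
    for j, d in enumerate(non_planted):
        drug_class[d] = 1 + j % max(n_classes - 1, 1)
    for d in drug_ids:
        n_targets = int(rng.integers(lo, hi + 1))
        pool = class_pools[drug_class[d]]
        n_targets = min(n_targets, len(pool))
        chosen = rng.choice(len(pool), size=n_targets, replace=False)
        name = f"drug-{d[1:]}"
        for i in np.sort(chosen):
            drug_lines.append(f"{d}\t{name}\t{pool[int(i)]}")
    (out / "drug_targets.tsv").write_text("\n".join(drug_lines) + "\n")

    (out / "trait_genes.txt").write_text("\n".join(trait_genes) + "\n")

    class_members: dict[int, list[str]] = {}
    for d in drug_ids:
        class_members.setdefault(drug_class[d], []).append(d)
    truth = GroundTruth(
        planted_processes=tuple(sorted(planted_processes)),
        planted_drugs=tuple(sorted(planted_drugs)),
        trait_genes=tuple(sorted(trait_genes)),
        drug_classes=tuple(
            tuple(sorted(class_members[c])) for c in sorted(class_members)
        ),
    )
    truth.to_json(out / "ground_truth.json")
    return truth


def score_recovery(truth: GroundTruth, candidates: Sequence[str]) -> RecoveryScore:
    """Recall and precision of *candidates* against the planted drugs.

    An empty candidate list yields recall 0 and an undefined precision,
    reported as 0 with ``empty_candidates=True``.
    """
    planted = set(truth.planted_drugs)
    cand = set(candidates)
    if not planted:
        raise ValueError("ground truth contains no planted drugs")
    if not cand:
        return RecoveryScore(recall=0.0, precision=0.0, empty_candidates=True)
    hit = len(cand & planted)
    return RecoveryScore(
        recall=hit / len(planted), precision=hit / len(cand), empty_candidates=False
    )
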