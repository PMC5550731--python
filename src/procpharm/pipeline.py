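"""End-to-end orchestration of the two analysis arms.

The *functional arm* characterises a trait gene set: over-representation
analysis of the set against the annotated background, the DAG of
significant terms, and its functional abstraction into headline areas.

The *repurposing arm* projects all drugs and the trait-derived virtual
drug into a shared biological-process space (drug x gene times
gene x process), restricts it to processes addressed by both, prunes the
drugs by nested ABC analysis of reciprocal Euclidean distances to the
virtual drug, trains an emergent SOM on the survivors, and reports the
drugs whose best-matching units share a U-matrix watershed basin with the
virtual drug.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drug_matrix as dm
from .abc_analysis import nested_abc_stages, select_by_reciprocal_distance
from .abstraction import HeadlineSet, select_functional_areas
from .enrichment import ORAConfig, ORAResult, run_ora, significant_subdag
from .esom import EsomConfig, EsomMap, extract_cluster
from .ontology import (
    AnnotationTable,
    EmptyInputError,
    Ontology,
    parse_annotations,
    parse_obo,
    propagate,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbstractionConfig:
    max_headlines: int = 10
    min_cover: float = 0.95


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs, thresholds and schedules of a pipeline run.

    The defaults encode the reference analysis: trait ORA at t_p = 0.05
    with Benjamini-Hochberg FDR, the drug-target process filter at
    t_p = 1e-15 with Bonferroni, nested ABC of depth 2, and a 50 x 80
    toroid ESOM trained for 50 epochs.
    """

    ontology_path: str = "ontology.obo"
    annotations_path: str = "annotations.tsv"
    drug_targets_path: str = "drug_targets.tsv"
    trait_genes_path: str = "trait_genes.txt"
    trait_ora: ORAConfig = field(default_factory=lambda: ORAConfig(0.05, "fdr_bh"))
    filter_ora: ORAConfig = field(
        default_factory=lambda: ORAConfig(1e-15, "bonferroni")
    )
    abstraction: AbstractionConfig = field(default_factory=AbstractionConfig)
    abc_depth: int = 2
    esom: EsomConfig = field(default_factory=EsomConfig)
    standardize_distances: bool = False
    virtual_drug_label: str = dm.VIRTUAL_DRUG_LABEL
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.abc_depth < 1:
            raise ValueError("abc_depth must be >= 1")

    # -- YAML round trip ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "trait_ora" in kwargs:
            kwargs["trait_ora"] = ORAConfig(**kwargs["trait_ora"])
        if "filter_ora" in kwargs:
            kwargs["filter_ora"] = ORAConfig(**kwargs["filter_ora"])
        if "abstraction" in kwargs:
            kwargs["abstraction"] = AbstractionConfig(**kwargs["abstraction"])
        if "esom" in kwargs:
            kwargs["esom"] = EsomConfig(**kwargs["esom"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class LoadedInputs:
    onto: Ontology
    table: AnnotationTable  # propagated
    trait_genes: tuple[str, ...]
    drugs: list[dm.DrugRecord]


def load_inputs(cfg: PipelineConfig, base_dir: str | Path = ".") -> LoadedInputs:
    """Parse and propagate all four inputs relative to *base_dir*."""
    base = Path(base_dir)
    onto = parse_obo(base / cfg.ontology_path)
    table = propagate(parse_annotations(base / cfg.annotations_path, onto), onto)
    trait_path = base / cfg.trait_genes_path
    trait_genes = tuple(
        line.strip()
        for line in trait_path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )
    if not trait_genes:
        raise EmptyInputError(f"no trait genes in {trait_path}")
    drugs = dm.read_drug_targets(base / cfg.drug_targets_path)
    return LoadedInputs(onto=onto, table=table, trait_genes=trait_genes, drugs=drugs)


@dataclass
class RunReport:
    """Everything the repurposing arm produced, plus provenance."""

    significant_terms: list[ORAResult]
    headline_set: HeadlineSet | None
    kept_processes: list[str]
    abc_survivors: list[str]
    distances: pd.Series
    candidates: list[str]
    seed_basin: int
    n_basins: int
    config: PipelineConfig
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "n_significant_terms": len(
                [r for r in self.significant_terms if r.significant]
            ),
            "headlines": [a.term_id for a in self.headline_set.areas]
            if self.headline_set
            else [],
            "kept_processes": self.kept_processes,
            "n_abc_survivors": len(self.abc_survivors),
            "abc_survivors": self.abc_survivors,
            "candidates": self.candidates,
            "seed_basin": self.seed_basin,
            "n_basins": self.n_basins,
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
        }


def run_functional_arm(
    cfg: PipelineConfig,
    inputs: LoadedInputs | None = None,
    base_dir: str | Path = ".",
) -> tuple[list[ORAResult], HeadlineSet]:
    """ORA of the trait gene set followed by functional abstraction."""
    if inputs is None:
        inputs = load_inputs(cfg, base_dir)
    results = run_ora(inputs.trait_genes, inputs.table, inputs.onto, cfg.trait_ora)
    sig_dag = significant_subdag(results, inputs.onto)
    if sig_dag.number_of_nodes() == 0:
        logger.warning("functional arm: no significant terms at t_p=%g", cfg.trait_ora.t_p)
        headlines = HeadlineSet(areas=(), residual=frozenset())
    else:
        headlines = select_functional_areas(
            sig_dag,
            results,
            inputs.table,
            inputs.onto,
            query_genes=inputs.trait_genes,
            max_headlines=cfg.abstraction.max_headlines,
            min_cover=cfg.abstraction.min_cover,
        )
    if cfg.out_dir:
        _write_functional_reports(cfg, results, headlines)
    return results, headlines


def run_repurposing_arm(
    cfg: PipelineConfig,
    inputs: LoadedInputs | None = None,
    base_dir: str | Path = ".",
) -> RunReport:
    """Full repurposing chain ending in the virtual drug's basin members."""
    if inputs is None:
        inputs = load_inputs(cfg, base_dir)
    results, headlines = run_functional_arm(cfg, inputs=inputs)

    dg = dm.build_drug_gene(inputs.drugs, inputs.table.genes)
    gp = dm.build_gene_process(
        dg.columns, inputs.table, inputs.onto, cfg.filter_ora
    )
    dp = dm.drug_process_product(dg, gp)
    vd = dm.build_virtual_drug(
        inputs.trait_genes, inputs.table, list(dp.columns), cfg.virtual_drug_label
    )
    restricted, kept = dm.restrict_shared(dp, vd)
    distances = dm.distances_to_virtual(
        restricted, cfg.virtual_drug_label, standardize=cfg.standardize_distances
    )

    selected = select_by_reciprocal_distance(
        distances.to_numpy(), depth=cfg.abc_depth
    )
    survivors = [str(distances.index[i]) for i in selected]
    training = restricted.loc[survivors + [cfg.virtual_drug_label]]

    esom_seed = int(
        np.random.SeedSequence(cfg.seed).generate_state(1)[0] & 0x7FFFFFFF
    )
    esom = EsomMap(**{**dataclasses.asdict(cfg.esom), "seed": esom_seed})
    # smooth_umatrix is consumed by the basin extraction, not by fit
    smooth = esom.smooth_umatrix
    esom.fit(training.to_numpy(dtype=float))
    bmus = esom.bmu_map(training.to_numpy(dtype=float), list(training.index))
    cluster = extract_cluster(
        esom.u_matrix_,
        bmus,
        seed_label=cfg.virtual_drug_label,
        toroid=esom.toroid,
        smooth=smooth,
        min_basin_depth=esom.min_basin_depth,
    )
    report = RunReport(
        significant_terms=results,
        headline_set=headlines,
        kept_processes=list(kept),
        abc_survivors=survivors,
        distances=distances,
        candidates=list(cluster.members),
        seed_basin=cluster.seed_basin,
        n_basins=cluster.n_basins,
        config=cfg,
        seed=cfg.seed,
    )
    if cfg.out_dir:
        _write_repurposing_reports(cfg, report, esom, bmus, cluster, restricted)
    return report


def scaled_study_config(
    seed: int = 0,
    out_dir: str | None = None,
    filter_disabled: bool = False,
) -> PipelineConfig:
    """Pipeline configuration for the synthetic benchmark scale.

    The reference thresholds and grid are tied to genome-scale inputs
    (~19k genes, ~5k drugs, 4000 neurons); at benchmark scale (400 genes,
    300 drugs) the process filter keeps its Bonferroni correction but uses
    t_p = 0.05, and the ESOM shrinks to a 20 x 30 toroid with a 10 -> 2
    radius schedule over the same 50 epochs.  ``filter_disabled`` switches
    the process filter off (t_p = 1), which a no-signal negative control
    needs in order to produce any shared process space at all.
    """
    return PipelineConfig(
        filter_ora=ORAConfig(1.0 if filter_disabled else 0.05, "bonferroni"),
        esom=EsomConfig(
            rows=20, cols=30, epochs=50, radius_start=10.0, radius_end=2.0
        ),
        out_dir=out_dir,
        seed=seed,
    )


# -- report writing ---------------------------------------------------------


def _write_functional_reports(cfg, results, headlines) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [dataclasses.asdict(r) for r in results]
    ).to_csv(out / "ora_trait.tsv", sep="\t", index=False)
    rows = [
        {
            "term_id": a.term_id,
            "name": a.name,
            "n_genes": a.n_genes,
            "covered_terms": ",".join(sorted(a.covered_terms)),
            "information_bits": a.information,
        }
        for a in headlines.areas
    ]
    pd.DataFrame(
        rows, columns=["term_id", "name", "n_genes", "covered_terms", "information_bits"]
    ).to_csv(out / "functional_areas.tsv", sep="\t", index=False)


def _write_repurposing_reports(cfg, report, esom, bmus, cluster, restricted) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report.distances.to_numpy()
    pos = np.flatnonzero(d > 0)
    flags = {1: set(np.flatnonzero(d == 0)), 2: set(np.flatnonzero(d == 0))}
    if len(pos):
        for level, stage in enumerate(
            nested_abc_stages(1.0 / d[pos], depth=cfg.abc_depth), start=1
        ):
            flags.setdefault(level, set(np.flatnonzero(d == 0)))
            flags[level].update(int(pos[i]) for i in stage)
    report.distances.to_frame().assign(
        abc_pass1=[i in flags.get(1, set()) for i in range(len(d))],
        abc_survivor=report.distances.index.isin(report.abc_survivors),
        candidate=report.distances.index.isin(report.candidates),
    ).to_csv(out / "distances.tsv", sep="\t")
    restricted.to_csv(out / "drug_process_restricted.tsv", sep="\t")
    (out / "kept_processes.txt").write_text("\n".join(report.kept_processes) + "\n")
    pd.DataFrame(
        [(lab, r, c) for lab, (r, c) in sorted(bmus.items())],
        columns=["label", "row", "col"],
    ).to_csv(out / "bmus.tsv", sep="\t", index=False)
    np.savetxt(out / "umatrix.tsv", esom.u_matrix_, delimiter="\t", fmt="%.6g")
    pd.DataFrame(
        {"label": list(cluster.members), "basin": cluster.seed_basin}
    ).to_csv(out / "basin_members.tsv", sep="\t", index=False)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=str)
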