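"""Drug/gene/process matrix algebra for the repurposing arm.

Drugs are linked to biological processes through their target genes: a
binary drug x gene matrix times a binary gene x process matrix yields a
count-valued drug x process matrix, whose entry (d, p) is the number of
d's targets annotated to process p.  A *virtual drug* summarising a trait
gene set is appended as an extra row: its entry for process p counts how
many trait genes are annotated to p.  The space is then restricted to
processes addressed by both the real drugs and the virtual drug, and
Euclidean distances from every drug to the virtual drug are computed on
the raw counts.

All matrices are labelled :class:`pandas.DataFrame` objects; alignment is
always by label, never by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import ORAConfig, run_ora
from .ontology import AnnotationTable, Ontology

logger = logging.getLogger(__name__)

VIRTUAL_DRUG_LABEL = "PainInsensitivity"


class MatrixBuildError(ValueError):
    """Structural failure while assembling a matrix (empty result, bad labels)."""


class NoSharedProcessError(ValueError):
    """Trait-derived processes and drug-addressed processes do not overlap."""


@dataclass(frozen=True)
class DrugRecord:
    """One drug and the genes coding for its molecular targets."""

    drug_id: str
    name: str
    targets: frozenset[str]


def read_drug_targets(path: str | Path) -> list[DrugRecord]:
    """Read a drug-target TSV (``drug_id  drug_name  gene_id``) into records.

    ``#`` comment lines and an optional header are skipped; duplicate
    (drug, target) pairs collapse to one (binary semantics).
    """
    targets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            drug_id, name, gene = (p.strip() for p in parts[:3])
            if (drug_id, gene) == ("drug_id", "gene_id"):
                continue
            n_rows += 1
            targets.setdefault(drug_id, set()).add(gene)
            names.setdefault(drug_id, name)
    if n_rows == 0:
        raise MatrixBuildError(f"no parseable drug-target rows in {path}")
    return [
        DrugRecord(drug_id=d, name=names[d], targets=frozenset(ts))
        for d, ts in sorted(targets.items())
    ]


def build_drug_gene(
    drugs: Sequence[DrugRecord], gene_universe: Iterable[str]
) -> pd.DataFrame:
    """Binary drug x gene matrix over targets inside *gene_universe*.

    Drugs whose targets all fall outside the universe are dropped with a
    warning; an empty result raises :class:`MatrixBuildError`.
    """
    universe = set(gene_universe)
    kept: list[DrugRecord] = []
    dropped = 0
    for d in drugs:
        if d.targets & universe:
            kept.append(d)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d drug(s) with no target in the gene universe", dropped)
    if not kept:
        raise MatrixBuildError("no drug has a target inside the gene universe")
    genes = sorted(set().union(*(d.targets & universe for d in kept)))
    gene_idx = {g: j for j, g in enumerate(genes)}
    mat = np.zeros((len(kept), len(genes)), dtype=np.int64)
    for i, d in enumerate(kept):
        for g in d.targets & universe:
            mat[i, gene_idx[g]] = 1
    return pd.DataFrame(mat, index=[d.drug_id for d in kept], columns=genes)


def build_gene_process(
    target_genes: Iterable[str],
    table: AnnotationTable,
    onto: Ontology,
    cfg: ORAConfig = ORAConfig(t_p=1e-15, correction="bonferroni"),
) -> pd.DataFrame:
    """Binary gene x process matrix over ORA-filtered process terms.

    The target-gene set is submitted to ORA purely as a *filter*: only terms
    significant at the (conservative) threshold become columns.  Every input
    gene keeps its row even if all-zero.  Zero surviving terms raises a
    :class:`MatrixBuildError` suggesting a relaxed threshold.
    """
    genes = sorted(set(target_genes))
    results = run_ora(genes, table, onto, cfg)
    terms = sorted(r.term_id for r in results if r.significant)
    if not terms:
        raise MatrixBuildError(
            f"no process term passes the ORA filter at t_p={cfg.t_p:g} "
            f"({cfg.correction}); consider relaxing the threshold"
        )
    term_idx = {t: j for j, t in enumerate(terms)}
    mat = np.zeros((len(genes), len(terms)), dtype=np.int64)
    for i, g in enumerate(genes):
        for t in table.terms_of(g):
            j = term_idx.get(t)
            if j is not None:
                mat[i, j] = 1
    return pd.DataFrame(mat, index=genes, columns=terms)


def drug_process_product(dg: pd.DataFrame, gp: pd.DataFrame) -> pd.DataFrame:
    """Label-aligned matrix product: entry (d, p) = # targets of d annotated to p."""
    if set(dg.columns) != set(gp.index):
        raise MatrixBuildError(
            "gene labels of the drug x gene and gene x process matrices differ"
        )
    aligned = gp.loc[dg.columns]
    return dg.dot(aligned)


def build_virtual_drug(
    trait_genes: Iterable[str],
    table: AnnotationTable,
    process_terms: Sequence[str],
    label: str = VIRTUAL_DRUG_LABEL,
) -> pd.Series:
    """Process-count vector of the trait gene set (the "virtual drug").

    ``counts[p]`` is the number of trait genes annotated to process p.  An
    all-zero vector (no overlap between trait functions and drug-addressable
    processes) raises :class:`NoSharedProcessError`.
    """
    trait = set(trait_genes)
    counts = np.zeros(len(process_terms), dtype=np.int64)
    for g in trait:
        terms = table.terms_of(g)
        for j, p in enumerate(process_terms):
            if p in terms:
                counts[j] += 1
    vd = pd.Series(counts, index=list(process_terms), name=label)
    if int(vd.sum()) == 0:
        raise NoSharedProcessError(
            "virtual drug is all-zero: trait genes share no process with the matrix"
        )
    return vd


def restrict_shared(
    dp: pd.DataFrame, vd: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Keep processes addressed by both the drugs and the virtual drug.

    A column survives iff the virtual drug's count is positive AND at least
    one drug addresses it.  Drug rows left all-zero are dropped.  The
    virtual drug is appended as the final row, so the result has
    (retained drugs + 1) rows.  Returns the matrix and the kept columns.
    """
    shared_vocab = [p for p in dp.columns if p in vd.index]
    if len(shared_vocab) != len(dp.columns) or len(shared_vocab) != len(vd.index):
        logger.warning(
            "process vocabularies differ; restricting to the %d shared labels",
            len(shared_vocab),
        )
    dp = dp[shared_vocab]
    vd = vd.loc[shared_vocab]
    kept = [p for p in shared_vocab if vd[p] > 0 and dp[p].sum() > 0]
    if not kept:
        raise NoSharedProcessError(
            "no process is addressed by both the drugs and the virtual drug"
        )
    restricted = dp[kept]
    nonzero = restricted.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropped %d drug(s) with no shared process", n_dropped)
    restricted = restricted.loc[nonzero]
    out = pd.concat([restricted, vd.loc[kept].to_frame().T])
    return out.astype(np.int64), kept


def distances_to_virtual(
    m: pd.DataFrame, label: str = VIRTUAL_DRUG_LABEL, standardize: bool = False
) -> pd.Series:
    """Euclidean distance of every drug row to the virtual-drug row.

    By default distances are computed on the raw association counts (no
    column scaling); ``standardize=True`` divides each column by its
    standard deviation first (constant columns are left untouched).  The
    virtual drug itself is excluded from the output.
    """
    if label not in m.index:
        raise MatrixBuildError(f"virtual drug row {label!r} missing from matrix")
    values = m.to_numpy(dtype=float)
    if standardize:
        sd = values.std(axis=0, ddof=0)
        values = values / np.where(sd > 0, sd, 1.0)
    values = pd.DataFrame(values, index=m.index, columns=m.columns)
    vd = values.loc[label].to_numpy(dtype=float)
    drugs = values.drop(index=label)
    diff = drugs.to_numpy(dtype=float) - vd
    return pd.Series(np.sqrt((diff**2).sum(axis=1)), index=drugs.index, name="distance")
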