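# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic benchmark, and the known limitations of `procpharm`.

## Ontology and annotation model

Terms form a directed acyclic multigraph with three edge kinds: `is_a`,
`part_of`, `regulates`. Annotation follows the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor reachable
through `is_a` and `part_of` edges. `regulates` edges remain in the graph
for traversal and for the significant-term DAG, but do not transmit
annotations — regulating a process does not make a gene a participant in
the regulated process. Obsolete terms are dropped at parse time; `alt_id`
aliases are ignored; identifiers are opaque, case-sensitive strings.
Parsing is delegated to `obonet`, with structural validation on top: a
parent referenced without a stanza of its own and any cycle among the
typed edges are hard errors.

The background universe N defaults to the number of distinct genes with at
least one annotation in the loaded table — the operational version of
"all annotated genes in the release being used". It can be overridden by
setting `AnnotationTable.n_background` when an external universe size is
more appropriate.

## Over-representation analysis

Per term with at least one annotated background gene, the query overlap k
is scored with the one-sided upper tail of the hypergeometric
distribution, `P(X >= k)` for `X ~ Hypergeom(N, K, n)` — the Fisher exact
test for over-representation. Only the upper tail is tested because the
question is whether a term covers *more* query genes than expected;
depletion is out of scope. Query genes absent from the background are
dropped (with a warning) before testing so that n and N stay consistent.
Raw p-values are corrected by Benjamini–Hochberg FDR (trait
characterization, threshold t_p = 0.05) or Bonferroni (process filter);
the threshold comparison is inclusive (`p_adj <= t_p`). Terms with K = 0
are untestable and skipped. Results are ordered by raw p, ties broken by
term id, so reports are byte-stable.

The ORA is a plain per-term test; no parent–child decorrelation
(elim/weight-style) is applied. Because annotations are propagated,
ancestors of a genuinely enriched term are usually enriched too — the
functional-abstraction step, not the test, is responsible for reducing
that redundancy.

## Functional abstraction

The DAG of significant terms is reduced to "functional areas" by a greedy
weighted set cover. Each significant term is a candidate headline covering
itself and its significant descendants (via propagating edges). At every
step the candidate maximizing

    (number of newly covered significant terms) x information content,

with information content `-log2(K/N)` bits, is promoted; ancestors and
descendants of a chosen headline leave the pool (non-redundancy), and the
loop stops at 95 % coverage or 10 headlines (both configurable). Ties
break by higher information content, then lexicographic term id, making
the selection deterministic. The product objective balances the two
failure modes of headline selection: picking the root (huge coverage, zero
information) and picking leaves (high information, no compression). The
uncovered remainder is reported explicitly as the residual rather than
silently absorbed.

## The drug / process matrix chain

All matrices are labelled pandas DataFrames, and every operation aligns by
label, never by position. The chain is:

1. **drug × gene** — binary; a drug's row marks the genes coding for its
   targets. Duplicate (drug, target) input rows collapse to one; drugs
   with no target inside the annotated gene universe are dropped with a
   warning.
2. **gene × process** — binary; columns are the terms that survive an ORA
   of the full target-gene set. This ORA is a *filter*, not an inference:
   a deliberately conservative threshold (Bonferroni) removes generic
   high-level terms so the process space stays specific.
3. **drug × process** = product of the two — integer-valued; entry (d, p)
   counts d's targets annotated to p.
4. **virtual drug** — the process-count vector of the trait gene set
   (`counts[p]` = number of trait genes annotated to p), appended as one
   more row. An all-zero vector aborts the run: the trait shares no
   process with the drug-addressable space.
5. **restriction** — keep only columns positive in the virtual drug *and*
   addressed by at least one drug; drop drug rows that become all-zero.
   The result has (supported drugs + 1) rows.
6. **distances** — Euclidean, on raw counts. No column standardization is
   applied by default because the virtual drug is count-valued by
   construction and rescaling would distort its saturation structure; a
   `standardize` switch exists for sensitivity analyses.

## Nested ABC analysis

The reciprocals of the distances (large = similar) are submitted to
computed ABC analysis: items are sorted in decreasing order and the
cumulative-share curve (x = item fraction, y = share of the total sum) is
cut where its slope reaches 1. The slope is evaluated on the discrete
curve segments — segment i has slope `n·v_(i)/Σv` — so set A is the items
before the first segment with slope ≤ 1 (kept inclusive when the slope is
exactly 1). This parameter-free rule is exactly testable and needs no
smoothing or interpolation of the empirical curve. For all-equal values
the convention is minimal-A (the single first item) so that nested
application terminates. The B|C boundary is placed at the curve point
after A closest to (1, 1); it is reported for completeness but nothing
downstream uses it.

"Nested" means A-of-A: the A set is re-submitted once more (depth 2 by
default). Items at distance zero from the virtual drug have an undefined
reciprocal; they bypass the analysis and are force-retained.

## Emergent SOM, U-matrix, and basin extraction

The pruned matrix rows (survivors plus the virtual drug, which trains like
any other row) are projected onto a toroid Kohonen lattice. Reference
geometry is 50 × 80 neurons trained for 50 epochs; weights initialize
uniformly within each data column's range. Training is online: per epoch
every row is presented in a seeded shuffled order, the best-matching unit
(BMU; ties resolve to the smallest (row, col)) is located, and every
neuron moves by `rate · exp(−g²/2r²) · (x − w)` with g the toroidal grid
distance to the BMU. Rate and radius decay linearly across epochs
(defaults 0.5 → 0.1 and 24 → 1 on the reference grid, following
Databionics ESOM conventions; the kernel and schedules are unstated in the
underlying method description and are therefore explicit configuration
here). Training is bitwise reproducible for a fixed seed; the master seed
fans out to separate init and shuffle streams.

The U-matrix assigns each neuron the mean Euclidean distance between its
weight and its 8 grid neighbours' weights (toroidal wrap; on a planar grid
border neurons average over existing neighbours). Valleys are clusters,
ridges are borders.

Basins are extracted by steepest-descent watershed: each neuron follows
its lowest neighbour downhill to a local minimum; plateau ties move to the
lexicographically smallest preceding equal-height neighbour, which
terminates and funnels flat regions deterministically. Two refinements
precede the raw descent in the extraction step, both switchable:

* a single-pass 3 × 3 mean smoothing of the U-heights (default on),
  suppressing single-neuron micro-basins;
* **shallow-basin merging** (default threshold 0.3): basins whose pour
  depth — lowest saddle to a deeper neighbouring basin minus own minimum —
  is below 30 % of the U-height range are merged into that neighbour,
  shallowest first. A raw watershed splits at *every* ridge regardless of
  amplitude, and a SOM whose grid is much larger than its data set always
  carries low-amplitude fold texture; without a persistence criterion that
  texture shreds one genuine cluster into several basins. Merging by pour
  depth is the standard remedy and leaves genuinely separated valleys
  (depth above threshold) untouched, as the two-valley fixtures in the
  test suite check.

The candidate list is the set of drugs whose BMUs share a basin with the
virtual drug's BMU, the virtual drug itself excluded.

## Synthetic benchmark

The generator emulates the statistical situation the analysis assumes,
not real GO/DrugBank topology. Reference condition: 150 terms in a
depth-5 layered DAG (acyclic by construction; each non-root term draws 1–2
parents from the previous layer, the first via `is_a` so annotation paths
propagate), 400 genes with ~4–5 random background annotations each
(written unpropagated, so the closure code is exercised), 300 drugs, and a
planted signal: 8 planted processes in the deepest layer, a 16-gene trait
panel, and 30 planted drugs. Genes fall into a druggable pool of 80; the
planted drugs draw their 10–12 targets from a 40-gene signal pool;
signal-pool genes and trait genes are annotated to each planted process
with probability 0.9 (signal), the other druggable genes with probability
0.05 (noise).

Three geometric properties drive these choices:

* the trait panel (16) is commensurate with drug target multiplicity
  (10–12), so the virtual drug's counts sit inside the planted cluster
  rather than dominating every distance;
* the signal pool is half the druggable pool, so non-planted drugs hit
  signal genes to a varying degree and the similarity to the virtual drug
  forms a continuum — the regime in which an ABC curve has meaningful
  structure rather than two isolated tiers;
* drugs are organized into ten classes sharing 40-gene repertoires, with
  the planted drugs as one class. When signal equals noise all classes
  are statistically identical, so the planted label is exchangeable —
  the negative control is unbiased, and permuting the planted label
  across classes is its exact null.

At this scale the genome-scale reference thresholds do not transfer: a
process filter at t_p = 1e-15 would always return zero terms from a
400-gene universe. The benchmark configuration (`scaled_study_config`)
therefore uses t_p = 0.05 with the same Bonferroni correction, and scales
the ESOM to 20 × 30 neurons with a 10 → 2 radius schedule over the same
50 epochs. The negative control additionally disables the filter
(t_p = 1): without signal no term passes any enrichment filter, and the
control needs a candidate list to score.

What passing the recovery study shows: the chain of ORA filter, matrix
algebra, ABC pruning and basin extraction preserves and isolates a
coherent process-similarity signal, and finds nothing systematic when no
signal exists. What it does not show: performance on real ontologies
(term-size power laws, evidence-code noise), real drug-target tables
(extreme multi-target skew, signed interactions), or the stability of the
candidate list under database revisions.

## Numerical and degenerate-input conventions

Hypergeometric tails come from `scipy.stats.hypergeom.sf`, clipped into
(0, 1]; corrections from `statsmodels.multipletests`. ABC analysis
requires strictly positive finite values and rejects anything else.
Constant data columns pin the corresponding weight component. A constant
U-matrix yields a single basin containing every label. Zero learning rate
leaves weights untouched; a zero final radius degenerates to BMU-only
updates. All stage outputs are sorted (term id, drug id, label) before
writing, so reruns with one seed are byte-identical.

## Known limitations

* Drug–target interactions are unsigned; an agonist and an antagonist of
  the same target are indistinguishable, so candidate lists can contain
  drugs expected to *worsen* the trait alongside those mimicking it.
* The per-term ORA ignores DAG correlation; headline selection compensates
  only heuristically.
* The greedy set cover is a stated, testable surrogate for functional
  abstraction; it is not a reimplementation of any published algorithm's
  internals, and its headline choice on real GO data may differ.
* Watershed results depend on the smoothing and merge-depth settings at
  small data-to-grid ratios; both are exposed in `EsomConfig` and should
  be reported with any result.
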