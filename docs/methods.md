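# Methods

## Ontology handling

The GO DAG is read from OBO 1.2 text. Only `is_a` and
`relationship: part_of` lines become edges; `regulates` and other relations
are dropped because the enrichment machinery (and the tooling lineage it
follows, topGO/GO.db) does not traverse them. Obsolete terms are retained
for lookup but carry no edges and never enter propagation or testing.
`alt_id`s resolve to their primary accession. Acyclicity is checked at load
and a violation reports one concrete cycle. Each namespace root is the term
with no same-namespace parents.

Annotation maps follow the true path rule: a gene annotated to a term is
annotated to every ancestor reachable via `is_a` and `part_of` (the relation
set is configurable). Propagation is computed in one reverse-topological
pass and is idempotent by construction. Annotations to unknown or obsolete
terms are skipped with a warning by default (`on_unknown="error"` raises);
the namespace of an annotation is taken from the term, not the annotation
line. GAF 2.x input keeps all evidence codes by default, IEA included — the
evidence filter is exposed but the default is deliberately permissive, since
electronic annotations dominate plant GO coverage.

## Reference sets

AGI locus ids are canonicalized by stripping whitespace, trimming a trailing
`.<integer>` splice suffix and uppercasing; all sets live at the gene level.
Per-site predictor scores lie in [0, 1] with −1 flagging a residue the
predictor did not score. Site → protein → gene collapse is max-aggregation
at both levels; −1 loses to any real score, so a gene scores −1 only when
every site is missing. Duplicate site records keep the max score, consistent
with the aggregation semantics. Genes in the universe but absent from a
score table behave as −1.

Classification is `score >= threshold` — the boundary is inclusive, the
usual ROC convention — and −1 is never positive. The predictor ensemble is a
set union: a gene is predicted phosphorylated if any component predictor
says so, which can only increase sensitivity. A second predictor distributed
as a pre-thresholded high-confidence site list is ingested directly as a
positive gene list. Reference augmentation (`Un11RS`-style) adds a sample's
novel phosphoproteins to the union reference and logs how many were
genuinely new; this guarantees the sample is contained in its comparison
universe.

Set reports state sizes, pairwise intersections/differences and percentages
of the genome at one decimal; containment violations are listed, never
silently dropped, and inclusion–exclusion holds exactly because everything
is genuine set algebra.

## Classifier evaluation

Positives are the experimentally observed phosphoprotein genes; the universe
is the scored genome. The ROC sweeps the unique valid scores as thresholds
(>=-inclusive); genes flagged −1 are negative at every score threshold. The
curve is closed with a sentinel above the maximum score (nothing predicted)
and a terminal predict-everything point, so the trapezoid AUC spans the unit
square even when positives carry missing flags. The operating point
maximizes Youden's J = tpr − fpr over the genuine score cutoffs only, with
ties broken toward the largest (strictest) threshold; a flat classifier
therefore returns its single score with J = 0.

The resampled threshold draws `floor(0.30 · |universe|)` genes without
replacement, 5000 times by default, recomputes the Youden optimum per
replicate and averages. Replicates lacking either class are redrawn (count
logged) so the replicate count stays fixed. A single seeded NumPy generator
drives everything; the same seed reproduces every replicate exactly.

## Enrichment testing

For a term annotating K of N feasible universe genes, with a sample of n
genes hitting k of them, the classic one-sided p-value is the upper
hypergeometric tail P(X ≥ k), evaluated by `scipy.stats.hypergeom.sf` in one
vectorized call per comparison. The feasible universe is the input universe
restricted to genes with at least one annotation in the namespace;
unannotated genes cannot influence counts. Terms annotating fewer than
`min_node_size` feasible genes (default 1) are not tested, but their gene
sets still contribute to parent pools.

The parent-child-union correction replaces the conditioning universe by the
genes annotated to the union of the term's parents (genes reaching several
parents count once): N′ = |∪ parents' genes|, n′ = |sample ∩ that pool|,
K and k as before. When the parents' pool covers the feasible universe the
statistic reduces exactly to the classic test; the namespace root scores
p = 1 by convention. The union variant was chosen over the intersection
variant as the standard default of the parent-child family; the direction is
one-sided over-representation only.

Adjustment is Benjamini–Hochberg within each namespace per comparison
(namespaces are reported separately, so the error rate is controlled where
the calls are made), significance at FDR < 0.01. Tables are ordered by FDR
then term id for determinism.

## Contrast and specific terms

The binary matrix has one row per term significant in at least one of the
ordered comparisons and a 1 wherever FDR < α. Terms untested in a comparison
(node-size filtered there) score 0 with a logged warning. Pattern groups are
the observed non-zero patterns, labelled in descending order of BP term
count with ties broken by the pattern read as a binary number, descending.
With three comparisons at most 2³ − 1 = 7 groups can occur. A term is
specific to the sample iff its row has 1 in both sample columns — the
reference-vs-genome column never affects the call, it only splits the
specific set into its two sub-patterns.

GenRatio is 100 · |sample ∩ term genes| / |term genes in universe|, with the
denominator taken from the genome-wide propagated annotation index; the
exact rational is kept internally and display rounds to one decimal.

## Semantic similarity and layout

Wang S-values: S(focal) = 1 and S(ancestor t) = max over in-closure edges
c → t of w(relation) · S(c), with the standard weights is_a = 0.8,
part_of = 0.6 (configurable; any (0,1) weights are accepted). Similarity of
two terms is Σ over shared closure terms of (S_a + S_b) divided by
(SV_a + SV_b); it is 1 on the diagonal, symmetric, bounded in [0, 1], and
unchanged by unrelated additions to the DAG.

The 2-D layout is classical (Torgerson) metric MDS on d = 1 − sim: double-
center −d²/2, take the top-2 eigenpairs of the symmetrized Gram matrix,
scale eigenvectors by √eigenvalue, zero any axis with a non-positive
eigenvalue. Each axis is oriented so its largest-|coordinate| term is
positive, making the embedding bit-reproducible; the centroid sits at the
origin by construction. Fit quality is reported as Kruskal stress-1.
Dissimilarities of embedding rank ≤ 2 are reproduced to ~1e−16. 1 − sim was
preferred over −log sim because it is bounded and standard for Wang plots.
The DOT export renders the ancestor closure of selected terms (solid is_a,
dashed part_of) as a portable substitute for dedicated DAG viewers.

## Synthetic data

All generators take a seed and are exactly reproducible. Gene ids follow the
AGI pattern (`AT<chr>G<5 digits>`, optional `.1` variants) so normalization
paths are exercised. Toy DAGs grow root-down — each new term attaches to one
or two existing parents — and are acyclic by construction, with mixed
is_a/part_of labels (part_of probability 0.25). Score tables draw positives
from Beta(9, 2) (mode ≈ 0.89) and negatives from Beta(2.8, 8.2)
(mode ≈ 0.2): the real per-site scores are only constrained to [0, 1] with
−1 missing flags, so a well-separated bimodal mixture with these modes is
the package's chosen emulation; a `separation` option forces perfectly
separable scores for boundary tests. Reference-set scenarios honour
requested cardinalities and overlaps exactly.

The contrast scenario used by the recovery analyses has a 2,000-gene
genome, a 60-term DAG and two disjoint ~80-gene terms: the *default* term is
over-represented in the phospho-reference (inclusion 0.9 vs 0.45
background), and the sample is a uniform 30% draw of that reference — so it
inherits the default enrichment at equal strength — plus the *planted*
term's genes at rate 0.8 against a diluted background, with the reference
augmented by the sample's novel genes before the sample-vs-reference
comparison. Terms are chosen so their parents' pools span ≥ 60% of the
genome, where the parent-child test has power; topologies without such a
pair are redrawn deterministically. These problem sizes keep a 50-seed
recovery analysis and a 500-run null control in the tens of seconds while
leaving the planted effect comfortably detectable.

What the generator does not emulate: correlated annotations between related
genes, study-specific biases in experimental lists, score calibration
differences between predictors, and the long-tailed term-size distribution
of the real GO. Passing tests therefore demonstrate the correctness and
calibration of the machinery under controlled conditions, not the
biological conclusions reachable from any particular real dataset.

## Numerical conventions and degenerate inputs

Zero-denominator metrics return NaN markers, never raise. Hypergeometric
tails are clamped to (0, 1]; K = 0 or n = 0 gives p = 1. BH inputs must lie
in (0, 1]. Empty samples after universe restriction, single-class label
sets, mixed-namespace similarity requests and infeasible scenario
cardinalities raise immediately with the offending items named. All
orderings (tables, matrices, groups) are deterministic.
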