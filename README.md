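# phosgo

Contrast-based GO enrichment for phosphoproteome samples.

## The problem

Standard GO over-representation analysis compares a gene list against the
genome. For a phosphoproteome sample that comparison is misleading: many GO
terms (protein phosphorylation, kinase activity, ...) are enriched in *any*
phosphoproteome by default, regardless of the biological condition under
study. `phosgo` implements a contrast strategy that separates those default
enrichments from condition-specific ones by testing the sample against two
universes:

1. **Et vs GenRS** — the sample against the whole genome;
2. **Et vs Un11RS** — the sample against a phosphoproteome reference set
   (the union of experimentally observed and predicted phosphoproteins,
   augmented with the sample's own novel phosphoproteins so the sample is
   fully contained in its comparison universe);
3. **Un11RS vs GenRS** — the reference against the genome, characterizing
   the default enrichment itself.

Each GO term gets a binary significance pattern over the ordered
comparisons; terms sharing a pattern form a contrast group (CG1, CG2, ...).
A term is **specific** to the sample when it is significant in both sample
comparisons — it stands out even against the phosphoproteome background.

The package targets *Arabidopsis thaliana* workflows (AGI locus ids,
splice-variant suffixes, MusiteDeep/PhosPhAt-style predictor scores) but the
machinery is organism-agnostic.

## Methods at the core

- **Reference sets** (`phosgo.refsets`): the experimental set ExpRS is a
  union of per-study phosphoprotein lists; the predicted set PredRS collapses
  per-site predictor scores to gene scores by
  `gene score = max over isoforms of (max over sites)` with `-1` flagging
  missing scores, thresholds the gene scores, and OR-ensembles predictors;
  UnRS = ExpRS ∪ PredRS.
- **Classifier evaluation** (`phosgo.predeval`): confusion counts against
  experimental labels, ROC with trapezoid AUC, and the operating threshold
  as the maximizer of Youden's J = tpr − fpr, stabilized as the mean of the
  per-replicate optimum over 5000 random 30% subsamples of the universe.
- **Enrichment** (`phosgo.enrichment`): one-sided hypergeometric
  (Fisher) over-representation with the **parent-child-union** correction —
  each term's count is conditioned on the genes annotated to the union of
  its parents, removing the inheritance-driven dependence that the true path
  rule (annotations propagate to all ancestors) induces between a term and
  its ancestors. Benjamini–Hochberg FDR within each namespace, significance
  at FDR < 0.01.
- **Contrast** (`phosgo.contrast`): binary significance matrices, pattern
  groups ordered by BP term count, specific-term calls, and GenRatio — the
  percentage of a term's annotated genes present in the sample.
- **Semantic similarity** (`phosgo.semsim`): Wang's graph-based similarity
  (is_a weight 0.8, part_of 0.6) and a deterministic classical-MDS 2-D
  layout of 1 − sim, with GenRatio node sizes; DOT export of term
  neighborhoods.
- **Synthetic data** (`phosgo.synthetic`): seed-deterministic toy DAGs,
  annotation maps, bimodal score tables, exact-cardinality reference-set
  scenarios, and planted-enrichment samples.

## Worked example

```python
from phosgo import (make_reference_scenario, set_report, make_contrast_scenario,
                    run_comparison, significance_matrix, specific_terms,
                    build_term_index, gen_ratio_table)

# reference-set algebra at the published Arabidopsis cardinalities
exp, pred, union, genome = make_reference_scenario(13137, 17156, 12024, 27655, seed=0)
rep = set_report([exp, pred, union], genome)
pw = rep["pairwise"]["ExpRS|PredRS"]
print(f"UnRS: {pw['union']} genes ({rep['sets']['UnRS']['pct_of_genome']}% of GenRS)")
print(f"ExpRS-only: {pw['only_ExpRS']}  PredRS-only: {pw['only_PredRS']}")

# a full synthetic contrast run with one planted sample-specific term and one
# term enriched equally in the sample and the phospho-reference
sc = make_contrast_scenario(seed=0)
ns = "biological_process"
tables = [
    run_comparison(sc.sample, sc.genome, sc.annotations, sc.dag, ns,
                   comparison="Et_vs_GenRS"),
    run_comparison(sc.sample, sc.augmented, sc.annotations, sc.dag, ns,
                   comparison="Et_vs_Un11RS"),
    run_comparison(sc.augmented, sc.genome, sc.annotations, sc.dag, ns,
                   comparison="Un11RS_vs_GenRS"),
]
matrix = significance_matrix(tables)
spec = specific_terms(matrix, "Et_vs_GenRS", "Et_vs_Un11RS")
print(f"planted term {sc.planted_term} specific: {sc.planted_term in spec}")
print(f"default-enriched term {sc.default_term} excluded: {sc.default_term not in spec}")
index = build_term_index(sc.annotations, sc.genome, ns)
print(gen_ratio_table(sorted(spec), sc.sample, index).to_string(index=False))
```

prints

```
UnRS: 18269 genes (66.1% of GenRS)
ExpRS-only: 1113  PredRS-only: 5132
planted term GO:9000014 specific: True
default-enriched term GO:9000004 excluded: True
      term  n_sample  n_term  gen_ratio_pct
GO:9000003       442    1661           26.6
GO:9000014       209     259           80.7
GO:9000053        60      70           85.7
GO:9000054        39      51           76.5
```

The union of a 13,137-gene experimental set and a 17,156-gene predicted set
sharing 12,024 genes contains 18,269 genes (66.1% of a 27,655-gene genome);
1,113 experimental phosphoproteins are missed by prediction and 5,132
predicted ones lack experimental evidence. In the contrast run the term
planted only into the sample is called specific, while the term the sample
merely inherits from its phosphoproteome reference is filtered out — the
point of the double comparison. The planted term's GenRatio (80.7%) shows
the sample covers most of its annotated genes.

A `phosgo` CLI mirrors the library
(`build-refsets`, `eval-predictor`, `enrich`, `contrast`, `genratio`,
`semsim`, `simulate`, `run-all`); `phosgo run-all --config config.json`
executes the whole strategy and writes all tables plus a provenance record.

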