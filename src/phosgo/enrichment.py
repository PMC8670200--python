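"""GO over-representation testing: classic and parent-child Fisher, BH-FDR.

The classic test treats every term independently: the probability that a
sample of n genes from a universe of N contains k or more of the K genes
annotated to a term is the upper tail of the hypergeometric law.  Because
annotations propagate up the DAG, a strongly enriched child drags its
parents along; the parent-child variant corrects for this by conditioning
each term's count on the genes annotated to the union of its parents, so a
term is only called enriched if it stands out within its parents' gene pool.
Adjusted p-values are Benjamini-Hochberg within each ontology namespace and
thresholded at FDR < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationMap, OntologyDAG
from .refsets import ReferenceSet

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01


@dataclass
class TermGeneIndex:
    """Propagated term -> universe-gene sets for one ontology namespace.

    ``feasible`` is the universe restricted to genes with at least one
    annotation in the namespace; unannotated genes cannot enter any count.
    ``tested_terms`` excludes terms annotating fewer than ``min_node_size``
    feasible genes, but ``term_genes`` keeps every term so that parent pools
    stay complete.
    """

    namespace: str
    feasible: frozenset[str]
    term_genes: dict[str, frozenset[str]]
    tested_terms: list[str]
    min_node_size: int = 1
    root: str | None = None
    _parent_pool: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)


def build_term_index(annotations: AnnotationMap, universe: ReferenceSet,
                     namespace: str, min_node_size: int = 1) -> TermGeneIndex:
    """Invert propagated annotations over the universe for one namespace."""
    view = annotations.namespace_view(namespace)
    feasible = frozenset(g for g in universe.members if g in view)
    if not feasible:
        raise ValueError(
            f"no annotated genes in namespace {namespace!r}: feasible universe is empty")
    term_genes: dict[str, set[str]] = {}
    for gene in feasible:
        for t in view[gene]:
            term_genes.setdefault(t, set()).add(gene)
    frozen = {t: frozenset(g) for t, g in term_genes.items()}
    tested = sorted(t for t, g in frozen.items() if len(g) >= min_node_size)
    root = annotations.dag.roots.get(namespace)
    return TermGeneIndex(namespace=namespace, feasible=feasible,
                         term_genes=frozen, tested_terms=tested,
                         min_node_size=min_node_size, root=root)


def _check_sample(sample: ReferenceSet, index: TermGeneIndex) -> None:
    outside = sample.members - index.feasible
    if outside:
        raise ValueError(
            "sample not contained in the feasible universe; offending ids: "
            f"{sorted(outside)[:10]}{'...' if len(outside) > 10 else ''}")


def fisher_classic(sample: ReferenceSet, index: TermGeneIndex, term: str) -> float:
    """One-sided hypergeometric over-representation p-value for one term."""
    _check_sample(sample, index)
    return _hypergeom_tail(
        n_universe=len(index.feasible),
        n_term=len(index.term_genes.get(term, frozenset())),
        n_sample=len(sample.members),
        n_hit=len(sample.members & index.term_genes.get(term, frozenset())),
    )


def _hypergeom_tail(n_universe: int, n_term: int, n_sample: int, n_hit: int) -> float:
    """P(X >= n_hit) for X ~ Hypergeom(N=n_universe, K=n_term, n=n_sample)."""
    if n_term == 0 or n_sample == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(n_hit - 1, n_universe, n_term, n_sample)))


def _parent_pool(index: TermGeneIndex, dag: OntologyDAG, term: str) -> frozenset[str]:
    """Feasible genes annotated to the union of a term's parents (cached)."""
    pool = index._parent_pool.get(term)
    if pool is None:
        genes: set[str] = set()
        for p in dag.parents(term):
            genes |= index.term_genes.get(p, frozenset())
        pool = frozenset(genes)
        index._parent_pool[term] = pool
    return pool


def parent_child_p(sample: ReferenceSet, index: TermGeneIndex, term: str,
                   dag: OntologyDAG) -> float:
    """Parent-child-union over-representation p-value.

    The conditioning universe is the set of feasible genes annotated to the
    union of the term's parents; genes reaching several parents count once.
    The namespace root has no parents and scores p = 1 by convention.
    """
    _check_sample(sample, index)
    if not dag.parents(term):
        return 1.0
    pool = _parent_pool(index, dag, term)
    term_set = index.term_genes.get(term, frozenset())
    return _hypergeom_tail(
        n_universe=len(pool),
        n_term=len(term_set),
        n_sample=len(sample.members & pool),
        n_hit=len(sample.members & term_set),
    )


def bh_fdr(pvalues: "list[float] | np.ndarray") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentTable:
    """Per-term enrichment results for one comparison in one namespace."""

    comparison: str
    namespace: str
    table: pd.DataFrame  # term, n_universe, n_sample, p, fdr, significant
    alpha: float = DEFAULT_ALPHA

    @property
    def significant_terms(self) -> set[str]:
        return set(self.table.loc[self.table["significant"], "term"])


def enrich_terms(sample: ReferenceSet, index: TermGeneIndex, dag: OntologyDAG,
                 alpha: float = DEFAULT_ALPHA, method: str = "parentchild",
                 comparison: str = "") -> EnrichmentTable:
    """Test every indexed term; BH-FDR within the namespace.

    ``method`` is ``"parentchild"`` (default) or ``"classic"``.  The sample
    must already lie inside the feasible universe.  All hypergeometric tails
    are evaluated in one vectorized call.
    """
    _check_sample(sample, index)
    if not sample.members:
        raise ValueError("sample is empty after restriction to the feasible universe")
    if method not in ("parentchild", "classic"):
        raise ValueError(f"method must be 'parentchild' or 'classic', got {method!r}")
    terms = index.tested_terms
    sample_set = sample.members
    N = np.empty(len(terms), dtype=np.int64)
    K = np.empty(len(terms), dtype=np.int64)
    n = np.empty(len(terms), dtype=np.int64)
    k = np.empty(len(terms), dtype=np.int64)
    is_root = np.zeros(len(terms), dtype=bool)
    for i, t in enumerate(terms):
        tg = index.term_genes[t]
        k[i] = len(sample_set & tg)
        K[i] = len(tg)
        if method == "classic":
            N[i] = len(index.feasible)
            n[i] = len(sample_set)
        else:
            if not dag.parents(t):
                is_root[i] = True
                N[i], n[i] = len(index.feasible), len(sample_set)
                continue
            pool = _parent_pool(index, dag, t)
            N[i] = len(pool)
            n[i] = len(sample_set & pool)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = hypergeom.sf(k - 1, N, K, n)
    p = np.minimum(1.0, np.where((K == 0) | (n == 0), 1.0, p))
    p[is_root] = 1.0
    fdr = bh_fdr(p)
    df = pd.DataFrame({
        "term": terms,
        "namespace": index.namespace,
        "n_universe_annotated": K,
        "n_sample_annotated": k,
        "p": p,
        "fdr": fdr,
        "significant": fdr < alpha,
    }).sort_values(["fdr", "term"], kind="stable").reset_index(drop=True)
    return EnrichmentTable(comparison=comparison, namespace=index.namespace,
                           table=df, alpha=alpha)


def run_comparison(sample: ReferenceSet, universe: ReferenceSet,
                   annotations: AnnotationMap, dag: OntologyDAG, namespace: str,
                   alpha: float = DEFAULT_ALPHA, min_node_size: int = 1,
                   method: str = "parentchild",
                   comparison: str | None = None) -> EnrichmentTable:
    """Full sample-vs-universe comparison for one namespace.

    Sample genes outside the feasible universe (unannotated, or not in the
    universe) are dropped with a logged count before testing.
    """
    index = build_term_index(annotations, universe, namespace, min_node_size)
    kept = sample.members & index.feasible
    dropped = len(sample.members) - len(kept)
    if dropped:
        log.warning("comparison %s/%s: dropped %d sample genes outside the "
                    "feasible universe", comparison or sample.name, namespace, dropped)
    restricted = ReferenceSet(sample.name, frozenset(kept))
    return enrich_terms(restricted, index, dag, alpha=alpha, method=method,
                        comparison=comparison or f"{sample.name}_vs_{universe.name}")
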