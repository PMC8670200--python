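"""Seed-deterministic generators for every stage of the pipeline.

Emulates the statistical shape of the real inputs — AGI-style gene ids,
toy GO DAGs grown root-down, annotation maps, bimodal per-gene predictor
scores with -1 missing flags, reference-set scenarios with exact
cardinalities and overlap, and samples with planted term enrichment — so the
whole strategy is testable without downloading anything.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationMap, GOTerm, OntologyDAG, propagate_annotations
from .refsets import MISSING_SCORE, GeneScoreTable, ReferenceSet, augment_reference

#: default score model: high component modes near 0.9, low near 0.2
POS_BETA = (9.0, 2.0)
NEG_BETA = (2.8, 8.2)


def make_gene_ids(n: int, prefix_variants: bool = False) -> list[str]:
    """n unique AGI-style locus ids (AT<chr>G<5 digits>), deterministic order.

    With ``prefix_variants`` a third of the ids get a ".1" splice suffix so
    normalization paths are exercised.
    """
    ids = []
    for chrom in itertools.count(1):
        for num in range(0, 100000, 7):  # stride keeps ids non-consecutive
            ids.append(f"AT{chrom}G{num:05d}")
            if len(ids) == n:
                if prefix_variants:
                    ids = [g + ".1" if i % 3 == 0 else g for i, g in enumerate(ids)]
                return ids
    raise AssertionError("unreachable")


def make_toy_dag(n_terms: int, namespace: str = "biological_process",
                 seed: int = 0, part_of_prob: float = 0.25,
                 id_offset: int = 0) -> OntologyDAG:
    """Random GO-like DAG grown root-down.

    The first term is the namespace root; each later term attaches to one or
    two already-existing parents, so the graph is acyclic by construction.
    Edge labels are is_a with probability ``1 - part_of_prob`` else part_of.
    """
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    ids = [f"GO:{9000000 + id_offset + i:07d}" for i in range(n_terms)]
    terms: dict[str, GOTerm] = {
        ids[0]: GOTerm(id=ids[0], name=f"{namespace} root", namespace=namespace)
    }
    for i in range(1, n_terms):
        n_parents = 1 if i == 1 else int(rng.integers(1, 3))
        parent_idx = rng.choice(i, size=min(n_parents, i), replace=False)
        parents = []
        for j in sorted(parent_idx):
            rel = "part_of" if rng.random() < part_of_prob else "is_a"
            parents.append((ids[j], rel))
        terms[ids[i]] = GOTerm(id=ids[i], name=f"synthetic term {i}",
                               namespace=namespace, parents=parents)
    return OntologyDAG(terms)


def make_annotation_map(dag: OntologyDAG, genes: list[str],
                        mean_terms_per_gene: float = 2.0,
                        seed: int = 0) -> AnnotationMap:
    """Random direct annotations (1 + Poisson terms per gene), propagated."""
    rng = np.random.default_rng(seed)
    term_ids = sorted(t for t, term in dag.terms.items() if not term.obsolete)
    direct: dict[str, set[str]] = {}
    for g in genes:
        k = 1 + rng.poisson(max(mean_terms_per_gene - 1.0, 0.0))
        picks = rng.choice(len(term_ids), size=min(k, len(term_ids)), replace=False)
        direct[g] = {term_ids[i] for i in picks}
    return propagate_annotations(dag, direct)


def make_reference_scenario(n_exp: int, n_pred: int, n_overlap: int,
                            n_genome: int, seed: int = 0
                            ) -> tuple[ReferenceSet, ReferenceSet, ReferenceSet, ReferenceSet]:
    """Synthetic (ExpRS, PredRS, UnRS, GenRS) with exact cardinalities.

    The experimental and predicted sets share exactly ``n_overlap`` genes
    inside a genome of ``n_genome`` ids.  Membership is shuffled by ``seed``
    but the requested counts hold exactly.
    """
    if n_overlap > min(n_exp, n_pred):
        raise ValueError("overlap exceeds one of the set cardinalities")
    n_union = n_exp + n_pred - n_overlap
    if n_union > n_genome:
        raise ValueError("union exceeds the genome size")
    rng = np.random.default_rng(seed)
    ids = make_gene_ids(n_genome)
    perm = rng.permutation(n_genome)
    shuffled = [ids[i] for i in perm]
    overlap = shuffled[:n_overlap]
    exp_only = shuffled[n_overlap:n_exp]
    pred_only = shuffled[n_exp:n_union]
    exp = ReferenceSet("ExpRS", frozenset(overlap + exp_only))
    pred = ReferenceSet("PredRS", frozenset(overlap + pred_only))
    union = ReferenceSet("UnRS", exp.members | pred.members)
    genome = ReferenceSet("GenRS", frozenset(ids))
    return exp, pred, union, genome


def make_score_sets(n_pos: int, n_neg: int, missing_rate: float = 0.0,
                    pos_beta: tuple[float, float] = POS_BETA,
                    neg_beta: tuple[float, float] = NEG_BETA,
                    separation: float | None = None,
                    seed: int = 0) -> tuple[GeneScoreTable, ReferenceSet, ReferenceSet]:
    """Bimodal gene scores with missing flags; returns (scores, positives, universe).

    Positives draw from the high beta component, negatives from the low one.
    ``separation`` forces perfectly separated scores (positives uniform in
    (separation, 1], negatives in [0, separation)).  A ``missing_rate``
    fraction of genes is flagged -1 regardless of label.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0,1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    genes = make_gene_ids(n_pos + n_neg)
    perm = rng.permutation(len(genes))
    pos_genes = [genes[i] for i in perm[:n_pos]]
    neg_genes = [genes[i] for i in perm[n_pos:]]
    if separation is not None:
        pos_scores = separation + (1.0 - separation) * (0.01 + 0.98 * rng.random(n_pos))
        neg_scores = separation * 0.98 * rng.random(n_neg)
    else:
        pos_scores = rng.beta(*pos_beta, size=n_pos)
        neg_scores = rng.beta(*neg_beta, size=n_neg)
    scores = dict(zip(pos_genes, pos_scores))
    scores.update(zip(neg_genes, neg_scores))
    if missing_rate > 0.0:
        miss = rng.random(len(genes)) < missing_rate
        for g, m in zip(genes, miss):
            if m:
                scores[g] = MISSING_SCORE
    return (GeneScoreTable({g: float(s) for g, s in scores.items()}),
            ReferenceSet("positives", frozenset(pos_genes)),
            ReferenceSet("universe", frozenset(genes)))


def make_enriched_sample(annotations: AnnotationMap, universe: ReferenceSet,
                         planted_terms: list[str], effect: float,
                         background_rate: float, seed: int = 0,
                         name: str = "sample") -> ReferenceSet:
    """Sample with planted term enrichment.

    Genes annotated (propagated) to a planted term enter the sample with
    probability ``effect``; every other universe gene with probability
    ``background_rate``.
    """
    if not 0.0 <= background_rate <= 1.0 or not 0.0 <= effect <= 1.0:
        raise ValueError("effect and background_rate must be in [0,1]")
    if planted_terms and effect <= background_rate:
        raise ValueError("planted effect must exceed the background rate")
    for t in planted_terms:
        if t not in annotations.dag:
            raise KeyError(f"planted term {t} not in the DAG")
    planted_genes = {
        g for g, terms in annotations.propagated.items()
        if any(t in terms for t in planted_terms)
    } & universe.members
    rng = np.random.default_rng(seed)
    members = set()
    for g in sorted(universe.members):
        p = effect if g in planted_genes else background_rate
        if rng.random() < p:
            members.add(g)
    return ReferenceSet(name, frozenset(members))


@dataclass
class ContrastScenario:
    """A full synthetic contrast setting: DAG, annotations, sets, planted truth."""

    dag: OntologyDAG
    annotations: AnnotationMap
    genome: ReferenceSet
    reference: ReferenceSet  # phospho-reference, enriched in default_term
    augmented: ReferenceSet  # reference + sample novelties (the comparison universe)
    sample: ReferenceSet
    planted_term: str  # enriched in the sample only -> should be specific
    default_term: str  # equally enriched in sample and reference -> excluded
    namespace: str = "biological_process"
    meta: dict = field(default_factory=dict)


def make_contrast_scenario(n_genes: int = 2000, n_terms: int = 60,
                           term_gene_target: int = 80,
                           ref_rate: float = 0.45, ref_term_rate: float = 0.9,
                           sample_from_ref: float = 0.3,
                           effect: float = 0.8, background_rate: float = 0.1,
                           seed: int = 0) -> ContrastScenario:
    """Scenario for specific-term recovery.

    One mid-DAG term (``default_term``) is over-represented in the
    phospho-reference itself; the sample is drawn uniformly from the
    reference (rate ``sample_from_ref``) so it inherits that enrichment with
    equal strength — such a term must not be called sample-specific.  A
    second disjoint term (``planted_term``) is planted into the sample at
    ``effect`` versus a ``background_rate`` of extra genome genes; it must be
    recovered as specific.  The reference is augmented with the sample's
    novel genes before the sample-vs-reference comparison, as the strategy
    requires the sample to be contained in its comparison universe.
    """
    rng = np.random.default_rng(seed)
    genes = make_gene_ids(n_genes)
    genome = ReferenceSet("GenRS", frozenset(genes))
    # pick two below-root terms whose parents' pools span most of the genome
    # (parent-child power needs the term to sit inside a broad parent pool)
    # and whose ancestor closures exclude each other, then widen their direct
    # annotation so each reaches roughly term_gene_target genes; some random
    # DAGs offer no such pair, so the topology is redrawn deterministically
    default_term = planted_term = None
    for _attempt in range(50):
        dag = make_toy_dag(n_terms, seed=int(rng.integers(2 ** 31)))
        annotations = make_annotation_map(dag, genes, mean_terms_per_gene=2.0,
                                          seed=int(rng.integers(2 ** 31)))
        closure = dag.ancestor_closure()
        term_cover = {
            t: sum(1 for ts in annotations.propagated.values() if t in ts)
            for t in dag.terms
        }
        candidates = []
        for t in sorted(dag.terms):
            parents = dag.parents(t)
            if not parents:
                continue
            pool = {g for g, ts in annotations.propagated.items() if ts & parents}
            if len(pool) >= 0.6 * n_genes and term_cover[t] <= 0.1 * n_genes:
                candidates.append(t)
        for a in candidates:
            for b in candidates:
                if a != b and a not in closure[b] and b not in closure[a]:
                    default_term, planted_term = a, b
                    break
            if default_term:
                break
        if default_term is not None:
            break
    if default_term is None:
        raise ValueError("no DAG with a suitable disjoint term pair after 50 draws")
    direct = {g: set(ts) for g, ts in annotations.direct.items()}
    pool = [g for g in genes]
    picks = rng.choice(len(pool), size=2 * term_gene_target, replace=False)
    for i in picks[:term_gene_target]:
        direct.setdefault(pool[i], set()).add(default_term)
        direct[pool[i]].discard(planted_term)
    for i in picks[term_gene_target:]:
        direct.setdefault(pool[i], set()).add(planted_term)
        direct[pool[i]].discard(default_term)
    annotations = propagate_annotations(dag, direct)
    default_genes = {g for g, ts in annotations.propagated.items() if default_term in ts}
    planted_genes = {g for g, ts in annotations.propagated.items() if planted_term in ts}
    # phospho-reference enriched in default_term
    ref_members = {
        g for g in genes
        if rng.random() < (ref_term_rate if g in default_genes else ref_rate)
    }
    reference = ReferenceSet("UnRS", frozenset(ref_members))
    # sample: uniform subsample of the reference + the planted term's genes
    sample_members = {g for g in sorted(ref_members) if rng.random() < sample_from_ref}
    for g in sorted(planted_genes):
        if rng.random() < effect:
            sample_members.add(g)
    for g in sorted(genome.members - ref_members - planted_genes):
        if rng.random() < background_rate * sample_from_ref:
            sample_members.add(g)
    sample = ReferenceSet("Et", frozenset(sample_members))
    augmented = augment_reference(reference, sample, name="UnRS+novel")
    return ContrastScenario(
        dag=dag, annotations=annotations, genome=genome, reference=reference,
        augmented=augmented, sample=sample, planted_term=planted_term,
        default_term=default_term,
        meta={"seed": seed, "n_genes": n_genes, "n_terms": n_terms,
              "effect": effect, "background_rate": background_rate},
    )
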