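"""Hypergeometric over-representation testing and BH-FDR."""

import math
from fractions import Fraction

import numpy as np
import pytest

from phosgo import (
    ReferenceSet,
    bh_fdr,
    build_term_index,
    fisher_classic,
    make_enriched_sample,
    make_toy_dag,
    parent_child_p,
    propagate_annotations,
    run_comparison,
)
from phosgo.synthetic import make_annotation_map, make_gene_ids

BP = "biological_process"


def exact_upper_tail(N, K, n, k):
    """Exhaustive hypergeometric sum, exact rational arithmetic."""
    if K == 0 or n == 0:
        return 1.0
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return float(min(total, Fraction(1)))


def _index_from(dag, direct, universe_genes, min_node_size=1):
    ann = propagate_annotations(dag, direct)
    universe = ReferenceSet("uni", frozenset(universe_genes))
    return ann, build_term_index(ann, universe, BP, min_node_size=min_node_size)


class TestTermIndex:
    def test_feasible_universe_excludes_unannotated(self, chain_dag):
        genes = [f"g{i}" for i in range(10)]
        direct = {g: {"GO:0000003"} for g in genes[:8]}
        _, index = _index_from(chain_dag, direct, genes)
        assert len(index.feasible) == 8

    def test_min_node_size_filters_small_terms(self, chain_dag):
        direct = {"g1": {"GO:0000003"}, "g2": {"GO:0000002"}, "g3": {"GO:0000002"}}
        _, index = _index_from(chain_dag, direct, ["g1", "g2", "g3"], min_node_size=3)
        assert "GO:0000003" not in index.tested_terms  # only g1 reaches the leaf
        assert "GO:0000002" in index.tested_terms

    def test_parent_superset_of_child_after_propagation(self):
        dag = make_toy_dag(40, seed=2)
        genes = make_gene_ids(100)
        ann = make_annotation_map(dag, genes, seed=3)
        index = build_term_index(ann, ReferenceSet("u", frozenset(genes)), BP)
        for tid, term in dag.terms.items():
            for pid, _ in term.parents:
                assert index.term_genes.get(tid, frozenset()) <= \
                    index.term_genes.get(pid, frozenset())


class TestFisherClassic:
    def test_worked_example(self, chain_dag):
        # N=20, K=5, n=8, k=4 -> 7280/125970
        genes = [f"g{i}" for i in range(20)]
        direct = {g: {"GO:0000003"} for g in genes[:5]}
        direct.update({g: {"GO:0000002"} for g in genes[5:]})
        _, index = _index_from(chain_dag, direct, genes)
        sample = ReferenceSet("s", frozenset(genes[:4] + genes[5:9]))
        p = fisher_classic(sample, index, "GO:0000003")
        assert p == pytest.approx(7280 / 125970, rel=1e-12)

    def test_boundaries(self, chain_dag):
        genes = [f"g{i}" for i in range(6)]
        direct = {g: {"GO:0000003"} for g in genes}
        _, index = _index_from(chain_dag, direct, genes)
        sample = ReferenceSet("s", frozenset(genes[:3]))
        # K = N: the term annotates everything, no enrichment possible
        assert fisher_classic(sample, index, "GO:0000003") == 1.0
        # unannotated term: K = 0
        assert fisher_classic(sample, index, "GO:0000002") == 1.0

    def test_sample_outside_universe_rejected(self, chain_dag):
        _, index = _index_from(chain_dag, {"g1": {"GO:0000003"}}, ["g1"])
        with pytest.raises(ValueError, match="offending"):
            fisher_classic(ReferenceSet("s", {"zz"}), index, "GO:0000003")

    def test_matches_exhaustive_oracle_on_random_instances(self):
        from phosgo.enrichment import _hypergeom_tail
        rng = np.random.default_rng(12345)
        for _ in range(300):
            N = int(rng.integers(2, 201))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, n + K - N)
            k = int(rng.integers(lo, min(K, n) + 1))
            expected = exact_upper_tail(N, K, n, k)
            got = _hypergeom_tail(N, K, n, k)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)


def naive_parent_child(sample, index, term, dag):
    """Independent parent-child-union reimplementation (pure python loops)."""
    parents = {p for p, _ in dag.terms[term].parents}
    if not parents:
        return 1.0
    pool = set()
    for g in index.feasible:
        for p in parents:
            if g in index.term_genes.get(p, frozenset()):
                pool.add(g)
    term_genes = index.term_genes.get(term, frozenset())
    return exact_upper_tail(len(pool), len(term_genes),
                            len(sample.members & pool),
                            len(sample.members & term_genes))


class TestParentChild:
    def test_reduces_to_classic_when_parents_cover_universe(self, chain_dag):
        genes = [f"g{i}" for i in range(30)]
        # every gene annotated somewhere below the root -> root covers all
        direct = {g: {"GO:0000002"} for g in genes[:20]}
        direct.update({g: {"GO:0000003"} for g in genes[20:]})
        ann, index = _index_from(chain_dag, direct, genes)
        sample = ReferenceSet("s", frozenset(genes[15:25]))
        pc = parent_child_p(sample, index, "GO:0000002", chain_dag)
        classic = fisher_classic(sample, index, "GO:0000002")
        assert pc == classic  # identical counts, machine-precision equality

    def test_root_scores_one(self, chain_dag):
        genes = ["g1", "g2"]
        _, index = _index_from(chain_dag, {g: {"GO:0000003"} for g in genes}, genes)
        sample = ReferenceSet("s", {"g1"})
        assert parent_child_p(sample, index, "GO:0000001", chain_dag) == 1.0

    def test_full_term_in_sample_beats_one(self):
        dag = make_toy_dag(15, seed=4)
        genes = make_gene_ids(60)
        ann = make_annotation_map(dag, genes, seed=4)
        index = build_term_index(ann, ReferenceSet("u", frozenset(genes)), BP)
        # find a term strictly smaller than its parent pool
        for t in index.tested_terms:
            tg = index.term_genes[t]
            pool = set().union(*(index.term_genes.get(p, frozenset())
                                 for p in dag.parents(t))) if dag.parents(t) else set()
            if tg and len(pool) > len(tg):
                sample = ReferenceSet("s", frozenset(tg))
                assert parent_child_p(sample, index, t, dag) < 1.0
                return
        pytest.fail("no suitable term in the toy DAG")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_implementation_on_toy_dags(self, seed):
        dag = make_toy_dag(20, seed=seed)
        genes = make_gene_ids(80)
        ann = make_annotation_map(dag, genes, seed=seed + 100)
        index = build_term_index(ann, ReferenceSet("u", frozenset(genes)), BP)
        rng = np.random.default_rng(seed)
        feasible = sorted(index.feasible)
        sample = ReferenceSet("s", frozenset(
            feasible[i] for i in rng.choice(len(feasible), size=20, replace=False)))
        for t in index.tested_terms:
            got = parent_child_p(sample, index, t, dag)
            expected = naive_parent_child(sample, index, t, dag)
            assert got == pytest.approx(expected, rel=1e-10)


class TestBhFdr:
    def test_textbook_monotone_case(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.random(50).clip(1e-9, 1.0)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    def test_null_uniform_controls_discoveries(self):
        # 200 uniform p-values per sim; mean BH discoveries at alpha stays small
        rng = np.random.default_rng(99)
        alpha = 0.05
        counts = []
        for _ in range(500):
            p = rng.random(200).clip(1e-12, 1.0)
            counts.append(int((bh_fdr(p) < alpha).sum()))
        assert np.mean(counts) <= alpha * 200


@pytest.fixture(scope="module")
def world():
    dag = make_toy_dag(40, seed=6)
    genes = make_gene_ids(400)
    ann = make_annotation_map(dag, genes, seed=6)
    return dag, ann, ReferenceSet("GenRS", frozenset(genes))


class TestRunComparison:

    def test_sample_equal_universe_yields_nothing(self, world):
        dag, ann, universe = world
        table = run_comparison(ReferenceSet("s", set(universe.members)),
                               universe, ann, dag, BP)
        assert not table.table["significant"].any()

    def test_planted_term_recovered(self, world):
        dag, ann, universe = world
        target = next(t for t in sorted(dag.terms)
                      if dag.parents(t) == {dag.roots[BP]}
                      and len([g for g, ts in ann.propagated.items() if t in ts]) >= 10)
        sample = make_enriched_sample(ann, universe, [target],
                                      effect=0.95, background_rate=0.05, seed=1)
        table = run_comparison(sample, universe, ann, dag, BP)
        sig = set(table.table.loc[table.table["significant"], "term"])
        assert target in sig

    def test_uniform_sample_rarely_significant(self, world):
        dag, ann, universe = world
        rng = np.random.default_rng(77)
        genes = sorted(universe.members)
        hits = 0
        for _ in range(40):
            sample = ReferenceSet("s", frozenset(
                genes[i] for i in rng.choice(len(genes), size=60, replace=False)))
            table = run_comparison(sample, universe, ann, dag, BP)
            hits += int(table.table["significant"].any())
        assert hits <= 2  # >= 95% of null draws stay silent

    def test_out_of_universe_sample_genes_dropped(self, world):
        dag, ann, universe = world
        genes = sorted(universe.members)
        sample = ReferenceSet("s", frozenset(genes[:30]) | {"ATZZ99999"})
        table = run_comparison(sample, universe, ann, dag, BP)
        assert table.table["n_sample_annotated"].max() <= 30

    def test_deterministic_ordering(self, world):
        dag, ann, universe = world
        genes = sorted(universe.members)
        sample = ReferenceSet("s", frozenset(genes[:50]))
        t1 = run_comparison(sample, universe, ann, dag, BP)
        t2 = run_comparison(sample, universe, ann, dag, BP)
        assert t1.table.equals(t2.table)
        assert (t1.table["fdr"].is_monotonic_increasing)
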