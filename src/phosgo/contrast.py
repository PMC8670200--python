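"""Significance-pattern contrast: the heart of the strategy.

A phosphoproteome sample is tested for GO enrichment not only against the
genome but also against a phosphoproteome reference set, and the reference
itself against the genome.  Each term then carries a binary significance
pattern over the ordered comparisons; terms sharing a pattern form a group.
A term is *specific* to the sample when it is significant both against the
genome and against the phospho-reference — enrichment seen only against the
genome is a default property of phosphoproteomes, not of the sample.
GenRatio quantifies how much of a term's annotated gene set the sample
covers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import EnrichmentTable, TermGeneIndex
from .refsets import ReferenceSet

log = logging.getLogger(__name__)


@dataclass
class SignificanceMatrix:
    """Terms x comparisons binary matrix for one ontology namespace.

    Rows are restricted to terms significant in at least one comparison.
    """

    namespace: str
    data: pd.DataFrame  # index: term ids; columns: comparison labels; values 0/1

    @property
    def comparisons(self) -> list[str]:
        return list(self.data.columns)

    @property
    def terms(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def significance_matrix(tables: Sequence[EnrichmentTable],
                        alpha: float | None = None) -> SignificanceMatrix:
    """Assemble the binary matrix from ordered per-comparison tables.

    Cell = 1 iff the term's FDR clears alpha in that comparison; terms never
    tested in a comparison (node-size filtered there) score 0 with a logged
    warning.  Rows significant nowhere are excluded.
    """
    if len(tables) < 2:
        raise ValueError("need at least two comparisons to contrast")
    namespaces = {t.namespace for t in tables}
    if len(namespaces) > 1:
        raise ValueError(f"tables mix namespaces: {sorted(namespaces)}")
    labels = [t.comparison for t in tables]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate comparison labels: {labels}")
    sig_sets = []
    for t in tables:
        a = alpha if alpha is not None else t.alpha
        sig_sets.append(set(t.table.loc[t.table["fdr"] < a, "term"]))
    rows = sorted(set().union(*sig_sets))
    data = pd.DataFrame(0, index=rows, columns=labels, dtype=int)
    for t, sig in zip(tables, sig_sets):
        tested = set(t.table["term"])
        untested = [r for r in rows if r not in tested]
        if untested:
            log.warning("%d matrix terms untested in comparison %s; scored 0",
                        len(untested), t.comparison)
        data.loc[[r for r in rows if r in sig], t.comparison] = 1
    return SignificanceMatrix(namespace=namespaces.pop(), data=data)


@dataclass
class PatternGroup:
    """Terms sharing one binary significance pattern across the comparisons."""

    label: str
    pattern: tuple[int, ...]
    terms: dict[str, set[str]]  # namespace -> terms
    bp_count: int

    @property
    def size(self) -> int:
        return sum(len(t) for t in self.terms.values())


def _pattern_value(pattern: tuple[int, ...]) -> int:
    value = 0
    for bit in pattern:
        value = (value << 1) | bit
    return value


def group_patterns(matrices: Mapping[str, SignificanceMatrix],
                   order_namespace: str = "BP",
                   prefix: str = "G") -> list[PatternGroup]:
    """Group matrix rows by their binary pattern across namespaces.

    Labels (``G1``.../``CG1``... via ``prefix``) are assigned by descending
    term count in ``order_namespace`` (ties: descending binary value of the
    pattern), mirroring the published group ordering by BP count.
    """
    comparison_lists = {tuple(m.comparisons) for m in matrices.values()}
    if len(comparison_lists) > 1:
        raise ValueError("matrices disagree on the comparison list")
    groups: dict[tuple[int, ...], dict[str, set[str]]] = {}
    for ns, m in matrices.items():
        for term, row in m.data.iterrows():
            pattern = tuple(int(v) for v in row)
            if not any(pattern):
                continue  # all-zero rows carry no signal
            groups.setdefault(pattern, {}).setdefault(ns, set()).add(term)
    ordered = sorted(
        groups.items(),
        key=lambda kv: (-len(kv[1].get(order_namespace, ())), -_pattern_value(kv[0])),
    )
    return [
        PatternGroup(label=f"{prefix}{i}", pattern=pattern, terms=terms,
                     bp_count=len(terms.get(order_namespace, ())))
        for i, (pattern, terms) in enumerate(ordered, start=1)
    ]


def specific_terms(matrix: SignificanceMatrix, sample_vs_genome: str,
                   sample_vs_ref: str) -> set[str]:
    """Terms significant both against the genome and against the phospho-reference.

    In the three-comparison layout this is the union of the two contrast
    groups whose pattern has 1 in both sample columns, whatever the
    reference-vs-genome column says.
    """
    for col in (sample_vs_genome, sample_vs_ref):
        if col not in matrix.data.columns:
            raise KeyError(f"unknown comparison column: {col}")
    mask = (matrix.data[sample_vs_genome] == 1) & (matrix.data[sample_vs_ref] == 1)
    return set(matrix.data.index[mask])


@dataclass(frozen=True)
class GenRatioRecord:
    """Share of a term's annotated genes present in the sample, as a percentage."""

    term: str
    numerator: int
    denominator: int

    @property
    def exact(self) -> Fraction:
        return Fraction(100 * self.numerator, self.denominator)

    @property
    def ratio(self) -> float:
        """Display value: percentage rounded to one decimal."""
        return round(float(self.exact), 1)


def gen_ratio(term: str, sample: ReferenceSet, index: TermGeneIndex) -> GenRatioRecord:
    """GenRatio of one term: 100 * |sample ∩ term genes| / |term genes in universe|."""
    genes = index.term_genes.get(term)
    if not genes:
        raise ValueError(f"term {term} has no annotated genes in the index")
    return GenRatioRecord(term=term,
                          numerator=len(sample.members & genes),
                          denominator=len(genes))


def gen_ratio_table(terms: Sequence[str], sample: ReferenceSet,
                    index: TermGeneIndex) -> pd.DataFrame:
    records = [gen_ratio(t, sample, index) for t in sorted(terms)]
    return pd.DataFrame({
        "term": [r.term for r in records],
        "n_sample": [r.numerator for r in records],
        "n_term": [r.denominator for r in records],
        "gen_ratio_pct": [r.ratio for r in records],
    })
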