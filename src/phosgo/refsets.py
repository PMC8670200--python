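"""Phosphoproteome reference sets.

Builds the gene-level reference sets the contrast strategy compares against:

* GenRS  — every protein-coding gene in the genome annotation (the universe);
* ExpRS  — union of genes with mass-spectrometry phosphorylation evidence
  across published studies;
* PredRS — genes called phosphorylated by an OR-ensemble of sequence-based
  predictors, with per-site scores collapsed to gene scores by max;
* UnRS   — ExpRS union PredRS;
* Un11RS — UnRS augmented with a sample's novel phosphoproteins.

All ids are AGI locus ids; splice-variant suffixes (".1", ".2", ...) are
trimmed so that sets live at the gene level.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

log = logging.getLogger(__name__)

_SPLICE_SUFFIX = re.compile(r"\.\d+$")

PHOSPHO_RESIDUES = ("S", "T", "Y")

#: flag for a residue the predictor produced no score for
MISSING_SCORE = -1.0


@dataclass(frozen=True)
class ReferenceSet:
    """A named set of normalized gene locus ids."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.name:
            raise ValueError("reference set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(self.members)

    def __or__(self, other: "ReferenceSet") -> "ReferenceSet":
        return ReferenceSet(f"{self.name}|{other.name}", self.members | other.members)


@dataclass(frozen=True)
class SiteScoreRecord:
    """One predictor score for one phospho-acceptor residue of one isoform."""

    protein_id: str
    residue: str
    position: int
    score: float

    def __post_init__(self):
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of {PHOSPHO_RESIDUES}, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not (self.score == MISSING_SCORE or 0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0,1] or -1, got {self.score}")


def normalize_gene_id(raw: str) -> str:
    """Canonical AGI locus id: strip whitespace, trim '.<n>' splice suffix, uppercase."""
    s = raw.strip()
    if not s:
        raise ValueError("empty gene id")
    return _SPLICE_SUFFIX.sub("", s).upper()


def read_gene_list(stream: IO[str] | Iterable[str]) -> list[str]:
    """One id per line; '#' comments and blank lines ignored. Ids not normalized."""
    out = []
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def build_reference_set(name: str, ids: Iterable[str]) -> ReferenceSet:
    return ReferenceSet(name, frozenset(normalize_gene_id(i) for i in ids))


def build_experimental_set(study_lists: Iterable[Iterable[str]],
                           name: str = "ExpRS") -> ReferenceSet:
    """Union of normalized ids over per-study gene lists.

    Logs per-study sizes and how many ids changed under normalization; an
    empty union signals malformed inputs and raises.
    """
    members: set[str] = set()
    for i, study in enumerate(study_lists, start=1):
        raw = list(study)
        norm = {normalize_gene_id(g) for g in raw}
        n_changed = sum(1 for g in raw if g != normalize_gene_id(g))
        log.info("study %d: %d ids (%d unique after normalization, %d rewritten)",
                 i, len(raw), len(norm), n_changed)
        members |= norm
    if not members:
        raise ValueError("experimental union is empty; check the study lists")
    return ReferenceSet(name, frozenset(members))


@dataclass
class GeneScoreTable:
    """Per-gene phosphorylation prediction scores; -1 flags a missing score."""

    scores: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]

    def genes(self) -> list[str]:
        return sorted(self.scores)


def gene_scores_from_sites(sites: Iterable[SiteScoreRecord]) -> GeneScoreTable:
    """Collapse site scores to gene scores.

    protein score = max over the protein's site scores (missing -1 loses to
    any real score); gene score = max over the gene's isoform scores.  A gene
    whose every site is missing scores -1.  Duplicate (protein, residue,
    position) records keep the max score.
    """
    protein_best: dict[str, float] = {}
    for rec in sites:
        cur = protein_best.get(rec.protein_id, MISSING_SCORE)
        protein_best[rec.protein_id] = max(cur, rec.score)
    gene_best: dict[str, float] = {}
    for pid, score in protein_best.items():
        gene = normalize_gene_id(pid)
        gene_best[gene] = max(gene_best.get(gene, MISSING_SCORE), score)
    return GeneScoreTable(gene_best)


def read_site_scores(stream: IO[str] | Iterable[str]) -> list[SiteScoreRecord]:
    """Site-score TSV: header then protein_id, residue, position, score columns."""
    it = iter(stream)
    try:
        header = next(it)
    except StopIteration:
        raise ValueError("site-score table is empty") from None
    cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
    required = ["protein_id", "residue", "position", "score"]
    if not all(c in cols for c in required):
        raise ValueError(f"site-score header must contain {required}, got {cols}")
    idx = {c: cols.index(c) for c in required}
    records = []
    for raw in it:
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        records.append(SiteScoreRecord(
            protein_id=parts[idx["protein_id"]].strip(),
            residue=parts[idx["residue"]].strip().upper(),
            position=int(parts[idx["position"]]),
            score=float(parts[idx["score"]]),
        ))
    return records


def classify_genes(scores: GeneScoreTable, threshold: float,
                   name: str = "predicted") -> ReferenceSet:
    """Genes with score >= threshold; the -1 missing flag is never positive."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    members = {g for g, s in scores.scores.items()
               if s != MISSING_SCORE and s >= threshold}
    return ReferenceSet(name, frozenset(members))


def ensemble_or(a: ReferenceSet, b: ReferenceSet, name: str = "PredRS") -> ReferenceSet:
    """OR-ensemble: positive if either component predictor calls it positive."""
    return ReferenceSet(name, a.members | b.members)


def augment_reference(base: ReferenceSet, novel: ReferenceSet,
                      name: str | None = None) -> ReferenceSet:
    """Add a sample's novel phosphoproteins to a reference set.

    Logs how many ids were genuinely new (the paper-style "Un11RS" update of
    the union reference with phosphoproteins first seen in the sample).
    """
    new = novel.members - base.members
    log.info("augmenting %s (+%d genuinely new of %d offered)",
             base.name, len(new), len(novel))
    return ReferenceSet(name or f"{base.name}+{len(new)}", base.members | new)


def set_report(sets: list[ReferenceSet], genome: ReferenceSet) -> dict:
    """Sizes, pairwise overlaps/differences and genome percentages (one decimal).

    Phospho sets are expected to be contained in the genome; violations are
    listed in the report rather than silently dropped.
    """
    report: dict = {
        "genome": {"name": genome.name, "size": len(genome)},
        "sets": {},
        "pairwise": {},
        "containment_violations": {},
    }
    for s in sets:
        outside = sorted(s.members - genome.members)
        if outside:
            report["containment_violations"][s.name] = outside
        report["sets"][s.name] = {
            "size": len(s),
            "pct_of_genome": round(100.0 * len(s) / len(genome), 1),
        }
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            inter = a.members & b.members
            union = a.members | b.members
            key = f"{a.name}|{b.name}"
            report["pairwise"][key] = {
                "intersection": len(inter),
                "union": len(union),
                "only_" + a.name: len(a.members - b.members),
                "only_" + b.name: len(b.members - a.members),
                "union_pct_of_genome": round(100.0 * len(union) / len(genome), 1),
                "intersection_pct_of_" + a.name:
                    round(100.0 * len(inter) / len(a), 1) if len(a) else None,
                "intersection_pct_of_" + b.name:
                    round(100.0 * len(inter) / len(b), 1) if len(b) else None,
                "only_" + a.name + "_pct_of_" + a.name:
                    round(100.0 * len(a.members - b.members) / len(a), 1) if len(a) else None,
            }
    return report
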