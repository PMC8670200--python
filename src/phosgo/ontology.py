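"""Gene Ontology DAG: OBO parsing, ancestor queries, true-path-rule propagation.

The ontology is a directed acyclic graph whose nodes are GO terms and whose
edges point from a child term to its more general parents via ``is_a`` or
``part_of`` relations.  Under the true path rule a gene annotated to a term is
implicitly annotated to every ancestor of that term, so annotation maps are
propagated upward before any counting takes place.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx

log = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: relations kept as DAG edges; every other relationship is dropped on parse
EDGE_RELATIONS = ("is_a", "part_of")

#: default relations followed when propagating annotations / taking ancestors
DEFAULT_RELATIONS = frozenset(EDGE_RELATIONS)


class OboParseError(ValueError):
    """Malformed OBO input; message names the offending line."""


class OntologyError(ValueError):
    """Structural problem in the loaded ontology (cycle, dangling edge)."""


@dataclass
class GOTerm:
    """A single GO term.

    ``parents`` holds ``(parent_id, relation)`` pairs with relation in
    ``{"is_a", "part_of"}``.  Obsolete terms keep no parents.
    """

    id: str
    name: str = ""
    namespace: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)
    obsolete: bool = False


class OntologyDAG:
    """The GO term graph with per-namespace roots and alt_id resolution."""

    def __init__(self, terms: Mapping[str, GOTerm], alt_ids: Mapping[str, str] | None = None):
        self.terms: dict[str, GOTerm] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._graph = nx.DiGraph()  # edges child -> parent, attr "relation"
        for term in self.terms.values():
            self._graph.add_node(term.id)
            for pid, rel in term.parents:
                if pid not in self.terms:
                    raise OntologyError(
                        f"term {term.id} references unknown parent {pid}"
                    )
                # a child may reach the same parent by both relations; is_a wins
                # for traversal purposes only when the edge is duplicated
                if self._graph.has_edge(term.id, pid):
                    if rel == "is_a":
                        self._graph[term.id][pid]["relation"] = "is_a"
                else:
                    self._graph.add_edge(term.id, pid, relation=rel)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"ontology graph contains a cycle: {path}")
        self.roots: dict[str, str] = {}
        for term in self.terms.values():
            if term.obsolete or term.namespace not in NAMESPACES:
                continue
            same_ns = [p for p, _ in term.parents
                       if self.terms[p].namespace == term.namespace]
            if not same_ns:
                if term.namespace in self.roots:
                    log.warning("multiple roots in namespace %s: %s and %s",
                                term.namespace, self.roots[term.namespace], term.id)
                else:
                    self.roots[term.namespace] = term.id

    # -- lookup -----------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise KeyError(f"unknown GO term: {term_id}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __getitem__(self, term_id: str) -> GOTerm:
        return self.terms[self.resolve(term_id)]

    def __len__(self) -> int:
        return len(self.terms)

    def parents(self, term_id: str,
                relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        """Direct parents of a term reachable via the given relations."""
        tid = self.resolve(term_id)
        rels = set(relations)
        return {p for p, rel in self.terms[tid].parents if rel in rels}

    def ancestors(self, term_id: str,
                  relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        """All terms reachable upward from ``term_id``; excludes the term itself."""
        tid = self.resolve(term_id)
        rels = set(relations)
        out: set[str] = set()
        stack = [tid]
        while stack:
            node = stack.pop()
            for p, rel in self.terms[node].parents:
                if rel in rels and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def ancestor_closure(self,
                         relations: Iterable[str] = DEFAULT_RELATIONS
                         ) -> dict[str, set[str]]:
        """Ancestors for every non-obsolete term, computed in one topological pass."""
        rels = set(relations)
        closure: dict[str, set[str]] = {}
        # edges run child -> parent, so reverse the order: parents first
        for tid in reversed(list(nx.topological_sort(self._graph))):
            term = self.terms[tid]
            anc: set[str] = set()
            for p, rel in term.parents:
                if rel in rels:
                    anc.add(p)
                    anc |= closure[p]
            closure[tid] = anc
        return closure


def ancestors(dag: OntologyDAG, term: str,
              relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
    """Functional alias for :meth:`OntologyDAG.ancestors`."""
    return dag.ancestors(term, relations)


# -- OBO parsing ----------------------------------------------------------

def parse_obo(stream: IO[str] | Iterable[str]) -> OntologyDAG:
    """Parse OBO 1.2 text into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas are read.  ``is_a`` and ``relationship: part_of``
    lines become edges; all other relationships are dropped.  Obsolete terms
    are kept for lookup but carry no edges.  Unknown tags are ignored.
    """
    terms: dict[str, GOTerm] = {}
    alt_ids: dict[str, str] = {}
    cur: GOTerm | None = None
    cur_alt: list[str] = []
    in_term = False

    def commit() -> None:
        nonlocal cur, cur_alt
        if cur is not None:
            if cur.obsolete:
                cur.parents = []
            terms[cur.id] = cur
            for a in cur_alt:
                alt_ids[a] = cur.id
        cur, cur_alt = None, []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            commit()
            in_term = line == "[Term]"
            continue
        if not in_term:
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {raw.strip()!r}")
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            if cur is not None:
                raise OboParseError(f"line {lineno}: duplicate id tag in stanza")
            if not GO_ID_RE.match(value):
                raise OboParseError(f"line {lineno}: invalid GO accession {value!r}")
            cur = GOTerm(id=value)
            continue
        if cur is None:
            raise OboParseError(f"line {lineno}: tag {tag!r} before id in [Term] stanza")
        if tag == "name":
            cur.name = value
        elif tag == "namespace":
            cur.namespace = value
        elif tag == "is_a":
            parent = value.split()[0]
            if not GO_ID_RE.match(parent):
                raise OboParseError(f"line {lineno}: invalid is_a target {parent!r}")
            cur.parents.append((parent, "is_a"))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"line {lineno}: malformed relationship {value!r}")
            rel, parent = parts[0], parts[1]
            if rel == "part_of":
                if not GO_ID_RE.match(parent):
                    raise OboParseError(f"line {lineno}: invalid part_of target {parent!r}")
                cur.parents.append((parent, "part_of"))
            # regulates and friends: not traversed by the enrichment stack
        elif tag == "alt_id":
            cur_alt.append(value)
        elif tag == "is_obsolete":
            cur.obsolete = value.lower() == "true"
    commit()
    return OntologyDAG(terms, alt_ids)


def load_obo(path: str) -> OntologyDAG:
    with open(path, encoding="utf-8") as fh:
        return parse_obo(fh)


# -- annotation maps ------------------------------------------------------

@dataclass
class AnnotationMap:
    """Direct and true-path-propagated gene -> GO term annotations."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    dag: OntologyDAG

    def namespace_view(self, namespace: str) -> dict[str, set[str]]:
        """Propagated annotations restricted to one ontology namespace."""
        out: dict[str, set[str]] = {}
        for gene, term_ids in self.propagated.items():
            keep = {t for t in term_ids if self.dag.terms[t].namespace == namespace}
            if keep:
                out[gene] = keep
        return out


def propagate_annotations(dag: OntologyDAG,
                          direct: Mapping[str, Iterable[str]],
                          relations: Iterable[str] = DEFAULT_RELATIONS,
                          on_unknown: str = "warn") -> AnnotationMap:
    """Close a direct annotation map under ancestry (the true path rule).

    Annotations to unknown or obsolete terms are skipped with a warning by
    default; pass ``on_unknown="error"`` to raise instead.  alt_ids are
    resolved to their primary term.
    """
    if on_unknown not in ("warn", "error"):
        raise ValueError(f"on_unknown must be 'warn' or 'error', got {on_unknown!r}")
    closure = dag.ancestor_closure(relations)
    clean_direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    n_skipped = 0
    for gene, term_ids in direct.items():
        kept: set[str] = set()
        full: set[str] = set()
        for t in term_ids:
            try:
                tid = dag.resolve(t)
            except KeyError:
                if on_unknown == "error":
                    raise OntologyError(f"gene {gene} annotated to unknown term {t}")
                n_skipped += 1
                continue
            if dag.terms[tid].obsolete:
                n_skipped += 1
                continue
            kept.add(tid)
            full.add(tid)
            full |= closure[tid]
        if kept:
            clean_direct[gene] = kept
            propagated[gene] = full
    if n_skipped:
        log.warning("skipped %d annotations to unknown or obsolete terms", n_skipped)
    return AnnotationMap(direct=clean_direct, propagated=propagated, dag=dag)


# -- annotation file readers ----------------------------------------------

def read_gaf(stream: IO[str] | Iterable[str],
             evidence_keep: set[str] | None = None) -> dict[str, set[str]]:
    """Read a GAF 2.x file into a direct annotation map.

    Column 2 is the object id, column 5 the GO id, column 7 the evidence code.
    ``evidence_keep=None`` keeps every annotation, IEA included.
    """
    direct: dict[str, set[str]] = {}
    for raw in stream:
        if not raw.strip() or raw.startswith("!"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 7:
            continue
        gene, go_id, evidence = cols[1], cols[4], cols[6]
        if evidence_keep is not None and evidence not in evidence_keep:
            continue
        direct.setdefault(gene, set()).add(go_id)
    return direct


def read_annotation_tsv(stream: IO[str] | Iterable[str]) -> dict[str, set[str]]:
    """Read a 2-column ``gene<TAB>GO_id`` file; '#' lines are comments."""
    direct: dict[str, set[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise OboParseError(f"line {lineno}: expected gene<TAB>GO_id, got {line!r}")
        direct.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return direct
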