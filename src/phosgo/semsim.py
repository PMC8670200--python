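"""Wang graph-based semantic similarity and a deterministic 2-D layout.

Wang's measure encodes each term's semantics as S-values over its ancestor
closure: the term itself contributes 1 and each ancestor contributes the
maximum product of edge weights along any path from the term, with is_a
edges weighted 0.8 and part_of edges 0.6 by default.  The similarity of two
terms is the summed contribution of their shared ancestors normalized by
their total semantic values, so terms meeting deep in the DAG score higher
than terms meeting only near the root.

The 2-D layout is classical (Torgerson) metric MDS on the dissimilarity
1 - sim: distances between plotted terms approximate their semantic
dissimilarity, and node sizes carry GenRatio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyDAG

#: Wang's standard semantic-contribution weights per relation
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class SValueMap:
    """Semantic contributions of a focal term's ancestor closure (self included)."""

    term: str
    svalues: dict[str, float]

    @property
    def sv(self) -> float:
        """Total semantic value; >= 1 because the focal term contributes 1."""
        return sum(self.svalues.values())


def wang_svalues(dag: OntologyDAG, term: str,
                 weights: Mapping[str, float] | None = None) -> SValueMap:
    """S-values of ``term``'s ancestor closure.

    S(term) = 1; for an ancestor t, S(t) is the maximum over edges c -> t
    inside the closure of w(relation) * S(c).
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    for rel, val in w.items():
        if not 0.0 < val < 1.0:
            raise ValueError(f"weight for {rel} must be in (0,1), got {val}")
    tid = dag.resolve(term)
    closure = {tid} | dag.ancestors(tid, relations=w.keys())
    # process children before parents: order by closure-internal topology
    s: dict[str, float] = {tid: 1.0}
    # iterate to fixed point; the closure is small, and max-product over a DAG
    # converges in at most depth iterations
    changed = True
    while changed:
        changed = False
        for node in closure:
            if node == tid:
                continue
            best = 0.0
            for child in closure:
                for pid, rel in dag.terms[child].parents:
                    if pid == node and rel in w and child in s:
                        cand = w[rel] * s[child]
                        if cand > best:
                            best = cand
            if best > 0.0 and s.get(node, 0.0) != best:
                s[node] = best
                changed = True
    return SValueMap(term=tid, svalues=s)


def wang_similarity(a: SValueMap, b: SValueMap) -> float:
    """Wang similarity: shared-ancestor contributions over total semantic value."""
    common = a.svalues.keys() & b.svalues.keys()
    if not common:
        return 0.0
    num = sum(a.svalues[t] + b.svalues[t] for t in common)
    return num / (a.sv + b.sv)


def similarity_matrix(dag: OntologyDAG, terms: Sequence[str],
                      weights: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Symmetric pairwise Wang similarity over terms of a single namespace."""
    ids = [dag.resolve(t) for t in terms]
    namespaces = {dag.terms[t].namespace for t in ids}
    if len(namespaces) > 1:
        raise ValueError(f"terms mix namespaces: {sorted(namespaces)}")
    maps = {t: wang_svalues(dag, t, weights) for t in dict.fromkeys(ids)}
    n = len(ids)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = wang_similarity(maps[ids[i]], maps[ids[j]])
    return pd.DataFrame(sim, index=ids, columns=ids)


@dataclass
class Embedding2D:
    """Deterministic 2-D coordinates whose distances approximate dissimilarity."""

    coords: pd.DataFrame  # index: term ids; columns x, y
    stress: float  # Kruskal stress-1
    eigenvalues: np.ndarray
    node_sizes: dict[str, float] | None = None


def mds_embedding(sim: pd.DataFrame,
                  node_sizes: Mapping[str, float] | None = None) -> Embedding2D:
    """Classical (Torgerson) metric MDS of d = 1 - sim into two dimensions.

    Double-centers the squared dissimilarities, takes the top-2 eigenpairs,
    and scales coordinates by the square root of the eigenvalues; axes with
    non-positive eigenvalues are zeroed with a warning via the returned
    eigenvalues.  Each axis is oriented so its largest-|coordinate| term is
    positive, making the layout reproducible bit-for-bit.
    """
    if sim.shape[0] < 2:
        raise ValueError("need at least two terms to embed")
    d = 1.0 - sim.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2.0  # symmetrize against round-off
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, 2))
    for axis in range(2):
        if axis < len(eigval) and eigval[axis] > 1e-12:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
    # sign convention: the largest-magnitude coordinate on each axis is positive
    for axis in range(2):
        col = coords[:, axis]
        if col.any():
            if col[np.argmax(np.abs(col))] < 0:
                coords[:, axis] = -col
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (emb ** 2).sum()
    stress = float(np.sqrt(((d - emb) ** 2).sum() / denom)) if denom > 0 else 0.0
    frame = pd.DataFrame(coords, index=sim.index, columns=["x", "y"])
    sizes = {t: float(node_sizes[t]) for t in sim.index} if node_sizes else None
    return Embedding2D(coords=frame, stress=stress, eigenvalues=eigval[:2],
                       node_sizes=sizes)


def export_dot(dag: OntologyDAG, terms: Iterable[str],
               highlight: Iterable[str] | None = None) -> str:
    """DOT text of the ancestor closure of the given terms.

    Solid edges are is_a, dashed are part_of; highlighted terms are filled.
    """
    focal = {dag.resolve(t) for t in terms}
    nodes = set(focal)
    for t in focal:
        nodes |= dag.ancestors(t)
    marked = {dag.resolve(t) for t in (highlight or focal)}
    lines = ["digraph GO {", "  rankdir=BT;",
             '  node [shape=box, fontsize=10];']
    for t in sorted(nodes):
        name = dag.terms[t].name.replace('"', r"\"")
        style = ', style=filled, fillcolor="lightgrey"' if t in marked else ""
        lines.append(f'  "{t}" [label="{t}\\n{name}"{style}];')
    for t in sorted(nodes):
        for pid, rel in dag.terms[t].parents:
            if pid in nodes:
                style = "solid" if rel == "is_a" else "dashed"
                lines.append(f'  "{t}" -> "{pid}" [style={style}, label="{rel}"];')
    lines.append("}")
    return "\n".join(lines)
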