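"""Wang graph-based term semantic similarity and set-level aggregation.

A term's semantic profile is the set of S-values of its ancestors: S of the
term itself is 1, and S decays multiplicatively along each edge toward the
root with a relation-specific weight (0.8 for is_a, 0.6 for part_of by
default), keeping the maximum over paths.  Two terms are compared by the
overlap of their S-value tables; genes and gene sets are compared by
best-match averaging (BMA) of the underlying term similarities.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, TermGraph, ValidationError

W_IS_A = 0.8
W_PART_OF = 0.6


def _ancestor_closure(t: str, graph: TermGraph) -> list[str]:
    """Terms reachable upward from t, in topological order (children first)."""
    closure: set[str] = set()
    stack = [t]
    while stack:
        u = stack.pop()
        if u in closure:
            continue
        closure.add(u)
        for parent, _ in graph.parents.get(u, ()):
            stack.append(parent)
    # topological order within the closure (Kahn on child -> parent edges):
    # remaining[u] = number of closure children pointing at u
    remaining = {u: 0 for u in closure}
    for c in closure:
        for p, _ in graph.parents[c]:
            remaining[p] += 1
    out: list[str] = []
    ready = [u for u, r in remaining.items() if r == 0]
    while ready:
        u = ready.pop()
        out.append(u)
        for parent, _ in graph.parents[u]:
            remaining[parent] -= 1
            if remaining[parent] == 0:
                ready.append(parent)
    return out


def s_values(
    t: str, graph: TermGraph, w_is_a: float = W_IS_A, w_part_of: float = W_PART_OF
) -> dict[str, float]:
    """S-value table of term ``t``: contribution of each ancestor to its semantics.

    S(t) = 1; S(ancestor) is the maximum over downward paths of the product
    of edge weights times the child's S-value.
    """
    if t not in graph.terms:
        raise ValidationError(f"term {t!r} is not in the graph")
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    S: dict[str, float] = {t: 1.0}
    for u in _ancestor_closure(t, graph):
        su = S.get(u)
        if su is None:
            continue
        for parent, rel in graph.parents[u]:
            cand = weights[rel] * su
            if cand > S.get(parent, 0.0):
                S[parent] = cand
    return S


def term_similarity(
    t1: str,
    t2: str,
    graph: TermGraph,
    w_is_a: float = W_IS_A,
    w_part_of: float = W_PART_OF,
) -> float:
    """Wang similarity: shared S-value mass over total S-value mass."""
    s1 = s_values(t1, graph, w_is_a, w_part_of)
    s2 = s_values(t2, graph, w_is_a, w_part_of)
    shared = set(s1) & set(s2)
    if not shared:
        return 0.0
    num = sum(s1[a] + s2[a] for a in shared)
    return num / (sum(s1.values()) + sum(s2.values()))


def _bma(matrix: np.ndarray) -> float:
    """Best-match average of a similarity matrix (rows vs columns)."""
    n, m = matrix.shape
    return float((matrix.max(axis=1).sum() + matrix.max(axis=0).sum()) / (n + m))


def termset_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    graph: TermGraph,
    cache: dict | None = None,
    **weights,
) -> float:
    ta = sorted(set(terms_a))
    tb = sorted(set(terms_b))
    if not ta or not tb:
        raise ValidationError("both term sets must be non-empty")
    mat = np.empty((len(ta), len(tb)))
    for i, u in enumerate(ta):
        for j, v in enumerate(tb):
            if cache is not None:
                key = (u, v) if u <= v else (v, u)
                if key not in cache:
                    cache[key] = term_similarity(u, v, graph, **weights)
                mat[i, j] = cache[key]
            else:
                mat[i, j] = term_similarity(u, v, graph, **weights)
    return _bma(mat)


def set_similarity(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    graph: TermGraph,
    cache: dict | None = None,
    **weights,
) -> float:
    """Similarity of two gene sets by two-level best-match averaging.

    Gene-gene similarity is the BMA over the genes' annotated term pairs;
    set-set similarity is the BMA over annotated gene pairs.  Genes without
    annotations are skipped; if either side has none annotated an error is
    raised.
    """
    ann_a = [sorted(graph.annotations[g]) for g in sorted(set(genes_a)) if graph.annotations.get(g)]
    ann_b = [sorted(graph.annotations[g]) for g in sorted(set(genes_b)) if graph.annotations.get(g)]
    if not ann_a or not ann_b:
        raise ValidationError("no annotated genes on one side of the comparison")
    cache = {} if cache is None else cache
    gene_mat = np.empty((len(ann_a), len(ann_b)))
    for i, ta in enumerate(ann_a):
        for j, tb in enumerate(ann_b):
            gene_mat[i, j] = termset_similarity(ta, tb, graph, cache=cache, **weights)
    return _bma(gene_mat)


class WangSimilarity:
    """Pathway-pair similarity provider backed by the Wang/BMA method.

    A pathway's terms are those annotated to its genes; an explicit
    ``pathway_terms`` mapping overrides that default.  Pairwise pathway
    similarity is the BMA over the two term sets.  Results and term-pair
    similarities are cached, so repeated queries are cheap.
    """

    def __init__(
        self,
        graph: TermGraph,
        collection: GeneSetCollection | None = None,
        pathway_terms: dict[str, set[str]] | None = None,
        w_is_a: float = W_IS_A,
        w_part_of: float = W_PART_OF,
    ) -> None:
        if collection is None and pathway_terms is None:
            raise ValidationError("need a gene-set collection or an explicit pathway->terms map")
        self.graph = graph
        self.collection = collection
        self.pathway_terms = pathway_terms or {}
        self.weights = {"w_is_a": w_is_a, "w_part_of": w_part_of}
        self._term_cache: dict[tuple[str, str], float] = {}
        self._pair_cache: dict[tuple[str, str], float] = {}

    def terms_of(self, pathway: str) -> set[str]:
        if pathway in self.pathway_terms:
            return set(self.pathway_terms[pathway])
        if self.collection is None or pathway not in self.collection:
            raise ValidationError(f"no terms available for pathway {pathway!r}")
        return self.graph.terms_for_genes(self.collection[pathway])

    def __call__(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._pair_cache:
            ta = self.terms_of(a)
            tb = self.terms_of(b)
            if not ta or not tb:
                raise ValidationError(f"pathway pair ({a}, {b}) has no annotated terms")
            self._pair_cache[key] = termset_similarity(
                ta, tb, self.graph, cache=self._term_cache, **self.weights
            )
        return self._pair_cache[key]

    def matrix(self, pathways: Iterable[str]) -> pd.DataFrame:
        ids = list(pathways)
        out = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
        for i, a in enumerate(ids):
            for b in ids[i:]:
                val = self(a, b)
                out.loc[a, b] = val
                out.loc[b, a] = val
        return out
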