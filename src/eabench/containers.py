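"""Domain containers shared across the benchmark framework.

All gene, pathway, sample and ontology-term identifiers are opaque strings;
no identifier mapping is performed anywhere in the package (inputs are
assumed pre-mapped to a common gene vocabulary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file could not be parsed into a domain object."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


@dataclass
class GeneSetCollection:
    """A named collection of pathway gene sets.

    Parameters
    ----------
    sets
        Mapping pathway-id -> set of gene-ids.  Every set must be non-empty.
    names
        Mapping pathway-id -> human-readable display name.
    """

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {pid: frozenset(genes) for pid, genes in self.sets.items()}
        for pid, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")
        for pid in self.sets:
            self.names.setdefault(pid, pid)
        self._universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()

    @property
    def universe(self) -> frozenset[str]:
        """All gene-ids appearing in any set."""
        return self._universe

    @property
    def ids(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def filtered(self, min_size: int) -> "GeneSetCollection":
        """Return a copy keeping only sets with at least ``min_size`` genes."""
        kept = {p: s for p, s in self.sets.items() if len(s) >= min_size}
        return GeneSetCollection(kept, {p: self.names[p] for p in kept})


class FunctionalNetwork:
    """Undirected, weighted gene association network.

    Stores an adjacency index for fast neighbourhood queries.  Each unordered
    pair is stored once; self-loops are rejected.  Edge weights are
    dimensionless confidence scores.
    """

    __slots__ = ("_adj", "_weights")

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()) -> None:
        self._adj: dict[str, set[str]] = {}
        self._weights: dict[tuple[str, str], float] = {}
        for u, v, w in edges:
            self.add_edge(u, v, w)

    @staticmethod
    def _key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if u <= v else (v, u)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r} is not allowed")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)
        self._weights[self._key(u, v)] = float(weight)

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def neighbors(self, gene: str) -> set[str]:
        return self._adj.get(gene, set())

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, ()))

    @property
    def degrees(self) -> dict[str, int]:
        return {g: len(nbrs) for g, nbrs in self._adj.items()}

    def has_edge(self, u: str, v: str) -> bool:
        return self._key(u, v) in self._weights

    def edge_weight(self, u: str, v: str) -> float:
        return self._weights[self._key(u, v)]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for (u, v), w in self._weights.items():
            yield u, v, w

    def number_of_edges(self) -> int:
        return len(self._weights)

    def number_of_nodes(self) -> int:
        return len(self._adj)

    def total_degree(self, genes: Iterable[str]) -> int:
        """Sum of network degrees over ``genes`` (absent genes count 0)."""
        return sum(len(self._adj.get(g, ())) for g in genes)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_weighted_edges_from(self.edges())
        return g

    def copy(self) -> "FunctionalNetwork":
        out = FunctionalNetwork()
        out._adj = {g: set(n) for g, n in self._adj.items()}
        out._weights = dict(self._weights)
        return out


VALID_CONDITIONS = ("case", "control")
VALID_PLATFORMS = ("microarray", "rnaseq")


@dataclass
class ExpressionDataset:
    """A case/control expression matrix (log2 intensity or log2 CPM)."""

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # genes x samples
    condition: dict[str, str]  # sample-id -> "case" | "control"
    platform: str = "microarray"
    target_pathway: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.platform not in VALID_PLATFORMS:
            raise ValidationError(f"{self.dataset_id}: unknown platform {self.platform!r}")
        for s in self.samples:
            if s not in self.condition:
                raise ValidationError(f"{self.dataset_id}: sample {s!r} missing from design")
            if self.condition[s] not in VALID_CONDITIONS:
                raise ValidationError(
                    f"{self.dataset_id}: unknown condition {self.condition[s]!r} for sample {s!r}"
                )
        labels = {self.condition[s] for s in self.samples}
        if set(VALID_CONDITIONS) - labels:
            raise ValidationError(f"{self.dataset_id}: both case and control samples are required")

    def sample_indices(self, condition: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.condition[s] == condition], dtype=int
        )

    @property
    def n_case(self) -> int:
        return int(len(self.sample_indices("case")))

    @property
    def n_control(self) -> int:
        return int(len(self.sample_indices("control")))

    def with_labels(self, genes: list[str], dataset_id: str | None = None) -> "ExpressionDataset":
        """Copy of this dataset with its gene labels replaced (values untouched)."""
        if len(genes) != len(self.genes):
            raise ValidationError("replacement label list has wrong length")
        return ExpressionDataset(
            dataset_id=dataset_id or self.dataset_id,
            genes=list(genes),
            samples=list(self.samples),
            values=self.values.copy(),
            condition=dict(self.condition),
            platform=self.platform,
            target_pathway=self.target_pathway,
        )


@dataclass
class TermGraph:
    """Ontology term DAG plus gene->term annotations.

    ``parents`` maps a term to its (parent, relation) pairs; relations are
    ``is_a`` or ``part_of``.  The parent graph must be acyclic.
    """

    parents: dict[str, set[tuple[str, str]]]
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        terms = set(self.parents)
        for child, rels in self.parents.items():
            for parent, rel in rels:
                terms.add(parent)
                if rel not in ("is_a", "part_of"):
                    raise ValidationError(f"unknown relation {rel!r} on edge {child}->{parent}")
        self.terms: set[str] = terms
        for t in terms:
            self.parents.setdefault(t, set())
        self._check_acyclic()
        for gene, anns in self.annotations.items():
            missing = anns - self.terms
            if missing:
                raise ValidationError(f"gene {gene!r} annotated to unknown terms {sorted(missing)}")

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on child -> parent edges.
        out_deg = {t: len(self.parents[t]) for t in self.terms}
        children: dict[str, list[str]] = {t: [] for t in self.terms}
        for child, rels in self.parents.items():
            for parent, _ in rels:
                children[parent].append(child)
        stack = [t for t, d in out_deg.items() if d == 0]
        seen = 0
        while stack:
            t = stack.pop()
            seen += 1
            for c in children[t]:
                out_deg[c] -= 1
                if out_deg[c] == 0:
                    stack.append(c)
        if seen != len(self.terms):
            raise ValidationError("term graph contains a cycle")

    def terms_for_genes(self, genes: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for g in genes:
            out |= self.annotations.get(g, set())
        return out


@dataclass
class EnrichmentResultMatrix:
    """Per-method matrix of enrichment p-values (pathways x datasets).

    Untested entries carry p = 1 and ``tested`` False, following the
    convention that a missing test counts as a non-detection.
    """

    method: str
    pvalues: pd.DataFrame
    tested: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.pvalues = self.pvalues.astype(float)
        vals = self.pvalues.to_numpy()
        if np.isnan(vals).any():
            raise ValidationError(f"{self.method}: p-value matrix contains missing entries")
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError(f"{self.method}: p-values outside [0, 1]")
        if self.tested is None:
            self.tested = pd.DataFrame(
                True, index=self.pvalues.index, columns=self.pvalues.columns
            )
        if not self.tested.index.equals(self.pvalues.index) or not self.tested.columns.equals(
            self.pvalues.columns
        ):
            raise ValidationError(f"{self.method}: tested-flag matrix is misaligned")

    @property
    def pathways(self) -> list[str]:
        return list(self.pvalues.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.pvalues.columns)


def pvalue_frame(
    pathways: Iterable[str], datasets: Iterable[str], fill: float = 1.0
) -> pd.DataFrame:
    """Convenience constructor for an all-``fill`` pathway x dataset frame."""
    return pd.DataFrame(fill, index=list(pathways), columns=list(datasets), dtype=float)


def as_mapping(obj: Mapping | pd.Series) -> dict:
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return dict(obj)
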