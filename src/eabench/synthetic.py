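"""Synthetic data generation for the whole benchmark pipeline.

Everything the framework consumes can be generated here with a fixed seed:
a heavy-tailed functional association network (configuration model),
pathway collections with planted related pairs (shared genes plus extra
cross-links), case/control expression datasets with planted differential
expression in a target pathway, and layered term DAGs with gene
annotations for the semantic-similarity weighting.

The generator emulates the benchmark's study conditions: pathways of 15+
genes on a network whose degree distribution is heavy-tailed (so the
degree-aware null has real work to do), case/control designs with 3+
samples per condition, Gaussian log-scale expression noise, and DEG
signal concentrated in the target pathway with a small background rate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .containers import (
    ExpressionDataset,
    FunctionalNetwork,
    GeneSetCollection,
    TermGraph,
    ValidationError,
)

_SALT_NETWORK = 0x11
_SALT_PATHWAYS = 0x22
_SALT_EXPRESSION = 0x33
_SALT_TERMS = 0x44


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults describe a small but structurally realistic instance: a
    2000-gene network with mean degree 10 and a heavy-tailed degree
    distribution, 20 pathways of 15-80 genes of which 3 pairs are related
    (half their genes shared, plus extra cross-links), and 3-vs-3
    case/control datasets with a 2-sigma expression shift on 80% of the
    target pathway's genes and a 1% background rate.
    """

    seed: int = 0
    # network
    n_genes: int = 2000
    mean_degree: float = 10.0
    heavy_tail: bool = True
    tail_exponent: float = 2.5  # power-law exponent of the degree sequence
    # pathway layout
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 80)
    n_related_pairs: int = 3
    overlap_fraction: float = 0.5
    cross_links: int = 150  # extra links wired between each related pair
    intralink_boost: int = 0  # extra internal links added to every pathway
    # expression
    samples_per_condition: int = 3
    effect_size: float = 2.0
    noise_sd: float = 1.0
    frac_de_target: float = 0.8
    frac_de_background: float = 0.01
    # term graph
    n_terms: int = 30
    n_term_layers: int = 4
    annotation_fraction: float = 0.9
    terms_per_gene: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.n_genes < 10 or self.n_pathways < 1:
            raise ValidationError("counts must be positive and non-trivial")
        if not (0 <= self.overlap_fraction < 1):
            raise ValidationError("overlap_fraction must lie in [0, 1)")
        if self.pathway_size_range[0] > self.pathway_size_range[1]:
            raise ValidationError("invalid pathway size range")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def gene_label(i: int) -> str:
    return f"g{i:05d}"


def _degree_sequence(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_genes
    if spec.heavy_tail:
        # discrete power law, rescaled to the requested mean degree
        raw = rng.zipf(spec.tail_exponent, size=n).astype(float)
        raw = np.minimum(raw, n / 4)
        seq = np.maximum(1, np.round(raw * spec.mean_degree / raw.mean())).astype(int)
    else:
        seq = np.maximum(1, rng.poisson(spec.mean_degree, size=n)).astype(int)
    seq = np.minimum(seq, n - 1)
    if seq.sum() % 2:
        seq[int(rng.integers(n))] += 1
    return seq


def make_network(spec: SyntheticSpec) -> FunctionalNetwork:
    """Configuration-model network on a heavy-tailed degree sequence.

    Self-loops and parallel edges of the stub-matching draw are discarded,
    so realized degrees sit slightly below the requested sequence.  Edge
    confidence scores are uniform on [0.5, 1].  Deterministic under the
    spec seed.
    """
    rng = spec.rng(_SALT_NETWORK)
    seq = _degree_sequence(spec, rng)  # config model tolerates any even-sum sequence
    g = nx.configuration_model(seq.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    net = FunctionalNetwork()
    for u, v in g.edges():
        net.add_edge(gene_label(u), gene_label(v), float(rng.uniform(0.5, 1.0)))
    return net


def plant_pathways(
    net: FunctionalNetwork, spec: SyntheticSpec
) -> tuple[GeneSetCollection, list[tuple[str, str]]]:
    """Sample a pathway collection and plant related pairs into the network.

    Related pairs share ``overlap_fraction`` of their genes and receive
    ``cross_links`` extra links wired between them; ``intralink_boost``
    extra internal links per pathway turn pathways into communities (used
    by the bias diagnostics).  The network is mutated in place.  Returns
    the collection and the ground-truth related pairs.
    """
    rng = spec.rng(_SALT_PATHWAYS)
    nodes = np.array(sorted(net.nodes), dtype=object)
    lo, hi = spec.pathway_size_range
    if hi > len(nodes):
        raise ValidationError("pathway sizes exceed the number of network genes")
    if 2 * spec.n_related_pairs > spec.n_pathways:
        raise ValidationError("more related pairs than pathway slots")
    ids = [f"P{i:03d}" for i in range(spec.n_pathways)]
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    sets: dict[str, frozenset[str]] = {}
    for pid, size in zip(ids, sizes):
        sets[pid] = frozenset(rng.choice(nodes, size=int(size), replace=False).tolist())
    truth: list[tuple[str, str]] = []
    for pair_idx in range(spec.n_related_pairs):
        pa, pb = ids[2 * pair_idx], ids[2 * pair_idx + 1]
        a = sorted(sets[pa])
        b = list(sorted(sets[pb]))
        n_share = int(round(spec.overlap_fraction * min(len(a), len(b))))
        if n_share > len(b):
            raise ValidationError("overlap demand exceeds pathway size")
        shared = rng.choice(np.array(a, dtype=object), size=n_share, replace=False).tolist()
        keep = [g for g in b if g not in shared]
        sets[pb] = frozenset((keep[: len(b) - n_share] + shared))
        # extra cross-links between the exclusive parts of the pair
        only_a = np.array(sorted(set(a) - set(shared)), dtype=object)
        only_b = np.array(sorted(set(sets[pb]) - set(shared)), dtype=object)
        for _ in range(spec.cross_links):
            u = str(rng.choice(only_a))
            v = str(rng.choice(only_b))
            if u != v:
                net.add_edge(u, v, 1.0)
        truth.append((pa, pb))
    if spec.intralink_boost:
        for pid in ids:
            members = np.array(sorted(sets[pid]), dtype=object)
            for _ in range(spec.intralink_boost):
                u, v = rng.choice(members, size=2, replace=False)
                net.add_edge(str(u), str(v), 1.0)
    collection = GeneSetCollection(sets, {pid: f"synthetic pathway {pid}" for pid in ids})
    return collection, truth


def make_expression(
    spec: SyntheticSpec,
    target: str,
    collection: GeneSetCollection,
    dataset_id: str | None = None,
    genes: list[str] | None = None,
    platform: str = "microarray",
) -> ExpressionDataset:
    """Case/control expression with planted DE in the target pathway.

    Gaussian log-scale noise; ``frac_de_target`` of the target pathway's
    genes and ``frac_de_background`` of the remaining genes get an
    ``effect_size`` mean shift in the case samples.  Deterministic under
    the spec seed (vary the seed, or the dataset_id salt, for replicates).
    """
    if target not in collection:
        raise ValidationError(f"target {target!r} not in the collection")
    dataset_id = dataset_id or f"synth_{target}"
    id_salt = zlib.crc32(dataset_id.encode()) & 0x7FFFFFFF  # stable across processes
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, _SALT_EXPRESSION, id_salt])
    )
    if genes is None:
        genes = [gene_label(i) for i in range(spec.n_genes)]
    s = spec.samples_per_condition
    samples = [f"case{i}" for i in range(s)] + [f"ctrl{i}" for i in range(s)]
    condition = {x: ("case" if x.startswith("case") else "control") for x in samples}
    values = rng.normal(0.0, spec.noise_sd, size=(len(genes), 2 * s)) + 8.0
    gene_index = {g: i for i, g in enumerate(genes)}
    target_genes = [g for g in sorted(collection[target]) if g in gene_index]
    n_de = int(round(spec.frac_de_target * len(target_genes)))
    de_genes = set(
        rng.choice(np.array(target_genes, dtype=object), size=n_de, replace=False).tolist()
    )
    background = [g for g in genes if g not in collection[target]]
    n_bg = int(round(spec.frac_de_background * len(background)))
    if n_bg:
        de_genes |= set(
            rng.choice(np.array(background, dtype=object), size=n_bg, replace=False).tolist()
        )
    rows = [gene_index[g] for g in sorted(de_genes)]
    signs = rng.choice([-1.0, 1.0], size=len(rows))
    values[rows, :s] += spec.effect_size * signs[:, None]
    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=list(genes),
        samples=samples,
        values=values,
        condition=condition,
        platform=platform,
        target_pathway=target,
    )


def make_term_graph(spec: SyntheticSpec, genes: list[str] | None = None) -> TermGraph:
    """Layered random DAG with is_a/part_of edges and random gene annotations.

    Terms are arranged in layers under a single root; each term gets one or
    two parents from the layer above, which makes the graph acyclic by
    construction.  ``annotation_fraction`` of the gene pool is annotated
    with 1-3 leaf-ward terms.
    """
    rng = spec.rng(_SALT_TERMS)
    if genes is None:
        genes = [gene_label(i) for i in range(spec.n_genes)]
    terms = [f"T{i:03d}" for i in range(spec.n_terms)]
    n_layers = max(2, spec.n_term_layers)
    # root is layer 0; later layers grow geometrically
    layer_of = {terms[0]: 0}
    remaining = terms[1:]
    cuts = np.linspace(0, len(remaining), n_layers)[1:].astype(int)
    start = 0
    layers: list[list[str]] = [[terms[0]]]
    for layer_idx, end in enumerate(cuts, start=1):
        layer = remaining[start:end]
        if not layer:
            continue
        layers.append(layer)
        for t in layer:
            layer_of[t] = layer_idx
        start = end
    parents: dict[str, set[tuple[str, str]]] = {t: set() for t in terms if t in layer_of}
    for layer_idx in range(1, len(layers)):
        above = layers[layer_idx - 1]
        for t in layers[layer_idx]:
            n_par = int(rng.integers(1, min(2, len(above)) + 1))
            chosen = rng.choice(np.array(above, dtype=object), size=n_par, replace=False)
            for p in chosen:
                rel = "is_a" if rng.random() < 0.7 else "part_of"
                parents[t].add((str(p), rel))
    n_annotated = int(round(spec.annotation_fraction * len(genes)))
    annotated = rng.choice(np.array(genes, dtype=object), size=n_annotated, replace=False)
    lo, hi = spec.terms_per_gene
    deep_terms = np.array([t for layer in layers[1:] for t in layer] or terms, dtype=object)
    annotations: dict[str, set[str]] = {}
    for g in annotated:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(deep_terms))
        annotations[str(g)] = set(rng.choice(deep_terms, size=k, replace=False).tolist())
    return TermGraph(parents, annotations)


def make_study(
    spec: SyntheticSpec, n_datasets_per_target: int = 1, targets: list[str] | None = None
):
    """Convenience bundle: network, collection, truth, datasets, term graph."""
    net = make_network(spec)
    collection, truth = plant_pathways(net, spec)
    if targets is None:
        targets = [a for a, _ in truth] or collection.ids[:1]
    datasets = []
    for target in targets:
        for rep in range(n_datasets_per_target):
            datasets.append(
                make_expression(spec, target, collection, dataset_id=f"{target}_d{rep}")
            )
    graph = make_term_graph(spec)
    return net, collection, truth, datasets, graph
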