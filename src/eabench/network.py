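"""Disease pathway network construction.

Two pathways are linked when both their gene overlap and their connectivity
in a functional association network are significant against a degree-aware
subsampling null.  Connectivity between pathways A and B is the
inter-pathway connectivity

    IPC(A, B) = DL(A, B) + SN(A, B),

the number of direct links between the two gene sets plus the number of
outside genes connected to both.  Overlap is the Jaccard index
|A n B| / |A u B|.  Each statistic is tested in both directions (A fixed,
B replaced by a degree-matched random set, and vice versa), the directional
empirical p-values are combined with Fisher's method, and edges passing a
BH-FDR gate on both statistics are weighted by semantic similarity and
pruned to each target's top-k neighbours.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FunctionalNetwork, GeneSetCollection, ValidationError
from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 100
DEFAULT_N_SAMPLES = 1000
DEFAULT_ALPHA = 0.05
DEFAULT_TOP_K = 20


def direct_links(A: Iterable[str], B: Iterable[str], net: FunctionalNetwork) -> int:
    """Number of network edges with one endpoint in A and the other in B.

    An edge between two genes that both lie in A n B is counted once.
    """
    A = set(A)
    B = set(B)
    # sum over B of neighbours in A counts edges inside A n B twice
    count = sum(len(net.neighbors(b) & A) for b in B)
    both = A & B
    internal_twice = sum(len(net.neighbors(g) & both) for g in both)
    return count - internal_twice // 2


def shared_neighbors(A: Iterable[str], B: Iterable[str], net: FunctionalNetwork) -> int:
    """Number of genes outside A u B connected to at least one gene in each."""
    A = set(A)
    B = set(B)
    nbrs_a: set[str] = set()
    for a in A:
        nbrs_a |= net.neighbors(a)
    nbrs_b: set[str] = set()
    for b in B:
        nbrs_b |= net.neighbors(b)
    return len((nbrs_a & nbrs_b) - (A | B))


def ipc(A: Iterable[str], B: Iterable[str], net: FunctionalNetwork) -> int:
    """Inter-pathway connectivity: direct links plus shared neighbours."""
    A = set(A)
    B = set(B)
    return direct_links(A, B, net) + shared_neighbors(A, B, net)


def jaccard(A: Iterable[str], B: Iterable[str]) -> float:
    A = set(A)
    B = set(B)
    union = A | B
    if not union:
        raise ValidationError("Jaccard index of two empty sets is undefined")
    return len(A & B) / len(union)


@dataclass
class DegreeBins:
    """Genes sorted by network degree and grouped into contiguous bins.

    All bins except possibly the last have exactly ``bin_size`` members.
    Genes absent from the network sit in the lowest bins with degree 0.
    """

    order: list[str]
    bin_of: dict[str, int]
    members: list[np.ndarray]

    @property
    def n_bins(self) -> int:
        return len(self.members)


def make_degree_bins(
    net: FunctionalNetwork, universe: Iterable[str], bin_size: int = DEFAULT_BIN_SIZE
) -> DegreeBins:
    """Sort ``universe`` by network degree and cut into bins of ``bin_size``.

    Degree ties are ordered by gene-id so the binning is deterministic.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty sampling universe")
    if bin_size < 1:
        raise ValidationError("bin_size must be positive")
    order = sorted(universe, key=lambda g: (net.degree(g), g))
    bin_of: dict[str, int] = {}
    members: list[np.ndarray] = []
    for start in range(0, len(order), bin_size):
        chunk = order[start : start + bin_size]
        idx = len(members)
        members.append(np.array(chunk, dtype=object))
        for g in chunk:
            bin_of[g] = idx
    return DegreeBins(order, bin_of, members)


def sample_matched(
    B: Iterable[str], bins: DegreeBins, rng: np.random.Generator
) -> set[str]:
    """Draw a degree-matched random replacement for gene set B.

    Each gene is replaced by a uniform draw from its degree bin, with no
    duplicates in the sampled set.  If a bin cannot supply enough distinct
    genes it is widened to adjacent bins with a warning.
    """
    need: dict[int, int] = {}
    for g in B:
        if g not in bins.bin_of:
            raise ValidationError(f"gene {g!r} is not in the sampling universe")
        need[bins.bin_of[g]] = need.get(bins.bin_of[g], 0) + 1
    out: list[str] = []
    for idx in sorted(need):
        k = need[idx]
        pool = bins.members[idx]
        if k <= len(pool):
            take = rng.choice(pool, size=k, replace=False)
        else:
            lo, hi = idx, idx
            widened = [pool]
            total = len(pool)
            while total < k and (lo > 0 or hi < bins.n_bins - 1):
                if lo > 0:
                    lo -= 1
                    widened.append(bins.members[lo])
                    total += len(bins.members[lo])
                if total < k and hi < bins.n_bins - 1:
                    hi += 1
                    widened.append(bins.members[hi])
                    total += len(bins.members[hi])
            logger.warning(
                "degree bin %d exhausted (need %d of %d); widened to bins %d-%d",
                idx, k, len(pool), lo, hi,
            )
            merged = np.concatenate(widened)
            if k > len(merged):
                raise ValidationError("sampling universe too small for the requested set")
            take = rng.choice(merged, size=k, replace=False)
        out.extend(take.tolist())
    return set(out)


_STATS: dict[str, Callable] = {
    "ipc": lambda A, B, net: ipc(A, B, net),
    "jaccard": lambda A, B, net: jaccard(A, B),
}


def subsample_pvalue(
    A: Iterable[str],
    B: Iterable[str],
    stat: str,
    net: FunctionalNetwork,
    bins: DegreeBins,
    n: int = DEFAULT_N_SAMPLES,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided degree-aware subsampling p-value for ``stat`` in {ipc, jaccard}.

    A stays fixed; B is replaced by ``n`` degree-matched random draws.  The
    empirical p-value uses the (r + 1) / (n + 1) pseudocount so it never
    reaches zero (Fisher combination downstream requires p > 0).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if stat not in _STATS:
        raise ValidationError(f"unknown statistic {stat!r}")
    rng = np.random.default_rng() if rng is None else rng
    A = set(A)
    B = set(B)
    fn = _STATS[stat]
    observed = fn(A, B, net)
    r = 0
    for _ in range(n):
        sampled = sample_matched(B, bins, rng)
        if fn(A, sampled, net) >= observed:
            r += 1
    return (r + 1) / (n + 1)


def combine_fisher(p1: float, p2: float) -> float:
    """Fisher's method for two p-values: chi-square(4) upper tail."""
    if p1 <= 0 or p2 <= 0 or p1 > 1 or p2 > 1:
        raise ValidationError("p-values must lie in (0, 1]")
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(sps.chi2.sf(x, df=4))


def _pair_rng(seed: int, a: str, b: str) -> np.random.Generator:
    """Deterministic per-pair generator, independent of iteration order."""
    digest = hashlib.sha256(f"{a}\t{b}".encode()).digest()
    child = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, child]))


def _draw_null_sets(
    B: set[str], bins: DegreeBins, n: int, rng: np.random.Generator
) -> list[set[str]]:
    """n degree-matched replacements for B, drawn bin-wise without replacement.

    Vectorized equivalent of n :func:`sample_matched` calls: within each
    degree bin the k replacement genes form a uniform k-subset of the bin.
    Falls back to the scalar sampler when a bin must be widened.
    """
    need: dict[int, int] = {}
    for g in B:
        if g not in bins.bin_of:
            raise ValidationError(f"gene {g!r} is not in the sampling universe")
        need[bins.bin_of[g]] = need.get(bins.bin_of[g], 0) + 1
    if any(k > len(bins.members[idx]) for idx, k in need.items()):
        return [sample_matched(B, bins, rng) for _ in range(n)]
    parts = []
    for idx in sorted(need):
        k = need[idx]
        pool = bins.members[idx]
        # row-wise top-k of uniform noise = uniform k-subset without replacement
        noise = rng.random((n, len(pool)))
        sel = np.argpartition(noise, k - 1, axis=1)[:, :k]
        parts.append(pool[sel])
    stacked = np.concatenate(parts, axis=1)
    return [set(row.tolist()) for row in stacked]


def _directional(
    A: set[str],
    B: set[str],
    net: FunctionalNetwork,
    bins: DegreeBins,
    n: int,
    rng: np.random.Generator,
    obs_ipc: int,
    obs_j: float,
) -> tuple[float, float]:
    """Empirical p-values for IPC and Jaccard sharing the same null draws.

    A stays fixed, so its neighbourhood union and per-gene link counts into
    A are cached across draws.
    """
    draws = _draw_null_sets(B, bins, n, rng)
    nbrs_a: set[str] = set()
    for a in A:
        nbrs_a |= net.neighbors(a)
    links_to_a: dict[str, int] = {}
    len_a = len(A)
    ge_ipc = 0
    ge_j = 0
    for sampled in draws:
        dl = 0
        both: set[str] = set()
        for g in sampled:
            la = links_to_a.get(g)
            if la is None:
                la = len(net.neighbors(g) & A)
                links_to_a[g] = la
            dl += la
            if g in A:
                both.add(g)
        if both:
            dl -= sum(len(net.neighbors(g) & both) for g in both) // 2
        nbrs_b: set[str] = set()
        for g in sampled:
            nbrs_b |= net.neighbors(g)
        sn = len((nbrs_a & nbrs_b) - A - sampled)
        if dl + sn >= obs_ipc:
            ge_ipc += 1
        inter = len(both)
        if inter / (len_a + len(sampled) - inter) >= obs_j:
            ge_j += 1
    return (ge_ipc + 1) / (n + 1), (ge_j + 1) / (n + 1)


def pairwise_stats(
    collection: GeneSetCollection,
    net: FunctionalNetwork,
    bin_size: int = DEFAULT_BIN_SIZE,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    universe: Iterable[str] | None = None,
    joint_fdr: bool = False,
) -> pd.DataFrame:
    """Connectivity and overlap statistics for every unordered pathway pair.

    Returns one row per pair with columns ``pathway_a, pathway_b, DL, SN,
    IPC, J, p_conn_ab, p_conn_ba, p_conn, p_olap_ab, p_olap_ba, p_olap,
    q_conn, q_olap``.  Both subsampling directions are run; directional
    p-values are Fisher-combined; BH adjustment is applied per statistic
    family across all pairs (or jointly with ``joint_fdr=True``).

    Per-pair child seeds are derived from ``seed`` and the pair identifiers,
    so results do not depend on iteration order.
    """
    sample_universe = set(universe) if universe is not None else set(collection.universe)
    bins = make_degree_bins(net, sample_universe, bin_size)
    ids = collection.ids
    rows = []
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            pa, pb = sorted((id_a, id_b))  # canonical pair orientation
            A = set(collection[pa])
            B = set(collection[pb])
            dl = direct_links(A, B, net)
            sn = shared_neighbors(A, B, net)
            j = jaccard(A, B)
            # one child stream per direction, keyed on the oriented pair
            p_conn_ab, p_olap_ab = _directional(
                A, B, net, bins, n_samples, _pair_rng(seed, pa, pb), dl + sn, j
            )
            p_conn_ba, p_olap_ba = _directional(
                B, A, net, bins, n_samples, _pair_rng(seed, pb, pa), dl + sn, j
            )
            rows.append(
                {
                    "pathway_a": pa,
                    "pathway_b": pb,
                    "DL": dl,
                    "SN": sn,
                    "IPC": dl + sn,
                    "J": j,
                    "p_conn_ab": p_conn_ab,
                    "p_conn_ba": p_conn_ba,
                    "p_conn": combine_fisher(p_conn_ab, p_conn_ba),
                    "p_olap_ab": p_olap_ab,
                    "p_olap_ba": p_olap_ba,
                    "p_olap": combine_fisher(p_olap_ab, p_olap_ba),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        for col in ("q_conn", "q_olap"):
            table[col] = []
        return table
    if joint_fdr:
        joint = bh_fdr(np.concatenate([table["p_conn"], table["p_olap"]]))
        table["q_conn"] = joint[: len(table)]
        table["q_olap"] = joint[len(table) :]
    else:
        table["q_conn"] = bh_fdr(table["p_conn"].to_numpy())
        table["q_olap"] = bh_fdr(table["p_olap"].to_numpy())
    return table


@dataclass
class DiseasePathwayNetwork:
    """FDR-gated, similarity-weighted pathway graph with top-k neighbour lists."""

    nodes: set[str]
    edges: dict[tuple[str, str], float]  # sorted pair -> semantic similarity weight
    targets: list[str]
    related: dict[str, list[str]]  # target -> up to k neighbours, best first

    def weight(self, a: str, b: str) -> float:
        return self.edges[(a, b) if a <= b else (b, a)]

    def positives_for(self, target: str) -> list[str]:
        """Target plus its related pathways (the positive set for a dataset)."""
        if target not in self.related:
            raise ValidationError(f"unknown target pathway {target!r}")
        return [target] + self.related[target]


SimilarityProvider = Callable[[str, str], float]


def _resolve_similarity(
    similarity: SimilarityProvider | pd.DataFrame | Mapping,
) -> SimilarityProvider:
    if callable(similarity):
        return similarity
    if isinstance(similarity, pd.DataFrame):
        frame = similarity

        def lookup(a: str, b: str) -> float:
            if a not in frame.index or b not in frame.columns:
                raise ValidationError(f"similarity matrix is missing the pair ({a}, {b})")
            return float(frame.loc[a, b])

        return lookup
    mapping = dict(similarity)

    def lookup_map(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in mapping:
            raise ValidationError(f"similarity provider is missing the pair ({a}, {b})")
        return float(mapping[key])

    return lookup_map


def assemble(
    table: pd.DataFrame,
    targets: Sequence[str],
    similarity: SimilarityProvider | pd.DataFrame | Mapping,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_TOP_K,
) -> DiseasePathwayNetwork:
    """Assemble the disease pathway network from pairwise statistics.

    Edges require ``q_conn < alpha`` and ``q_olap < alpha``; accepted edges
    are weighted by semantic similarity; each target's related list keeps
    its ``k`` highest-weight neighbours (ties broken by smaller ``q_conn``,
    then pathway-id).
    """
    known = set(table["pathway_a"]) | set(table["pathway_b"]) if len(table) else set()
    for t in targets:
        if t not in known:
            raise ValidationError(f"target {t!r} does not appear in the pairwise table")
    sim = _resolve_similarity(similarity)
    accepted = table[(table["q_conn"] < alpha) & (table["q_olap"] < alpha)]
    edges: dict[tuple[str, str], float] = {}
    neighbors: dict[str, list[tuple[float, float, str]]] = {t: [] for t in targets}
    for row in accepted.itertuples(index=False):
        a, b = row.pathway_a, row.pathway_b
        w = float(sim(a, b))
        edges[(a, b) if a <= b else (b, a)] = w
        if a in neighbors:
            neighbors[a].append((w, row.q_conn, b))
        if b in neighbors:
            neighbors[b].append((w, row.q_conn, a))
    related = {}
    for t in targets:
        ranked = sorted(neighbors[t], key=lambda x: (-x[0], x[1], x[2]))
        related[t] = [pid for _, _, pid in ranked[:k]]
    nodes = set(targets)
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
    return DiseasePathwayNetwork(nodes, edges, list(targets), related)
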