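"""In-repo enrichment analysis methods and conventions for external results.

Implemented here: Fisher's exact overlap test, its conservative EASE
variant (overlap reduced by one), a hypergeometric network-crosstalk test
and a misspecified binomial variant of it, and a calibrated permutation
reference whose null p-values are uniform by construction.  Externally
computed methods enter as p-value matrices through
:func:`eabench.io.read_pvalue_matrix`.

Conventions: a depleted gene set reports 1 - p as its enrichment
significance, and any missing test carries p = 1.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    EnrichmentResultMatrix,
    ExpressionDataset,
    FunctionalNetwork,
    GeneSetCollection,
    ValidationError,
)
from .diffexpr import DEGSet, QCFailure, moderated_t, quantile_normalize, select_degs
from .network import direct_links

logger = logging.getLogger(__name__)

BUILTIN_METHODS = ("fisher", "ease", "crosstalk", "crosstalk_binomial", "permref")


def _overlap_table(degs: Iterable[str], pathway: Iterable[str], universe: Iterable[str]):
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    degs = set(degs) & universe
    pathway = set(pathway) & universe
    if not pathway:
        raise ValidationError("pathway has no genes in the universe")
    return len(degs & pathway), len(universe), len(pathway), len(degs)


def fisher_enrichment(
    degs: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided Fisher's exact test for DEG over-representation in a pathway.

    Equivalent to the upper hypergeometric tail P(X >= overlap) with the
    pathway as successes and the DEG list as draws.
    """
    k, M, K, N = _overlap_table(degs, pathway, universe)
    return float(sps.hypergeom.sf(k - 1, M, K, N))


def ease_enrichment(
    degs: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> float:
    """EASE score: Fisher's exact test with the overlap reduced by one.

    The reduction is floored at zero, so an overlap of 0 or 1 gives p = 1.
    Always at least as conservative as :func:`fisher_enrichment`.
    """
    k, M, K, N = _overlap_table(degs, pathway, universe)
    return float(sps.hypergeom.sf(max(k - 1, 0) - 1, M, K, N))


def crosstalk_hypergeom(
    degs: Iterable[str], pathway: Iterable[str], net: FunctionalNetwork
) -> tuple[float, bool]:
    """Network crosstalk against a hypergeometric null on edge endpoints.

    The observed statistic is the number of direct links between the DEG
    set and the pathway.  The null treats the 2m edge endpoints of the
    network as a population, the pathway's total degree as successes and
    the DEG set's total degree as draws.  Returns the upper-tail p-value
    and a depleted flag set when the null expectation exceeds the
    observation.  If either side carries zero total degree the test is
    undefined and (1.0, False) is returned.
    """
    degs = set(degs)
    pathway = set(pathway)
    d_degs = net.total_degree(degs)
    d_path = net.total_degree(pathway)
    two_m = 2 * net.number_of_edges()
    if d_degs == 0 or d_path == 0 or two_m == 0:
        return 1.0, False
    observed = direct_links(degs, pathway, net)
    expected = d_degs * d_path / two_m
    draws = min(d_degs, two_m)
    succ = min(d_path, two_m)
    p = float(sps.hypergeom.sf(observed - 1, two_m, succ, draws))
    return p, expected > observed


def crosstalk_binomial(
    degs: Iterable[str], pathway: Iterable[str], net: FunctionalNetwork
) -> tuple[float, bool]:
    """Crosstalk against a binomial null with a network-wide link probability.

    Deliberately ignores pathway-specific structure: the success
    probability is the pathway's share of edge endpoints, applied
    independently to every DEG endpoint.  Community-like pathways violate
    this independence, which inflates false positives for them - the bias
    mode this package's diagnostics are designed to expose.
    """
    degs = set(degs)
    pathway = set(pathway)
    d_degs = net.total_degree(degs)
    d_path = net.total_degree(pathway)
    two_m = 2 * net.number_of_edges()
    if d_degs == 0 or d_path == 0 or two_m == 0:
        return 1.0, False
    observed = direct_links(degs, pathway, net)
    prob = d_path / two_m
    expected = d_degs * prob
    p = float(sps.binom.sf(observed - 1, d_degs, prob))
    return p, expected > observed


def to_enrichment(p: float, depleted: bool) -> float:
    """Convert a depletion-aware p-value to an enrichment significance.

    Depletion is not scored as enrichment: a depleted set reports 1 - p.
    """
    if not (0 <= p <= 1):
        raise ValidationError("p must lie in [0, 1]")
    return 1.0 - p if depleted else p


def permutation_reference(
    degs: Iterable[str],
    pathway: Iterable[str],
    universe: Iterable[str],
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Calibrated reference method: overlap against uniform DEG-label draws.

    The observed DEG/pathway overlap is compared with ``n`` uniform random
    gene sets of the same size drawn from the universe; the empirical
    p-value uses the (r + 1) / (n + 1) pseudocount.  Under random DEG
    labels its p-values are uniform on the (n + 1) grid by construction.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    universe_arr = np.array(sorted(set(universe)), dtype=object)
    degs = set(degs) & set(universe_arr.tolist())
    pathway = set(pathway)
    observed = len(degs & pathway)
    member = np.array([g in pathway for g in universe_arr])
    k = len(degs)
    r = 0
    for _ in range(n):
        idx = rng.choice(len(universe_arr), size=k, replace=False)
        if int(member[idx].sum()) >= observed:
            r += 1
    return (r + 1) / (n + 1)


def overlap_enrichment_profile(
    degs: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    ease: bool = False,
) -> dict[str, float]:
    """Fisher (or EASE) enrichment of one DEG set against every pathway.

    Vectorized equivalent of calling :func:`fisher_enrichment` /
    :func:`ease_enrichment` per pathway; used for large null batteries.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    degs = set(degs) & universe
    m = len(universe)
    n_degs = len(degs)
    ids = collection.ids
    k_path = np.array([len(set(collection[pid]) & universe) for pid in ids])
    if (k_path == 0).any():
        bad = ids[int(np.argmax(k_path == 0))]
        raise ValidationError(f"pathway {bad!r} has no genes in the universe")
    overlap = np.array([len(set(collection[pid]) & degs) for pid in ids])
    if ease:
        overlap = np.maximum(overlap - 1, 0)
    p = sps.hypergeom.sf(overlap - 1, m, k_path, n_degs)
    return {pid: float(pi) for pid, pi in zip(ids, p)}


def permutation_reference_battery(
    degs: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    n: int = 1000,
    rng: np.random.Generator | None = None,
    chunk: int = 256,
) -> dict[str, float]:
    """Vectorized permutation reference over every pathway of a collection.

    Shares the same ``n`` random DEG-label draws across pathways, which
    matches running :func:`permutation_reference` per pathway on a common
    permutation stream while being fast enough for large null batteries.
    """
    rng = np.random.default_rng() if rng is None else rng
    universe_list = sorted(set(universe))
    index = {g: i for i, g in enumerate(universe_list)}
    m = len(universe_list)
    degs = [g for g in set(degs) if g in index]
    k = len(degs)
    ids = collection.ids
    membership = np.zeros((len(ids), m), dtype=np.int32)
    for row, pid in enumerate(ids):
        for g in collection[pid]:
            if g in index:
                membership[row, index[g]] = 1
    deg_vec = np.zeros(m, dtype=np.int32)
    for g in degs:
        deg_vec[index[g]] = 1
    observed = membership @ deg_vec
    ge = np.zeros(len(ids), dtype=int)
    done = 0
    while done < n:
        b = min(chunk, n - done)
        # top-k indices of uniform noise give k-subsets without replacement
        noise = rng.random((b, m))
        idx = np.argpartition(noise, k - 1, axis=1)[:, :k] if k > 0 else np.empty((b, 0), int)
        draw = np.zeros((b, m), dtype=np.int32)
        rows = np.repeat(np.arange(b), k)
        draw[rows, idx.ravel()] = 1
        null_overlap = draw @ membership.T  # b x pathways
        ge += (null_overlap >= observed[None, :]).sum(axis=0)
        done += b
    return {pid: (ge[i] + 1) / (n + 1) for i, pid in enumerate(ids)}


def derive_degs(dataset: ExpressionDataset, **deg_kwargs) -> DEGSet | QCFailure:
    """Normalize (microarray only), run the moderated t-test, select DEGs."""
    ds = dataset
    if dataset.platform == "microarray":
        ds = ExpressionDataset(
            dataset.dataset_id,
            dataset.genes,
            dataset.samples,
            quantile_normalize(dataset.values),
            dataset.condition,
            dataset.platform,
            dataset.target_pathway,
        )
    stats_list = moderated_t(ds)
    return select_degs(stats_list, **deg_kwargs)


def _resolve_universe(
    mode: str,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    net: FunctionalNetwork | None,
) -> set[str]:
    if mode == "dataset":
        return set(dataset.genes) & set(collection.universe)
    if mode == "collection":
        return set(collection.universe)
    if mode == "network":
        if net is None:
            raise ValidationError("universe mode 'network' requires a network")
        return net.nodes
    raise ValidationError(f"unknown universe mode {mode!r}")


def run_battery(
    methods: Sequence[str],
    datasets: Sequence[ExpressionDataset],
    collection: GeneSetCollection,
    net: FunctionalNetwork | None = None,
    universe_mode: str = "dataset",
    n_perm: int = 1000,
    seed: int = 0,
    deg_kwargs: dict | None = None,
) -> dict[str, EnrichmentResultMatrix]:
    """Run the built-in methods on every dataset against every pathway.

    A method failing on a dataset (or a dataset failing DEG-based QC)
    leaves that column untested with p = 1; the run continues.
    """
    unknown = [m for m in methods if m not in BUILTIN_METHODS]
    if unknown:
        raise ValidationError(f"unknown methods {unknown}; available: {BUILTIN_METHODS}")
    needs_net = {"crosstalk", "crosstalk_binomial"} & set(methods)
    if needs_net and net is None:
        raise ValidationError(f"methods {sorted(needs_net)} require a functional network")
    deg_kwargs = deg_kwargs or {}
    ids = collection.ids
    columns = [d.dataset_id for d in datasets]
    pvals = {m: pd.DataFrame(1.0, index=ids, columns=columns) for m in methods}
    tested = {m: pd.DataFrame(False, index=ids, columns=columns) for m in methods}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0BA77E]))

    for dataset in datasets:
        col = dataset.dataset_id
        try:
            deg_result = derive_degs(dataset, **deg_kwargs)
        except Exception:  # pragma: no cover - defensive
            logger.exception("DEG derivation failed for %s; column left untested", col)
            continue
        if isinstance(deg_result, QCFailure):
            logger.warning("%s failed QC (%s); column left untested", col, deg_result.reason)
            continue
        degs = set(deg_result.genes)
        universe = _resolve_universe(universe_mode, dataset, collection, net)
        for m in methods:
            try:
                if m == "permref":
                    ps = permutation_reference_battery(
                        degs, collection, universe, n=n_perm, rng=rng
                    )
                    for pid, p in ps.items():
                        pvals[m].loc[pid, col] = p
                        tested[m].loc[pid, col] = True
                    continue
                for pid in ids:
                    pathway = set(collection[pid])
                    if m == "fisher":
                        p = fisher_enrichment(degs, pathway, universe)
                    elif m == "ease":
                        p = ease_enrichment(degs, pathway, universe)
                    elif m == "crosstalk":
                        p = to_enrichment(*crosstalk_hypergeom(degs, pathway, net))
                    else:  # crosstalk_binomial
                        p = to_enrichment(*crosstalk_binomial(degs, pathway, net))
                    pvals[m].loc[pid, col] = p
                    tested[m].loc[pid, col] = True
            except Exception:
                logger.exception("method %s failed on %s; column left untested", m, col)
                pvals[m][col] = 1.0
                tested[m][col] = False
    return {m: EnrichmentResultMatrix(m, pvals[m], tested[m]) for m in methods}
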