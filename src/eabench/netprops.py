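"""Pathway-level network properties and their correlation with false positives.

Crosstalk-based enrichment tests that assume network-wide randomness are
biased for pathways that behave like communities (many internal links,
hubs).  These diagnostics quantify that: per-pathway structural metrics on
the functional network, correlated against per-pathway false positive
rates from a null battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FunctionalNetwork, GeneSetCollection, ValidationError

DEFAULT_HUB_FRACTION = 0.2


def hubs(net: FunctionalNetwork, fraction: float = DEFAULT_HUB_FRACTION) -> set[str]:
    """The ceil(fraction * n) highest-degree nodes of the network.

    Degree ties at the boundary are broken by gene-id (lexicographically
    smaller ids included first) so the hub set is deterministic.
    """
    if not (0 < fraction < 1):
        raise ValidationError("hub fraction must lie in (0, 1)")
    nodes = sorted(net.nodes, key=lambda g: (-net.degree(g), g))
    n_hubs = math.ceil(fraction * len(nodes))
    return set(nodes[:n_hubs])


@dataclass(frozen=True)
class PathwayProperties:
    size: int
    n_components: int
    mean_clustering: float
    median_degree: float
    max_degree: int
    frac_intralinks: float
    frac_hubs: float
    density_hubs: float
    density_links: float


def pathway_properties(
    pathway: Iterable[str],
    net: FunctionalNetwork,
    hub_set: set[str],
    graph: nx.Graph | None = None,
) -> PathwayProperties:
    """Structural metrics of one pathway on the functional network.

    * frac_intralinks: internal links over all links incident to pathway
      genes (an internal edge counts once in both numerator and
      denominator); 0 when the pathway has no incident links.
    * density_links: internal links over the n(n-1)/2 possible pairs of
      pathway genes.
    * frac_hubs: pathway hubs over all network hubs; density_hubs: pathway
      hubs over pathway size.
    * degree/clustering/component metrics are computed on the full network
      (clustering) and the induced subgraph (components); pathway genes
      absent from the network carry degree 0.
    """
    pathway = set(pathway)
    if not pathway:
        raise ValidationError("empty pathway")
    present = pathway & net.nodes
    intralinks = sum(len(net.neighbors(g) & present) for g in present) // 2
    incident = net.total_degree(present) - intralinks
    degrees = [net.degree(g) for g in pathway]
    n = len(pathway)
    if present:
        g = net.to_networkx() if graph is None else graph
        sub = g.subgraph(present)
        n_components = nx.number_connected_components(sub)
        mean_clustering = float(np.mean(list(nx.clustering(g, present).values())))
    else:
        n_components = 0
        mean_clustering = 0.0
    n_hub_overlap = len(pathway & hub_set)
    return PathwayProperties(
        size=n,
        n_components=n_components,
        mean_clustering=mean_clustering,
        median_degree=float(np.median(degrees)),
        max_degree=int(max(degrees)),
        frac_intralinks=intralinks / incident if incident else 0.0,
        frac_hubs=n_hub_overlap / len(hub_set) if hub_set else 0.0,
        density_hubs=n_hub_overlap / n,
        density_links=intralinks / (n * (n - 1) / 2) if n > 1 else 0.0,
    )


def properties_table(
    collection: GeneSetCollection,
    net: FunctionalNetwork,
    hub_fraction: float = DEFAULT_HUB_FRACTION,
) -> pd.DataFrame:
    """Property table over every pathway of a collection (rows = pathways)."""
    hub_set = hubs(net, hub_fraction)
    graph = net.to_networkx()
    rows = {
        pid: asdict(pathway_properties(collection[pid], net, hub_set, graph))
        for pid in collection.ids
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def fpr_property_correlation(
    props: pd.DataFrame, fpr: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    """Tie-corrected Spearman correlation of each property with per-pathway FPR.

    Constant properties have an undefined coefficient and are reported as
    missing (NaN).
    """
    fpr = pd.Series(dict(fpr) if not isinstance(fpr, pd.Series) else fpr)
    common = [p for p in props.index if p in fpr.index]
    if len(common) < 3:
        raise ValidationError("need at least 3 pathways for a correlation")
    y = fpr.loc[common].to_numpy(dtype=float)
    rows = []
    for prop in props.columns:
        x = props.loc[common, prop].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"property": prop, "spearman_rho": np.nan, "p_value": np.nan})
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append({"property": prop, "spearman_rho": float(rho), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("property")
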