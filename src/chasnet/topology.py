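"""Centralities, communities, bridgeness and feature-enrichment statistics.

Betweenness centrality counts all-pairs shortest paths through a node.
Non-overlapping chromatin communities come from greedy modularity
optimisation; overlapping communities from clique percolation (k = 3), with
nodes outside any percolating community kept as singleton modules so the
cover is total.  A node's bridgeness is the number of communities it belongs
to.  Feature enrichment in top-scoring nodes or within a module is a
ratio-of-means statistic with a resampling (add-one empirical p) null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .network import ContactNetwork, largest_component
from .nulls import _replicate_rng

log = logging.getLogger(__name__)


@dataclass
class CommunityAssignment:
    """Node-to-modules cover, overlapping or not.

    ``modules`` maps module id -> node set; ``membership`` maps node ->
    set of module ids.  In non-overlapping mode every node sits in exactly
    one module; in overlapping mode in at least one.
    """

    modules: dict[int, set[str]]
    method: str
    membership: dict[str, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            for mod, members in self.modules.items():
                for node in members:
                    self.membership.setdefault(node, set()).add(mod)

    @property
    def overlapping(self) -> bool:
        return any(len(mods) > 1 for mods in self.membership.values())

    def bridgeness(self, node: str) -> int:
        return len(self.membership[node])

    def bridgeness_series(self) -> pd.Series:
        return pd.Series(
            {n: len(mods) for n, mods in self.membership.items()},
            name="bridgeness",
        ).sort_index()

    def partition_labels(self) -> pd.Series:
        """Node -> module id for a non-overlapping assignment."""
        if self.overlapping:
            raise ValueError("assignment is overlapping; no unique partition")
        return pd.Series(
            {n: next(iter(mods)) for n, mods in self.membership.items()},
            name="module",
        ).sort_index()

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"fragment_id": n, "module": m, "bridgeness": len(mods)}
            for n, mods in sorted(self.membership.items())
            for m in sorted(mods)
        ]
        return pd.DataFrame(rows, columns=["fragment_id", "module", "bridgeness"])


def _sorted_modules(communities: Sequence[set[str]]) -> dict[int, set[str]]:
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {i: set(c) for i, c in enumerate(ordered)}


def betweenness(net: ContactNetwork, lcc_only: bool = True) -> pd.Series:
    """Exact unnormalized shortest-path betweenness.

    Computed on the largest connected component by default (the component
    the community analyses run on); set ``lcc_only=False`` for the whole
    network.
    """
    target = largest_component(net) if lcc_only else net
    bc = nx.betweenness_centrality(target.graph, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


def communities_greedy(net: ContactNetwork) -> CommunityAssignment:
    """Non-overlapping modules by greedy modularity maximisation (CNM).

    Runs per connected component implicitly; deterministic for a given
    network (nodes and edges are fed in sorted order).
    """
    g = nx.Graph()
    g.add_nodes_from(net.fragment_ids)
    g.add_edges_from(net.edges())
    if g.number_of_edges() == 0:
        comms = [{n} for n in g.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    return CommunityAssignment(
        modules=_sorted_modules(comms), method="greedy_modularity"
    )


def communities_overlapping(net: ContactNetwork, k: int = 3) -> CommunityAssignment:
    """Overlapping modules by clique percolation; singleton fill-in.

    k-clique percolation (default k = 3, i.e. triangle percolation) yields
    overlapping communities; a node shared between two dense modules belongs
    to both, so bridgeness = number of communities containing the node.
    Nodes in no percolating community become singleton modules so that the
    cover spans all nodes.
    """
    g = nx.Graph()
    g.add_nodes_from(net.fragment_ids)
    g.add_edges_from(net.edges())
    comms = [set(c) for c in nx.community.k_clique_communities(g, k)]
    covered = set().union(*comms) if comms else set()
    comms.extend({n} for n in g.nodes if n not in covered)
    return CommunityAssignment(
        modules=_sorted_modules(comms),
        method=f"clique_percolation(k={k})+singletons",
    )


def top_node_enrichment(
    matrix: FeatureMatrix,
    scores: pd.Series,
    top_n: int = 500,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature enrichment in the top-N nodes of a score ranking.

    enrichment = mean feature value over the top_n nodes by score, divided
    by the mean over all scored nodes (NaN when the global mean is zero).
    The empirical p (greater, add-one) comes from ``n_reps`` random node
    subsets of size top_n.  Ties at the boundary break by fragment_id.
    """
    nodes = scores.index.to_list()
    if top_n > len(nodes):
        raise ValueError(f"top_n={top_n} exceeds {len(nodes)} scored nodes")
    missing = set(nodes) - set(matrix.index)
    if missing:
        raise KeyError(f"scored nodes missing from matrix: {sorted(missing)[:5]}")
    order = sorted(nodes, key=lambda n: (-scores[n], n))
    top = order[:top_n]
    sub = matrix.loc[nodes]
    global_mean = sub.mean(axis=0)
    top_mean = matrix.loc[top].mean(axis=0)

    vals = sub.to_numpy(dtype=float)
    n_nodes = len(nodes)
    null_means = np.empty((n_reps, vals.shape[1]))
    for r in range(n_reps):
        rng = _replicate_rng(seed, r)
        idx = rng.choice(n_nodes, size=top_n, replace=False)
        null_means[r] = vals[idx].mean(axis=0)

    rows = []
    for j, feat in enumerate(matrix.columns):
        if global_mean[feat] == 0:
            enr = float("nan")
        else:
            enr = float(top_mean[feat] / global_mean[feat])
        k = int(np.sum(null_means[:, j] >= top_mean[feat]))
        rows.append(
            {
                "feature": feat,
                "top_mean": float(top_mean[feat]),
                "global_mean": float(global_mean[feat]),
                "enrichment": enr,
                "p": (k + 1) / (n_reps + 1),
            }
        )
    return pd.DataFrame(rows)


def date_party_scores(
    enrich_bridge: pd.DataFrame,
    enrich_between: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Date/party quadrant labels from two enrichment tables.

    Date features sit in high-bridgeness nodes (one community at a time,
    many communities overall); party features sit in high-betweenness,
    single-community nodes.  A feature is labeled ``date`` when its
    bridgeness enrichment exceeds ``threshold``, ``party`` when only its
    betweenness enrichment does, ``neutral`` when neither does, and
    ``undefined`` when either enrichment is NaN.
    """
    b = enrich_bridge.set_index("feature")["enrichment"]
    c = enrich_between.set_index("feature")["enrichment"]
    if set(b.index) != set(c.index):
        raise ValueError("enrichment tables cover different feature sets")
    rows = []
    for feat in b.index:
        eb, ec = float(b[feat]), float(c[feat])
        if np.isnan(eb) or np.isnan(ec):
            label = "undefined"
        elif eb > threshold:
            label = "date"
        elif ec > threshold:
            label = "party"
        else:
            label = "neutral"
        rows.append(
            {
                "feature": feat,
                "bridgeness_enrichment": eb,
                "betweenness_enrichment": ec,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def module_feature_enrichment(
    communities: CommunityAssignment,
    matrix: FeatureMatrix,
    n_reps: int = 1000,
    seed: int = 0,
    min_size: int = 1,
) -> pd.DataFrame:
    """Module-by-feature matrix of empirical enrichment p values.

    For each (module, feature): observed = mean feature value in the module;
    null = means over ``n_reps`` random node sets of the same size drawn
    from the covered nodes; p = add-one empirical p (greater).  Modules
    smaller than ``min_size`` are skipped.
    """
    universe = sorted(communities.membership)
    missing = set(universe) - set(matrix.index)
    if missing:
        raise KeyError(f"community nodes missing from matrix: {sorted(missing)[:5]}")
    vals = matrix.loc[universe].to_numpy(dtype=float)
    pos = {n: i for i, n in enumerate(universe)}
    out = {}
    for mod, members in sorted(communities.modules.items()):
        if len(members) < min_size:
            continue
        idx = np.array([pos[n] for n in members], dtype=np.int64)
        observed = vals[idx].mean(axis=0)
        null_means = np.empty((n_reps, vals.shape[1]))
        for r in range(n_reps):
            rng = _replicate_rng(seed, (mod + 1) * 1_000_003 + r)
            pick = rng.choice(len(universe), size=len(members), replace=False)
            null_means[r] = vals[pick].mean(axis=0)
        k = np.sum(null_means >= observed[None, :], axis=0)
        out[mod] = (k + 1) / (n_reps + 1)
    table = pd.DataFrame.from_dict(out, orient="index", columns=matrix.columns)
    table.index.name = "module"
    return table
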