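"""Substructure-similarity network: filtering, communities, edge significance.

The network keeps compound pairs whose Tanimoto similarity clears a
threshold (default 0.3). Communities are found with the Walktrap
random-walk agglomerative method, cutting the dendrogram at maximum
modularity. Within each community an edge is flagged significant when
its similarity sits at least ``z_threshold`` sample standard deviations
above the community's mean edge similarity; the threshold is one-sided
because chemical significance here means unusually HIGH overlap.
Inter-community edges stay in the graph but are never significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .fingerprints import canonical_pair

DEFAULT_MIN_SIMILARITY = 0.3
DEFAULT_Z_THRESHOLD = 1.0
DEFAULT_WALK_LENGTH = 4


@dataclass(frozen=True)
class SimilarityEdge:
    pair: tuple[str, str]
    score: float
    community_id: int | None = None
    zscore: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class Community:
    """A Walktrap community with its intra-edge similarity statistics.

    ``threshold`` = edge_mean + z_threshold * edge_sd is the similarity
    an intra-community edge must reach to be flagged significant.
    """

    community_id: int
    members: frozenset[str]
    edge_mean: float | None = None
    edge_sd: float | None = None
    threshold: float | None = None


@dataclass
class SimilarityNetwork:
    nodes: list[str]
    edges: dict[tuple[str, str], SimilarityEdge]
    communities: dict[int, Community] = field(default_factory=dict)
    node_attrs: dict[str, dict] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @property
    def membership(self) -> dict[str, int]:
        """compound_id -> community_id for all assigned nodes."""
        out: dict[str, int] = {}
        for com in self.communities.values():
            for m in com.members:
                out[m] = com.community_id
        return out

    def degree(self, node: str) -> int:
        return sum(1 for p in self.edges if node in p)


def build_network(
    similarities: dict[tuple[str, str], float],
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
    nodes: list[str] | None = None,
    node_attrs: dict[str, dict] | None = None,
) -> SimilarityNetwork:
    """Filter a pairwise score table into a similarity network.

    Edges are exactly the pairs with score >= ``min_similarity``. All
    compounds stay as nodes even when isolated, so downstream counts are
    not silently deflated by the filter.
    """
    if not 0.0 <= min_similarity <= 1.0:
        raise ValueError(f"min_similarity must be in [0,1], got {min_similarity}")
    node_set: set[str] = set(nodes or [])
    edges: dict[tuple[str, str], SimilarityEdge] = {}
    for (a, b), score in similarities.items():
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} for pair ({a},{b}) outside [0,1]")
        pair = canonical_pair(a, b)
        node_set.update(pair)
        if score >= min_similarity:
            edges[pair] = SimilarityEdge(pair=pair, score=float(score))
    return SimilarityNetwork(
        nodes=sorted(node_set),
        edges=edges,
        node_attrs=dict(node_attrs or {}),
        parameters={"min_similarity": min_similarity},
    )


def detect_communities(
    net: SimilarityNetwork,
    walk_length: int = DEFAULT_WALK_LENGTH,
    seed: int = 0,
) -> SimilarityNetwork:
    """Assign Walktrap communities at the maximum-modularity cut.

    Walktrap is deterministic despite the random-walk framing (it works
    on walk transition probabilities, not sampled walks); ``seed`` is
    recorded for provenance. Isolated nodes become singleton
    communities. Community ids are renumbered by the lexicographically
    smallest member so the labelling is stable across runs.
    """
    if walk_length < 1:
        raise ValueError("walk_length must be positive")
    connected = sorted({n for pair in net.edges for n in pair})
    membership: dict[str, int] = {}
    if connected:
        index = {n: i for i, n in enumerate(connected)}
        g = ig.Graph(
            n=len(connected),
            edges=[(index[a], index[b]) for a, b in net.edges],
        )
        g.es["weight"] = [net.edges[p].score for p in net.edges]
        dendro = g.community_walktrap(weights="weight", steps=walk_length)
        clustering = dendro.as_clustering()
        for node, cid in zip(connected, clustering.membership):
            membership[node] = cid
    next_id = max(membership.values(), default=-1) + 1
    for node in net.nodes:
        if node not in membership:
            membership[node] = next_id
            next_id += 1
    # stable renumbering: sort groups by smallest member id
    groups: dict[int, list[str]] = {}
    for node, cid in membership.items():
        groups.setdefault(cid, []).append(node)
    ordered = sorted(groups.values(), key=min)
    communities = {
        i: Community(community_id=i, members=frozenset(members))
        for i, members in enumerate(ordered)
    }
    relabel = {m: c.community_id for c in communities.values() for m in c.members}
    edges = {
        pair: replace(
            edge,
            community_id=(
                relabel[pair[0]] if relabel[pair[0]] == relabel[pair[1]] else None
            ),
        )
        for pair, edge in net.edges.items()
    }
    params = dict(net.parameters, walk_length=walk_length, random_seed=seed)
    return SimilarityNetwork(
        nodes=net.nodes,
        edges=edges,
        communities=communities,
        node_attrs=net.node_attrs,
        parameters=params,
    )


def flag_significant_edges(
    net: SimilarityNetwork,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> SimilarityNetwork:
    """Flag intra-community edges with Z >= z_threshold as significant.

    Z-scores use each community's own intra-edge mean and sample (n-1)
    standard deviation. Communities with fewer than two intra edges, or
    zero spread, yield no significant edges: the Z-score is undefined
    there and a conservative call beats a division by zero.
    """
    if not net.communities:
        raise ValueError("communities must be assigned before flagging edges")
    intra: dict[int, list[tuple[tuple[str, str], float]]] = {}
    for pair, edge in net.edges.items():
        if edge.community_id is not None:
            intra.setdefault(edge.community_id, []).append((pair, edge.score))
    stats: dict[int, tuple[float, float]] = {}
    communities: dict[int, Community] = {}
    for cid, com in net.communities.items():
        scores = [s for _, s in intra.get(cid, [])]
        if len(scores) >= 2:
            mean = float(np.mean(scores))
            sd = float(np.std(scores, ddof=1))
            communities[cid] = replace(
                com,
                edge_mean=mean,
                edge_sd=sd,
                threshold=mean + z_threshold * sd,
            )
            if sd > 0:
                stats[cid] = (mean, sd)
        else:
            communities[cid] = replace(
                com, edge_mean=None, edge_sd=None, threshold=None
            )
    edges: dict[tuple[str, str], SimilarityEdge] = {}
    for pair, edge in net.edges.items():
        z = None
        sig = False
        if edge.community_id in stats:
            mean, sd = stats[edge.community_id]
            z = (edge.score - mean) / sd
            sig = z >= z_threshold
        edges[pair] = replace(edge, zscore=z, significant=sig)
    params = dict(net.parameters, z_threshold=z_threshold)
    return SimilarityNetwork(
        nodes=net.nodes,
        edges=edges,
        communities=communities,
        node_attrs=net.node_attrs,
        parameters=params,
    )


def to_networkx(net: SimilarityNetwork) -> nx.Graph:
    g = nx.Graph()
    membership = net.membership
    for node in net.nodes:
        attrs = dict(net.node_attrs.get(node, {}))
        attrs = {k: v for k, v in attrs.items() if v is not None}
        if node in membership:
            attrs["community_id"] = int(membership[node])
        g.add_node(node, **attrs)
    for (a, b), edge in net.edges.items():
        attrs = {"score": edge.score, "significant": bool(edge.significant)}
        if edge.zscore is not None:
            attrs["zscore"] = float(edge.zscore)
        g.add_edge(a, b, **attrs)
    return g


def write_graphml(net: SimilarityNetwork, path) -> None:
    """GraphML export with node (category, superclass, community_id) and
    edge (score, zscore, significant) attributes."""
    nx.write_graphml(to_networkx(net), path)


def read_graphml(path) -> SimilarityNetwork:
    g = nx.read_graphml(path)
    node_attrs: dict[str, dict] = {}
    membership: dict[str, int] = {}
    for node, attrs in g.nodes(data=True):
        a = dict(attrs)
        if "community_id" in a:
            membership[node] = int(a.pop("community_id"))
        node_attrs[node] = a
    edges: dict[tuple[str, str], SimilarityEdge] = {}
    for a, b, attrs in g.edges(data=True):
        pair = canonical_pair(a, b)
        cid = (
            membership[pair[0]]
            if membership.get(pair[0]) is not None
            and membership.get(pair[0]) == membership.get(pair[1])
            else None
        )
        edges[pair] = SimilarityEdge(
            pair=pair,
            score=float(attrs["score"]),
            community_id=cid,
            zscore=float(attrs["zscore"]) if "zscore" in attrs else None,
            significant=bool(attrs.get("significant", False)),
        )
    groups: dict[int, set[str]] = {}
    for node, cid in membership.items():
        groups.setdefault(cid, set()).add(node)
    communities = {
        cid: Community(community_id=cid, members=frozenset(members))
        for cid, members in groups.items()
    }
    return SimilarityNetwork(
        nodes=sorted(g.nodes),
        edges=edges,
        communities=communities,
        node_attrs=node_attrs,
    )


def write_edge_list(net: SimilarityNetwork, path) -> None:
    """TSV mirror of the edge set: one row per edge with scores and flags."""
    rows = [
        {
            "source": pair[0],
            "target": pair[1],
            "score": edge.score,
            "community_id": "" if edge.community_id is None else edge.community_id,
            "zscore": "" if edge.zscore is None else edge.zscore,
            "significant": edge.significant,
        }
        for pair, edge in sorted(net.edges.items())
    ]
    pd.DataFrame(
        rows,
        columns=["source", "target", "score", "community_id", "zscore", "significant"],
    ).to_csv(path, sep="\t", index=False)
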