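"""Rho-statistic clade ages from haplotype networks.

Rho is the average number of mutations separating sampled individuals from
a designated ancestral node; under a molecular clock it is proportional to
the clade's age, so the ratio of a nested clade's rho to the whole
network's rho converts a calibrated total divergence time into the nested
clade's age.  The standard deviation follows Saillard's estimator: on the
genealogy rooted at the ancestral node,

    sd^2 = (1 / n^2) * sum over mutational links of (descendants of link)^2

where each unit of edge weight is one mutational link subtending the
individuals below it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .network import NetworkGraph, hamming


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    sd: float
    n: int
    ancestral_node: str

    def __post_init__(self) -> None:
        if self.rho < 0 or self.sd < 0 or self.n < 1:
            raise ValueError("invalid rho estimate")


@dataclass(frozen=True)
class AgeEstimate:
    """Clade age from a rho ratio.

    ``t_low``/``t_high`` carry the reported bounds, rounded to two
    significant figures; the exact values are kept alongside.
    """

    ratio: float
    t_total: float
    t_point: float
    t_low: float
    t_high: float
    t_low_exact: float
    t_high_exact: float


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sigfigs - 1))


def resolve_tree(net: NetworkGraph, root: str) -> dict[str, str]:
    """Resolve reticulations into a shortest-path tree rooted at ``root``.

    Returns a child -> parent map.  Each node's parent is the neighbour that
    lies on a minimum-weight path to the root, ties broken by (distance to
    root, node id) so the resolution is deterministic.
    """
    if root not in net.graph:
        raise KeyError(f"root node {root!r} not in network")
    dist = nx.single_source_dijkstra_path_length(net.graph, root,
                                                 weight="weight")
    missing = set(net.graph.nodes) - set(dist)
    if missing:
        raise ValueError(f"nodes unreachable from root: {sorted(missing)}")
    parent: dict[str, str] = {}
    for node in sorted(dist, key=lambda x: (dist[x], x)):
        if node == root:
            continue
        candidates = [
            nbr for nbr in net.graph[node]
            if dist[nbr] + net.graph[node][nbr]["weight"] == dist[node]
        ]
        parent[node] = min(candidates, key=lambda x: (dist[x], x))
    return parent


def rho_estimate(
    net: NetworkGraph,
    ancestral_node: str,
    members: Sequence[str],
) -> RhoEstimate:
    """Rho and its Saillard standard deviation for ``members``.

    ``members`` are sample labels; each maps to the network node carrying
    it, and each counts once (a node with multiplicity m carrying m members
    contributes m equal path lengths).  Paths are measured on the
    shortest-path tree rooted at ``ancestral_node``.
    """
    if not members:
        raise ValueError("no members to average over")
    if ancestral_node not in net.graph:
        raise KeyError(f"ancestral node {ancestral_node!r} not in network")
    member_node = {lab: net.node_of_sample(lab) for lab in members}

    parent = resolve_tree(net, ancestral_node)
    # members per node
    node_members: dict[str, int] = {}
    for lab, node in member_node.items():
        node_members[node] = node_members.get(node, 0) + 1

    # path length of each member node along the tree
    def tree_depth(node: str) -> int:
        depth = 0
        while node != ancestral_node:
            p = parent[node]
            depth += net.graph[node][p]["weight"]
            node = p
        return depth

    n = len(members)
    rho = sum(node_members[nd] * tree_depth(nd) for nd in node_members) / n

    # descendants subtended by each tree edge
    children: dict[str, list[str]] = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)

    def subtree_members(node: str) -> int:
        total = node_members.get(node, 0)
        for ch in children.get(node, []):
            total += subtree_members(ch)
        return total

    var_sum = 0.0
    for child, par in parent.items():
        desc = subtree_members(child)
        if desc == 0:
            continue
        w = net.graph[child][par]["weight"]
        var_sum += w * desc ** 2  # w unit mutational links on this edge
    sd = math.sqrt(var_sum) / n
    return RhoEstimate(rho=rho, sd=sd, n=n, ancestral_node=ancestral_node)


def clade_age(
    rho_clade: RhoEstimate,
    rho_total: RhoEstimate,
    t_total: float = 470_000.0,
) -> AgeEstimate:
    """Convert a clade/total rho ratio into a calibrated age.

    t_point = (rho_clade / rho_total) * t_total; the bounds move the clade
    rho by one SD while holding the denominator fixed, floored at zero, and
    are reported rounded to two significant figures.
    """
    if rho_total.rho <= 0:
        raise ValueError("total rho must be positive for calibration")
    ratio = rho_clade.rho / rho_total.rho
    if ratio > 1:
        warnings.warn(
            f"clade rho exceeds total rho (ratio {ratio:.3f}); the clade "
            "may not be nested in the calibrated split", stacklevel=2
        )
    t_point = ratio * t_total
    low = max(0.0, rho_clade.rho - rho_clade.sd) / rho_total.rho * t_total
    high = (rho_clade.rho + rho_clade.sd) / rho_total.rho * t_total
    return AgeEstimate(
        ratio=ratio, t_total=t_total, t_point=t_point,
        t_low=round_sigfigs(low), t_high=round_sigfigs(high),
        t_low_exact=low, t_high_exact=high,
    )


def clade_ancestor_vector(
    net: NetworkGraph, members: Sequence[str]
) -> np.ndarray:
    """State vector of the clade's ancestral haplotype: exactly the
    mutations shared by every member."""
    if not members:
        raise ValueError("no members")
    states = [net.state(net.node_of_sample(lab)) for lab in members]
    out = states[0].copy()
    for s in states[1:]:
        out &= s
    return out


def find_clade_ancestor(net: NetworkGraph, members: Sequence[str]) -> str:
    """Node carrying the mutations shared by all clade members,
    materialised as a median node when no existing node carries it."""
    return net.ensure_node(clade_ancestor_vector(net, members))
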