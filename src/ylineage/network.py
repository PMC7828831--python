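"""Median-joining haplotype networks for binary-coded SNP panels.

The construction follows the Bandelt–Forster–Röhl scheme specialised to
bi-allelic characters: observed haplotypes are collapsed into weighted
nodes; the epsilon-relaxed minimum spanning network (the union of all
minimum spanning trees, plus links within epsilon of the connecting cost)
links them; for every node triple carrying at least two network links the
quasi-median — for binary states simply the sitewise majority vector — is
added whenever it does not increase the local connection cost; the process
repeats until no further medians arise, unsupported medians are pruned, and
a designated root haplotype (the outgroup consensus) is attached.

With homoplasy-free data (each site mutated once) the result is exactly the
underlying genealogy with unsampled internal haplotypes materialised as
median nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .matrix import Call, HaplotypeMatrix

MEDIAN_PREFIX = "mv"
ROOT_NAME = "root"


class NetworkGraph:
    """A haplotype network over binary state vectors.

    Wraps an undirected :class:`networkx.Graph` whose nodes carry
    ``state`` (uint8 vector), ``multiplicity``, ``labels``, ``populations``,
    ``is_median`` and ``is_root`` attributes, and whose edges carry
    ``weight`` (the Hamming distance between their endpoints) and ``loci``
    (the differing locus ids).
    """

    def __init__(
        self,
        graph: nx.Graph,
        site_ids: list[str],
        epsilon: int = 0,
        root: str | None = None,
        meta: dict | None = None,
    ) -> None:
        self.graph = graph
        self.site_ids = list(site_ids)
        self.epsilon = int(epsilon)
        self.root = root
        self.meta = dict(meta or {})

    # -- accessors ---------------------------------------------------------

    def state(self, node: str) -> np.ndarray:
        return self.graph.nodes[node]["state"]

    def node_of_sample(self, label: str) -> str:
        for node, attrs in self.graph.nodes(data=True):
            if label in attrs["labels"]:
                return node
        raise KeyError(f"sample {label!r} is not carried by any network node")

    def observed_nodes(self) -> list[str]:
        return sorted(
            n for n, a in self.graph.nodes(data=True) if not a["is_median"]
        )

    def median_nodes(self) -> list[str]:
        return sorted(
            n for n, a in self.graph.nodes(data=True) if a["is_median"]
        )

    def node_for_state(self, state: np.ndarray) -> str | None:
        state = np.asarray(state, dtype=np.uint8)
        for node in sorted(self.graph.nodes):
            if np.array_equal(self.graph.nodes[node]["state"], state):
                return node
        return None

    def total_cost(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges(data="weight")))

    def validate(self) -> None:
        roots = [n for n, a in self.graph.nodes(data=True) if a["is_root"]]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root node, found {roots}")
        for a, b, attrs in self.graph.edges(data=True):
            h = hamming(self.state(a), self.state(b))
            if attrs["weight"] != h:
                raise ValueError(f"edge {a}--{b} weight {attrs['weight']} != "
                                 f"Hamming distance {h}")
        if self.graph.number_of_nodes() > 1 and not nx.is_connected(self.graph):
            raise ValueError("network is not connected")

    def ensure_node(self, state: np.ndarray, name: str | None = None) -> str:
        """Return the node carrying ``state``, materialising it as a median
        node (and relinking the network) if absent."""
        existing = self.node_for_state(state)
        if existing is not None:
            return existing
        if name is None:
            k = len(self.median_nodes()) + 1
            name = f"{MEDIAN_PREFIX}{k:02d}"
            while name in self.graph:
                k += 1
                name = f"{MEDIAN_PREFIX}{k:02d}"
        self.graph.add_node(
            name, state=np.asarray(state, dtype=np.uint8), multiplicity=0,
            labels=(), populations=(), is_median=True, is_root=False,
        )
        states = {n: self.graph.nodes[n]["state"] for n in self.graph.nodes}
        _relink(self.graph, states, self.epsilon, self.site_ids)
        return name


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def quasi_median(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sitewise majority of three binary state vectors.

    For bi-allelic characters the Bandelt quasi-median set collapses to this
    single vector: at every site the output carries the state shared by at
    least two of the three inputs.
    """
    u = np.asarray(u, dtype=np.uint8)
    v = np.asarray(v, dtype=np.uint8)
    w = np.asarray(w, dtype=np.uint8)
    if not (u.shape == v.shape == w.shape):
        raise ValueError("state vectors must have equal length")
    return ((u.astype(np.int16) + v + w) >= 2).astype(np.uint8)


# ---------------------------------------------------------------------------
# epsilon-relaxed minimum spanning network
# ---------------------------------------------------------------------------

class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def msn_edges(states: dict[str, np.ndarray], epsilon: int = 0) -> set[tuple[str, str]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A candidate link (u, v) is kept iff its Hamming weight is within
    ``epsilon`` of the connection level of u and v — the smallest distance
    class at which their components fuse when links are admitted in
    increasing weight order (Kruskal processed level by level).  At
    epsilon = 0 this is exactly the union of all minimum spanning trees.
    """
    ids = sorted(states)
    if len(ids) < 2:
        return set()
    dist = {
        (a, b): hamming(states[a], states[b])
        for a, b in itertools.combinations(ids, 2)
    }
    levels = sorted(set(dist.values()))
    dsu = _DSU(ids)
    conn_level: dict[tuple[str, str], int] = {}
    for delta in levels:
        for (a, b), d in dist.items():
            if d == delta:
                dsu.union(a, b)
        for pair in dist:
            if pair not in conn_level and dsu.find(pair[0]) == dsu.find(pair[1]):
                conn_level[pair] = delta
        if len(conn_level) == len(dist):
            break
    return {
        pair for pair, d in dist.items()
        if pair in conn_level and d <= conn_level[pair] + epsilon
    }


def _relink(
    g: nx.Graph,
    states: dict[str, np.ndarray],
    epsilon: int,
    site_ids: list[str],
) -> None:
    g.remove_edges_from(list(g.edges))
    for a, b in sorted(msn_edges(states, epsilon)):
        diff = np.flatnonzero(states[a] != states[b])
        g.add_edge(a, b, weight=int(diff.size),
                   loci=tuple(site_ids[j] for j in diff))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def construct_mj_network(
    m: HaplotypeMatrix,
    epsilon: int = 0,
    root_vector: np.ndarray | None = None,
    max_iterations: int = 64,
) -> NetworkGraph:
    """Build the median-joining network of a complete bi-allelic matrix.

    The matrix must contain no missing calls (impute or subset first).  The
    root haplotype — by default the all-ancestral outgroup-consensus vector —
    is attached after construction, as a multiplicity-0 node if no observed
    or median node already carries it.  Construction is deterministic: ties
    are broken by lexicographic node id, then site index.
    """
    if m.has_missing():
        raise ValueError(
            "matrix contains missing calls; run impute_missing (or subset to "
            "complete samples) before network construction"
        )
    if m.n_samples == 0:
        raise ValueError("matrix contains no samples")

    # 1. collapse identical rows into observed nodes
    groups: dict[bytes, list[int]] = {}
    for i in range(m.n_samples):
        groups.setdefault(m.calls[i].astype(np.uint8).tobytes(), []).append(i)
    g = nx.Graph()
    states: dict[str, np.ndarray] = {}
    for key, idxs in groups.items():
        labels = tuple(sorted(m.samples[i].identifier for i in idxs))
        name = labels[0] if len(labels) == 1 else "|".join(labels)
        state = np.frombuffer(key, dtype=np.uint8).copy()
        pops = tuple(m.samples[i].population for i in idxs)
        g.add_node(name, state=state, multiplicity=len(idxs), labels=labels,
                   populations=pops, is_median=False, is_root=False)
        states[name] = state

    # 2-4. alternate MSN linking with quasi-median insertion
    median_count = 0
    cost_trace: list[int] = []
    for _ in range(max_iterations):
        edges = msn_edges(states, epsilon)
        cost_trace.append(
            sum(hamming(states[a], states[b]) for a, b in edges)
        )
        adj: dict[str, set[str]] = {n: set() for n in states}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen = {s.tobytes() for s in states.values()}
        new: list[np.ndarray] = []
        for u, v, w in itertools.combinations(sorted(states), 3):
            n_links = sum(
                1 for x, y in ((u, v), (u, w), (v, w)) if y in adj[x]
            )
            if n_links < 2:
                continue
            med = quasi_median(states[u], states[v], states[w])
            key = med.tobytes()
            if key in seen:
                continue
            duv = hamming(states[u], states[v])
            duw = hamming(states[u], states[w])
            dvw = hamming(states[v], states[w])
            cost_now = duv + duw + dvw - max(duv, duw, dvw)
            cost_med = (
                hamming(states[u], med)
                + hamming(states[v], med)
                + hamming(states[w], med)
            )
            if cost_med <= cost_now + epsilon:
                seen.add(key)
                new.append(med)
        if not new:
            break
        for med in new:
            median_count += 1
            name = f"{MEDIAN_PREFIX}{median_count:02d}"
            g.add_node(name, state=med, multiplicity=0, labels=(),
                       populations=(), is_median=True, is_root=False)
            states[name] = med

    # 5. prune unsupported medians: degree <= 2 and on no shortest path
    #    between observed nodes
    observed = [n for n, a in g.nodes(data=True) if not a["is_median"]]
    while True:
        _relink(g, states, epsilon, m.locus_ids)
        removed = False
        sp = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for med in sorted(n for n, a in g.nodes(data=True) if a["is_median"]):
            if g.degree(med) > 2:
                continue
            supported = any(
                sp[a][med] + sp[med][b] == sp[a][b]
                for a, b in itertools.combinations(observed, 2)
            )
            if not supported:
                g.remove_node(med)
                del states[med]
                removed = True
                break
        if not removed:
            break

    # 6. attach the root haplotype
    if root_vector is None:
        root_vector = m.ancestral_row
    root_vector = np.asarray(root_vector, dtype=np.uint8)
    root_node = None
    for name in sorted(states):
        if np.array_equal(states[name], root_vector):
            root_node = name
            break
    if root_node is None:
        root_node = ROOT_NAME
        g.add_node(root_node, state=root_vector, multiplicity=0, labels=(),
                   populations=(), is_median=False, is_root=True)
        states[root_node] = root_vector
        _relink(g, states, epsilon, m.locus_ids)
    else:
        g.nodes[root_node]["is_root"] = True

    net = NetworkGraph(
        g, site_ids=m.locus_ids, epsilon=epsilon, root=root_node,
        meta={"median_iteration_costs": cost_trace},
    )
    net.validate()
    return net


def path_mutations(net: NetworkGraph, from_node: str, to_node: str) -> int:
    """Minimum number of mutations along the network between two nodes.

    The weight of the lightest path (edge weights are Hamming distances);
    for homoplasy-free data this equals the Hamming distance between the
    endpoint state vectors.
    """
    for node in (from_node, to_node):
        if node not in net.graph:
            raise KeyError(f"node {node!r} not in network")
    try:
        return int(
            nx.dijkstra_path_length(net.graph, from_node, to_node,
                                    weight="weight")
        )
    except nx.NetworkXNoPath:
        raise ValueError(
            f"nodes {from_node!r} and {to_node!r} are disconnected"
        ) from None
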