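"""Median-joining networks and neighbor-joining trees over genotype classes.

Each somatic SNV is one binary character (het = derived state 1); genotype
classes are binary vectors.  The median-joining construction follows the
classic intraspecific-network recipe: an epsilon-relaxed minimum spanning
network is augmented with majority-consensus median vectors (inferred,
unsampled intermediates) whenever that strictly reduces the cost of spanning
the node set, and medians that become obsolete are pruned.  The NJ tree uses
the standard Q-criterion agglomeration with deterministic tie-breaking.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx

from .ancestry import DistanceMatrix
from .genotypes import GenotypeClass

log = logging.getLogger(__name__)


def _hamming(u: tuple, v: tuple) -> int:
    return sum(a != b for a, b in zip(u, v))


def _mst_cost(vectors: list[tuple]) -> int:
    """Prim's algorithm on hamming distances; total weight of an MST."""
    n = len(vectors)
    if n < 2:
        return 0
    in_tree = [False] * n
    best = [10 ** 9] * n
    best[0] = 0
    total = 0
    for _ in range(n):
        u = min((i for i in range(n) if not in_tree[i]), key=lambda i: best[i])
        in_tree[u] = True
        total += best[u]
        for v in range(n):
            if not in_tree[v]:
                d = _hamming(vectors[u], vectors[v])
                if d < best[v]:
                    best[v] = d
    return total


@dataclass
class CloneNetwork:
    """Genotype-class network: observed + median nodes, per-edge mutation lists."""

    graph: nx.Graph                 # nodes carry vector/kind/frequency attrs
    site_ids: list[str]
    epsilon: int

    def degree_of(self, node: str) -> int:
        return self.graph.degree(node) if node in self.graph else 0

    def observed_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed")

    def median_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "median")

    def vector(self, node: str) -> tuple:
        return self.graph.nodes[node]["vector"]

    def edge_sites(self, u: str, v: str) -> list[str]:
        return self.graph.edges[u, v]["mutations"]

    def check_invariants(self) -> None:
        assert nx.is_connected(self.graph), "network must be connected"
        for u, v, data in self.graph.edges(data=True):
            h = _hamming(self.vector(u), self.vector(v))
            assert len(data["mutations"]) == h == data["weight"]


def minimum_spanning_network(vectors: dict[str, tuple], epsilon: int = 0) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over labelled binary vectors.

    An edge (u, v) is kept iff d(u, v) <= lambda(u, v) + epsilon, where
    lambda is the minimax connection cost (the Kruskal merge weight); with
    epsilon = 0 this is the union of all minimum spanning trees.
    """
    labels = sorted(vectors)
    pairs = {(a, b): _hamming(vectors[a], vectors[b])
             for a, b in itertools.combinations(labels, 2)}
    # Kruskal union-find to obtain lambda(u, v) = weight at which components merge
    parent = {l: l for l in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merge_weight: dict[frozenset, int] = {}
    comp_members = {l: {l} for l in labels}
    for (a, b), w in sorted(pairs.items(), key=lambda kv: (kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            for x in comp_members[ra]:
                for y in comp_members[rb]:
                    merge_weight[frozenset((x, y))] = w
            parent[rb] = ra
            comp_members[ra] |= comp_members[rb]
            del comp_members[rb]
    g = nx.Graph()
    for l in labels:
        g.add_node(l, vector=vectors[l])
    for (a, b), w in pairs.items():
        if w <= merge_weight[frozenset((a, b))] + epsilon and w > 0:
            g.add_edge(a, b, weight=w)
    return g


def _median_vector(u: tuple, v: tuple, w: tuple) -> tuple:
    return tuple(1 if (a + b + c) >= 2 else 0 for a, b, c in zip(u, v, w))


def median_joining(classes: list[GenotypeClass] | dict[str, tuple],
                   site_ids: list[str] | None = None,
                   epsilon: int = 0, max_medians: int = 64) -> CloneNetwork:
    """Median-joining network over genotype-class binary vectors.

    Iteratively adds the majority-consensus median of a node triplet whenever
    it strictly reduces the minimum cost of spanning the node set (choosing,
    deterministically, the candidate with the largest reduction, ties broken
    by lexicographic vector), then prunes medians whose removal leaves that
    cost unchanged.  The returned network is the epsilon-relaxed minimum
    spanning network over the final node set, with per-edge mutation lists.
    """
    if isinstance(classes, dict):
        vectors = {k: tuple(int(x) for x in v) for k, v in classes.items()}
        freqs = {k: 1 for k in vectors}
    else:
        vectors = {c.class_id: tuple(int(x) for x in c.state_vector) for c in classes}
        freqs = {c.class_id: c.frequency for c in classes}
    if len(vectors) < 2:
        raise ValueError("need >= 2 genotype classes")
    seen: dict[tuple, str] = {}
    for k in sorted(vectors):
        v = vectors[k]
        if v in seen:
            raise ValueError(f"duplicate vectors for {seen[v]} and {k}; "
                             "collapse samples into genotype classes first")
        seen[v] = k
    if site_ids is None:
        site_ids = [f"s{j}" for j in range(len(next(iter(vectors.values()))))]

    nodes = dict(vectors)  # label -> vector (observed + medians)
    n_median = 0
    while n_median < max_medians:
        vecs = [nodes[l] for l in sorted(nodes)]
        base_cost = _mst_cost(vecs)
        best: tuple[int, tuple] | None = None  # (new_cost, median_vector)
        tried: set[tuple] = set()
        present = set(nodes.values())
        for u, v, w in itertools.combinations(sorted(nodes), 3):
            m = _median_vector(nodes[u], nodes[v], nodes[w])
            if m in present or m in tried:
                continue
            tried.add(m)
            new_cost = _mst_cost(vecs + [m])
            if new_cost < base_cost and (best is None or (new_cost, m) < best):
                best = (new_cost, m)
        if best is None:
            break
        n_median += 1
        label = f"MV-{n_median:02d}"
        nodes[label] = best[1]
        log.debug("median_joining: added %s (cost %d -> %d)", label, base_cost, best[0])

    # prune medians that no longer pay for themselves
    changed = True
    while changed:
        changed = False
        median_labels = sorted(l for l in nodes if l.startswith("MV-"))
        all_vecs = [nodes[l] for l in sorted(nodes)]
        cost = _mst_cost(all_vecs)
        for l in median_labels:
            rest = [nodes[k] for k in sorted(nodes) if k != l]
            if _mst_cost(rest) <= cost:
                del nodes[l]
                changed = True
                break

    g = minimum_spanning_network(nodes, epsilon=epsilon)
    for l in g.nodes:
        kind = "median" if l.startswith("MV-") else "observed"
        g.nodes[l]["kind"] = kind
        g.nodes[l]["frequency"] = freqs.get(l, 0)
    for u, v in g.edges:
        diff = [site_ids[j] for j, (a, b) in enumerate(zip(nodes[u], nodes[v])) if a != b]
        g.edges[u, v]["mutations"] = diff
        assert len(diff) == g.edges[u, v]["weight"]
    net = CloneNetwork(graph=g, site_ids=list(site_ids), epsilon=epsilon)
    net.check_invariants()
    log.info("median_joining: %d observed + %d median nodes, %d edges",
             len(net.observed_nodes()), len(net.median_nodes()), g.number_of_edges())
    return net


def edge_mutations(network: CloneNetwork) -> dict[tuple[str, str], list[str]]:
    """Per-edge mutation-site lists (symmetric difference of endpoint vectors)."""
    out = {}
    for u, v in sorted(network.graph.edges):
        sites = network.edge_sites(u, v)
        if not sites:
            raise ValueError(f"edge ({u}, {v}) joins identical vectors")
        out[(u, v)] = sites
    return out


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NJTree:
    graph: nx.Graph        # unrooted; leaves are item ids, internal nodes "I*"
    newick: str

    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.nodes[n].get("leaf"))


def _nj_newick(graph: nx.Graph, leaves: set[str]) -> str:
    # root the unrooted tree at the highest-degree internal node (or any leaf pair)
    internal = [n for n in graph if n not in leaves]
    root = max(internal, key=lambda n: (graph.degree(n), str(n))) if internal else sorted(leaves)[0]

    def rec(node, parent):
        children = [c for c in graph.neighbors(node) if c != parent]
        if not children:
            return str(node)
        parts = [f"{rec(c, node)}:{graph.edges[node, c]['length']:.6g}" for c in sorted(children, key=str)]
        name = node if node in leaves else ""
        return f"({','.join(parts)}){name}"

    return rec(root, None) + ";"


def neighbor_joining(dm: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Deterministic tie-breaking by sorted id pair; a negative branch length is
    clamped to zero with the excess moved onto the sibling branch.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 items")
    d = {(a, b): dm.get(a, b) for a in ids for b in ids}
    active = list(ids)
    graph = nx.Graph()
    for l in ids:
        graph.add_node(l, leaf=True)
    counter = itertools.count(1)

    while len(active) > 3:
        n = len(active)
        totals = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best_pair, best_q = None, None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (n - 2) * d[(a, b)] - totals[a] - totals[b]
            if best_q is None or q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        u = f"I{next(counter)}"
        la = 0.5 * d[(a, b)] + (totals[a] - totals[b]) / (2 * (n - 2))
        lb = d[(a, b)] - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        graph.add_node(u, leaf=False)
        graph.add_edge(u, a, length=la)
        graph.add_edge(u, b, length=lb)
        for c in active:
            if c not in (a, b):
                d[(u, c)] = d[(c, u)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active, key=str)
    u = f"I{next(counter)}"
    graph.add_node(u, leaf=False)
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    for leaf, ln in ((a, la), (b, lb), (c, lc)):
        graph.add_edge(u, leaf, length=max(ln, 0.0))
    newick = _nj_newick(graph, set(ids))
    return NJTree(graph=graph, newick=newick)


# ---------------------------------------------------------------------------
# lineage partition
# ---------------------------------------------------------------------------

@dataclass
class CladeAssignment:
    assignments: dict[str, str]   # class_id -> clade label
    rooting_node: str

    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, lab in sorted(self.assignments.items()):
            out.setdefault(lab, []).append(cid)
        return out


def partition_lineages(network: CloneNetwork, root_class: str,
                       min_branch_size: int = 1) -> CladeAssignment:
    """Partition observed classes into clades hanging off the root class.

    Each connected component left after removing the root is a candidate
    clade; components with fewer than ``min_branch_size`` observed classes
    fold into the root clade.  Labels A, B, C... are assigned by descending
    clade size (observed classes), ties broken by smallest member id.
    """
    g = network.graph
    if root_class not in g:
        raise ValueError(f"root class {root_class!r} not present in network")
    observed = set(network.observed_nodes())
    rest = g.copy()
    rest.remove_node(root_class)
    root_clade = [root_class]
    candidates: list[list[str]] = []
    for comp in nx.connected_components(rest):
        members = sorted(comp & observed)
        if len(members) < min_branch_size:
            root_clade.extend(members)
        else:
            candidates.append(members)
    clades = [sorted(root_clade)] + candidates
    clades.sort(key=lambda m: (-len(m), m[0] if m else ""))
    assignments: dict[str, str] = {}
    for i, members in enumerate(clades):
        label = chr(ord("A") + i)
        for cid in members:
            assignments[cid] = label
    return CladeAssignment(assignments=assignments, rooting_node=root_class)
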