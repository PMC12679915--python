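"""Median-joining networks, NJ trees, edge mutations, clade partition."""

import itertools

import networkx as nx
import numpy as np
import pytest

from clonotrace import ancestry, phylo, pipeline, simdata
from clonotrace.genotypes import GenotypeClass


def _classes(vectors):
    return [GenotypeClass(class_id=k, state_vector=np.array(v, dtype=np.int8),
                          member_samples=[f"{k}-m"]) for k, v in sorted(vectors.items())]


class TestMedianJoining:
    def test_two_classes_single_edge(self):
        net = phylo.median_joining(_classes({"A": [0, 0, 1], "B": [1, 0, 0]}),
                                   site_ids=["s1", "s2", "s3"])
        assert set(net.graph.edges) == {("A", "B")}
        assert sorted(net.edge_sites("A", "B")) == ["s1", "s3"]

    def test_three_class_path_needs_no_median(self):
        # median(000, 100, 111) = 100 is already observed
        net = phylo.median_joining(_classes({"A": [0, 0, 0], "B": [1, 0, 0],
                                             "C": [1, 1, 1]}))
        assert net.median_nodes() == []
        assert set(net.graph.edges) == {("A", "B"), ("B", "C")}

    def test_star_data_infers_central_median(self):
        # three vectors with disjoint private mutations of size 2: the
        # all-zero consensus is an unsampled intermediate worth inferring
        net = phylo.median_joining(_classes({
            "A": [1, 1, 0, 0, 0, 0], "B": [0, 0, 1, 1, 0, 0], "C": [0, 0, 0, 0, 1, 1]}))
        assert len(net.median_nodes()) == 1
        m = net.median_nodes()[0]
        assert net.vector(m) == (0, 0, 0, 0, 0, 0)
        assert net.graph.degree(m) == 3

    def test_duplicate_vectors_rejected(self):
        with pytest.raises(ValueError, match="collapse"):
            phylo.median_joining(_classes({"A": [0, 1], "B": [0, 1]}))

    def test_homoplasy_free_genealogy_recovered(self):
        tree = simdata.random_propagation_tree(8, seed=5)
        cfg = simdata.small_config(seed=5, propagation_tree=tree,
                                   min_edge_mutations=3, mu_edge=4.0,
                                   samples_per_node=2,
                                   germline_het_sites=0, n_parent_ambiguous=0)
        truth = simdata.simulate_clonal_lineage(cfg)
        res = pipeline.reconstruct_lineages(truth.genotype_matrix())
        assert pipeline.network_matches_tree(truth, res)

    def test_unsampled_ancestor_recovered_as_median(self):
        # genealogy root + three children, root NOT sampled: the founder
        # vector must come back as an inferred median node
        site_ids = [f"s{i}" for i in range(6)]
        child_vecs = {"A": [1, 1, 0, 0, 0, 0], "B": [0, 0, 1, 1, 0, 0],
                      "C": [0, 0, 0, 0, 1, 1]}
        net = phylo.median_joining(_classes(child_vecs), site_ids=site_ids)
        medians = [net.vector(m) for m in net.median_nodes()]
        assert (0, 0, 0, 0, 0, 0) in medians

    def test_msn_contains_every_exhaustive_mst(self):
        # brute-force oracle: enumerate spanning trees in weight order and
        # check each minimum one is inside the epsilon=0 spanning network
        for seed in (0, 1, 2):
            rng = np.random.default_rng(1000 + seed)
            vecs, seen = {}, set()
            while len(vecs) < 5:
                v = tuple(rng.integers(0, 2, 6))
                if v not in seen:
                    seen.add(v)
                    vecs[f"C{len(vecs)}"] = v
            msn = phylo.minimum_spanning_network(vecs)
            g = nx.Graph()
            for (a, va), (b, vb) in itertools.combinations(vecs.items(), 2):
                g.add_edge(a, b, weight=sum(x != y for x, y in zip(va, vb)))
            it = iter(nx.SpanningTreeIterator(g))
            first = next(it)
            best = first.size(weight="weight")
            msts = [first]
            for t in it:
                if t.size(weight="weight") > best + 1e-9:
                    break
                msts.append(t)
            for t in msts:
                assert all(msn.has_edge(u, v) for u, v in t.edges)

    def test_steiner_bound_against_exhaustive_single_median(self):
        # MJ's spanning cost never exceeds the best achievable by adding any
        # single extra vector, found by exhaustive search
        for seed in (11, 23, 42):
            rng = np.random.default_rng(seed)
            k = 7
            vecs, seen = {}, set()
            while len(vecs) < 6:
                v = tuple(rng.integers(0, 2, k))
                if v not in seen:
                    seen.add(v)
                    vecs[f"C{len(vecs)}"] = v
            net = phylo.median_joining(vecs)
            final = [net.vector(n) for n in net.graph.nodes]
            mj_cost = phylo._mst_cost(final)
            base = list(vecs.values())
            best = min(phylo._mst_cost(base + [m])
                       for m in itertools.product((0, 1), repeat=k)
                       if m not in seen)
            best = min(best, phylo._mst_cost(base))
            assert mj_cost <= best

    def test_invariants_hold_on_simulated_network(self, default_lineage):
        default_lineage.network.check_invariants()


class TestEdgeMutations:
    def test_counts_are_symmetric_differences(self):
        net = phylo.median_joining(_classes({"A": [0, 0, 0, 0], "B": [1, 0, 0, 1]}),
                                   site_ids=["s1", "s2", "s3", "s4"])
        muts = phylo.edge_mutations(net)
        assert muts[("A", "B")] == ["s1", "s4"]

    def test_minimum_count_one_for_direct_neighbours(self, default_lineage):
        muts = phylo.edge_mutations(default_lineage.network)
        assert min(len(v) for v in muts.values()) >= 1


class TestNeighborJoining:
    def test_additive_four_taxon_metric_recovered_exactly(self):
        # true tree: ((a:2,b:3):1,(c:4,d:5)) -> additive distances
        d = {("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 8,
             ("b", "c"): 8, ("b", "d"): 9, ("c", "d"): 9}
        ids = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            m[i, j] = m[j, i] = v
        tree = phylo.neighbor_joining(ancestry.DistanceMatrix(ids, m, "hamming"))
        g = tree.graph
        # topology: a-b cherry separated from c-d cherry
        pa = next(iter(g.neighbors("a")))
        assert set(g.neighbors(pa)) >= {"a", "b"}
        lengths = {frozenset((u, v)): g.edges[u, v]["length"] for u, v in g.edges}
        assert lengths[frozenset((pa, "a"))] == pytest.approx(2.0)
        assert lengths[frozenset((pa, "b"))] == pytest.approx(3.0)
        # internal edge of length 1, and c/d terminal branches 4/5
        pc = next(iter(g.neighbors("c")))
        assert lengths[frozenset((pc, "c"))] == pytest.approx(4.0)
        assert lengths[frozenset((pc, "d"))] == pytest.approx(5.0)
        assert lengths[frozenset((pa, pc))] == pytest.approx(1.0)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = phylo.neighbor_joining(ancestry.DistanceMatrix(["a", "b", "c"], m, "hamming"))
        g = tree.graph
        hub = next(n for n in g if not g.nodes[n].get("leaf"))
        assert g.edges[hub, "a"]["length"] == pytest.approx(1.0)
        assert g.edges[hub, "b"]["length"] == pytest.approx(3.0)
        assert g.edges[hub, "c"]["length"] == pytest.approx(5.0)

    def test_fewer_than_three_items_rejected(self):
        m = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match=">= 3"):
            phylo.neighbor_joining(ancestry.DistanceMatrix(["a", "b"], m, "hamming"))

    def test_topology_invariant_to_input_order(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        pts = rng.random((6, 3)) * 10
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(6)]
        base = phylo.neighbor_joining(ancestry.DistanceMatrix(ids, d, "euclidean"))
        perm = list(rng.permutation(6))
        dp = d[np.ix_(perm, perm)]
        other = phylo.neighbor_joining(
            ancestry.DistanceMatrix([ids[i] for i in perm], dp, "euclidean"))
        t1 = skbio.TreeNode.read([base.newick])
        t2 = skbio.TreeNode.read([other.newick])
        assert t1.compare_rfd(t2) == 0

    def test_matches_reference_nj_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(19)
        pts = rng.random((7, 4)) * 5
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(7)]
        mine = phylo.neighbor_joining(ancestry.DistanceMatrix(ids, d, "euclidean"))
        theirs = skbio_nj(skbio.DistanceMatrix(d, ids=ids))
        t1 = skbio.TreeNode.read([mine.newick])
        assert t1.compare_rfd(theirs) == 0

    def test_simulated_topology_rf_zero(self):
        tree = simdata.random_propagation_tree(9, seed=3)
        cfg = simdata.small_config(seed=3, propagation_tree=tree,
                                   min_edge_mutations=3, samples_per_node=2,
                                   germline_het_sites=0, n_parent_ambiguous=0)
        truth = simdata.simulate_clonal_lineage(cfg)
        res = pipeline.reconstruct_lineages(truth.genotype_matrix())
        assert pipeline.nj_matches_tree(truth, res)


class TestPartitionLineages:
    def test_star_network_folds_singleton_branches(self):
        vectors = {"R": [0] * 6, "A": [1, 1, 0, 0, 0, 0], "B": [0, 0, 1, 1, 0, 0],
                   "C": [0, 0, 0, 0, 1, 1]}
        net = phylo.median_joining(_classes(vectors))
        clades = phylo.partition_lineages(net, "R", min_branch_size=2)
        # every neighbour branch has one observed class -> all fold into root
        assert set(clades.assignments.values()) == {"A"}

    def test_path_network_single_clade(self):
        vectors = {"R": [0, 0, 0], "X": [1, 0, 0], "Y": [1, 1, 0], "Z": [1, 1, 1]}
        net = phylo.median_joining(_classes(vectors))
        clades = phylo.partition_lineages(net, "R")
        labels = clades.assignments
        assert labels["X"] == labels["Y"] == labels["Z"]
        assert len(set(labels.values())) == 2  # root clade + the chain

    def test_three_founder_daughters_give_three_clades(self):
        t = nx.DiGraph()
        t.add_node("N00", region="RJ")
        for i, sub in enumerate(("A", "B", "C")):
            for j in range(3):
                t.add_node(f"{sub}{j}", region="RJ")
            t.add_edge("N00", f"{sub}0")
            t.add_edge(f"{sub}0", f"{sub}1")
            t.add_edge(f"{sub}1", f"{sub}2")
        cfg = simdata.small_config(seed=6, propagation_tree=t, min_edge_mutations=3,
                                   samples_per_node=2,
                                   germline_het_sites=0, n_parent_ambiguous=0)
        truth = simdata.simulate_clonal_lineage(cfg)
        res = pipeline.reconstruct_lineages(truth.genotype_matrix())
        root_class = next(c.class_id for c in res.classes
                          if truth.sample_node[c.member_samples[0]] == "N00")
        clades = phylo.partition_lineages(res.network, root_class)
        _, class_to_node = pipeline.true_class_graph(truth, res.classes)
        groups = {}
        for cid, lab in clades.assignments.items():
            if cid != root_class:
                groups.setdefault(lab, set()).add(class_to_node[cid][0])
        # each non-root clade contains exactly one founder-daughter subtree
        assert sorted(groups.values(), key=sorted) == [{"A"}, {"B"}, {"C"}]

    def test_missing_root_raises(self, default_lineage):
        with pytest.raises(ValueError, match="not present"):
            phylo.partition_lineages(default_lineage.network, "GT-99")
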