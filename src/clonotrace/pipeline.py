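"""End-to-end composition of the analysis stages.

These helpers wire the module surfaces together in the pipeline order
(simulate -> filter -> collapse -> ancestry -> network -> panel -> report)
and provide the truth-comparison utilities used to audit recovery on
simulated cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import ancestry, genotypes, io, phylo, simdata, varfilter

log = logging.getLogger(__name__)


@dataclass
class FilterRunResult:
    somatic_sites: list[str]
    removed_germline: dict[str, list[str]]
    verdicts: list
    passed_by_site: dict[str, set[str]]

    def precision_recall(self, truth: simdata.TruthRecord) -> tuple[float, float]:
        true_set = set(truth.somatic_site_ids())
        called = set(self.somatic_sites)
        tp = len(called & true_set)
        precision = tp / len(called) if called else 0.0
        recall = tp / len(true_set) if true_set else 0.0
        return precision, recall


def run_filters(vcf_path, fasta_path, bed_path, germline_lookup,
                config: varfilter.FilterConfig | None = None) -> FilterRunResult:
    """Candidate VCF -> high-confidence somatic site set.

    ``germline_lookup`` is either the TSV emitted by the simulator or a pair
    of site->alt dicts (reference clone, alternate haplophase).
    """
    config = config or varfilter.FilterConfig()
    _, calls = io.read_vcf(vcf_path)
    reference = io.ReferenceSequence(fasta_path)
    exclusion = io.BedIntervals.from_file(bed_path) if bed_path else None
    verdicts, passed_by_site = varfilter.filter_calls(calls, reference, config,
                                                      exclusion=exclusion)
    alleles = {c.site_id: (c.ref, c.alt) for c in calls}
    candidates = {s: alleles[s] for s in passed_by_site}
    if isinstance(germline_lookup, tuple):
        refclone, althap = germline_lookup
    else:
        import pandas as pd
        df = pd.read_csv(germline_lookup, sep="\t")
        refclone = dict(df[df.source == "refclone"][["site_id", "alt"]].values)
        althap = dict(df[df.source == "althap"][["site_id", "alt"]].values)
    somatic, removed = varfilter.subtract_germline(candidates, refclone, althap)
    return FilterRunResult(somatic_sites=somatic, removed_germline=removed,
                           verdicts=verdicts, passed_by_site=passed_by_site)


@dataclass
class LineageResult:
    matrix: genotypes.GenotypeMatrix          # over retained shared sites
    partition: genotypes.SharingPartition
    retained_sites: list[str]
    classes: list[genotypes.GenotypeClass]
    network: phylo.CloneNetwork


def reconstruct_lineages(matrix: genotypes.GenotypeMatrix,
                         epsilon: int = 0) -> LineageResult:
    """Genotype matrix -> shared-site curation -> classes -> MJ network."""
    part = genotypes.partition_sharing(matrix)
    shared = matrix.subset_sites(part.shared_sites)
    retained, _ = genotypes.curate_shared(shared)
    curated = matrix.subset_sites(retained)
    classes = genotypes.collapse_genotypes(curated)
    network = phylo.median_joining(classes, site_ids=retained, epsilon=epsilon)
    return LineageResult(matrix=curated, partition=part, retained_sites=retained,
                         classes=classes, network=network)


def true_class_graph(truth: simdata.TruthRecord,
                     classes: list[genotypes.GenotypeClass]) -> tuple[nx.Graph, dict[str, str]]:
    """Map each genotype class to its true clone node and build the true
    propagation topology over mapped nodes (for isomorphism checks)."""
    class_to_node: dict[str, str] = {}
    for c in classes:
        nodes = {truth.sample_node[s] for s in c.member_samples}
        if len(nodes) != 1:
            raise ValueError(f"class {c.class_id} mixes clone nodes {sorted(nodes)}")
        class_to_node[c.class_id] = nodes.pop()
    expected = nx.Graph()
    expected.add_nodes_from(truth.config.propagation_tree.nodes)
    expected.add_edges_from(truth.config.propagation_tree.edges)
    return expected, class_to_node


def network_matches_tree(truth: simdata.TruthRecord,
                         result: LineageResult) -> bool:
    """Label-respecting topology comparison of the inferred network against
    the true propagation tree (median nodes must be absent when every clone
    node was sampled)."""
    try:
        expected, class_to_node = true_class_graph(truth, result.classes)
    except ValueError:
        return False
    if set(class_to_node.values()) != set(expected.nodes):
        return False
    g = result.network.graph
    if result.network.median_nodes():
        return False
    actual_edges = {frozenset((class_to_node[u], class_to_node[v])) for u, v in g.edges}
    expected_edges = {frozenset(e) for e in expected.edges}
    return actual_edges == expected_edges


def nj_matches_tree(truth: simdata.TruthRecord, result: LineageResult) -> bool:
    """Robinson-Foulds-zero check of the NJ topology against the true tree.

    The true propagation tree (with every node sampled) induces, for each
    internal edge, a bipartition of the clone set; the NJ tree over hamming
    distances must show exactly the same set of non-trivial bipartitions.
    """
    _, class_to_node = true_class_graph(truth, result.classes)
    vectors = {class_to_node[c.class_id]: c.state_vector for c in result.classes}
    dm = ancestry.pairwise_distance(vectors, metric="hamming")
    tree = phylo.neighbor_joining(dm)
    taxa = frozenset(vectors)

    def bipartitions(graph: nx.Graph, leaves: frozenset) -> set[frozenset]:
        out = set()
        for u, v in graph.edges:
            h = graph.copy()
            h.remove_edge(u, v)
            side = frozenset(n for n in nx.node_connected_component(h, u) if n in leaves)
            if 1 < len(side) < len(leaves) - 1:
                out.add(min(side, leaves - side, key=sorted))
        return out

    # every clone (sampled ancestors included) is a leaf label of the NJ
    # tree; zero-length internal NJ edges are resolutions of the true tree's
    # multifurcations, so contract them before comparing split sets
    nj_graph = tree.graph.copy()
    changed = True
    while changed:
        changed = False
        for u, v, data in list(nj_graph.edges(data=True)):
            if u not in taxa and v not in taxa and data["length"] < 1e-9:
                nj_graph = nx.contracted_edge(nj_graph, (u, v), self_loops=False)
                changed = True
                break
    true_graph = nx.Graph(truth.config.propagation_tree.edges)
    return bipartitions(nj_graph, taxa) == bipartitions(true_graph, taxa)


def recovery_experiment(seed: int, n_replicates: int = 100,
                        n_clones_range: tuple[int, int] = (8, 12),
                        min_edge_mutations: int = 3) -> dict[str, float]:
    """Replicated end-to-end recovery audit on homoplasy-free cohorts.

    Each replicate simulates a random propagation tree of 8-12 clones (two
    sampled plants per clone, >= 3 mutations per edge so every clone is
    genotypically distinct), reconstructs lineages, and scores: median-joining
    topology identity with the true tree, NJ split identity (Robinson-Foulds
    zero after collapsing zero-length resolutions), whether the true founder
    class ranks first among ancestral candidates, and allele-polarisation
    accuracy at the determined sites.
    """
    rng = np.random.default_rng(seed)
    mj_ok = nj_ok = rank1_ok = 0
    pol_correct = pol_total = 0
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        n_clones = int(rng.integers(n_clones_range[0], n_clones_range[1] + 1))
        tree = simdata.random_propagation_tree(n_clones, seed=rep_seed)
        cfg = simdata.small_config(seed=rep_seed, propagation_tree=tree,
                                   samples_per_node=2,
                                   min_edge_mutations=min_edge_mutations,
                                   mu_edge=4.0, mu_private=8.0,
                                   germline_het_sites=0, n_parent_ambiguous=2)
        truth = simdata.simulate_clonal_lineage(cfg)
        result = reconstruct_lineages(truth.genotype_matrix())
        mj_ok += network_matches_tree(truth, result)
        nj_ok += nj_matches_tree(truth, result)
        att, ranking, polarity = ancestral_analysis(truth, result)
        founder_class = next(c.class_id for c in result.classes
                             if truth.sample_node[c.member_samples[0]] == cfg.root)
        rank1_ok += ranking[0].class_id == founder_class
        somatic = set(truth.somatic_site_ids())
        for sid in att.determined_sites:
            pol_total += 1
            pol_correct += (polarity[sid] == ancestry.DERIVED_IS_HET and sid in somatic)
    return {"n": n_replicates, "mj_topology_ok": mj_ok, "nj_rf_zero": nj_ok,
            "founder_ranked_first": rank1_ok,
            "polarization_accuracy": pol_correct / pol_total if pol_total else 0.0}


def ancestral_analysis(truth: simdata.TruthRecord, result: LineageResult):
    """Parent tables -> ancestral genotype -> candidate ranking -> polarity."""
    att = ancestry.infer_ancestral(truth.parent1, truth.parent2, result.retained_sites)
    ranking = ancestry.rank_ancestral_candidates(result.classes, att,
                                                 result.retained_sites,
                                                 network=result.network)
    polarity = ancestry.polarize_alleles(result.retained_sites, att)
    return att, ranking, polarity
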