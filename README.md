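# clonotrace

Somatic-SNV clonal lineage reconstruction for vegetatively propagated
cultivars.

Clonally propagated crops — grapevine being the canonical case — accumulate
spontaneous somatic mutations over centuries of cutting-based multiplication.
Because every new somatic SNV arises on one chromosome copy, these markers are
heterozygous and are inherited by every plant propagated downstream of the
mutation event. The set of somatic SNVs carried by each plant therefore
encodes the propagation history of the cultivar: plants collapse into
multilocus *genotype classes* (GT-00, GT-01, ...), classes arrange into a
phylogenetic network whose edges are the mutations separating them, and the
class closest to the genotype of the cultivar's original seedling is the
ancestral lineage from which all others derive. `clonotrace` implements this
whole analysis as a tested, reusable pipeline for geneticists studying
intra-varietal diversity:

* **varfilter** — stringent post-calling filters on candidate VCF calls
  (genotype quality, depth, allele balance, strand bias, homopolymer context,
  mappability, het-only), germline subtraction against the reference-clone and
  alternate-haplophase lookups, and two-state re-genotyping of target
  positions from pileup summaries.
* **genotypes** — sample x SNV matrix, singleton/shared partition, missing-data
  curation, the six-class mutation spectrum (transition fraction), and
  collapse into genotype classes.
* **ancestry** — the in-silico ancestral genotype from the two parents
  (a site is ancestrally homozygous-reference iff both parents are;
  parental heterozygosity excludes the site), classical PCoA, pairwise
  relatedness (similarity-index moment estimator in the Wang family), ranking
  of ancestral candidates, and ancestral/derived allele polarisation.
* **phylo** — median-joining networks (epsilon-relaxed minimum spanning
  network plus cost-reducing majority-consensus medians) and neighbor-joining
  trees, per-edge mutation lists, and clade partitions.
* **panel** — a minimal branch-representative SNV panel with >= 60 bp assay
  flanks, and exact-match assignment of newly genotyped samples to classes
  (minting new GT-xx labels for novel profiles).
* **loh** — leaf-vs-root loss-of-heterozygosity profiles along a chromosome
  and periclinal-chimera detection (L2-layer deletions show LoH in
  adventitious roots but not in leaves).
* **simdata** — a clonal-propagation simulator (founder cross, regional
  dissemination tree, transition-biased heterozygous mutations, sequencing
  noise, germline contaminants, filterable artifacts, chimeric deletions)
  that makes every stage testable end to end with no external data.

## The model in brief

Given a rooted propagation tree, each edge *e* receives *K<sub>e</sub>* ~
Poisson(mu<sub>e</sub>) new heterozygous SNVs under infinite sites; a plant's
genotype is the union of mutations on its root path. Genotype classes are the
distinct 0/1 (hom-ref/het) vectors over the shared, fully genotyped SNVs.
The median-joining network connects classes with hamming-distance edges and
inferred median (unsampled intermediate) nodes; on homoplasy-free data it
reproduces the propagation tree exactly. The ancestral genotype (the founder
seedling's states) is determined at sites where both parents are homozygous
reference, and the het state at those sites is the derived allele, so
derived-allele counts order regions along dissemination routes.

## Worked example

```python
from clonotrace import simdata, pipeline, panel

cfg = simdata.SimConfig(seed=7)                      # 13-clone regional tree, 39 plants
truth = simdata.simulate_clonal_lineage(cfg)
result = pipeline.reconstruct_lineages(truth.genotype_matrix())
att, ranking, polarity = pipeline.ancestral_analysis(truth, result)
design = panel.select_key_snvs(result.network)

print(f"samples: {len(truth.sample_ids)}")
print(f"somatic SNVs: {len(truth.somatic_site_ids())} "
      f"({len(result.partition.singleton_sites)} singletons, "
      f"{len(result.retained_sites)} shared retained)")
print(f"genotype classes: {len(result.classes)} "
      f"(max frequency {max(c.frequency for c in result.classes)})")
print(f"network: {len(result.network.observed_nodes())} observed nodes, "
      f"{result.network.graph.number_of_edges()} edges")
top = ranking[0]
print(f"top ancestral candidate: {top.class_id} "
      f"(distance to ancestral genotype {top.distance_to_att:.0f}, frequency {top.frequency})")
print(f"panel: {len(design.sites)} SNVs covering {len(design.edge_coverage)} edges")
```

prints

```
samples: 39
somatic SNVs: 1267 (1222 singletons, 45 shared retained)
genotype classes: 13 (max frequency 3)
network: 13 observed nodes, 12 edges
top ancestral candidate: GT-00 (distance to ancestral genotype 0, frequency 3)
panel: 30 SNVs covering 12 edges
```

Most simulated SNVs are plant-specific singletons (mutations on each plant's
own sampling branch); only the 45 shared SNVs are phylogenetically
informative. The 39 plants collapse to 13 classes — one per simulated clone —
the network's 12 edges reproduce the 12 propagation edges, the founder class
GT-00 sits at hamming distance 0 from the parent-determined ancestral
genotype, and the panel covers every branch with up to 3 SNVs.

The same stages are available from the shell:

```bash
clonotrace simulate --seed 7 --out sim/
clonotrace filter --vcf sim/candidates.vcf --fasta sim/reference.fasta \
    --exclude-bed sim/lowmap.bed --germline-lookup sim/germline_lookup.tsv --out filtered/
clonotrace collapse --matrix sim/truth_genotypes.tsv --out-classes classes.tsv
clonotrace network --matrix sim/truth_genotypes.tsv --out net/
clonotrace panel --matrix sim/truth_genotypes.tsv --fasta sim/reference.fasta --out panel.tsv
```

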