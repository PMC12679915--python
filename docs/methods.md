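# Methods

## The analysis problem

A vegetatively propagated cultivar is a single genet multiplied by cuttings.
Somatic point mutations arise during this multiplication, always on one
chromosome copy, so a true somatic SNV is heterozygous in every plant that
carries it and is inherited by everything propagated downstream of the plant
in which it arose. `clonotrace` reconstructs that propagation history from
per-sample candidate variant calls: it curates the calls to a high-confidence
somatic set, collapses plants into multilocus genotype classes, infers the
genotype the original seedling must have had from its two parents, builds
median-joining and neighbor-joining phylogenies over the classes, designs a
small genotyping panel representing every branch, and profiles
loss-of-heterozygosity (LoH) to detect periclinal chimerism.

## Somatic-call filtering (varfilter)

Candidate calls (one per sample per VCF record) are judged against every
criterion without short-circuiting, so a verdict carries the complete list of
failing codes. Defaults, all overridable in `FilterConfig`:

| parameter | default | rationale |
|---|---|---|
| `min_gq` | 30 (phred) | conventional "99.9% confident genotype" floor |
| `min_depth` | 10 reads | below this a het call is unreliable |
| `max_depth` | 3 x the sample's own median depth | collapsed repeats attract excess coverage; per-sample normalisation because cohort coverage varies |
| `allele_balance_window` | [0.25, 0.75] | a true het has alt fraction near 0.5; the lower bound echoes a 25% minimum alternate-fraction calling convention |
| `max_strand_skew` | 0.9 | > 90% of alt reads on one strand indicates a mapping/chemistry artifact |
| `homopolymer_min_run` | 5 bp | mononucleotide runs of >= 5 inflate sequencing error |
| `require_het` | on | somatic SNVs in a clonal lineage are het by construction |

The homopolymer test fails a site when a mononucleotide run of at least the
configured length begins or ends within 1 bp of it — a standard proxy for
slippage-induced miscalls. Low mappability is a BED interval lookup, not a
recomputation, mirroring the use of precomputed repeat/mappability tracks.
The published analyses this pipeline generalises name these criteria classes
but keep the numeric thresholds in external scripts; the values above are
this package's declared defaults, not inferred constants.

Germline subtraction removes any site whose alternate allele is evidenced in
the reference-clone resequencing data, matches the alternate haplophase of
the diploid assembly, or (optionally) is carried by a parent cultivar. The
partition is exact — somatic plus removed equals the input — and missing
lookups leave a site retained and logged.

Target re-genotyping (`genotype_targets`) consumes quality-filtered pileup
counts (the caller is expected to have applied base/mapping-quality floors
such as BQ >= 20, MQ >= 20): depth < 8 is a no-call, alt reads <= 1 with
adequate depth is hom-ref, alt reads >= 4 with alt fraction inside the
allele-balance window is het, anything else is missing.

## Genotype classes (genotypes)

The matrix holds states {0 hom-ref, 1 het, NA}. Sites het in exactly one
sample are singletons; shared sites (het in >= 2) are the phylogenetically
informative markers. Curation drops any shared site with missing data in any
sample — the conservative published rule; no imputation. Classes are distinct
state vectors over the retained sites, numbered GT-00 upward by descending
frequency then lexicographic vector (deterministic; an optional relabel map
reproduces a historical published numbering). The mutation spectrum collapses
the twelve substitutions onto the six pyrimidine-strand classes (C>T with
G>A, etc.); the transition fraction is (C>T + T>C)/total.

## Ancestral genotype and relatedness (ancestry)

At a retained somatic site, both parents homozygous reference forces the
founder seedling to be homozygous reference. Any parental heterozygosity,
homozygous-alternate state or missing datum makes the founder state a coin
flip or impossible to determine, so the site is excluded; both parents
hom-alt is additionally flagged inconsistent, since such a site cannot be a
somatic variant. Determined ancestral states are therefore always hom-ref.
Distances to the ancestral genotype use pairwise deletion of excluded sites;
full vectors are used everywhere else.

PCoA is classical metric scaling (double-centre −½D², eigendecompose, scale
eigenvectors by the square root of positive eigenvalues); negative
eigenvalues are reported and their axes dropped. On Euclidean distances of
binary vectors (Euclidean = sqrt(hamming)) the configuration reproduces the
input distances to numerical precision.

Pairwise relatedness uses a similarity-index moment estimator in the Wang
family, specialised to biallelic loci with genotypes coded as alt-allele
counts {0, 1, 2}. For a dyad at one locus the genotype pair falls in one of
three categories — identical, homozygote/heterozygote sharing an allele, or
opposite homozygotes — whose probabilities are linear in the two IBD-sharing
coefficients Δ (both allele pairs IBD) and φ (one pair IBD), with
unrelated-baseline terms that are polynomials in the allele frequency.
The three category-moment equations are solved jointly across loci by
weighted least squares with locus weights 1/(2a₂ − a₃), aᵢ = pⁱ + qⁱ, and
r̂ = Δ̂ + φ̂/2. The estimator is unbiased by construction; on simulated dyads
at 200 loci it recovers r ≈ 0.5 for full sibs and r ≈ 0 for unrelated pairs.
Allele frequencies default to those of the supplied panel counted once per
genotype class (not per plant), so clonal redundancy does not distort them; a
sample-weighted mode and user-supplied frequencies are available.

Ancestral candidates are ranked by (1) ascending hamming distance to the
determined ancestral states, breaking ties by (2) majority support at the
excluded (parent-ambiguous) sites — a class carrying a state unique to itself
there is more plausibly derived than ancestral — then (3) descending class
frequency, then (4) descending network degree. Allele polarisation marks the
het state derived at every determined site and undetermined elsewhere.

## Phylogenies (phylo)

Each somatic SNV is one binary character (het = derived); heterozygous
genotypes are not split into haplotypes, because with het-only somatic states
the character coding is already unambiguous.

The median-joining construction follows the classic intraspecific recipe.
An ε-relaxed minimum spanning network keeps an edge (u, v) iff
d(u, v) ≤ λ(u, v) + ε, where λ is the minimax connection cost; ε = 0 (the
default, matching common practice) gives the union of all minimum spanning
trees. Majority-consensus medians of node triplets are added one at a time,
choosing the candidate that most reduces the minimum spanning cost of the
node set (ties broken by lexicographic vector), until no candidate reduces
it; medians whose removal leaves the cost unchanged are pruned. Candidate
triplets are drawn from all current nodes rather than only connected triples
— a deterministic superset that leaves results unchanged on homoplasy-free
data because additions require a strict cost reduction. Per-edge mutation
lists are the symmetric differences of endpoint vectors, so every edge length
equals the hamming distance of its endpoints (asserted after construction).

Neighbor joining is the standard Q-criterion agglomeration with
deterministic tie-breaking by sorted id pair. A negative branch length is
clamped to zero and the excess moved onto the sibling branch, preserving the
pair's path length. On additive distances the tree is exact; on
homoplasy-free clonal data, where sampled ancestors sit at internal points,
the binary NJ tree resolves multifurcations with zero-length edges, which are
contracted before topology comparison.

Clade partition removes the root class; each remaining connected component is
a candidate clade, components with fewer observed classes than
`min_branch_size` fold into the root clade, and labels A, B, C... follow
descending clade size.

## Panel design and assignment (panel)

Every network edge contributes min(`max_per_edge`, edge length) SNVs, default
cap 3 with a floor of 1, preferring chromosomes least represented in the
panel so far (ties by site id) so the assay spreads across the genome. Assay
flanks of >= 60 bp are cut from the reference strand with BED-style 0-based
half-open arithmetic; known variants within a flank's reach are reported as
warnings since they compromise primer specificity. Assignment is exact-match
on the called (non-missing) panel sites — the assay is two-state by design —
requiring 90% site coverage by default: one match assigns the class, zero
matches mints a new GT-xx label (one per distinct novel profile), several
matches are reported ambiguous rather than resolved by distance.

## LoH and chimerism (loh)

Leaves develop from meristem layers L1+L2; adventitious roots from L2 only.
At markers verified heterozygous in the unmutated reference plant, a het call
is "het-retained" and any homozygous call is LoH. A sample is a periclinal
chimera when some marker is het-retained in one tissue and LoH in the other.
LoH segments are maximal runs of LoH markers; missing calls break segments
(no deletion span is invented across a gap). Pattern identity is the root
(L2) state vector — the deletions being tracked are L2 events and leaf
profiles mix layers — with a strict mode requiring both tissues to match;
patterns are labelled I, II, ... in order of first appearance over samples
sorted by id. A phenotype present without any LoH is simply reported as such
(an alteration other than a hemizygous deletion); no lesion-class inference
is attempted.

## The simulator (simdata)

The generator produces the statistical structure the analysis assumes, not
reads: evidence is summarised at VCF fields (GT, DP, AD, GQ, SAF/SAR).

* **Founder**: one allele drawn per parent per site; sites with a het parent
  are recorded ambiguous.
* **Propagation**: a rooted tree with region labels; per edge,
  K ~ Poisson(`mu_edge`, default 4) new SNVs at uniform unused positions
  (infinite sites — mutations are lineage markers, so no site mutates twice);
  per sampled plant, K ~ Poisson(`mu_private`, default 30) singleton SNVs on
  its own sampling branch. With the default 13-node tree (depth <= 4, three
  plants per node, 39 plants) per-plant totals fall in the ~19-88 range
  observed in resequenced clonal cohorts. A `min_edge_mutations` floor
  supports homoplasy-free recovery experiments; per-edge rate overrides model
  the strongly heterogeneous branch lengths real cohorts show.
* **Mutation types**: transitions with probability `ts_fraction` = 0.674
  (the transition bias reported for somatic spectra in clonal crops),
  otherwise a uniform transversion partner.
* **Noise**: depth ~ negative binomial (mean 60, size 8); het alt fraction ~
  Beta centred on 0.5 (concentration 40) with binomial read sampling; strand
  counts ~ Binomial(0.5); GQ uniform on [60, 99]. Non-carriers get a 0.2%
  alt-read error rate.
* **Contaminants and artifacts**: germline het sites present in every plant
  and evidenced in the reference-clone and/or alternate-haplophase lookups
  (30% also parent-carried); injected false candidates that each violate one
  filter by construction — GQ in [2, 15], 100% one-strand alt reads, a
  planted mononucleotide run of 6 starting 1 bp from the site, or placement
  inside an emitted low-mappability BED interval. True somatic and germline
  positions avoid the BED intervals, as a mappability-aware caller would.
* **Chimeras**: `simulate_chimeric_loh` applies per-layer deletion intervals
  over an ordered marker ladder; roots reflect L2 only, leaves require both
  layers deleted to lose heterozygosity.

One `numpy` generator seeded from `SimConfig.seed` drives the lineage
(emission uses the derived stream `[seed, 1]`); identical config and seed
give byte-identical outputs. Emission registers its injected artifact sites
in the truth record so audits can compare verdicts to site classes.

What the simulator does *not* emulate: alignment and calling error structure
beyond the summarised fields (no read-level errors, no mapping ambiguity
beyond the BED mask), homoplasy/back-mutation, copy-number variation,
inter-sample contamination, and index hopping. Passing tests therefore
demonstrate correctness of the analysis logic under the stated generative
assumptions, not robustness to every failure mode of real resequencing data.

## Problem sizes and numerical conventions

Validation runs use a 39-plant default cohort (~1,250 somatic + 300 germline
+ 100 artifact sites over a 19 x 120 kb genome) and 100 replicated 8-12-clone
cohorts on reduced genomes — sizes chosen so the full audit completes in
seconds while leaving every per-site computation identical to a full-genome
run (all coordinates and formats are genome-scale-agnostic). Tie-breaks are
lexicographic everywhere (site ids, class ids, vectors) for exact
reproducibility. Coordinates are 1-based in VCF and site ids, 0-based
half-open in BED and flank extraction, converted only at the I/O boundary.
PCoA drops eigenvalues below 1e-9 of the spectrum scale; NJ treats Q-value
ties beyond 1e-12 as exact ties.

## Known limitations

* Median search evaluates all node triplets; fine for the tens of classes
  this analysis targets, quadratic-cubic beyond that.
* The relatedness estimator is the biallelic specialisation of the
  similarity-index family; multi-allelic markers (e.g. SSRs) are out of scope.
* Exact-match panel assignment cannot absorb genotyping error at a called
  site; such a sample surfaces as a new or ambiguous genotype for manual
  review rather than being force-assigned.
* The missing-data curation rule is the only automated site-removal step;
  visual (IGV-style) curation of borderline calls is not reproduced.
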