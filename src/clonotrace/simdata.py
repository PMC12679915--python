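"""Clonal-propagation simulator.

Generates fully synthetic inputs with the statistical structure the downstream
analysis assumes: an F1 founder drawn from two parental genotype tables, a
rooted regional propagation tree along which heterozygous somatic SNVs
accumulate (infinite-sites, transition-biased), multi-sample candidate VCFs
with sequencing noise and injected germline/artifact records, and paired
leaf/root marker tables carrying layer-specific hemizygous deletions
(periclinal chimeras).

All randomness flows through one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .util import BASES, GT, TRANSITIONS, site_id, site_sort_key

SOMATIC = "somatic"
GERMLINE = "germline"
ARTIFACT = "artifact"

#: transversion partners per reference base
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


def default_propagation_tree() -> nx.DiGraph:
    """A 13-clone regional dissemination tree.

    Shape emulates a single origin region (RJ) with a stepwise westward
    spread through intermediate regions (RD) towards terminal ones (TO, DO,
    AL), plus shallow local offshoots — the kind of sequential human-mediated
    dispersal a traditional cultivar undergoes.
    """
    t = nx.DiGraph()
    regions = {
        "N00": "RJ", "N01": "RJ", "N02": "RJ", "N03": "NV", "N04": "RJ",
        "N05": "RD", "N06": "TO", "N07": "RD", "N08": "DO", "N09": "AL",
        "N10": "CR", "N11": "PN", "N12": "CG",
    }
    for n, r in regions.items():
        t.add_node(n, region=r)
    t.add_edges_from([
        ("N00", "N01"), ("N00", "N02"), ("N00", "N03"), ("N00", "N11"),
        ("N01", "N04"), ("N02", "N05"), ("N05", "N06"), ("N05", "N07"),
        ("N05", "N12"), ("N07", "N08"), ("N08", "N09"), ("N03", "N10"),
    ])
    return t


def random_propagation_tree(n_clones: int, seed: int, n_regions: int = 5) -> nx.DiGraph:
    """Random rooted tree by uniform attachment, with cyclic region labels —
    the replicate topologies used for recovery experiments."""
    rng = np.random.default_rng(seed)
    t = nx.DiGraph()
    region_codes = [f"R{i:02d}" for i in range(n_regions)]
    t.add_node("N00", region=region_codes[0])
    for i in range(1, n_clones):
        parent = f"N{int(rng.integers(0, i)):02d}"
        t.add_node(f"N{i:02d}", region=region_codes[i % n_regions])
        t.add_edge(parent, f"N{i:02d}")
    return t


@dataclass
class ArtifactRates:
    """Counts of injected false-candidate records per emitted VCF."""

    low_gq: int = 30
    strand_bias: int = 30
    homopolymer: int = 30
    low_mappability: int = 10

    def total(self) -> int:
        return self.low_gq + self.strand_bias + self.homopolymer + self.low_mappability


@dataclass
class DepthModel:
    """Negative-binomial per-call sequencing depth (mean, dispersion=NB size)."""

    mean: float = 60.0
    dispersion: float = 8.0


@dataclass
class LoHConfig:
    n_markers: int = 48
    chrom: str = "B_chr02"


@dataclass
class SimConfig:
    """Study conditions for one simulated clonal cohort.

    Defaults emulate the published cohort scale: a 13-node propagation tree
    sampled 3x per node (39 plants), ~30 private (singleton) mutations per
    plant plus ~4 shared mutations per propagation edge so per-plant totals
    fall in the 19-88 range, and a 67.4% transition fraction.
    """

    seed: int = 7
    n_regions: int = 9
    propagation_tree: nx.DiGraph = field(default_factory=default_propagation_tree)
    samples_per_node: int = 3
    mu_edge: float = 4.0
    mu_private: float = 30.0
    min_edge_mutations: int = 0
    edge_mu_overrides: dict = field(default_factory=dict)
    ts_fraction: float = 0.674
    n_chroms: int = 19
    chrom_length: int = 120_000
    germline_het_sites: int = 300
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    depth_model: DepthModel = field(default_factory=DepthModel)
    het_allele_balance: float = 40.0  # Beta concentration around 0.5
    gq_range: tuple[int, int] = (60, 99)
    n_parent_ambiguous: int = 3
    homopolymer_run_length: int = 6
    n_lowmap_intervals_per_chrom: int = 3
    lowmap_interval_length: int = 2000
    loh: LoHConfig = field(default_factory=LoHConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ts_fraction <= 1.0:
            raise ValueError("ts_fraction must be in [0, 1]")
        if self.mu_edge < 0 or self.mu_private < 0:
            raise ValueError("mutation rates must be >= 0")
        for name in ("samples_per_node", "n_chroms", "chrom_length",
                     "germline_het_sites", "min_edge_mutations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t = self.propagation_tree
        roots = [n for n in t if t.in_degree(n) == 0]
        if len(roots) != 1 or not nx.is_arborescence(t):
            raise ValueError("propagation_tree must be a rooted tree (single root, acyclic, connected)")

    @property
    def root(self) -> str:
        t = self.propagation_tree
        return next(n for n in t if t.in_degree(n) == 0)

    @property
    def chroms(self) -> list[str]:
        return [f"B_chr{i:02d}" for i in range(1, self.n_chroms + 1)]


@dataclass
class SiteTruth:
    site_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    cls: str  # somatic | germline | artifact
    origin_edge: tuple[str, str] | None = None
    artifact_kind: str | None = None
    germline_evidence: frozenset = frozenset()


@dataclass
class TruthRecord:
    """Complete ground truth for one simulated cohort."""

    config: SimConfig
    sample_ids: list[str]
    sample_node: dict[str, str]
    node_sites: dict[str, set[str]]       # somatic sites carried by a clone node
    sample_private: dict[str, set[str]]   # singleton sites per sampled plant
    sites: dict[str, SiteTruth]
    ref_seqs: dict[str, np.ndarray]       # chrom -> uint8 index into BASES
    bed_intervals: list[tuple[str, int, int]]  # 0-based half-open low-mappability
    refclone_alt: dict[str, str]          # germline evidence lookups
    althap_alt: dict[str, str]
    parent1: dict[str, GT]                # parental states at somatic sites
    parent2: dict[str, GT]
    parent_ambiguous_sites: list[str]

    # -- derived views -------------------------------------------------
    def somatic_site_ids(self) -> list[str]:
        return sorted((s for s, t in self.sites.items() if t.cls == SOMATIC),
                      key=site_sort_key)

    def germline_site_ids(self) -> list[str]:
        return sorted((s for s, t in self.sites.items() if t.cls == GERMLINE),
                      key=site_sort_key)

    def artifact_site_ids(self) -> list[str]:
        return sorted((s for s, t in self.sites.items() if t.cls == ARTIFACT),
                      key=site_sort_key)

    def sample_sites(self, sample: str) -> set[str]:
        """All somatic sites at which a sampled plant is heterozygous."""
        return self.node_sites[self.sample_node[sample]] | self.sample_private[sample]

    def carriers(self, sid: str) -> set[str]:
        return {s for s in self.sample_ids if sid in self.sample_sites(s)}

    def shared_site_ids(self) -> list[str]:
        """Somatic sites carried by >= 2 sampled plants (the lineage markers)."""
        return sorted((s for s in self.somatic_site_ids() if len(self.carriers(s)) >= 2),
                      key=site_sort_key)

    def genotype_matrix(self, sites: list[str] | None = None):
        from .genotypes import GenotypeMatrix
        if sites is None:
            sites = self.somatic_site_ids()
        samples = sorted(self.sample_ids)
        grid = np.zeros((len(samples), len(sites)), dtype=np.int8)
        for i, sample in enumerate(samples):
            carried = self.sample_sites(sample)
            for j, sid in enumerate(sites):
                if sid in carried:
                    grid[i, j] = GT.HET
        return GenotypeMatrix(sample_ids=samples, site_ids=list(sites), states=grid)

    def true_class_of(self, sample: str) -> str:
        """True genotype-class label = the clone node the plant was sampled from."""
        return self.sample_node[sample]

    def ref_base(self, chrom: str, pos: int) -> str:
        return BASES[self.ref_seqs[chrom][pos - 1]]


@dataclass
class EmittedPaths:
    vcf: Path
    fasta: Path
    bed: Path
    truth_tsv: Path
    germline_lookup_tsv: Path


@dataclass
class FounderResult:
    genotype: dict[str, GT]
    ambiguous_sites: list[str]


def simulate_founder(parent1: dict[str, GT], parent2: dict[str, GT],
                     seed: int) -> FounderResult:
    """Draw an F1 founder genotype: one allele per parent per site.

    Sites at which either parent is heterozygous are flagged ambiguous —
    the founder state there is a coin flip, exactly the situation that later
    forces exclusion from the inferred ancestral genotype.
    """
    s1, s2 = set(parent1), set(parent2)
    if s1 != s2:
        first = sorted(s1 ^ s2, key=site_sort_key)[0]
        raise ValueError(f"parental tables cover different sites; first discordant: {first}")
    rng = np.random.default_rng(seed)
    genotype: dict[str, GT] = {}
    ambiguous: list[str] = []
    for sid in sorted(parent1, key=site_sort_key):
        alleles = 0
        amb = False
        for state in (parent1[sid], parent2[sid]):
            if state == GT.HOM_ALT:
                alleles += 1
            elif state == GT.HET:
                alleles += int(rng.integers(0, 2))
                amb = True
            elif state != GT.HOM_REF:
                raise ValueError(f"parental state at {sid} must be hom-ref/het/hom-alt")
        genotype[sid] = GT(alleles)
        if amb:
            ambiguous.append(sid)
    return FounderResult(genotype=genotype, ambiguous_sites=ambiguous)


class _PositionPool:
    """Uniform draws of unused 1-based genome positions, avoiding masked intervals."""

    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 masked: list[tuple[str, int, int]]):
        self.config = config
        self.rng = rng
        self.used: set[tuple[str, int]] = set()
        self.masked: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in masked:
            self.masked.setdefault(chrom, []).append((s, e))
        self.capacity = config.n_chroms * config.chrom_length

    def _is_masked(self, chrom: str, pos: int) -> bool:
        return any(s < pos <= e for s, e in self.masked.get(chrom, ()))

    def draw(self, avoid_masked: bool = True) -> tuple[str, int]:
        if len(self.used) >= self.capacity:
            raise ValueError("requested mutations exceed available genome positions")
        for _ in range(100_000):
            chrom = self.config.chroms[int(self.rng.integers(self.config.n_chroms))]
            pos = int(self.rng.integers(1, self.config.chrom_length + 1))
            if (chrom, pos) in self.used:
                continue
            if avoid_masked and self._is_masked(chrom, pos):
                continue
            self.used.add((chrom, pos))
            return chrom, pos
        raise ValueError("position pool exhausted")  # pragma: no cover

    def draw_in_masked(self) -> tuple[str, int]:
        for _ in range(100_000):
            chrom = self.config.chroms[int(self.rng.integers(self.config.n_chroms))]
            intervals = self.masked.get(chrom)
            if not intervals:
                continue
            s, e = intervals[int(self.rng.integers(len(intervals)))]
            pos = int(self.rng.integers(s + 1, e + 1))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise ValueError("no free masked position")  # pragma: no cover


def _draw_mutation(rng: np.random.Generator, ref: str, ts_fraction: float) -> str:
    if rng.random() < ts_fraction:
        return TRANSITIONS[ref]
    a, b = _TRANSVERSIONS[ref]
    return a if rng.random() < 0.5 else b


def simulate_clonal_lineage(config: SimConfig) -> TruthRecord:
    """Accumulate heterozygous somatic SNVs along the propagation tree.

    Per propagation edge, K ~ Poisson(mu_edge) new sites arise (infinite
    sites: positions never reused) and are inherited by every clone below the
    edge.  Each sampled plant additionally receives K ~ Poisson(mu_private)
    singleton mutations on its own sampling branch.  Mutations are transitions
    with probability ``ts_fraction``, otherwise one of the transversions.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.propagation_tree

    ref_seqs = {c: rng.integers(0, 4, size=config.chrom_length).astype(np.uint8)
                for c in config.chroms}

    bed: list[tuple[str, int, int]] = []
    for chrom in config.chroms:
        for _ in range(config.n_lowmap_intervals_per_chrom):
            start = int(rng.integers(0, config.chrom_length - config.lowmap_interval_length))
            bed.append((chrom, start, start + config.lowmap_interval_length))

    pool = _PositionPool(config, rng, bed)
    sites: dict[str, SiteTruth] = {}

    def new_somatic(edge: tuple[str, str]) -> str:
        chrom, pos = pool.draw()
        ref = BASES[ref_seqs[chrom][pos - 1]]
        alt = _draw_mutation(rng, ref, config.ts_fraction)
        sid = site_id(chrom, pos)
        sites[sid] = SiteTruth(sid, chrom, pos, ref, alt, SOMATIC, origin_edge=edge)
        return sid

    root = config.root
    node_sites: dict[str, set[str]] = {root: set()}
    for parent, child in nx.bfs_edges(tree, root, sort_neighbors=sorted):
        mu = float(config.edge_mu_overrides.get((parent, child), config.mu_edge))
        k = max(int(rng.poisson(mu)), config.min_edge_mutations)
        node_sites[child] = node_sites[parent] | {new_somatic((parent, child)) for _ in range(k)}

    sample_ids: list[str] = []
    sample_node: dict[str, str] = {}
    sample_private: dict[str, set[str]] = {}
    for node in sorted(tree.nodes):
        for k in range(1, config.samples_per_node + 1):
            sample = f"TT-{node}-{k:02d}"
            sample_ids.append(sample)
            sample_node[sample] = node
            kk = int(rng.poisson(config.mu_private))
            sample_private[sample] = {new_somatic((node, sample)) for _ in range(kk)}

    # Germline contaminant sites: heterozygous in every plant, evidenced in the
    # reference-clone reads and/or the alternate haplophase assembly.
    refclone_alt: dict[str, str] = {}
    althap_alt: dict[str, str] = {}
    germline_parent_carrier: dict[str, int] = {}
    for _ in range(config.germline_het_sites):
        chrom, pos = pool.draw()
        ref = BASES[ref_seqs[chrom][pos - 1]]
        alt = _draw_mutation(rng, ref, 0.5)
        sid = site_id(chrom, pos)
        u = rng.random()
        ev = set()
        if u < 0.45:
            ev = {"refclone"}
        elif u < 0.75:
            ev = {"althap"}
        else:
            ev = {"refclone", "althap"}
        if rng.random() < 0.3:
            ev.add("parent")
            germline_parent_carrier[sid] = int(rng.integers(1, 3))
        sites[sid] = SiteTruth(sid, chrom, pos, ref, alt, GERMLINE,
                               germline_evidence=frozenset(ev))
        if "refclone" in ev:
            refclone_alt[sid] = alt
        if "althap" in ev:
            althap_alt[sid] = alt

    # Parental genotypes at the somatic sites: hom-ref everywhere except a few
    # sites where one parent is heterozygous (ambiguous for ancestral inference).
    shared_pool = sorted(
        {s for n, ss in node_sites.items() if n != root for s in ss},
        key=site_sort_key)
    parent1 = {s: GT.HOM_REF for s in sites if sites[s].cls == SOMATIC}
    parent2 = dict(parent1)
    n_amb = min(config.n_parent_ambiguous, len(shared_pool))
    amb_sites = [shared_pool[i] for i in
                 sorted(rng.choice(len(shared_pool), size=n_amb, replace=False))] if n_amb else []
    for sid in amb_sites:
        (parent1 if rng.random() < 0.5 else parent2)[sid] = GT.HET

    return TruthRecord(
        config=config, sample_ids=sample_ids, sample_node=sample_node,
        node_sites=node_sites, sample_private=sample_private, sites=sites,
        ref_seqs=ref_seqs, bed_intervals=bed, refclone_alt=refclone_alt,
        althap_alt=althap_alt, parent1=parent1, parent2=parent2,
        parent_ambiguous_sites=amb_sites)


def _seq_to_str(seq: np.ndarray) -> str:
    return "".join(BASES[b] for b in seq)


def emit_candidate_vcf(truth: TruthRecord, config: SimConfig, out_dir,
                       noise: bool = True, artifacts: bool = True) -> EmittedPaths:
    """Write the candidate multi-sample VCF, reference FASTA, mappability BED,
    truth table and germline lookup tables for one simulated cohort.

    Evidence fields follow the candidate-call contract: GT, DP (depth), AD
    (ref,alt reads), GQ, SAF/SAR (alt reads on forward/reverse strand).  With
    ``noise=False`` every true call gets clean mid-range evidence; with
    ``artifacts=False`` no false candidates are injected.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 1])
    dm, conc = config.depth_model, config.het_allele_balance
    ref_seqs = {c: s.copy() for c, s in truth.ref_seqs.items()}
    sites: dict[str, SiteTruth] = dict(truth.sites)
    pool = _PositionPool(config, rng, truth.bed_intervals)
    for t in truth.sites.values():
        pool.used.add((t.chrom, t.pos))

    run_len = config.homopolymer_run_length

    def inject_artifact(kind: str) -> None:
        if kind == "low_mappability":
            chrom, pos = pool.draw_in_masked()
        elif kind == "homopolymer":
            # plant a mononucleotide run beginning immediately after the site;
            # keep the planted window clear of every other simulated site so
            # their reference context is untouched
            while True:
                chrom, pos = pool.draw()
                if pos + run_len <= config.chrom_length and not any(
                        (chrom, p) in pool.used for p in range(pos + 1, pos + run_len + 1)):
                    break
            base = int(rng.integers(0, 4))
            ref_seqs[chrom][pos:pos + run_len] = base
            if ref_seqs[chrom][pos - 1] == base:  # keep the site itself distinct
                ref_seqs[chrom][pos - 1] = (base + 1) % 4
        else:
            chrom, pos = pool.draw()
        ref = BASES[ref_seqs[chrom][pos - 1]]
        alt = _draw_mutation(rng, ref, 0.5)
        sid = site_id(chrom, pos)
        sites[sid] = SiteTruth(sid, chrom, pos, ref, alt, ARTIFACT, artifact_kind=kind)

    if artifacts:
        ar = config.artifact_rates
        for kind, count in (("low_gq", ar.low_gq), ("strand_bias", ar.strand_bias),
                            ("homopolymer", ar.homopolymer),
                            ("low_mappability", ar.low_mappability)):
            for _ in range(count):
                inject_artifact(kind)
        # register the injected false candidates in the truth record so
        # downstream audits can compare verdicts against site classes
        for sid, t in sites.items():
            if t.cls == ARTIFACT:
                truth.sites.setdefault(sid, t)

    samples = truth.sample_ids
    artifact_carriers = {
        sid: set(rng.choice(samples, size=int(rng.integers(1, 3)), replace=False))
        for sid, t in sites.items() if t.cls == ARTIFACT}

    def nb_depth() -> int:
        n = dm.dispersion
        p = n / (n + dm.mean)
        return max(int(rng.negative_binomial(n, p)), 2)

    def het_fields(kind: str | None = None) -> str:
        if not noise and kind is None:
            return "0/1:60:30,30:99:15:15"
        dp = nb_depth()
        frac = rng.beta(conc / 2, conc / 2)
        ad = int(np.clip(rng.binomial(dp, frac), 1, dp - 1))
        saf = int(rng.binomial(ad, 0.5))
        gq = int(rng.integers(config.gq_range[0], config.gq_range[1] + 1))
        if kind == "low_gq":
            gq = int(rng.integers(2, 16))
        elif kind == "strand_bias":
            saf = ad if rng.random() < 0.5 else 0
        return f"0/1:{dp}:{dp - ad},{ad}:{gq}:{saf}:{ad - saf}"

    def homref_fields() -> str:
        if not noise:
            return "0/0:60:60,0:99:0:0"
        dp = nb_depth()
        ad = int(rng.binomial(dp, 0.002))
        saf = int(rng.binomial(ad, 0.5)) if ad else 0
        gq = int(rng.integers(config.gq_range[0], config.gq_range[1] + 1))
        return f"0/0:{dp}:{dp - ad},{ad}:{gq}:{saf}:{ad - saf}"

    ordered = sorted(sites.values(), key=lambda t: (t.chrom, t.pos))
    vcf_path = out_dir / "candidates.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonotrace-simdata\n")
        for chrom in config.chroms:
            fh.write(f"##contig=<ID={chrom},length={config.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=SAF,Number=1,Type=Integer,Description="Alt reads on forward strand">\n')
        fh.write('##FORMAT=<ID=SAR,Number=1,Type=Integer,Description="Alt reads on reverse strand">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for t in ordered:
            if t.cls == SOMATIC:
                carrier_set = truth.carriers(t.site_id)
                kind = None
            elif t.cls == GERMLINE:
                carrier_set = set(samples)
                kind = None
            else:
                carrier_set = artifact_carriers[t.site_id]
                kind = t.artifact_kind
            cols = [het_fields(kind) if s in carrier_set else homref_fields()
                    for s in samples]
            fh.write(f"{t.chrom}\t{t.pos}\t{t.site_id}\t{t.ref}\t{t.alt}\t100\tPASS\t.\t"
                     "GT:DP:AD:GQ:SAF:SAR\t" + "\t".join(cols) + "\n")

    fasta_path = out_dir / "reference.fasta"
    with open(fasta_path, "w") as fh:
        for chrom in config.chroms:
            fh.write(f">{chrom}\n")
            s = _seq_to_str(ref_seqs[chrom])
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")

    bed_path = out_dir / "lowmap.bed"
    with open(bed_path, "w") as fh:
        for chrom, s, e in sorted(truth.bed_intervals):
            fh.write(f"{chrom}\t{s}\t{e}\n")

    truth_path = out_dir / "truth_sites.tsv"
    rows = [{"site_id": t.site_id, "chrom": t.chrom, "pos": t.pos, "ref": t.ref,
             "alt": t.alt, "class": t.cls,
             "origin_edge": "|".join(t.origin_edge) if t.origin_edge else "",
             "artifact_kind": t.artifact_kind or ""}
            for t in ordered]
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)

    lookup_path = out_dir / "germline_lookup.tsv"
    lk = [{"site_id": s, "source": "refclone", "alt": a}
          for s, a in sorted(truth.refclone_alt.items())]
    lk += [{"site_id": s, "source": "althap", "alt": a}
           for s, a in sorted(truth.althap_alt.items())]
    pd.DataFrame(lk).to_csv(lookup_path, sep="\t", index=False)

    return EmittedPaths(vcf=vcf_path, fasta=fasta_path, bed=bed_path,
                        truth_tsv=truth_path, germline_lookup_tsv=lookup_path)


def simulate_chimeric_loh(n_markers: int,
                          deletion_intervals: dict[str, dict[str, list[tuple[int, int]]]],
                          seed: int = 0, chrom: str = "B_chr02",
                          missing_rate: float = 0.0):
    """Paired leaf/root marker genotypes under layer-specific deletions.

    ``deletion_intervals`` maps sample id -> meristem layer ("L1"/"L2") ->
    list of inclusive 1-based marker-index intervals deleted in that layer.
    Adventitious roots derive from L2 only, so a root marker shows LoH (hom)
    exactly inside an L2 deletion; leaves mix L1+L2 and stay het unless both
    layers are deleted (the periclinal-chimera signature).

    Returns ``(leaf_table, root_table, marker_ids)`` as pandas DataFrames
    (sample x marker) with values "het"/"hom"/"missing".
    """
    rng = np.random.default_rng(seed)
    markers = [f"{chrom}_M{i:02d}" for i in range(1, n_markers + 1)]

    def covered(intervals: list[tuple[int, int]], idx: int) -> bool:
        return any(a <= idx <= b for a, b in intervals)

    for sample, layers in deletion_intervals.items():
        for layer, ivs in layers.items():
            ivs = sorted(ivs)
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 <= b1:
                    raise ValueError(
                        f"overlapping contradictory intervals for {sample}/{layer}: "
                        f"({a1},{b1}) and ({a2},{b2})")
            for a, b in ivs:
                if not (1 <= a <= b <= n_markers):
                    raise ValueError(f"interval ({a},{b}) outside marker range 1..{n_markers}")

    leaf_rows, root_rows = {}, {}
    for sample in sorted(deletion_intervals):
        layers = deletion_intervals[sample]
        l1 = layers.get("L1", [])
        l2 = layers.get("L2", [])
        leaf, root = [], []
        for i in range(1, n_markers + 1):
            in1, in2 = covered(l1, i), covered(l2, i)
            leaf.append("hom" if (in1 and in2) else "het")
            root.append("hom" if in2 else "het")
        if missing_rate > 0:
            for arr in (leaf, root):
                drop = rng.random(n_markers) < missing_rate
                for j in np.flatnonzero(drop):
                    arr[j] = "missing"
        leaf_rows[sample] = leaf
        root_rows[sample] = root

    leaf_df = pd.DataFrame.from_dict(leaf_rows, orient="index", columns=markers)
    root_df = pd.DataFrame.from_dict(root_rows, orient="index", columns=markers)
    return leaf_df, root_df, markers


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A reduced cohort (5 clones, 1 sample each, small genome) for fast tests."""
    t = nx.DiGraph()
    for n, r in [("N0", "RJ"), ("N1", "RJ"), ("N2", "RD"), ("N3", "TO"), ("N4", "RD")]:
        t.add_node(n, region=r)
    t.add_edges_from([("N0", "N1"), ("N0", "N2"), ("N2", "N3"), ("N2", "N4")])
    defaults = dict(seed=seed, propagation_tree=t, samples_per_node=1,
                    mu_edge=4.0, mu_private=8.0, n_chroms=5, chrom_length=50_000,
                    germline_het_sites=40, n_regions=3,
                    artifact_rates=ArtifactRates(5, 5, 5, 3),
                    n_parent_ambiguous=2)
    defaults.update(overrides)
    return SimConfig(**defaults)


def config_to_dict(config: SimConfig) -> dict:
    """JSON-serialisable view of a config (run manifests)."""
    d = dataclasses.asdict(config)
    t = config.propagation_tree
    d["propagation_tree"] = {
        "nodes": {n: t.nodes[n].get("region", "") for n in sorted(t)},
        "edges": sorted(t.edges),
    }
    d["edge_mu_overrides"] = {"|".join(k): v for k, v in config.edge_mu_overrides.items()}
    return d
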