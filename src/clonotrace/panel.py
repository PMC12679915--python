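"""Branch-representative SNV genotyping panel: site selection, assay flank
extraction, and assignment of newly genotyped samples to genotype classes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeClass
from .phylo import CloneNetwork
from .util import GT, parse_site_id

log = logging.getLogger(__name__)


@dataclass
class PanelDesign:
    sites: list[str]
    edge_coverage: dict[tuple[str, str], list[str]]  # network edge -> selected sites
    flanks: dict[str, "Flanks"] = field(default_factory=dict)

    def covers_all_edges(self) -> bool:
        return all(len(v) >= 1 for v in self.edge_coverage.values())


def select_key_snvs(network: CloneNetwork, max_per_edge: int = 3,
                    prefer_distinct_chromosomes: bool = True) -> PanelDesign:
    """Select up to ``max_per_edge`` SNVs from every network edge (floor 1).

    When ``prefer_distinct_chromosomes`` is set, sites on chromosomes least
    represented in the panel so far are preferred (greedy), so the panel
    spreads across the genome; ties always break by site id.
    """
    if max_per_edge < 1:
        raise ValueError("max_per_edge must be >= 1")
    chrom_counts: dict[str, int] = {}
    selected: list[str] = []
    chosen: set[str] = set()
    coverage: dict[tuple[str, str], list[str]] = {}
    for u, v in sorted(network.graph.edges):
        sites = sorted(network.edge_sites(u, v))
        take = min(max_per_edge, len(sites))
        picked: list[str] = []
        pool = list(sites)
        for _ in range(take):
            if prefer_distinct_chromosomes:
                pool.sort(key=lambda s: (chrom_counts.get(parse_site_id(s)[0], 0), s))
            best = pool.pop(0)
            picked.append(best)
            chrom_counts[parse_site_id(best)[0]] = chrom_counts.get(parse_site_id(best)[0], 0) + 1
        coverage[(u, v)] = picked
        for s in picked:
            if s not in chosen:
                chosen.add(s)
                selected.append(s)
    design = PanelDesign(sites=sorted(selected), edge_coverage=coverage)
    log.info("select_key_snvs: %d sites covering %d edges", len(design.sites),
             len(coverage))
    return design


@dataclass
class Flanks:
    site_id: str
    chrom: str
    pos: int
    upstream: str
    downstream: str
    warnings: list[str] = field(default_factory=list)


def extract_flanks(reference, sid: str, flank_bp: int = 60,
                   known_variants: Sequence[str] = ()) -> Flanks:
    """Assay flanks around a panel SNV from the reference strand.

    The 1-based site position converts to 0-based half-open extraction:
    upstream = [pos-1-flank, pos-1), downstream = [pos, pos+flank).  Any known
    variant within +/- flank_bp is reported as a warning (nearby variants
    compromise primer specificity).
    """
    chrom, pos = parse_site_id(sid)
    length = reference.length(chrom)
    if pos < flank_bp + 1 or pos > length - flank_bp:
        raise ValueError(f"{sid}: site within {flank_bp} bp of a contig end")
    up = reference.fetch(chrom, pos - 1 - flank_bp, pos - 1)
    down = reference.fetch(chrom, pos, pos + flank_bp)
    warnings = []
    for other in known_variants:
        ochrom, opos = parse_site_id(other)
        if other != sid and ochrom == chrom and abs(opos - pos) <= flank_bp:
            warnings.append(f"variant {other} within {abs(opos - pos)} bp of {sid}")
    return Flanks(site_id=sid, chrom=chrom, pos=pos, upstream=up,
                  downstream=down, warnings=warnings)


def design_panel(network: CloneNetwork, reference=None, max_per_edge: int = 3,
                 flank_bp: int = 60, known_variants: Sequence[str] = ()) -> PanelDesign:
    """Full design: select sites, then (when a reference is given) attach flanks."""
    design = select_key_snvs(network, max_per_edge=max_per_edge)
    if reference is not None:
        for sid in design.sites:
            design.flanks[sid] = extract_flanks(reference, sid, flank_bp,
                                                known_variants=known_variants)
    return design


ASSIGNED = "assigned"
NEW_GENOTYPE = "new-genotype"
AMBIGUOUS = "ambiguous"
NO_CALL = "no-call"


@dataclass
class AssignmentResult:
    sample_id: str
    status: str
    class_id: str | None = None
    matches: list[str] = field(default_factory=list)
    reason: str | None = None


def assign_sample(sample_id: str, profile: Mapping[str, GT],
                  known_classes: list[GenotypeClass], panel_sites: Sequence[str],
                  min_coverage: float = 0.9) -> AssignmentResult:
    """Assign a two-state panel profile (het / hom-ref / missing) to a class.

    Exact match on the non-missing panel sites to exactly one known class
    gives that class; zero matches mints a new genotype; several matches are
    reported ambiguous without assignment; insufficient coverage is a no-call.
    """
    called = [s for s in panel_sites if profile.get(s, GT.MISSING) != GT.MISSING]
    coverage = len(called) / len(panel_sites) if panel_sites else 0.0
    if coverage < min_coverage:
        return AssignmentResult(sample_id, NO_CALL,
                                reason=f"coverage {coverage:.2f} < {min_coverage:.2f}")
    site_pos = {s: j for j, s in enumerate(panel_sites)}
    matches = []
    for cls in known_classes:
        vec = np.asarray(cls.state_vector)
        if all(vec[site_pos[s]] == profile[s] for s in called):
            matches.append(cls.class_id)
    if len(matches) == 1:
        return AssignmentResult(sample_id, ASSIGNED, class_id=matches[0],
                                matches=matches)
    if not matches:
        return AssignmentResult(sample_id, NEW_GENOTYPE)
    return AssignmentResult(sample_id, AMBIGUOUS, matches=sorted(matches))


def mint_new_classes(results: list[AssignmentResult],
                     profiles: Mapping[str, Mapping[str, GT]],
                     panel_sites: Sequence[str],
                     start_index: int) -> dict[str, str]:
    """Give each distinct new-genotype panel profile a fresh GT-xx label."""
    minted: dict[tuple, str] = {}
    out: dict[str, str] = {}
    idx = start_index
    for res in sorted((r for r in results if r.status == NEW_GENOTYPE),
                      key=lambda r: r.sample_id):
        prof = profiles[res.sample_id]
        key = tuple(int(prof.get(s, GT.MISSING)) for s in panel_sites)
        if key not in minted:
            minted[key] = f"GT-{idx:02d}"
            idx += 1
        out[res.sample_id] = minted[key]
    return out
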