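"""Stringent post-calling filters reducing candidate SNV calls to a
high-confidence somatic set.

Three stages mirror a stringent somatic-SNV workflow: per-call evidence
filters (genotype quality, depth, allele balance, strand bias, homopolymer
context, mappability, heterozygosity), germline subtraction against the
reference-clone reads / alternate haplophase / optional parental genotypes,
and lightweight re-genotyping of target positions in extra samples from
quality-filtered pileup summaries.

Every criterion is evaluated (no short-circuit) so a verdict carries the full
list of failing reason codes.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping

from .util import GT, site_sort_key

log = logging.getLogger(__name__)

# canonical evaluation order of reason codes
NON_SNV = "NON_SNV"
NOT_HET = "NOT_HET"
LOW_GQ = "LOW_GQ"
DEPTH_LOW = "DEPTH_LOW"
DEPTH_HIGH = "DEPTH_HIGH"
ALLELE_BALANCE = "ALLELE_BALANCE"
STRAND_BIAS = "STRAND_BIAS"
HOMOPOLYMER = "HOMOPOLYMER"
LOW_MAPPABILITY = "LOW_MAPPABILITY"
GERMLINE_REFCLONE = "GERMLINE_REFCLONE"
GERMLINE_ALTHAP = "GERMLINE_ALTHAP"
GERMLINE_PARENT = "GERMLINE_PARENT"


@dataclass
class CandidateCall:
    """One candidate SNV observation in one sample."""

    site_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    genotype_state: GT
    depth: int
    alt_depth: int
    alt_forward: int
    alt_reverse: int
    genotype_quality: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: pos must be >= 1")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(f"{self.site_id}/{self.sample_id}: alt_depth outside [0, depth]")
        if self.alt_forward + self.alt_reverse != self.alt_depth:
            raise ValueError(f"{self.site_id}/{self.sample_id}: strand counts do not sum to alt_depth")


@dataclass
class FilterConfig:
    min_gq: float = 30.0
    min_depth: int = 10
    max_depth: int | None = None          # absolute cap; None -> per-sample factor
    max_depth_factor: float = 3.0         # x sample median depth when max_depth is None
    allele_balance_window: tuple[float, float] = (0.25, 0.75)
    max_strand_skew: float = 0.9
    homopolymer_min_run: int = 5
    require_het: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.allele_balance_window
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("allele_balance_window must satisfy 0 <= lo < hi <= 1")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")


@dataclass
class FilterVerdict:
    site_id: str
    sample_id: str
    passed: bool
    reason_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.passed == (not self.reason_codes)


@dataclass
class FastaWindow:
    """Reference sequence window; ``start`` is the 1-based position of seq[0]."""

    seq: str
    start: int

    def base(self, pos: int) -> str | None:
        i = pos - self.start
        return self.seq[i] if 0 <= i < len(self.seq) else None

    def covers(self, lo: int, hi: int) -> bool:
        return self.start <= max(lo, 1) and hi <= self.start + len(self.seq) - 1


def _homopolymer_near(window: FastaWindow, pos: int, min_run: int) -> bool:
    """True when a mononucleotide run of >= min_run begins or ends within 1 bp
    of ``pos`` (a standard sequencing-error proxy around homopolymers)."""
    seq = window.seq.upper()
    n = len(seq)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run_len = j - i
        if run_len >= min_run:
            start_pos = window.start + i
            end_pos = window.start + j - 1
            if abs(start_pos - pos) <= 1 or abs(end_pos - pos) <= 1:
                return True
        i = j
    return False


def apply_site_filters(call: CandidateCall, context: FastaWindow,
                       config: FilterConfig, exclusion=None,
                       max_depth: int | None = None) -> FilterVerdict:
    """Evaluate every evidence criterion for one candidate call.

    ``exclusion`` is an optional low-mappability interval lookup exposing
    ``contains(chrom, pos)``; ``max_depth`` overrides the config cap (used by
    the pipeline to pass each sample's own 3x-median bound).
    """
    r = config.homopolymer_min_run
    if not context.covers(call.pos - r, call.pos + r):
        raise ValueError(f"{call.site_id}: reference context window too short "
                         f"(need [{call.pos - r}, {call.pos + r}])")

    codes: list[str] = []
    if len(call.ref) != 1 or len(call.alt) != 1:
        codes.append(NON_SNV)
    if config.require_het and call.genotype_state != GT.HET:
        codes.append(NOT_HET)
    if call.genotype_quality < config.min_gq:
        codes.append(LOW_GQ)
    if call.depth < config.min_depth:
        codes.append(DEPTH_LOW)
    cap = max_depth if max_depth is not None else config.max_depth
    if cap is not None and call.depth > cap:
        codes.append(DEPTH_HIGH)
    lo, hi = config.allele_balance_window
    if call.depth > 0:
        frac = call.alt_depth / call.depth
        if call.genotype_state == GT.HET and not lo <= frac <= hi:
            codes.append(ALLELE_BALANCE)
    if call.alt_depth > 0:
        skew = max(call.alt_forward, call.alt_reverse) / call.alt_depth
        if skew > config.max_strand_skew:
            codes.append(STRAND_BIAS)
    if _homopolymer_near(context, call.pos, r):
        codes.append(HOMOPOLYMER)
    if exclusion is not None and exclusion.contains(call.chrom, call.pos):
        codes.append(LOW_MAPPABILITY)
    return FilterVerdict(call.site_id, call.sample_id, passed=not codes,
                         reason_codes=codes)


def sample_median_depths(calls: Iterable[CandidateCall]) -> dict[str, float]:
    """Median per-call depth per sample (each sample is its own coverage norm)."""
    depths: dict[str, list[int]] = {}
    for c in calls:
        depths.setdefault(c.sample_id, []).append(c.depth)
    return {s: statistics.median(d) for s, d in depths.items()}


def filter_calls(calls: list[CandidateCall], reference, config: FilterConfig,
                 exclusion=None) -> tuple[list[FilterVerdict], dict[str, set[str]]]:
    """Verdict every candidate het call; return verdicts plus the per-site set
    of samples whose call passed.

    ``reference`` exposes ``window(chrom, lo, hi) -> FastaWindow`` (see
    :class:`clonotrace.io.ReferenceSequence`).
    """
    medians = sample_median_depths(calls)
    caps = None
    if config.max_depth is None:
        caps = {s: config.max_depth_factor * m for s, m in medians.items()}
    verdicts: list[FilterVerdict] = []
    passed_by_site: dict[str, set[str]] = {}
    r = config.homopolymer_min_run
    for call in calls:
        if call.genotype_state != GT.HET:
            continue  # only het claims are somatic candidates
        ctx = reference.window(call.chrom, call.pos - r - 1, call.pos + r + 1)
        cap = caps.get(call.sample_id) if caps is not None else None
        v = apply_site_filters(call, ctx, config, exclusion=exclusion, max_depth=cap)
        verdicts.append(v)
        if v.passed:
            passed_by_site.setdefault(call.site_id, set()).add(call.sample_id)
    log.info("filter_calls: %d het candidate calls, %d passing, %d sites with >=1 pass",
             len(verdicts), sum(v.passed for v in verdicts), len(passed_by_site))
    return verdicts, passed_by_site


def subtract_germline(candidates: Mapping[str, tuple[str, str]],
                      reference_clone_alt: Mapping[str, str],
                      alt_haplophase_alt: Mapping[str, str],
                      parent_genotypes: Mapping[str, Mapping[str, GT]] | None = None,
                      ) -> tuple[list[str], dict[str, list[str]]]:
    """Partition candidate sites into somatic and germline-removed.

    ``candidates`` maps site id -> (ref, alt).  A site is removed when its alt
    allele is evidenced in the reference-clone reads, matches the alternate
    haplophase allele, or (if parental tables are supplied) is carried by a
    parent.  The partition is exact: somatic + removed = input.
    """
    somatic: list[str] = []
    removed: dict[str, list[str]] = {}
    for sid in sorted(candidates, key=site_sort_key):
        _, alt = candidates[sid]
        codes: list[str] = []
        if reference_clone_alt.get(sid) == alt:
            codes.append(GERMLINE_REFCLONE)
        if alt_haplophase_alt.get(sid) == alt:
            codes.append(GERMLINE_ALTHAP)
        if parent_genotypes:
            for table in parent_genotypes.values():
                if table.get(sid, GT.HOM_REF) in (GT.HET, GT.HOM_ALT):
                    codes.append(GERMLINE_PARENT)
                    break
        if codes:
            removed[sid] = codes
        else:
            somatic.append(sid)
    log.info("subtract_germline: %d candidates -> %d somatic, %d removed",
             len(candidates), len(somatic), len(removed))
    return somatic, removed


@dataclass
class GenotypeTargetConfig:
    min_depth: int = 8
    min_alt_depth: int = 4
    noise_floor: int = 1  # alt reads <= floor with adequate depth -> hom-ref
    allele_balance_window: tuple[float, float] = (0.25, 0.75)


def genotype_targets(site_list: list[str],
                     pileups: Mapping[tuple[str, str], tuple[int, int]],
                     config: GenotypeTargetConfig | None = None,
                     ) -> dict[tuple[str, str], GT]:
    """Two-state genotyping of target positions from quality-filtered pileups.

    ``pileups`` maps (sample, site) -> (ref_reads, alt_reads) where counts are
    already restricted to reads passing base/mapping-quality thresholds.
    """
    config = config or GenotypeTargetConfig()
    known = set(site_list)
    lo, hi = config.allele_balance_window
    out: dict[tuple[str, str], GT] = {}
    for (sample, sid), (ref_n, alt_n) in pileups.items():
        if sid not in known:
            log.warning("genotype_targets: unknown site %s ignored", sid)
            continue
        depth = ref_n + alt_n
        if depth < config.min_depth:
            out[(sample, sid)] = GT.MISSING
        elif alt_n <= config.noise_floor:
            out[(sample, sid)] = GT.HOM_REF
        elif alt_n >= config.min_alt_depth and lo <= alt_n / depth <= hi:
            out[(sample, sid)] = GT.HET
        else:
            out[(sample, sid)] = GT.MISSING
    return out
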