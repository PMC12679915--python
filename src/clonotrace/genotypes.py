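"""Sample x SNV genotype matrix, sharing partition, curation, mutation
spectrum, and collapse into multilocus genotype classes (GT-xx)."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .util import GT, is_transition, parse_site_id, site_sort_key

log = logging.getLogger(__name__)

#: conventional strand-collapsed substitution classes (pyrimidine-based)
SPECTRUM_CLASSES = ("C>T", "T>C", "C>A", "C>G", "T>A", "T>G")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypeMatrix:
    """States grid over {0 hom-ref, 1 het, -1 missing}; rows samples, cols sites."""

    sample_ids: list[str]
    site_ids: list[str]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.sample_ids), len(self.site_ids)):
            raise ValueError("states grid does not match id lists")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site_ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states.astype(float), index=self.sample_ids,
                          columns=self.site_ids)
        return df.replace(float(GT.MISSING), np.nan)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        states = df.to_numpy(dtype=float)
        states = np.where(np.isnan(states), float(GT.MISSING), states)
        return cls(sample_ids=list(df.index.astype(str)),
                   site_ids=list(df.columns.astype(str)),
                   states=states.astype(np.int8))

    def subset_sites(self, sites: Iterable[str]) -> "GenotypeMatrix":
        sites = list(sites)
        idx = {s: j for j, s in enumerate(self.site_ids)}
        cols = [idx[s] for s in sites]
        return GenotypeMatrix(list(self.sample_ids), sites, self.states[:, cols])

    def row(self, sample: str) -> np.ndarray:
        return self.states[self.sample_ids.index(sample)]


def build_matrix(calls: Mapping[tuple[str, str], GT] | Iterable[tuple[str, str, GT]],
                 samples: list[str], sites: list[str]) -> GenotypeMatrix:
    """Assemble the matrix from (sample, site) -> state calls.

    Absent pairs become missing; conflicting duplicate calls raise, naming the
    pair.  Row/column order is deterministic: samples as given, sites sorted
    by (chrom, pos).
    """
    if not isinstance(calls, Mapping):
        merged: dict[tuple[str, str], GT] = {}
        for sample, sid, state in calls:
            key = (sample, sid)
            if key in merged and merged[key] != state:
                raise ValueError(f"conflicting duplicate call for {key}")
            merged[key] = state
        calls = merged
    sites = sorted(sites, key=site_sort_key)
    grid = np.full((len(samples), len(sites)), GT.MISSING, dtype=np.int8)
    site_idx = {s: j for j, s in enumerate(sites)}
    sample_idx = {s: i for i, s in enumerate(samples)}
    for (sample, sid), state in calls.items():
        if sample in sample_idx and sid in site_idx:
            grid[sample_idx[sample], site_idx[sid]] = state
    return GenotypeMatrix(sample_ids=list(samples), site_ids=sites, states=grid)


@dataclass
class SharingPartition:
    singleton_sites: list[str]
    shared_sites: list[str]
    per_sample_counts: dict[str, int]
    per_chrom_counts: dict[str, dict[str, int]]  # chrom -> {"singleton": n, "shared": n}


def partition_sharing(matrix: GenotypeMatrix, na_policy: str = "absent") -> SharingPartition:
    """Split het-somewhere sites into singletons (het in exactly one sample)
    and shared (het in >= 2).

    ``na_policy``: "absent" treats missing as not-observed-het; "strict"
    raises on any missing state.
    """
    if na_policy not in ("absent", "strict"):
        raise ValueError("na_policy must be 'absent' or 'strict'")
    if na_policy == "strict" and (matrix.states == GT.MISSING).any():
        raise ValueError("missing states present under strict na_policy")
    het = matrix.states == GT.HET
    carriers = het.sum(axis=0)
    singleton = [s for s, c in zip(matrix.site_ids, carriers) if c == 1]
    shared = [s for s, c in zip(matrix.site_ids, carriers) if c >= 2]
    per_sample = {s: int(n) for s, n in zip(matrix.sample_ids, het.sum(axis=1))}
    per_chrom: dict[str, dict[str, int]] = {}
    for group, sites in (("singleton", singleton), ("shared", shared)):
        for sid in sites:
            chrom, _ = parse_site_id(sid)
            per_chrom.setdefault(chrom, {"singleton": 0, "shared": 0})[group] += 1
    log.info("partition_sharing: %d singleton, %d shared of %d sites",
             len(singleton), len(shared), len(matrix.site_ids))
    return SharingPartition(singleton, shared, per_sample, per_chrom)


def curate_shared(matrix: GenotypeMatrix) -> tuple[list[str], list[str]]:
    """Drop any shared site lacking data in at least one sample."""
    missing_any = (matrix.states == GT.MISSING).any(axis=0)
    retained = [s for s, m in zip(matrix.site_ids, missing_any) if not m]
    dropped = [s for s, m in zip(matrix.site_ids, missing_any) if m]
    if dropped:
        log.info("curate_shared: dropped %d sites with missing data: %s",
                 len(dropped), ", ".join(dropped[:5]))
    return retained, dropped


@dataclass
class SpectrumTally:
    counts: dict[str, int]
    ts_fraction: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _spectrum_class(ref: str, alt: str) -> str:
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT allele in {ref}>{alt}")
    if ref in "AG":  # collapse onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    assert cls in SPECTRUM_CLASSES
    return cls


def mutation_spectrum(sites: Iterable[tuple[str, str]]) -> SpectrumTally:
    """Tally the six strand-collapsed substitution classes.

    ``sites`` yields (ref, alt) pairs as called on the reference strand; each
    class merges a substitution with its reverse complement (C>T with G>A
    etc.), and the transition fraction is (C>T + T>C) / total.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    total = ts = 0
    for ref, alt in sites:
        counts[_spectrum_class(ref, alt)] += 1
        total += 1
        ts += int(is_transition(ref, alt))
    return SpectrumTally(counts=counts, ts_fraction=ts / total if total else 0.0)


@dataclass
class GenotypeClass:
    class_id: str
    state_vector: np.ndarray
    member_samples: list[str]

    @property
    def frequency(self) -> int:
        return len(self.member_samples)


def collapse_genotypes(matrix: GenotypeMatrix,
                       relabel: Mapping[str, str] | None = None) -> list[GenotypeClass]:
    """Collapse samples with identical state vectors into genotype classes.

    Classes are numbered GT-00 upward after sorting by (descending frequency,
    lexicographic vector); a ``relabel`` map (e.g. a historical published
    labelling) can be applied on top.
    """
    if (matrix.states == GT.MISSING).any():
        raise ValueError("matrix contains missing states; run curate_shared first")
    groups: dict[tuple, list[str]] = {}
    for sample in sorted(matrix.sample_ids):
        vec = tuple(int(x) for x in matrix.row(sample))
        groups.setdefault(vec, []).append(sample)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    classes = []
    for i, (vec, members) in enumerate(ordered):
        cid = f"GT-{i:02d}"
        if relabel:
            cid = relabel.get(cid, cid)
        classes.append(GenotypeClass(class_id=cid,
                                     state_vector=np.array(vec, dtype=np.int8),
                                     member_samples=members))
    assert sum(c.frequency for c in classes) == len(matrix.sample_ids)
    log.info("collapse_genotypes: %d samples -> %d classes (max frequency %d)",
             len(matrix.sample_ids), len(classes),
             max(c.frequency for c in classes) if classes else 0)
    return classes


def class_vectors(classes: list[GenotypeClass]) -> dict[str, np.ndarray]:
    return {c.class_id: c.state_vector for c in classes}
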