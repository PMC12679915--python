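"""Standard-format I/O and reporting.

Coordinate conventions are converted at this boundary: VCF positions and
site ids are 1-based; BED and flank extraction are 0-based half-open.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .util import GT, site_id
from .varfilter import CandidateCall

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotype table TSV dialect: first column sample_id, remaining columns site
# ids, cells in {0, 1, NA}
# ---------------------------------------------------------------------------

def write_genotype_table(matrix: GenotypeMatrix, path) -> None:
    df = matrix.to_frame()
    out = df.map(lambda x: "NA" if pd.isna(x) else str(int(x)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_genotype_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id",
                     na_values=["NA"], dtype=str)
    df = df.apply(pd.to_numeric)
    return GenotypeMatrix.from_frame(df)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[list[str], list[CandidateCall]]:
    """Map VCF v4.2 records (GT/DP/AD/GQ + SAF/SAR strand fields) onto
    candidate calls, one per sample per record."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[CandidateCall] = []
    state_of = {0: GT.HOM_REF, 1: GT.HET, 2: GT.MISSING, 3: GT.HOM_ALT}
    def fmt(var, key):
        try:
            return var.format(key)
        except KeyError:
            return None

    for var in vcf:
        if var.ALT and len(var.ALT) > 1:
            raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}; split first")
        alt = var.ALT[0] if var.ALT else "."
        sid = var.ID or site_id(var.CHROM, var.POS)
        dp = fmt(var, "DP")
        ad = fmt(var, "AD")
        gq = fmt(var, "GQ")
        saf = fmt(var, "SAF")
        sar = fmt(var, "SAR")
        for i, sample in enumerate(samples):
            depth = int(dp[i][0]) if dp is not None else 0
            alt_depth = int(ad[i][1]) if ad is not None and ad.shape[1] > 1 else 0
            fwd = int(saf[i][0]) if saf is not None else alt_depth
            rev = int(sar[i][0]) if sar is not None else 0
            calls.append(CandidateCall(
                site_id=sid, chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                sample_id=sample, genotype_state=state_of[var.gt_types[i]],
                depth=depth, alt_depth=alt_depth, alt_forward=fwd,
                alt_reverse=rev,
                genotype_quality=float(gq[i][0]) if gq is not None else 0.0))
    log.info("read_vcf: %d calls over %d samples from %s", len(calls), len(samples), path)
    return samples, calls


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class ReferenceSequence:
    """Random access to a reference, from a FASTA file (pyfaidx) or an
    in-memory chrom -> str mapping."""

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta
            self._fa = Fasta(str(source))
            self._mem = None
        else:
            self._fa = None
            self._mem = dict(source)

    def length(self, chrom: str) -> int:
        if self._mem is not None:
            return len(self._mem[chrom])
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """0-based half-open extraction."""
        start0 = max(start0, 0)
        if self._mem is not None:
            return self._mem[chrom][start0:end0]
        return str(self._fa[chrom][start0:end0])

    def window(self, chrom: str, start0: int, end0: int):
        from .varfilter import FastaWindow
        start0 = max(start0, 0)
        end0 = min(end0, self.length(chrom))
        return FastaWindow(seq=self.fetch(chrom, start0, end0), start=start0 + 1)


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open)
# ---------------------------------------------------------------------------

class BedIntervals:
    """Interval membership for 1-based positions against 0-based half-open
    BED intervals: interval [100, 200) contains positions 101..200."""

    def __init__(self, intervals: list[tuple[str, int, int]]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        per: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if e < s:
                raise ValueError(f"BED interval end < start: {chrom} {s} {e}")
            per.setdefault(chrom, []).append((s, e))
        for chrom, ivs in per.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            ends = [e for _, e in ivs]
            self._by_chrom[chrom] = (starts, ends)

    @classmethod
    def from_file(cls, path) -> "BedIntervals":
        intervals = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: malformed BED line")
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals)

    def contains(self, chrom: str, pos1: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = bisect.bisect_right(starts, pos1 - 1) - 1
        # scan left while intervals may still overlap (intervals can nest)
        while i >= 0:
            if ends[i] >= pos1:
                if starts[i] < pos1:
                    return True
                i -= 1
            else:
                break
        return False


# ---------------------------------------------------------------------------
# tree / network exports
# ---------------------------------------------------------------------------

def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_graphml(network, path) -> None:
    g = network.graph.copy()
    for u, v in g.edges:
        g.edges[u, v]["mutations"] = ",".join(g.edges[u, v]["mutations"])
    for n in g.nodes:
        g.nodes[n]["vector"] = "".join(str(x) for x in g.nodes[n]["vector"])
    nx.write_graphml(g, path)


def write_edge_list(network, path) -> None:
    rows = [{"node_a": u, "node_b": v,
             "n_mutations": len(network.edge_sites(u, v)),
             "mutations": ",".join(network.edge_sites(u, v))}
            for u, v in sorted(network.graph.edges)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region / trait reporting
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    frequency_tables: dict[str, dict[str, int]]   # region -> class -> count
    mean_derived_distance: dict[str, float]       # region -> mean hamming to ancestral class

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.frequency_tables):
            for cid, n in sorted(self.frequency_tables[region].items()):
                rows.append({"region": region, "class_id": cid, "count": n,
                             "mean_derived_distance": self.mean_derived_distance[region]})
        return pd.DataFrame(rows)


def summarize_regions(class_of_sample: dict[str, str],
                      region_of_sample: dict[str, str],
                      class_vectors: dict[str, np.ndarray],
                      ancestral_class: str) -> RegionSummary:
    """Per-region genotype-class frequency tables and the mean number of
    derived alleles separating a region's samples from the ancestral class —
    the quantity that orders regions along a dissemination route."""
    anc = np.asarray(class_vectors[ancestral_class])
    tables: dict[str, dict[str, int]] = {}
    dists: dict[str, list[float]] = {}
    for sample, cid in sorted(class_of_sample.items()):
        region = region_of_sample.get(sample, "Unknown")
        tables.setdefault(region, {}).setdefault(cid, 0)
        tables[region][cid] += 1
        d = float(np.sum(np.asarray(class_vectors[cid]) != anc))
        dists.setdefault(region, []).append(d)
    means = {r: float(np.mean(v)) for r, v in dists.items()}
    return RegionSummary(frequency_tables=tables, mean_derived_distance=means)


@dataclass
class TraitReport:
    values: dict[str, float]
    categories: dict[str, str]   # clone -> low | high
    mean: float
    value_range: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"clone_id": list(self.values),
                             "value": list(self.values.values()),
                             "category": [self.categories[c] for c in self.values]})


def classify_trait_extremes(trait_values: dict[str, float],
                            low_label: str = "low", high_label: str = "high") -> TraitReport:
    """Mean-split categorisation of per-clone trait values (e.g. harvest-date
    or Brix BLUPs); values equal to the mean fall in the lower category."""
    clean = {k: float(v) for k, v in trait_values.items() if not pd.isna(v)}
    if not clean:
        raise ValueError("empty trait table")
    mean = float(np.mean(list(clean.values())))
    cats = {k: (low_label if v <= mean else high_label) for k, v in clean.items()}
    rng = float(max(clean.values()) - min(clean.values()))
    return TraitReport(values=clean, categories=cats, mean=mean, value_range=rng)


# ---------------------------------------------------------------------------
# config / manifest
# ---------------------------------------------------------------------------

def read_toml_config(path) -> dict:
    import tomllib
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def write_run_manifest(out_dir, seed: int, config: dict) -> Path:
    """Machine-readable provenance beside the outputs."""
    from . import __version__
    payload = {"seed": seed, "config": config,
               "config_sha256": hashlib.sha256(
                   json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
               "clonotrace_version": __version__,
               "python": platform.python_version()}
    path = Path(out_dir) / "run_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
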