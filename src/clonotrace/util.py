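"""Shared primitives: genotype state codes, site identifiers, small helpers."""

from __future__ import annotations

import re
from enum import IntEnum


class GT(IntEnum):
    """Diploid genotype state at a biallelic site.

    Somatic SNVs in a clonal lineage are expected to be heterozygous; the
    hom-alt state exists only for germline/parental genotypes.
    """

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


_SITE_RE = re.compile(r"^(?P<chrom>.+)_(?P<pos>\d+)$")

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = "ACGT"


def site_id(chrom: str, pos: int) -> str:
    """Render a site identifier ``<chrom>_<pos>`` (1-based position)."""
    return f"{chrom}_{pos}"


def parse_site_id(sid: str) -> tuple[str, int]:
    m = _SITE_RE.match(sid)
    if m is None:
        raise ValueError(f"malformed site id: {sid!r}")
    return m.group("chrom"), int(m.group("pos"))


def site_sort_key(sid: str) -> tuple[str, int]:
    """Deterministic (chrom, pos) ordering used for every site list."""
    return parse_site_id(sid)


def is_transition(ref: str, alt: str) -> bool:
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"non-ACGT allele: {ref}>{alt}")
    return TRANSITIONS[ref] == alt


def roman(n: int) -> str:
    """Roman numeral for a positive integer (LoH pattern labels)."""
    if n < 1:
        raise ValueError("roman() requires n >= 1")
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)
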