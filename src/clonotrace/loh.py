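"""Loss-of-heterozygosity profiles along a chromosome and periclinal-chimera
detection.

Leaves develop from the L1 and L2 meristem cell layers while adventitious
roots derive from L2 only, so comparing leaf and root genotypes at markers
known to be heterozygous in the unmutated cultivar separates layer-specific
hemizygous deletions: a marker heterozygous in the leaf but LoH in the root
(or the converse) is the signature of a periclinal chimera.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

HET_RETAINED = "het-retained"
LOH = "LoH"
MISSING = "missing"

_STATE_MAP = {"het": HET_RETAINED, "hom": LOH, "missing": MISSING,
              HET_RETAINED: HET_RETAINED, LOH: LOH}


@dataclass
class LoHProfile:
    sample_id: str
    markers: list[str]                       # ordered along the chromosome
    leaf_states: list[str]
    root_states: list[str]
    leaf_segments: list[tuple[int, int]]     # maximal LoH runs, marker indices (incl.)
    root_segments: list[tuple[int, int]]
    chimera: bool
    excluded_markers: list[str] = field(default_factory=list)

    def pattern_key(self, tissue: str = "root") -> tuple:
        states = self.root_states if tissue == "root" else self.leaf_states
        return tuple(states)


def _segments(states: Sequence[str]) -> list[tuple[int, int]]:
    """Maximal runs of LoH markers; missing calls break segments (conservative:
    a gap is never bridged by imputation)."""
    segs = []
    start = None
    for i, s in enumerate(states):
        if s == LOH:
            if start is None:
                start = i
        else:
            if start is not None:
                segs.append((start, i - 1))
                start = None
    if start is not None:
        segs.append((start, len(states) - 1))
    return segs


def call_profile(sample_id: str, leaf_calls: Mapping[str, str],
                 root_calls: Mapping[str, str], markers: Sequence[str],
                 reference_het_markers: Iterable[str] | None = None) -> LoHProfile:
    """Build a per-tissue LoH profile over ordered markers.

    Markers not confirmed heterozygous in the reference control plant are
    excluded (and logged): a marker that is not het in the unmutated cultivar
    cannot report LoH.  het -> het-retained, hom (either homozygote) -> LoH.
    """
    ref_het = set(reference_het_markers) if reference_het_markers is not None else set(markers)
    kept, excluded = [], []
    for m in markers:
        (kept if m in ref_het else excluded).append(m)
    if excluded:
        log.info("call_profile(%s): excluded %d markers not het in reference control",
                 sample_id, len(excluded))

    def states(calls: Mapping[str, str]) -> list[str]:
        out = []
        for m in kept:
            raw = calls.get(m, "missing")
            if raw not in _STATE_MAP and raw != "missing":
                raise ValueError(f"unknown marker call {raw!r} at {m}")
            out.append(_STATE_MAP.get(raw, MISSING))
        return out

    leaf = states(leaf_calls)
    root = states(root_calls)
    chimera = any((a == HET_RETAINED and b == LOH) or (a == LOH and b == HET_RETAINED)
                  for a, b in zip(leaf, root))
    return LoHProfile(sample_id=sample_id, markers=kept, leaf_states=leaf,
                      root_states=root, leaf_segments=_segments(leaf),
                      root_segments=_segments(root), chimera=chimera,
                      excluded_markers=excluded)


def cluster_patterns(profiles: list[LoHProfile], tissue: str = "root",
                     strict: bool = False) -> tuple[dict[str, str], int]:
    """Group profiles into LoH patterns labelled I, II, ... in order of first
    appearance (samples sorted by id).

    Pattern identity is defined on the root (L2) state vector by default —
    the deletions being tracked are L2 events and leaf profiles mix layers;
    ``strict`` requires both tissue vectors to match.
    """
    from .util import roman

    marker_sets = {tuple(p.markers) for p in profiles}
    if len(marker_sets) > 1:
        raise ValueError("profiles cover heterogeneous marker sets")
    patterns: dict[tuple, str] = {}
    assignment: dict[str, str] = {}
    for p in sorted(profiles, key=lambda p: p.sample_id):
        key = (p.pattern_key("root"), p.pattern_key("leaf")) if strict else p.pattern_key(tissue)
        if key not in patterns:
            patterns[key] = roman(len(patterns) + 1)
        assignment[p.sample_id] = patterns[key]
    return assignment, len(patterns)
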