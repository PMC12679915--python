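"""Ancestral-genotype inference, ordination, relatedness, and allele polarity.

The ancestral multilocus genotype is reconstructed from the two parents of
the cultivar: at a somatic-SNV position where both parents are homozygous
reference, the original seedling must also have been homozygous reference;
any parental heterozygosity (or missing data) leaves the site ambiguous and
it is excluded.  Genotype classes are then ranked as ancestral candidates by
distance to that inferred genotype, ordination (classical PCoA) and a
similarity-index pairwise relatedness estimator give the supporting views,
and alleles are polarised ancestral/derived for dissemination analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeClass
from .util import GT, site_sort_key

log = logging.getLogger(__name__)

DETERMINED_HOM_REF = "determined:hom-ref"
AMBIGUOUS_EXCLUDED = "ambiguous-excluded"


@dataclass
class AncestralGenotype:
    site_status: dict[str, str]          # site -> DETERMINED_HOM_REF | AMBIGUOUS_EXCLUDED
    determined_sites: list[str]
    excluded_sites: list[str]
    inconsistent_sites: list[str]        # both parents hom-alt: impossible for a somatic site

    def determined_vector(self, sites: Sequence[str]) -> np.ndarray:
        """ATT states over ``sites`` with -1 at excluded positions."""
        det = set(self.determined_sites)
        return np.array([GT.HOM_REF if s in det else GT.MISSING for s in sites],
                        dtype=np.int8)


def infer_ancestral(parent1: Mapping[str, GT], parent2: Mapping[str, GT],
                    retained_sites: Sequence[str]) -> AncestralGenotype:
    """Infer the ancestral genotype over the retained somatic sites.

    Both parents hom-ref -> determined hom-ref.  A parent het, hom-alt or
    missing -> ambiguous-excluded.  Both parents hom-alt is additionally
    flagged inconsistent: the site cannot then be a somatic variant.
    """
    status: dict[str, str] = {}
    determined, excluded, inconsistent = [], [], []
    for sid in sorted(retained_sites, key=site_sort_key):
        s1 = parent1.get(sid, GT.MISSING)
        s2 = parent2.get(sid, GT.MISSING)
        if sid not in parent1 or sid not in parent2:
            log.warning("infer_ancestral: %s missing from a parental table; excluded", sid)
        if s1 == GT.HOM_REF and s2 == GT.HOM_REF:
            status[sid] = DETERMINED_HOM_REF
            determined.append(sid)
        else:
            status[sid] = AMBIGUOUS_EXCLUDED
            excluded.append(sid)
            if s1 == GT.HOM_ALT and s2 == GT.HOM_ALT:
                inconsistent.append(sid)
    log.info("infer_ancestral: %d determined, %d excluded (%d inconsistent)",
             len(determined), len(excluded), len(inconsistent))
    return AncestralGenotype(site_status=status, determined_sites=determined,
                             excluded_sites=excluded, inconsistent_sites=inconsistent)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str  # hamming | euclidean

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        assert np.allclose(self.matrix, self.matrix.T)
        assert np.allclose(np.diag(self.matrix), 0.0)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def _masked_hamming(u: np.ndarray, v: np.ndarray) -> float:
    ok = (u != GT.MISSING) & (v != GT.MISSING)
    return float(np.sum(u[ok] != v[ok]))


def pairwise_distance(vectors: Mapping[str, np.ndarray],
                      metric: str = "euclidean") -> DistanceMatrix:
    """Hamming (site-count) or Euclidean (= sqrt hamming on 0/1 states)
    distances.  Entries coded -1 are treated as undetermined and dropped
    pairwise — this is how comparisons against the ancestral genotype use
    only its determined sites.
    """
    if metric not in ("hamming", "euclidean"):
        raise ValueError("metric must be 'hamming' or 'euclidean'")
    ids = list(vectors)
    arrs = [np.asarray(vectors[i], dtype=np.int8) for i in ids]
    n_sites = {a.shape[0] for a in arrs}
    if len(n_sites) > 1:
        raise ValueError("state vectors have mismatched lengths")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            h = _masked_hamming(arrs[i], arrs[j])
            d[i, j] = d[j, i] = np.sqrt(h) if metric == "euclidean" else h
    return DistanceMatrix(ids=ids, matrix=d, metric=metric)


@dataclass
class PCoAResult:
    ids: list[str]
    coordinates: np.ndarray       # item x axis
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives reported)
    proportions: np.ndarray       # variance fractions of the retained (positive) axes

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical metric scaling: double-centre -0.5*D^2, eigendecompose, scale
    eigenvectors by sqrt of the positive eigenvalues.  Negative eigenvalues
    are reported but their axes dropped."""
    d2 = dm.matrix ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-9 * max(abs(evals[0]), 1.0)
    n_pos = int(pos.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    if n_axes is not None and n_axes > n_pos:
        log.warning("pcoa: requested %d axes, only %d positive; returning %d",
                    n_axes, n_pos, n_pos)
    coords = evecs[:, :keep] * np.sqrt(evals[:keep])
    denom = evals[pos].sum()
    props = evals[:keep] / denom if denom > 0 else np.zeros(keep)
    return PCoAResult(ids=list(dm.ids), coordinates=coords,
                      eigenvalues=evals, proportions=props)


# ---------------------------------------------------------------------------
# pairwise relatedness (similarity-index moment estimator, Wang-style)
# ---------------------------------------------------------------------------

@dataclass
class RelatednessMatrix:
    ids: list[str]
    matrix: np.ndarray
    allele_frequencies: dict[str, float]

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def _wang_locus_terms(p: np.ndarray):
    """Per-locus design pieces for the moment estimator at biallelic loci.

    Categories of a dyad's genotype pair: 1 = identical genotypes,
    2 = one homozygote / one heterozygote sharing an allele,
    4 = opposite homozygotes.  Conditional probabilities given 2, 1, 0
    pairs of alleles IBD follow from the allele frequency p (alt) alone.
    Returns the unrelated-baseline probabilities (b1, b2, b4), the one-pair-
    IBD probabilities (a2, 2pq, 0) and the locus weights 1/u, u = 2*a2 - a3.
    """
    q = 1.0 - p
    a2 = p ** 2 + q ** 2
    a3 = p ** 3 + q ** 3
    b1 = p ** 4 + q ** 4 + 4 * p ** 2 * q ** 2
    b2 = 4 * p * q * a2
    b4 = 2 * p ** 2 * q ** 2
    u = 2 * a2 - a3
    return a2, b1, b2, b4, 1.0 / u


def _pair_r(gi: np.ndarray, gj: np.ndarray, terms) -> float:
    """Weighted-least-squares solve of the three category-moment equations for
    (Delta = both pairs IBD, phi = one pair IBD); r = Delta + phi/2."""
    a2, b1, b2, b4, w = terms
    i1 = (gi == gj).astype(float)
    hom_het = ((gi != gj) & ((gi == 1) | (gj == 1))).astype(float)
    opp_hom = ((gi * gj == 0) & (gi + gj == 2)).astype(float)
    # design rows per locus: [coef_Delta, coef_phi], response = I_k - b_k
    # cat1: Delta*(1-b1) + phi*(a2-b1) = I1 - b1
    # cat2: Delta*(-b2)  + phi*(2pq-b2) = I2 - b2
    # cat4: Delta*(-b4)  + phi*(-b4)   = I4 - b4
    two_pq = 1.0 - a2
    rows = [
        ((1.0 - b1), (a2 - b1), i1 - b1),
        ((-b2), (two_pq - b2), hom_het - b2),
        ((-b4), (-b4), opp_hom - b4),
    ]
    ata = np.zeros((2, 2))
    atb = np.zeros(2)
    for c_d, c_p, y in rows:
        ata[0, 0] += np.sum(w * c_d * c_d)
        ata[0, 1] += np.sum(w * c_d * c_p)
        ata[1, 1] += np.sum(w * c_p * c_p)
        atb[0] += np.sum(w * c_d * y)
        atb[1] += np.sum(w * c_p * y)
    ata[1, 0] = ata[0, 1]
    delta, phi = np.linalg.solve(ata, atb)
    return float(delta + phi / 2.0)


def wang_relatedness(genotypes: Mapping[str, np.ndarray],
                     allele_frequencies: Mapping[str, float] | None = None,
                     site_ids: Sequence[str] | None = None) -> RelatednessMatrix:
    """Pairwise relatedness r over biallelic loci coded as alt-allele counts
    {0, 1, 2}.

    A moment estimator in the similarity-index family: per locus the dyad's
    genotype-pair category probabilities are linear in the two IBD-sharing
    coefficients (Delta, phi), solved jointly across loci by weighted least
    squares with locus weights 1/(2*a2 - a3); r = Delta + phi/2.  Allele
    frequencies default to those computed from the supplied panel itself
    (each entry counted once, i.e. over genotype classes, not over clonal
    copies); monomorphic loci are skipped.
    """
    ids = list(genotypes)
    if len(ids) < 2:
        raise ValueError("need >= 2 genotypes")
    g = np.vstack([np.asarray(genotypes[i], dtype=float) for i in ids])
    n_loci = g.shape[1]
    if site_ids is None:
        site_ids = [f"L{j}" for j in range(n_loci)]
    if allele_frequencies is None:
        p = g.mean(axis=0) / 2.0
    else:
        p = np.array([allele_frequencies[s] for s in site_ids], dtype=float)
    keep = (p > 0.0) & (p < 1.0)
    if not keep.any():
        raise ValueError("all loci monomorphic; relatedness undefined")
    if (~keep).any():
        log.info("wang_relatedness: skipping %d monomorphic loci", int((~keep).sum()))
    g = g[:, keep]
    p = p[keep]
    terms = _wang_locus_terms(p)
    n = len(ids)
    r = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = _pair_r(g[i], g[j], terms)
    freqs = {s: float(pp) for s, pp in zip(np.array(site_ids)[keep], p)}
    return RelatednessMatrix(ids=ids, matrix=r, allele_frequencies=freqs)


# ---------------------------------------------------------------------------
# ancestral candidate ranking and allele polarisation
# ---------------------------------------------------------------------------

@dataclass
class CandidateScore:
    class_id: str
    distance_to_att: float
    ambiguous_support: int   # classes sharing the candidate's state at ambiguous sites
    frequency: int
    network_degree: int

    def sort_key(self):
        return (self.distance_to_att, -self.ambiguous_support,
                -self.frequency, -self.network_degree, self.class_id)


def rank_ancestral_candidates(classes: list[GenotypeClass],
                              att: AncestralGenotype,
                              site_ids: Sequence[str],
                              network=None) -> list[CandidateScore]:
    """Rank genotype classes as ancestral candidates.

    Primary key: hamming distance to the ancestral genotype over its
    determined sites.  Ties break by (i) majority support at ambiguous sites
    — a candidate whose state there is shared by more classes outranks one
    carrying a unique state, (ii) descending frequency, (iii) descending
    network degree.
    """
    if not classes:
        raise ValueError("empty class list")
    site_pos = {s: j for j, s in enumerate(site_ids)}
    det_idx = [site_pos[s] for s in att.determined_sites if s in site_pos]
    amb_idx = [site_pos[s] for s in att.excluded_sites if s in site_pos]
    states = {c.class_id: np.asarray(c.state_vector) for c in classes}
    scores = []
    for c in classes:
        vec = states[c.class_id]
        dist = float(np.sum(vec[det_idx] != GT.HOM_REF)) if det_idx else 0.0
        support = 0
        for j in amb_idx:
            support += sum(int(states[o.class_id][j] == vec[j]) for o in classes)
        degree = 0
        if network is not None:
            degree = network.degree_of(c.class_id)
        scores.append(CandidateScore(c.class_id, dist, support, c.frequency, degree))
    scores.sort(key=CandidateScore.sort_key)
    return scores


DERIVED_IS_HET = "derived-is-het"
UNDETERMINED = "undetermined"


def polarize_alleles(site_ids: Sequence[str], att: AncestralGenotype) -> dict[str, str]:
    """Orient each site ancestral/derived.

    At determined sites the ancestral state is hom-ref, so the heterozygous
    (alt-carrying) state is the derived one; excluded sites stay undetermined.
    """
    det = set(att.determined_sites)
    return {s: (DERIVED_IS_HET if s in det else UNDETERMINED) for s in site_ids}
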