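"""Ancestral inference, ordination, relatedness, candidate ranking."""

import numpy as np
import pytest

from clonotrace import ancestry, pipeline
from clonotrace.genotypes import GenotypeClass
from clonotrace.util import GT


class TestInferAncestral:
    def test_double_homref_determined(self):
        att = ancestry.infer_ancestral({"B_chr01_1": GT.HOM_REF},
                                       {"B_chr01_1": GT.HOM_REF}, ["B_chr01_1"])
        assert att.site_status["B_chr01_1"] == ancestry.DETERMINED_HOM_REF

    def test_het_parent_excludes_site(self):
        att = ancestry.infer_ancestral({"B_chr19_11789116": GT.HET},
                                       {"B_chr19_11789116": GT.HOM_REF},
                                       ["B_chr19_11789116"])
        assert att.excluded_sites == ["B_chr19_11789116"]

    def test_missing_parent_entry_excluded(self):
        att = ancestry.infer_ancestral({}, {"B_chr01_1": GT.HOM_REF}, ["B_chr01_1"])
        assert att.excluded_sites == ["B_chr01_1"]

    def test_double_homalt_flagged_inconsistent(self):
        att = ancestry.infer_ancestral({"B_chr01_1": GT.HOM_ALT},
                                       {"B_chr01_1": GT.HOM_ALT}, ["B_chr01_1"])
        assert att.inconsistent_sites == ["B_chr01_1"]
        assert att.excluded_sites == ["B_chr01_1"]

    def test_retained_table_with_three_het_positions_excludes_three(self):
        # a 158-site parental table with exactly three parent-het positions
        sites = [f"B_chr{(i % 19) + 1:02d}_{1000 + i}" for i in range(158)]
        het_at = {sites[10], sites[77], sites[150]}
        p1 = {s: (GT.HET if s in het_at else GT.HOM_REF) for s in sites}
        p2 = {s: GT.HOM_REF for s in sites}
        att = ancestry.infer_ancestral(p1, p2, sites)
        assert len(att.excluded_sites) == 3
        assert set(att.excluded_sites) == het_at
        assert len(att.determined_sites) == 155


class TestPairwiseDistance:
    def test_identical_and_differing_vectors(self):
        v = {"a": np.array([0, 1, 0, 1, 1]), "b": np.array([0, 1, 0, 1, 1]),
             "c": np.array([1, 0, 1, 0, 1])}
        dm_h = ancestry.pairwise_distance(v, metric="hamming")
        dm_e = ancestry.pairwise_distance(v, metric="euclidean")
        assert dm_h.get("a", "b") == 0
        assert dm_h.get("a", "c") == 4
        assert dm_e.get("a", "c") == 2.0  # sqrt(4)

    def test_masked_entries_dropped_pairwise(self):
        v = {"att": np.array([0, -1, 0, -1]), "x": np.array([1, 1, 0, 1])}
        dm = ancestry.pairwise_distance(v, metric="hamming")
        assert dm.get("att", "x") == 1  # only determined sites compared

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            ancestry.pairwise_distance({"a": np.zeros(3), "b": np.zeros(4)})


class TestPcoa:
    def test_two_items_closed_form(self):
        dm = ancestry.DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]),
                                     "euclidean")
        res = ancestry.pcoa(dm)
        assert res.coordinates.shape == (2, 1)
        assert np.allclose(np.abs(res.coordinates[:, 0]), 1.0)

    def test_collinear_points_single_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        res = ancestry.pcoa(ancestry.DistanceMatrix(list("abcd"), d, "euclidean"))
        assert res.proportions[0] == pytest.approx(1.0)

    def test_distance_reconstruction_identity(self):
        rng = np.random.default_rng(3)
        vecs = {f"g{i}": rng.integers(0, 2, 30) for i in range(12)}
        dm = ancestry.pairwise_distance(vecs, metric="euclidean")
        res = ancestry.pcoa(dm)
        rec = np.sqrt(((res.coordinates[:, None, :] - res.coordinates[None, :, :]) ** 2).sum(-1))
        assert np.max(np.abs(rec - dm.matrix)) < 1e-8

    def test_binary_euclidean_is_embeddable(self):
        rng = np.random.default_rng(4)
        vecs = {f"g{i}": rng.integers(0, 2, 20) for i in range(10)}
        dm = ancestry.pairwise_distance(vecs, metric="euclidean")
        res = ancestry.pcoa(dm)
        assert res.eigenvalues.min() >= -1e-9 * max(res.eigenvalues.max(), 1.0)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(5)
        vecs = {f"g{i}": rng.integers(0, 2, 25) for i in range(8)}
        dm = ancestry.pairwise_distance(vecs, metric="euclidean")
        mine = ancestry.pcoa(dm)
        theirs = skbio_pcoa(skbio.DistanceMatrix(dm.matrix, ids=dm.ids))
        n = mine.coordinates.shape[1]
        ref = theirs.samples.to_numpy()[:, :n]
        for k in range(n):
            a, b = mine.coordinates[:, k], ref[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6


def _wang_oracle(gi, gj, p):
    """Straightforward per-locus transcription of the moment equations,
    solved by weighted least squares with numpy.linalg.lstsq."""
    rows_a, rows_y = [], []
    for x, y, pl in zip(gi, gj, p):
        q = 1 - pl
        a2 = pl ** 2 + q ** 2
        b1 = pl ** 4 + q ** 4 + 4 * pl ** 2 * q ** 2
        b2 = 4 * pl * q * a2
        b4 = 2 * pl ** 2 * q ** 2
        w = np.sqrt(1.0 / (2 * a2 - (pl ** 3 + q ** 3)))
        i1 = 1.0 if x == y else 0.0
        i2 = 1.0 if (x != y and (x == 1 or y == 1)) else 0.0
        i4 = 1.0 if {x, y} == {0, 2} else 0.0
        rows_a.append([w * (1 - b1), w * (a2 - b1)])
        rows_y.append(w * (i1 - b1))
        rows_a.append([w * (-b2), w * (2 * pl * q - b2)])
        rows_y.append(w * (i2 - b2))
        rows_a.append([w * (-b4), w * (-b4)])
        rows_y.append(w * (i4 - b4))
    sol, *_ = np.linalg.lstsq(np.array(rows_a), np.array(rows_y), rcond=None)
    return sol[0] + sol[1] / 2


class TestWangRelatedness:
    def test_symmetry(self):
        rng = np.random.default_rng(7)
        g = {f"s{i}": rng.binomial(2, 0.4, 50) for i in range(6)}
        rel = ancestry.wang_relatedness(g)
        assert np.allclose(rel.matrix, rel.matrix.T)
        assert np.isfinite(rel.matrix).all()

    def test_agrees_with_independent_transcription(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 40
            p = rng.uniform(0.1, 0.9, n)
            gi = rng.binomial(2, p)
            gj = rng.binomial(2, p)
            rel = ancestry.wang_relatedness(
                {"a": gi, "b": gj},
                allele_frequencies={f"L{k}": p[k] for k in range(n)})
            assert rel.get("a", "b") == pytest.approx(_wang_oracle(gi, gj, p), abs=1e-6)

    @pytest.mark.parametrize("related", [True, False])
    def test_mendelian_simulation_means(self, related):
        # 500 dyads at 200 loci, allele frequency 0.5: full sibs have expected
        # r = 0.5, unrelated pairs 0
        rng = np.random.default_rng(9 if related else 10)
        n_loci, p = 200, 0.5
        freqs = {f"L{j}": p for j in range(n_loci)}
        rs = []
        for _ in range(500):
            if related:
                pa = rng.binomial(1, p, (2, n_loci))
                pb = rng.binomial(1, p, (2, n_loci))
                idx = np.arange(n_loci)
                g = {"a": pa[rng.integers(0, 2, n_loci), idx] + pb[rng.integers(0, 2, n_loci), idx],
                     "b": pa[rng.integers(0, 2, n_loci), idx] + pb[rng.integers(0, 2, n_loci), idx]}
            else:
                g = {"a": rng.binomial(2, p, n_loci), "b": rng.binomial(2, p, n_loci)}
            rs.append(ancestry.wang_relatedness(g, allele_frequencies=freqs).get("a", "b"))
        target = 0.5 if related else 0.0
        assert abs(np.mean(rs) - target) < 0.05

    def test_all_monomorphic_raises(self):
        g = {"a": np.zeros(10), "b": np.zeros(10)}
        with pytest.raises(ValueError, match="monomorphic"):
            ancestry.wang_relatedness(g)


def _mk_classes(vectors, freqs=None):
    out = []
    for i, (cid, vec) in enumerate(sorted(vectors.items())):
        f = (freqs or {}).get(cid, 1)
        out.append(GenotypeClass(class_id=cid, state_vector=np.array(vec, dtype=np.int8),
                                 member_samples=[f"{cid}-m{k}" for k in range(f)]))
    return out


class TestRankAncestralCandidates:
    def test_single_class_is_ancestral(self):
        sites = ["B_chr01_1"]
        att = ancestry.infer_ancestral({"B_chr01_1": GT.HOM_REF},
                                       {"B_chr01_1": GT.HOM_REF}, sites)
        classes = _mk_classes({"GT-00": [0]})
        ranking = ancestry.rank_ancestral_candidates(classes, att, sites)
        assert ranking[0].class_id == "GT-00"

    def test_unique_state_at_ambiguous_site_ranks_lower(self):
        # two classes equidistant from the determined sites; the one carrying
        # the majority state at the parent-ambiguous site wins the tie
        sites = ["B_chr01_1", "B_chr19_9"]
        p1 = {"B_chr01_1": GT.HOM_REF, "B_chr19_9": GT.HET}
        p2 = {s: GT.HOM_REF for s in sites}
        att = ancestry.infer_ancestral(p1, p2, sites)
        classes = _mk_classes({"GT-00": [0, 0], "GT-08": [0, 1], "GT-02": [1, 0]})
        ranking = ancestry.rank_ancestral_candidates(classes, att, sites)
        assert [s.class_id for s in ranking][:2] == ["GT-00", "GT-08"]

    def test_order_invariance(self):
        sites = [f"B_chr01_{i}" for i in range(1, 6)]
        att = ancestry.infer_ancestral({s: GT.HOM_REF for s in sites},
                                       {s: GT.HOM_REF for s in sites}, sites)
        vectors = {"GT-00": [0, 0, 0, 0, 0], "GT-01": [1, 0, 0, 0, 0],
                   "GT-02": [1, 1, 0, 0, 0], "GT-03": [0, 0, 1, 1, 1]}
        a = ancestry.rank_ancestral_candidates(_mk_classes(vectors), att, sites)
        b = ancestry.rank_ancestral_candidates(list(reversed(_mk_classes(vectors))),
                                               att, sites)
        assert [s.class_id for s in a] == [s.class_id for s in b]

    def test_empty_class_list_raises(self):
        att = ancestry.infer_ancestral({}, {}, [])
        with pytest.raises(ValueError, match="empty"):
            ancestry.rank_ancestral_candidates([], att, [])


class TestPolarizeAlleles:
    def test_determined_sites_derived_is_het(self):
        sites = ["B_chr01_1", "B_chr02_2"]
        att = ancestry.infer_ancestral(
            {"B_chr01_1": GT.HOM_REF, "B_chr02_2": GT.HET},
            {s: GT.HOM_REF for s in sites}, sites)
        pol = ancestry.polarize_alleles(sites, att)
        assert pol["B_chr01_1"] == ancestry.DERIVED_IS_HET
        assert pol["B_chr02_2"] == ancestry.UNDETERMINED

    def test_simulated_orientation_matches_origin_edges(self, default_truth,
                                                        default_lineage):
        att, _, pol = pipeline.ancestral_analysis(default_truth, default_lineage)
        # every retained site is a true somatic mutation: the het state is the
        # derived one wherever the parents determine the ancestral state
        for sid in att.determined_sites:
            assert pol[sid] == ancestry.DERIVED_IS_HET
        for sid in att.excluded_sites:
            assert pol[sid] == ancestry.UNDETERMINED
        assert set(att.excluded_sites) == set(default_truth.parent_ambiguous_sites) & set(
            default_lineage.retained_sites)
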