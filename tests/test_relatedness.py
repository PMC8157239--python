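import numpy as np
import pytest

from famvar.pedigree import DEGREE_UNRELATED, RelationshipDegree
from famvar.relatedness import (
    IBDSegment,
    concordance_check,
    degree_from_ibd,
    estimate_kinship_moment,
    find_ibd_segments,
)
from famvar.simulate import simulate_degree_pair


class TestMomentEstimator:
    def test_identical_genotypes_half(self):
        g = np.array([0, 1, 2, 1, 0, 1], dtype=np.int8)
        est = estimate_kinship_moment(g, g)
        assert est.phi_hat == pytest.approx(0.5)
        assert est.degree == "self/MZ"

    def test_zero_denominator_flagged_not_silent(self):
        gi = np.array([0, 2, 0, 2], dtype=np.int8)
        gj = np.array([2, 0, 2, 0], dtype=np.int8)
        est = estimate_kinship_moment(gi, gj)
        assert est.undefined
        assert np.isnan(est.phi_hat)
        assert est.degree == DEGREE_UNRELATED

    def test_all_het_vs_opposite_homs_degenerate(self):
        # no het/het pairs and no opposite homozygotes involving a het sample:
        # the estimate collapses to 0 and classifies unrelated
        m = 50
        gi = np.ones(m, dtype=np.int8)
        gj = np.tile([0, 2], m // 2).astype(np.int8)
        est = estimate_kinship_moment(gi, gj)
        assert est.phi_hat == pytest.approx(0.0)
        assert est.degree == DEGREE_UNRELATED

    def test_negative_estimate_clamped_to_unrelated(self):
        gi = np.array([1] + [0, 2] * 20, dtype=np.int8)
        gj = np.array([1] + [2, 0] * 20, dtype=np.int8)
        est = estimate_kinship_moment(gi, gj)
        assert est.phi_hat < -0.5  # raw value reported un-clamped
        assert est.degree == DEGREE_UNRELATED

    def test_missing_markers_skipped(self):
        gi = np.array([1, -1, 1], dtype=np.int8)
        gj = np.array([1, 2, 1], dtype=np.int8)
        est = estimate_kinship_moment(gi, gj)
        assert est.n_markers_used == 2
        assert est.phi_hat == pytest.approx(0.5)

    def test_misaligned_vectors_error(self):
        with pytest.raises(ValueError):
            estimate_kinship_moment(np.zeros(3, dtype=np.int8), np.zeros(4, dtype=np.int8))

    def test_parent_offspring_simulation(self):
        # gene-dropping oracle: expectation 1/4 at 20k markers
        pair = simulate_degree_pair(1, seed=11, n_markers_per_chrom=10_000, n_chroms=2)
        est = estimate_kinship_moment(pair["genotypes_i"], pair["genotypes_j"])
        assert 0.23 <= est.phi_hat <= 0.27
        assert est.degree == "1"

    @pytest.mark.parametrize("alpha,beta", [(0.2, 0.2), (2.0, 2.0), (1.0, 3.0)])
    def test_af_robustness_unrelated(self, alpha, beta):
        # simulated unrelated pairs give ~0 regardless of the AF spectrum
        rng = np.random.default_rng(int(alpha * 10 + beta))
        n = 50_000
        af = np.clip(rng.beta(alpha, beta, size=n), 0.01, 0.99)
        gi = (rng.random((2, n)) < af).sum(axis=0).astype(np.int8)
        gj = (rng.random((2, n)) < af).sum(axis=0).astype(np.int8)
        est = estimate_kinship_moment(gi, gj)
        assert abs(est.phi_hat) < 0.02


def _hap_pair(h0, h1):
    return {"1": np.stack([np.asarray(h0, dtype=np.uint8), np.asarray(h1, dtype=np.uint8)])}


class TestIBDSegments:
    def test_self_spans_chromosome(self):
        rng = np.random.default_rng(0)
        haps = {c: (rng.random((2, 500)) < 0.5).astype(np.uint8) for c in ("1", "2")}
        gmap = {c: np.linspace(0, 100, 500) for c in ("1", "2")}
        segs = find_ibd_segments(haps, haps, gmap, min_cm=3)
        half = [s for s in segs if not s.ibd2]
        assert len(half) == 2
        assert all(s.start_marker == 0 and s.end_marker == 499 for s in half)
        ibd2 = [s for s in segs if s.ibd2]
        assert len(ibd2) == 2

    def test_no_sharing_empty(self):
        n = 400
        h = np.zeros(n, dtype=np.uint8)
        i = _hap_pair(h, h)
        j = _hap_pair(1 - h, 1 - h)
        gmap = {"1": np.linspace(0, 100, n)}
        assert find_ibd_segments(i, j, gmap, min_cm=1) == []

    def test_planted_segment_recovered_exactly(self):
        # all four pairings mismatch outside the planted window by construction
        rng = np.random.default_rng(3)
        n = 1000
        gmap = {"1": np.linspace(0, 100, n)}
        base = (rng.random(n) < 0.5).astype(np.uint8)
        i = _hap_pair(base, base)
        j0 = (1 - base).copy()
        a, b = 300, 399  # ~10 cM
        j0[a : b + 1] = base[a : b + 1]
        j = _hap_pair(j0, 1 - base)
        segs = [s for s in find_ibd_segments(i, j, gmap, min_cm=3) if not s.ibd2]
        assert len(segs) == 1
        assert (segs[0].start_marker, segs[0].end_marker) == (a, b)
        assert segs[0].cm == pytest.approx(gmap["1"][b] - gmap["1"][a])

    def test_min_cm_filters_short_segments(self):
        n = 1000
        base = np.zeros(n, dtype=np.uint8)
        j0 = np.ones(n, dtype=np.uint8)
        j0[500:510] = 0  # ~1 cM
        i = _hap_pair(base, base)
        j = _hap_pair(j0, np.ones(n, dtype=np.uint8))
        gmap = {"1": np.linspace(0, 100, n)}
        assert find_ibd_segments(i, j, gmap, min_cm=3, min_informative=5) == []
        assert len(find_ibd_segments(i, j, gmap, min_cm=0.5, min_informative=5)) == 1

    def test_unmapped_chromosome_errors(self):
        i = _hap_pair([0, 1], [1, 0])
        with pytest.raises(KeyError):
            find_ibd_segments(i, i, {"2": np.array([0.0, 1.0])}, min_cm=1)

    def test_parent_offspring_half_ibd_spans_genome(self):
        pair = simulate_degree_pair(1, seed=5, n_markers_per_chrom=4000, n_chroms=2)
        segs = find_ibd_segments(
            pair["haplotypes_i"], pair["haplotypes_j"], pair["genetic_map"], min_cm=3
        )
        half_total = sum(s.cm for s in segs if not s.ibd2)
        assert half_total >= 0.98 * pair["genome_cm"]


class TestDegreeFromIBD:
    def test_zero_segments_unrelated(self):
        est = degree_from_ibd([], genome_cm=3000.0)
        assert est.phi_hat == 0.0
        assert est.degree == DEGREE_UNRELATED

    def test_full_genome_ibd2_is_half(self):
        segs = [
            IBDSegment("1", 0, 99, 100.0, ibd2=False),
            IBDSegment("1", 0, 99, 100.0, ibd2=True),
        ]
        est = degree_from_ibd(segs, genome_cm=100.0)
        assert est.phi_hat == pytest.approx(0.5)
        assert est.degree == "self/MZ"

    def test_half_genome_ibd1_is_parent_offspring(self):
        segs = [IBDSegment("1", 0, 99, 100.0, ibd2=False)]
        est = degree_from_ibd(segs, genome_cm=100.0)
        assert est.phi_hat == pytest.approx(0.25)
        assert est.degree == "1"


class TestConcordance:
    def _rels(self):
        return [
            RelationshipDegree(("a", "b"), 0.25, "1"),
            RelationshipDegree(("c", "d"), 1 / 64, "5"),
        ]

    def test_perfect_agreement_no_flags(self):
        from famvar.relatedness import KinshipEstimate

        ests = [
            KinshipEstimate(("a", "b"), 0.24, 100, "moment", "1"),
            KinshipEstimate(("c", "d"), 0.014, 100, "ibd_segment", "5"),
        ]
        report = concordance_check(self._rels(), ests)
        assert not any(c.flagged for c in report)

    def test_missing_estimate_untestable(self):
        report = concordance_check(self._rels(), [])
        assert all(c.flagged and c.reason == "untestable" for c in report)

    def test_tolerance(self):
        from famvar.relatedness import KinshipEstimate

        ests = [
            KinshipEstimate(("a", "b"), 0.13, 100, "moment", "2"),  # off by 1: ok
            KinshipEstimate(("c", "d"), 0.25, 100, "moment", "1"),  # off by 4: flag
        ]
        report = concordance_check(self._rels(), ests, tolerance=1)
        assert [c.flagged for c in report] == [False, True]

    def test_simulated_cross_family_pairs_unrelated(self, sim):
        # affected samples from different families classify deep or unrelated
        # under the two-stage (moment -> IBD fallback) classifier
        import itertools

        from famvar.pedigree import degree_as_int
        from famvar.relatedness import classify_pair

        cm_map = {c: cm for c, (_, cm) in sim.genetic_map.items()}
        fams = sim.cohort.families
        for (fa, ma), (fb, mb) in itertools.combinations(fams.items(), 2):
            est = classify_pair(
                sim.haplotypes[ma[0]], sim.haplotypes[mb[0]], cm_map,
                sim.genome_cm, (ma[0], mb[0]),
            )
            assert degree_as_int(est.degree) >= 8

    def test_simulated_close_pairs_classified_within_one(self, sim):
        # degree-1/2 within-family pairs land within one degree of the
        # pedigree; degree-5 pairs are detected as related (their realized
        # kinship on a 200 cM genome varies too much for an exact call)
        from famvar.pedigree import degree_as_int
        from famvar.relatedness import classify_pair

        cm_map = {c: cm for c, (_, cm) in sim.genetic_map.items()}
        truth = {tuple(k.split(",")): d for k, d in sim.ground_truth.degrees.items()}
        for (m1, m2), degree in truth.items():
            est = classify_pair(
                sim.haplotypes[m1], sim.haplotypes[m2], cm_map,
                sim.genome_cm, (m1, m2),
            )
            if degree <= 2:
                assert abs(degree_as_int(est.degree) - degree) <= 1
            else:
                assert est.degree not in ("unrelated",)
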