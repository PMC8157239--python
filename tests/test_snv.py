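import numpy as np
import pytest

from famvar.snv import (
    FilterTrace,
    annotate_cancer_genes,
    cadd_tier,
    consequence_filter,
    cross_family_variants,
    exonic_window,
    filter_pon,
    filter_rare,
    locus_scan,
    recurrent_genes,
    run_snv_pipeline,
    shared_within_family,
)
from famvar.variant_model import AnnotatedVariant, BreakendPair, FamilyCohort, GeneModel
from oracles import naive_snv_stages, random_cohort


def mkvar(pos=100, chrom="1", ref="A", alt="T", **kw):
    defaults = dict(chrom=chrom, pos=pos, ref=ref, alt=alt)
    defaults.update(kw)
    return AnnotatedVariant(**defaults)


class TestSharedWithinFamily:
    def test_both_het_kept(self):
        v = mkvar(genotypes={"a": 1, "b": 1})
        assert shared_within_family([v], ["a", "b"]) == [v]

    def test_one_homref_dropped(self):
        v = mkvar(genotypes={"a": 1, "b": 0})
        assert shared_within_family([v], ["a", "b"]) == []

    def test_missing_genotype_dropped(self):
        v = mkvar(genotypes={"a": 1, "b": None})
        assert shared_within_family([v], ["a", "b"]) == []

    def test_het_hom_mixture_kept(self):
        v = mkvar(genotypes={"a": 1, "b": 2})
        assert shared_within_family([v], ["a", "b"]) == [v]

    def test_small_family_errors(self):
        with pytest.raises(ValueError):
            shared_within_family([], ["only"])


class TestFilterRare:
    def test_boundaries(self):
        kept = filter_rare(
            [mkvar(pop_af=0.0005), mkvar(pop_af=0.002), mkvar(pop_af=None), mkvar(pop_af=0.001)]
        )
        assert [v.pop_af for v in kept] == [0.0005, None, 0.001]


class TestFilterPon:
    def test_flag_dropped(self):
        assert filter_pon([mkvar(in_pon=True)]) == []
        v = mkvar(in_pon=False)
        assert filter_pon([v]) == [v]

    def test_unnormalized_pon_entry_still_matches(self):
        # variant is the trimmed form; the PoN holds a padded representation
        v = mkvar(pos=100, ref="AT", alt="A")
        pon = {("1", 100, "ATT", "AT")}
        assert filter_pon([v], pon) == []

    def test_commutes_with_rare(self):
        rng = np.random.default_rng(5)
        variants, *_ , pon = random_cohort(rng, 200)
        a = [v.vid for v in filter_rare(filter_pon(variants, pon))]
        b = [v.vid for v in filter_pon(filter_rare(variants), pon)]
        assert a == b


class TestExonicWindow:
    GM = [GeneModel(gene="g1", chrom="1", strand="+", exons=[(1000, 2000)])]

    def test_pad_boundary_inclusive(self):
        kept, _ = exonic_window([mkvar(pos=990)], self.GM, pad=10)
        assert len(kept) == 1
        kept, _ = exonic_window([mkvar(pos=989)], self.GM, pad=10)
        assert kept == []

    def test_overlapping_genes_single_variant_both_genes(self):
        gms = self.GM + [GeneModel(gene="g2", chrom="1", strand="-", exons=[(1500, 2500)])]
        kept, gene_map = exonic_window([mkvar(pos=1600)], gms, pad=10)
        assert len(kept) == 1
        assert gene_map[kept[0].vid] == frozenset({"g1", "g2"})

    def test_wrong_chromosome_dropped(self):
        kept, _ = exonic_window([mkvar(pos=1500, chrom="2")], self.GM)
        assert kept == []


class TestConsequenceFilter:
    def test_truncating_kept_without_predictors(self):
        v = mkvar(effect="frameshift", predictor_calls=("benign",) * 5)
        kept, exc = consequence_filter([v])
        assert kept == [v] and exc == []

    def test_nonsynonymous_three_of_five_kept(self):
        v = mkvar(effect="nonsynonymous",
                  predictor_calls=("pathogenic",) * 3 + ("benign",) * 2)
        kept, exc = consequence_filter([v])
        assert kept == [v]

    def test_nonsynonymous_two_of_five_is_exception(self):
        v = mkvar(effect="nonsynonymous",
                  predictor_calls=("pathogenic",) * 2 + ("benign",) * 3)
        kept, exc = consequence_filter([v])
        assert kept == [] and exc == [v]

    def test_missing_counts_against(self):
        v = mkvar(effect="nonsynonymous",
                  predictor_calls=("pathogenic", "pathogenic", "missing", "missing", "missing"))
        kept, exc = consequence_filter([v])
        assert kept == [] and exc == [v]

    def test_synonymous_never_kept(self):
        v = mkvar(effect="synonymous", predictor_calls=("pathogenic",) * 5)
        kept, exc = consequence_filter([v])
        assert kept == [] and exc == []


class TestCaddTier:
    @pytest.mark.parametrize(
        "score,tier",
        [(None, "none"), (4.99, "none"), (5.0, "annotate"), (19.99, "annotate"),
         (20.0, "assess"), (30.0, "assess"), (30.01, "highlight")],
    )
    def test_boundaries(self, score, tier):
        assert cadd_tier(mkvar(cadd_phred=score)) == tier


class TestCancerGenes:
    def test_flagging_never_filters(self):
        from famvar.snv import CandidateVariant

        cands = [
            CandidateVariant(mkvar(), frozenset({"A"}), genes=frozenset({"TP53"})),
            CandidateVariant(mkvar(pos=5), frozenset({"A"}), genes=frozenset({"OTHER"})),
        ]
        out = annotate_cancer_genes(cands, ["tp53"])
        assert [c.cancer_gene for c in out] == [True, False]
        assert len(out) == 2

    def test_empty_list_flags_nothing(self):
        from famvar.snv import CandidateVariant

        out = annotate_cancer_genes(
            [CandidateVariant(mkvar(), frozenset({"A"}), genes=frozenset({"TP53"}))], []
        )
        assert not out[0].cancer_gene


class TestCrossFamilyAndRecurrence:
    def test_cross_family_reports_family_set(self):
        v = mkvar()
        out = cross_family_variants({"A": [v], "B": [], "C": [v]})
        assert out[v.vid][1] == frozenset({"A", "C"})

    def test_single_family_excluded(self):
        assert cross_family_variants({"A": [mkvar()], "B": []}) == {}

    def test_recurrent_genes_different_variants_same_gene(self):
        va, vb = mkvar(pos=10), mkvar(pos=20)
        out = recurrent_genes(
            {"A": [(va, frozenset({"g"}))], "B": [(vb, frozenset({"g"}))]}
        )
        assert out == {"g": frozenset({"A", "B"})}

    def test_gene_twice_in_one_family_excluded(self):
        out = recurrent_genes(
            {"A": [(mkvar(pos=10), frozenset({"g"})), (mkvar(pos=20), frozenset({"g"}))]}
        )
        assert out == {}

    def test_blacklist_excluded(self):
        va, vb = mkvar(pos=10), mkvar(pos=20)
        out = recurrent_genes(
            {"A": [(va, frozenset({"MUC99"}))], "B": [(vb, frozenset({"MUC99"}))]},
            blacklist=["muc99"],
        )
        assert out == {}

    def test_quality_fail_support_removed(self):
        va = mkvar(pos=10, quality_pass=False)
        vb = mkvar(pos=20)
        out = recurrent_genes(
            {"A": [(va, frozenset({"g"}))], "B": [(vb, frozenset({"g"}))]}
        )
        assert out == {}


class TestLocusScan:
    GM = [GeneModel(gene="target", chrom="1", strand="+", exons=[(200_000, 220_000)])]

    def test_flank_boundaries(self):
        inside = mkvar(pos=200_000 - 74_999, pop_af=None)
        outside = mkvar(pos=200_000 - 75_001, pop_af=None, alt="G")
        res = locus_scan([inside, outside], [], self.GM, ["target"])
        assert [v.vid for v in res["target"]["snvs"]] == [inside.vid]

    def test_common_variants_ignored(self):
        common = mkvar(pos=210_000, pop_af=0.2)
        res = locus_scan([common], [], self.GM, ["target"])
        assert res["target"]["snvs"] == []

    def test_sv_span_overlap(self):
        sv = BreakendPair("d1", "DEL", "1", 100_000, "+", "1", 130_000, "-", sample="s")
        far = BreakendPair("d2", "DEL", "1", 500_000, "+", "1", 502_000, "-", sample="s")
        res = locus_scan([], [sv, far], self.GM, ["target"])
        assert [s.sv_id for s in res["target"]["svs"]] == ["d1"]

    def test_quiet_loci_clean_on_default_cohort(self, sim):
        res = locus_scan(
            sim.variants, sim.svs, sim.gene_models, sim.ground_truth.quiet_genes
        )
        for gene in sim.ground_truth.quiet_genes:
            assert res[gene]["snvs"] == []
            assert res[gene]["svs"] == []


class TestFilterTrace:
    def test_monotonicity_enforced(self):
        trace = FilterTrace()
        trace.add("a", ["x", "y"], ["x"])
        with pytest.raises(ValueError):
            trace.add("b", ["x"], ["x", "y"])
        with pytest.raises(ValueError):
            trace.add("c", ["x"], ["z"])


def _printed_table_fixture():
    """The published per-family candidate table re-encoded as variants:
    19 criteria-meeting entries plus one 2/5 near-miss tumor-suppressor."""
    rows = [
        ("A", "HTRA4", "nonsynonymous", 3), ("A", "LRP2", "nonsynonymous", 4),
        ("A", "PCSK9", "nonsynonymous", 3),
        ("B", "BMP5", "nonsynonymous", 5), ("B", "CRLF2", "frameshift", 0),
        ("B", "FSCN3", "nonsynonymous", 3), ("B", "HFM1", "nonsynonymous", 4),
        ("B", "MET", "nonsynonymous", 3), ("B", "NOX5", "nonsynonymous", 3),
        ("B", "SPTBN5", "nonsynonymous", 4), ("B", "TEAD2", "frameshift", 0),
        ("C", "CBX8", "nonsynonymous", 3), ("C", "HYDIN", "frameshift", 1),
        ("C", "IGSF1", "nonsynonymous", 4), ("C", "LAMA3", "nonsynonymous", 3),
        ("C", "PSMD5", "nonsynonymous", 3), ("C", "PXDN", "nonsynonymous", 5),
        ("C", "TBP", "frameshift", 0),
        ("D", "USP44", "nonsynonymous", 3), ("D", "RASSF2", "nonsynonymous", 2),
    ]
    cohort = FamilyCohort(
        families={f: [f + "1", f + "2"] for f in "ABCD"}, reference_samples=[]
    )
    variants, gene_models = [], []
    for k, (fam, gene, effect, n_path) in enumerate(rows):
        pos = 10_000 + 1000 * k
        gene_models.append(
            GeneModel(gene=gene, chrom="1", strand="+", exons=[(pos - 50, pos + 50)])
        )
        genotypes = {s: 0 for f in "ABCD" for s in (f + "1", f + "2")}
        genotypes[fam + "1"] = genotypes[fam + "2"] = 1
        calls = ("pathogenic",) * n_path + ("benign",) * (5 - n_path)
        variants.append(
            mkvar(pos=pos, gene=gene, effect=effect, predictor_calls=calls,
                  pop_af=None, cadd_phred=22.0, genotypes=genotypes)
        )
    return variants, cohort, gene_models


class TestPipeline:
    def test_printed_table_fixture(self):
        variants, cohort, gene_models = _printed_table_fixture()
        trace, candidates, _ = run_snv_pipeline(variants, cohort, gene_models)
        passing = [c for c in candidates if not c.exception]
        exceptions = [c for c in candidates if c.exception]
        assert len(passing) == 19
        assert len(exceptions) == 1
        assert exceptions[0].genes == frozenset({"RASSF2"})
        assert exceptions[0].families == frozenset({"D"})

    def test_empty_input_all_zero_trace(self):
        cohort = FamilyCohort(families={"A": ["A1", "A2"]})
        trace, candidates, branch_b = run_snv_pipeline([], cohort, [])
        assert all(n_in == 0 and n_out == 0 for _, n_in, n_out in trace.counts())
        assert candidates == []
        assert branch_b["cross_family"] == {}

    def test_planted_variants_survive_branch_a(self, sim):
        trace, candidates, _ = run_snv_pipeline(
            sim.variants, sim.cohort, sim.gene_models, pon=sim.pon
        )
        surviving = {c.variant.vid for c in candidates if not c.exception}
        for fam, pv in sim.ground_truth.planted_branch_a.items():
            assert pv.vid in surviving
            (cand,) = [c for c in candidates if c.variant.vid == pv.vid]
            assert fam in cand.families
            assert pv.gene in cand.genes

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_funnel_monotone_on_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        variants, cohort, gene_models, pon = random_cohort(rng, 250)
        trace, _, _ = run_snv_pipeline(variants, cohort, gene_models, pon=pon)
        for _, n_in, n_out in trace.counts():
            assert n_out <= n_in

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_equivalence_with_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        variants, cohort, gene_models, pon = random_cohort(rng, 400)
        trace, _, branch_b = run_snv_pipeline(variants, cohort, gene_models, pon=pon)
        naive = naive_snv_stages(variants, cohort, gene_models, pon)
        got = {name: set(ids) for name, _, _, ids in trace.stages}
        for stage, expected_ids in naive["stages"].items():
            assert got[stage] == expected_ids, stage
        assert set(branch_b["cross_family"]) == naive["cross_family"]
        assert set(branch_b["recurrent_genes"]) == naive["recurrent_genes"]
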