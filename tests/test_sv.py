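import numpy as np
import pytest

from famvar.sv import (
    breakends_overlap,
    chrom_dosage_check,
    family_shared_groups,
    filter_sv_catalogue,
    genes_in_sv,
    group_svs,
    sv_recurrent_genes,
)
from famvar.variant_model import BreakendPair, FamilyCohort, GeneModel
from oracles import closure_partition, random_svs


def mkdel(sv_id="d", pos1=1000, pos2=3000, chrom="1", sample="s", sv_type="DEL",
          ci=(0, 0), in_catalogue=False):
    o1, o2 = ("+", "-") if sv_type != "DUP" else ("-", "+")
    return BreakendPair(sv_id, sv_type, chrom, pos1, o1, chrom, pos2, o2,
                        ci1=ci, ci2=ci, sample=sample, in_catalogue=in_catalogue)


class TestBreakendsOverlap:
    def test_identical(self):
        assert breakends_overlap(mkdel("a"), mkdel("b"))

    def test_shifted_within_gap(self):
        assert breakends_overlap(mkdel("a"), mkdel("b", pos1=1080, pos2=3080))

    def test_shifted_beyond_gap(self):
        assert not breakends_overlap(mkdel("a"), mkdel("b", pos1=1300, pos2=3300))

    def test_ci_expansion_rescues(self):
        a = mkdel("a")
        b = mkdel("b", pos1=1150, pos2=3150, ci=(-60, 60))
        assert breakends_overlap(a, b, max_gap=100)

    def test_type_mismatch(self):
        assert not breakends_overlap(mkdel("a"), mkdel("b", sv_type="DUP"))

    def test_orientation_mismatch(self):
        a = mkdel("a")
        b = BreakendPair("b", "DEL", "1", 1000, "-", "1", 3000, "-", sample="s")
        assert not breakends_overlap(a, b)

    def test_chromosome_mismatch(self):
        assert not breakends_overlap(mkdel("a"), mkdel("b", chrom="2"))

    def test_bnd_canonical_slot_matching(self):
        a = BreakendPair("a", "BND", "1", 100, "+", "2", 5000, "-", sample="s")
        b = BreakendPair("b", "BND", "2", 5020, "-", "1", 120, "+", sample="t")
        assert breakends_overlap(a, b)


class TestGroupSvs:
    def test_chain_transitivity(self):
        a = mkdel("a", pos1=1000, pos2=3000)
        b = mkdel("b", pos1=1120, pos2=3120)
        c = mkdel("c", pos1=1240, pos2=3240)
        assert not breakends_overlap(a, c)
        groups = group_svs([a, b, c])
        assert len(groups) == 1
        assert len(groups[0].members) == 3

    def test_partition_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        svs = random_svs(rng, 30)
        groups = group_svs(svs)
        members = sorted(m for g in groups for m in g.members)
        assert members == sorted((s.sample, s.sv_id) for s in svs)
        perm = [svs[i] for i in rng.permutation(len(svs))]
        regrouped = group_svs(perm)
        assert {frozenset(g.members) for g in groups} == {
            frozenset(g.members) for g in regrouped
        }
        assert [g.group_id for g in groups] == [g.group_id for g in regrouped]

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_closure(self, seed):
        rng = np.random.default_rng(seed)
        svs = random_svs(rng, int(rng.integers(5, 50)))
        got = {frozenset(g.members) for g in group_svs(svs, max_gap=100)}
        expected = closure_partition(svs, max_gap=100)
        assert got == expected

    def test_deterministic_consensus(self):
        a, b = mkdel("a", pos1=1000, pos2=3000), mkdel("b", pos1=1100, pos2=3100)
        (g,) = group_svs([a, b])
        assert g.consensus[0][1] in (1000, 1100)


class TestCatalogueFilter:
    def test_exact_match_dropped(self):
        cat = [mkdel("cat", in_catalogue=True)]
        assert filter_sv_catalogue([mkdel("x")], cat) == []

    def test_near_match_dropped(self):
        cat = [mkdel("cat", in_catalogue=True)]
        assert filter_sv_catalogue([mkdel("x", pos1=1090, pos2=3090)], cat) == []

    def test_disjoint_kept(self):
        cat = [mkdel("cat", in_catalogue=True)]
        sv = mkdel("x", pos1=50_000, pos2=60_000)
        assert filter_sv_catalogue([sv], cat) == [sv]

    def test_flagged_member_dropped_without_catalogue(self):
        assert filter_sv_catalogue([mkdel("x", in_catalogue=True)], []) == []

    def test_subset_property(self):
        rng = np.random.default_rng(9)
        svs = random_svs(rng, 40)
        cat = random_svs(rng, 5)
        kept = filter_sv_catalogue(svs, cat)
        assert {s.sv_id for s in kept} <= {s.sv_id for s in svs}


COHORT = FamilyCohort(families={"A": ["A1", "A2"], "B": ["B1", "B2"]})


class TestFamilySharedGroups:
    def test_full_family_kept(self):
        groups = group_svs([mkdel("a", sample="A1"), mkdel("b", sample="A2")])
        kept = family_shared_groups(groups, COHORT)
        assert len(kept) == 1
        assert kept[0].families == frozenset({"A"})

    def test_split_across_families_dropped(self):
        groups = group_svs([mkdel("a", sample="A1"), mkdel("b", sample="B1")])
        assert family_shared_groups(groups, COHORT) == []

    def test_singleton_dropped(self):
        groups = group_svs([mkdel("a", sample="A1")])
        assert family_shared_groups(groups, COHORT) == []

    def test_planted_family_groups_recovered(self, sim):
        kept = filter_sv_catalogue(sim.svs, sim.sv_catalogue)
        groups = group_svs(kept)
        fam_groups = family_shared_groups(groups, sim.cohort)
        fams_seen = {f for g in fam_groups for f in g.families}
        assert fams_seen == set(sim.cohort.families)
        planted_ids = {
            i for d in sim.ground_truth.planted_svs.values() for i in d["sv_ids"]
        }
        kept_ids = {sv_id for g in fam_groups for _, sv_id in g.members}
        assert planted_ids <= kept_ids

    def test_decoys_never_join_planted_groups(self, sim):
        groups = group_svs(sim.svs)
        for g in groups:
            ids = {sv_id for _, sv_id in g.members}
            if any("planted" in i for i in ids):
                assert all("planted" in i for i in ids)


class TestGenesInSv:
    GM = [
        GeneModel(gene="inside", chrom="1", strand="+", exons=[(1500, 2500)]),
        GeneModel(gene="outside", chrom="1", strand="+", exons=[(50_000, 51_000)]),
        GeneModel(gene="nearbnd", chrom="2", strand="+", exons=[(10_500, 11_000)]),
    ]

    def test_gene_inside_del(self):
        (g,) = group_svs([mkdel("a", pos1=1000, pos2=3000)])
        assert genes_in_sv(g, self.GM) == frozenset({"inside"})

    def test_bnd_flank(self):
        sv = BreakendPair("b", "BND", "1", 100, "+", "2", 10_000, "-", sample="s")
        (g,) = group_svs([sv])
        assert genes_in_sv(g, self.GM, bnd_flank=1000) == frozenset({"nearbnd"})
        assert genes_in_sv(g, self.GM, bnd_flank=100) == frozenset()

    def test_empty_models(self):
        (g,) = group_svs([mkdel("a")])
        assert genes_in_sv(g, []) == frozenset()


class TestSvRecurrentGenes:
    def test_two_family_gene_reported(self):
        gm = [GeneModel(gene="hit", chrom="1", strand="+", exons=[(1000, 40_000)])]
        groups = group_svs(
            [mkdel("a", sample="A1"), mkdel("b", sample="A2"),
             mkdel("c", pos1=30_000, pos2=35_000, sample="B1"),
             mkdel("d", pos1=30_000, pos2=35_000, sample="B2")]
        )
        fam = family_shared_groups(groups, COHORT)
        assert sv_recurrent_genes(fam, gm) == {"hit": frozenset({"A", "B"})}

    def test_two_groups_same_family_excluded(self):
        gm = [GeneModel(gene="hit", chrom="1", strand="+", exons=[(1000, 40_000)])]
        groups = group_svs(
            [mkdel("a", sample="A1"), mkdel("b", sample="A2"),
             mkdel("c", pos1=30_000, pos2=35_000, sample="A1"),
             mkdel("d", pos1=30_000, pos2=35_000, sample="A2")]
        )
        fam = family_shared_groups(groups, COHORT)
        assert sv_recurrent_genes(fam, gm) == {}

    def test_planted_recurrent_gene_on_default_cohort(self, sim):
        kept = filter_sv_catalogue(sim.svs, sim.sv_catalogue)
        fam_groups = family_shared_groups(group_svs(kept), sim.cohort)
        recurrent = sv_recurrent_genes(fam_groups, sim.gene_models)
        truth = sim.ground_truth
        assert recurrent == {
            truth.sv_recurrent_gene: frozenset(truth.sv_recurrent_families)
        }


class TestChromDosage:
    def _family_group(self, chrom, sv_type, samples=("A1", "A2")):
        svs = [mkdel(f"{s}_x", chrom=chrom, sample=s, sv_type=sv_type) for s in samples]
        return family_shared_groups(group_svs(svs), COHORT)

    def test_no_svs_empty(self):
        assert chrom_dosage_check([]) == []

    def test_chr14_dup_single_family(self):
        flags = chrom_dosage_check(self._family_group("14", "DUP"))
        assert len(flags) == 1
        assert flags[0]["families"] == ["A"]
        assert not flags[0]["multiple_families"]

    def test_chr22_del_two_families_flagged_multiple(self):
        svs = [mkdel(f"{s}_x", chrom="chr22", sample=s) for s in ("A1", "A2", "B1", "B2")]
        flags = chrom_dosage_check(family_shared_groups(group_svs(svs), COHORT))
        assert len(flags) == 1
        assert flags[0]["multiple_families"]

    def test_other_chrom_ignored(self):
        assert chrom_dosage_check(self._family_group("5", "DUP")) == []
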