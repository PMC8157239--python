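"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (nested loops, no indexes, no shared
code with the package internals) so it can serve as a second route for
equivalence checks.
"""

from __future__ import annotations

import numpy as np

from famvar.pedigree import Pedigree
from famvar.variant_model import AnnotatedVariant, BreakendPair, FamilyCohort, GeneModel

# ---------------------------------------------------------------------------
# allele trimming


def brute_trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared suffix then shared prefix characters one at a time,
    keeping at least one character in each allele."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref = ref[:-1]
        alt = alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# Monte-Carlo kinship by single-locus gene dropping


def mc_kinship(ped: Pedigree, i: str, j: str, n_drops: int, rng: np.random.Generator) -> float:
    """Estimate P(random allele of i IBD to random allele of j) by dropping
    uniquely labelled founder alleles through the pedigree ``n_drops`` times
    (vectorized over drops)."""
    order = sorted(ped.individuals, key=lambda x: ped._depth[x])
    alleles: dict[str, np.ndarray] = {}
    label = 0
    for iid in order:
        ind = ped.individuals[iid]
        if ped.is_founder(iid):
            a = np.full((n_drops, 2), 0, dtype=np.int32)
            a[:, 0] = label
            a[:, 1] = label + 1
            label += 2
            alleles[iid] = a
        else:
            a = np.empty((n_drops, 2), dtype=np.int32)
            for slot, parent in enumerate((ind.father, ind.mother)):
                pick = rng.integers(0, 2, size=n_drops)
                a[:, slot] = alleles[parent][np.arange(n_drops), pick]
            alleles[iid] = a
    ai, aj = alleles[i], alleles[j]
    ibd = np.zeros(n_drops)
    for s in range(2):
        for t in range(2):
            ibd += (ai[:, s] == aj[:, t]).astype(float)
    return float(ibd.mean() / 4.0)


# ---------------------------------------------------------------------------
# naive SNV stage cascade


def naive_snv_stages(
    variants,
    cohort: FamilyCohort,
    gene_models,
    pon,
    pop_af_max=0.001,
    pad=10,
    predictor_min=3,
    min_families=2,
) -> dict:
    """Nested-loop reimplementation of the SNV cascade; returns per-stage
    surviving id sets and branch-B outputs for equivalence checks."""

    def carrier(v, s):
        gt = v.genotypes.get(s)
        return gt is not None and gt >= 1

    per_family = {}
    for fam, members in cohort.families.items():
        kept = []
        for v in variants:
            if all(carrier(v, s) for s in members):
                kept.append(v)
        per_family[fam] = kept

    def union(pf):
        ids = set()
        for vs in pf.values():
            for v in vs:
                ids.add(v.vid)
        return ids

    stages = {"shared_within_family": union(per_family)}

    per_family = {f: [v for v in vs if v.quality_pass] for f, vs in per_family.items()}
    stages["quality_pass"] = union(per_family)
    per_family = {
        f: [v for v in vs if v.pop_af is None or v.pop_af <= pop_af_max]
        for f, vs in per_family.items()
    }
    stages["rare"] = union(per_family)

    def in_pon(v):
        if v.in_pon:
            return True
        if pon:
            p, r, a = brute_trim(v.pos, v.ref, v.alt)
            for (pc, pp, pr, pa) in pon:
                qp, qr, qa = brute_trim(pp, pr, pa)
                if (v.chrom, p, r, a) == (pc, qp, qr, qa):
                    return True
        return False

    per_family = {f: [v for v in vs if not in_pon(v)] for f, vs in per_family.items()}
    stages["pool_of_normals"] = union(per_family)
    per_family_filtered = per_family

    def exon_genes(v):
        genes = set()
        for gm in gene_models:
            if gm.chrom != v.chrom:
                continue
            for (s, e) in gm.exons:
                if s - pad <= v.pos <= e + pad:
                    genes.add(gm.gene)
        return genes

    per_family_exonic = {
        f: [v for v in vs if exon_genes(v)] for f, vs in per_family_filtered.items()
    }
    stages["exonic_window"] = union(per_family_exonic)

    def conseq(v):
        if v.effect in {"frameshift", "stop_gain", "stop_loss", "start_loss"}:
            return True
        if v.effect == "nonsynonymous":
            return sum(c == "pathogenic" for c in v.predictor_calls) >= predictor_min
        return False

    per_family_conseq = {
        f: [v for v in vs if conseq(v)] for f, vs in per_family_exonic.items()
    }
    stages["consequence"] = union(per_family_conseq)

    fam_sets = {}
    for fam, vs in per_family_filtered.items():
        for v in vs:
            fam_sets.setdefault(v.vid, set()).add(fam)
    cross = {vid for vid, fams in fam_sets.items() if len(fams) >= min_families}
    stages["cross_family"] = cross

    gene_fams = {}
    for fam, vs in per_family_conseq.items():
        for v in vs:
            if not v.quality_pass:
                continue
            for g in exon_genes(v):
                gene_fams.setdefault(g, set()).add(fam)
    recurrent = {g for g, fams in gene_fams.items() if len(fams) >= min_families}
    return {"stages": stages, "cross_family": cross, "recurrent_genes": recurrent}


# ---------------------------------------------------------------------------
# naive SV overlap + transitive closure


def naive_overlap(a: BreakendPair, b: BreakendPair, max_gap: int) -> bool:
    if a.sv_type != b.sv_type:
        return False
    ends_a = sorted([(a.chrom1, a.pos1, a.orient1, a.ci1), (a.chrom2, a.pos2, a.orient2, a.ci2)],
                    key=lambda t: (t[0], t[1]))
    ends_b = sorted([(b.chrom1, b.pos1, b.orient1, b.ci1), (b.chrom2, b.pos2, b.orient2, b.ci2)],
                    key=lambda t: (t[0], t[1]))
    for (ca, pa, oa, cia), (cb, pb, ob, cib) in zip(ends_a, ends_b):
        if ca != cb or oa != ob:
            return False
        if pa + cia[1] + max_gap < pb + cib[0] - max_gap:
            return False
        if pb + cib[1] + max_gap < pa + cia[0] - max_gap:
            return False
    return True


def closure_partition(svs, max_gap: int) -> set[frozenset]:
    """O(n^3) Floyd–Warshall transitive closure of the overlap matrix."""
    n = len(svs)
    reach = [[naive_overlap(svs[i], svs[j], max_gap) or i == j for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    parts = set()
    for i in range(n):
        parts.add(frozenset((svs[j].sample, svs[j].sv_id) for j in range(n) if reach[i][j]))
    return parts


# ---------------------------------------------------------------------------
# random cohorts for equivalence testing


EFFECT_POOL = [
    "frameshift", "stop_gain", "stop_loss", "start_loss", "nonsynonymous",
    "synonymous", "splice_region", "intronic", "intergenic", "other",
]


def random_cohort(rng: np.random.Generator, n_variants: int = 300):
    """Random variants, two 2-member families plus reference samples, random
    gene models and a small PoN — adversarial input for stage equivalence."""
    cohort = FamilyCohort(
        families={"F1": ["F1a", "F1b"], "F2": ["F2a", "F2b"]},
        reference_samples=["R1", "R2"],
    )
    samples = cohort.all_samples
    gene_models = []
    for k in range(6):
        start = 1000 + k * 5000
        exons = [(start, start + 400), (start + 1000, start + 1400)]
        gene_models.append(GeneModel(gene=f"GX{k}", chrom="1", strand="+", exons=exons))
    # overlapping gene pair
    gene_models.append(GeneModel(gene="GOVL", chrom="1", strand="-", exons=[(1200, 2600)]))
    variants = []
    pon = set()
    for i in range(n_variants):
        pos = int(rng.integers(1, 40_000))
        ref, alt = ("A", "T") if rng.random() < 0.7 else ("AT", "A")
        genotypes = {}
        for s in samples:
            r = rng.random()
            genotypes[s] = None if r < 0.05 else int(rng.choice([0, 0, 1, 1, 2]))
        pop_af = None if rng.random() < 0.2 else float(rng.choice([0.0, 0.0005, 0.001, 0.002, 0.05]))
        calls = tuple(rng.choice(["pathogenic", "benign", "missing"], size=5).tolist())
        v = AnnotatedVariant(
            chrom="1",
            pos=pos,
            ref=ref,
            alt=alt,
            effect=str(rng.choice(EFFECT_POOL)),
            pop_af=pop_af,
            cadd_phred=float(rng.uniform(0, 40)),
            predictor_calls=calls,
            in_pon=bool(rng.random() < 0.1),
            quality_pass=bool(rng.random() < 0.9),
            genotypes=genotypes,
        )
        variants.append(v)
        if rng.random() < 0.05:
            pon.add(v.key)
    return variants, cohort, gene_models, pon


def random_svs(rng: np.random.Generator, n: int):
    svs = []
    for k in range(n):
        chrom = str(rng.integers(1, 3))
        p1 = int(rng.integers(1000, 40_000))
        length = int(rng.integers(500, 5000))
        ci = (-int(rng.integers(0, 80)), int(rng.integers(0, 80)))
        svs.append(
            BreakendPair(
                sv_id=f"sv{k}",
                sv_type=str(rng.choice(["DEL", "DUP", "INV"])),
                chrom1=chrom,
                pos1=p1,
                orient1="+" if rng.random() < 0.8 else "-",
                chrom2=chrom,
                pos2=p1 + length,
                orient2="-" if rng.random() < 0.8 else "+",
                ci1=ci,
                ci2=ci,
                sample=f"S{int(rng.integers(1, 5))}",
            )
        )
    return svs


# ---------------------------------------------------------------------------
# permutation t-test oracle


def permutation_p(a, b, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value of the Welch t statistic (vectorized)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size

    def welch_t(x, y, axis=-1):
        mx, my = x.mean(axis=axis), y.mean(axis=axis)
        vx, vy = x.var(axis=axis, ddof=1), y.var(axis=axis, ddof=1)
        return (mx - my) / np.sqrt(vx / x.shape[axis] + vy / y.shape[axis])

    t_obs = abs(welch_t(a, b))
    perm = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    shuffled = pooled[perm]
    t_null = np.abs(welch_t(shuffled[:, :na], shuffled[:, na:]))
    return float((np.sum(t_null >= t_obs) + 1) / (n_perm + 1))
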