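"""SNV/indel prioritization: within-family sharing, the rarity / pool-of-normals
filter cascade, exonic-window and consequence consensus filters, CADD tiers,
cross-family recurrence, recurrent genes, and candidate-locus scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .variant_model import (
    CODING_EFFECTS,
    AnnotatedVariant,
    BreakendPair,
    FamilyCohort,
    GeneModel,
    trim_alleles,
)

__all__ = [
    "FilterTrace",
    "CandidateVariant",
    "shared_within_family",
    "filter_rare",
    "filter_quality",
    "filter_pon",
    "exonic_window",
    "consequence_filter",
    "annotate_cancer_genes",
    "cadd_tier",
    "cross_family_variants",
    "recurrent_genes",
    "locus_scan",
    "run_snv_pipeline",
]

CADD_TIERS = ("none", "annotate", "assess", "highlight")


@dataclass
class FilterTrace:
    """Ordered per-stage record of the filter funnel: counts plus surviving ids."""

    stages: list[tuple[str, int, int, tuple[str, ...]]] = field(default_factory=list)

    def add(self, name: str, input_ids: Sequence[str], output_ids: Sequence[str]) -> None:
        if len(output_ids) > len(input_ids):
            raise ValueError(f"stage {name!r} emitted more variants than it received")
        if not set(output_ids) <= set(input_ids):
            raise ValueError(f"stage {name!r} emitted variants it never received")
        self.stages.append((name, len(input_ids), len(output_ids), tuple(output_ids)))

    def counts(self) -> list[tuple[str, int, int]]:
        return [(name, n_in, n_out) for name, n_in, n_out, _ in self.stages]


@dataclass
class CandidateVariant:
    """A surviving variant with its sharing scope and triage flags."""

    variant: AnnotatedVariant
    families: frozenset[str]
    genes: frozenset[str] = frozenset()
    cancer_gene: bool = False
    cadd_tier: str = "none"
    consequence_pass: bool = True
    exception: bool = False  # near-miss reported outside the inclusion criteria

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("candidate must be carried by at least one family")


def shared_within_family(
    variants: Iterable[AnnotatedVariant], family_samples: Sequence[str]
) -> list[AnnotatedVariant]:
    """Variants carried by every affected, sequenced member of one family.

    Carrier status means allele count >= 1; a missing genotype in any member
    disqualifies the variant (conservative: no-calls never create sharing).
    """
    members = list(family_samples)
    if len(members) < 2:
        raise ValueError(f"family must have >= 2 sequenced samples, got {len(members)}")
    return [v for v in variants if all(v.carrier(s) for s in members)]


def filter_rare(
    variants: Iterable[AnnotatedVariant], pop_af_max: float = 0.001
) -> list[AnnotatedVariant]:
    """Keep rare variants: population AF <= threshold, or AF missing.

    Absence from population databases is treated as evidence of rarity; the
    frequency filter removes only variants observed above the threshold.
    """
    return [v for v in variants if v.pop_af is None or v.pop_af <= pop_af_max]


def filter_quality(variants: Iterable[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep variants passing the caller FILTER."""
    return [v for v in variants if v.quality_pass]


def filter_pon(
    variants: Iterable[AnnotatedVariant],
    pon: Optional[set[tuple[str, int, str, str]]] = None,
) -> list[AnnotatedVariant]:
    """Drop pool-of-normals members.

    Uses the ``in_pon`` flag; when an explicit PoN key set is supplied the
    membership test additionally matches on the normalized
    (chrom, pos, ref, alt) key, so differently padded representations of the
    same allele still hit.
    """
    if pon:
        pon = {(c, *trim_alleles(p, r, a)) for c, p, r, a in pon}
    out = []
    for v in variants:
        if v.in_pon:
            continue
        if pon and v.key in pon:
            continue
        out.append(v)
    return out


class _ExonIndex:
    """Flat padded-exon interval index per chromosome for point queries."""

    def __init__(self, gene_models: Sequence[GeneModel], pad: int):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gm in gene_models:
            for s, e in gm.exons:
                per_chrom.setdefault(gm.chrom, []).append(
                    (max(1, s - pad), e + pad, gm.gene)
                )
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = np.array([s for s, _, _ in ivals], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivals], dtype=np.int64)
            genes = [g for _, _, g in ivals]
            self._by_chrom[chrom] = (starts, ends, genes)

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return set()
        starts, ends, genes = entry
        hi = int(np.searchsorted(starts, pos, side="right"))
        return {genes[k] for k in range(hi) if ends[k] >= pos}


def exonic_window(
    variants: Iterable[AnnotatedVariant],
    gene_models: Sequence[GeneModel],
    pad: int = 10,
) -> tuple[list[AnnotatedVariant], dict[str, frozenset[str]]]:
    """Restrict to exonic positions (+/- ``pad`` bp into introns).

    A variant qualifies if its position falls inside any padded exon of any
    transcript. Returns the surviving variants plus a vid -> gene-set map;
    a variant under two overlapping genes appears once in the variant list
    and under both genes in the map.
    """
    index = _ExonIndex(gene_models, pad)
    kept: list[AnnotatedVariant] = []
    gene_map: dict[str, frozenset[str]] = {}
    for v in variants:
        genes = index.genes_at(v.chrom, v.pos)
        if genes:
            kept.append(v)
            gene_map[v.vid] = frozenset(genes)
    return kept, gene_map


def consequence_filter(
    variants: Iterable[AnnotatedVariant], predictor_min: int = 3
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Consequence / pathogenicity-consensus filter.

    Keeps frameshift and stop/start loss/gain outright, and nonsynonymous
    variants called pathogenic by >= ``predictor_min`` of the five
    predictors (missing calls count against the consensus). Returns
    ``(kept, exceptions)`` where exceptions are nonsynonymous near-misses
    (exactly ``predictor_min - 1`` pathogenic calls): reportable for manual
    review, never automatically included.
    """
    kept: list[AnnotatedVariant] = []
    exceptions: list[AnnotatedVariant] = []
    for v in variants:
        if v.effect in CODING_EFFECTS:
            kept.append(v)
        elif v.effect == "nonsynonymous":
            if v.n_pathogenic >= predictor_min:
                kept.append(v)
            elif v.n_pathogenic == predictor_min - 1:
                exceptions.append(v)
    return kept, exceptions


def annotate_cancer_genes(
    candidates: Iterable[CandidateVariant], gene_list: Iterable[str]
) -> list[CandidateVariant]:
    """Flag (never filter) candidates whose gene is on a cancer-gene list.

    Matching is case-insensitive; a hit that required case folding is still
    flagged (the caller may warn on such entries).
    """
    folded = {g.upper() for g in gene_list}
    out = []
    for c in candidates:
        hit = bool(folded) and any(
            g.upper() in folded for g in (set(c.genes) | ({c.variant.gene} if c.variant.gene else set()))
        )
        c.cancer_gene = hit
        out.append(c)
    return out


def cadd_tier(
    variant: AnnotatedVariant,
    annotate: float = 5.0,
    assess: float = 20.0,
    highlight: float = 30.0,
) -> str:
    """Highest applicable CADD tier.

    ``annotate`` and ``assess`` boundaries are inclusive; ``highlight`` is
    strict (> 30). Missing score maps to ``none``.
    """
    score = variant.cadd_phred
    if score is None:
        return "none"
    if score > highlight:
        return "highlight"
    if score >= assess:
        return "assess"
    if score >= annotate:
        return "annotate"
    return "none"


def cross_family_variants(
    per_family: Mapping[str, Sequence[AnnotatedVariant]], min_families: int = 2
) -> dict[str, tuple[AnnotatedVariant, frozenset[str]]]:
    """Variants fully shared within >= ``min_families`` families.

    Keyed by normalized variant id; reports the carrying family set.
    """
    seen: dict[str, tuple[AnnotatedVariant, set[str]]] = {}
    for fam, variants in per_family.items():
        for v in variants:
            entry = seen.setdefault(v.vid, (v, set()))
            entry[1].add(fam)
    return {
        vid: (v, frozenset(fams))
        for vid, (v, fams) in seen.items()
        if len(fams) >= min_families
    }


def recurrent_genes(
    per_family_genes: Mapping[str, Sequence[tuple[AnnotatedVariant, frozenset[str]]]],
    blacklist: Iterable[str] = (),
    min_families: int = 2,
) -> dict[str, frozenset[str]]:
    """Genes hit by qualifying variants (identical or different) in >= 2 families.

    ``per_family_genes`` maps family -> [(variant, genes)] for that family's
    qualifying variants. Blacklisted genes and genes supported only by
    quality-failing variants are removed.
    """
    black = {g.upper() for g in blacklist}
    gene_fams: dict[str, set[str]] = {}
    for fam, items in per_family_genes.items():
        for variant, genes in items:
            if not variant.quality_pass:
                continue
            for g in genes:
                if g.upper() in black:
                    continue
                gene_fams.setdefault(g, set()).add(fam)
    return {
        g: frozenset(fams) for g, fams in gene_fams.items() if len(fams) >= min_families
    }


def locus_scan(
    variants: Iterable[AnnotatedVariant],
    svs: Iterable[BreakendPair],
    gene_models: Sequence[GeneModel],
    symbols: Sequence[str],
    flank: int = 75_000,
    pop_af_max: float = 0.001,
) -> dict[str, dict[str, list]]:
    """Rare SNVs and SVs within ``flank`` bp of each candidate locus.

    For every requested gene symbol, returns rare (per :func:`filter_rare`)
    SNVs whose position lies in [tx_start - flank, tx_end + flank] and SVs
    with a breakend in, or an intrachromosomal span overlapping, that window.
    """
    wanted = {s.upper() for s in symbols}
    models = [gm for gm in gene_models if gm.gene.upper() in wanted]
    rare = filter_rare(list(variants), pop_af_max)
    svs = list(svs)
    out: dict[str, dict[str, list]] = {}
    for gm in models:
        lo, hi = max(1, gm.tx_start - flank), gm.tx_end + flank
        snv_hits = [v for v in rare if v.chrom == gm.chrom and lo <= v.pos <= hi]
        sv_hits = []
        for sv in svs:
            if sv.sv_type != "BND" and sv.chrom1 == gm.chrom:
                if sv.pos1 <= hi and sv.pos2 >= lo:
                    sv_hits.append(sv)
                    continue
            for chrom, pos, _, _ in sv.breakends():
                if chrom == gm.chrom and lo <= pos <= hi:
                    sv_hits.append(sv)
                    break
        out[gm.gene] = {"snvs": snv_hits, "svs": sv_hits}
    return out


def run_snv_pipeline(
    variants: Sequence[AnnotatedVariant],
    cohort: FamilyCohort,
    gene_models: Sequence[GeneModel],
    pop_af_max: float = 0.001,
    pad: int = 10,
    predictor_min: int = 3,
    cadd_thresholds: tuple[float, float, float] = (5.0, 20.0, 30.0),
    cancer_genes: Iterable[str] = (),
    blacklist: Iterable[str] = (),
    pon: Optional[set[tuple[str, int, str, str]]] = None,
    min_families: int = 2,
) -> tuple[FilterTrace, list[CandidateVariant], dict]:
    """Full tier-1/tier-2 SNV analysis.

    Stage order: per-family sharing -> caller-quality gate -> rarity ->
    pool-of-normals, then branch A (exonic window -> consequence consensus ->
    cancer-gene annotation) and branch B (genome-wide CADD tiers ->
    cross-family variants -> recurrent genes). Returns the funnel trace, the
    branch-A candidates (exceptions flagged), and a dict of branch-B results.
    """
    trace = FilterTrace()
    all_ids = [v.vid for v in variants]

    per_family: dict[str, list[AnnotatedVariant]] = {}
    for fam, members in cohort.families.items():
        per_family[fam] = shared_within_family(variants, members)

    def union_ids(pf: Mapping[str, Sequence[AnnotatedVariant]]) -> list[str]:
        return sorted({v.vid for vs in pf.values() for v in vs})

    trace.add("shared_within_family", all_ids, union_ids(per_family))
    stages = [
        ("quality_pass", lambda vs: filter_quality(vs)),
        ("rare", lambda vs: filter_rare(vs, pop_af_max)),
        ("pool_of_normals", lambda vs: filter_pon(vs, pon)),
    ]
    for name, fn in stages:
        before = union_ids(per_family)
        per_family = {fam: fn(vs) for fam, vs in per_family.items()}
        trace.add(name, before, union_ids(per_family))
    per_family_filtered = per_family

    # branch A: exonic, consequence consensus, cancer-gene annotation
    per_family_exonic: dict[str, list[AnnotatedVariant]] = {}
    gene_maps: dict[str, dict[str, frozenset[str]]] = {}
    for fam, vs in per_family_filtered.items():
        kept, gmap = exonic_window(vs, gene_models, pad)
        per_family_exonic[fam] = kept
        gene_maps[fam] = gmap
    trace.add("exonic_window", union_ids(per_family_filtered), union_ids(per_family_exonic))

    per_family_conseq: dict[str, list[AnnotatedVariant]] = {}
    per_family_except: dict[str, list[AnnotatedVariant]] = {}
    for fam, vs in per_family_exonic.items():
        kept, exceptions = consequence_filter(vs, predictor_min)
        per_family_conseq[fam] = kept
        per_family_except[fam] = exceptions
    trace.add("consequence", union_ids(per_family_exonic), union_ids(per_family_conseq))

    ann, assess, high = cadd_thresholds
    candidates: dict[str, CandidateVariant] = {}
    for fam, vs in per_family_conseq.items():
        for v in vs:
            c = candidates.get(v.vid)
            if c is None:
                candidates[v.vid] = CandidateVariant(
                    variant=v,
                    families=frozenset({fam}),
                    genes=gene_maps[fam].get(v.vid, frozenset()),
                    cadd_tier=cadd_tier(v, ann, assess, high),
                )
            else:
                c.families = c.families | {fam}
                c.genes = c.genes | gene_maps[fam].get(v.vid, frozenset())
    for fam, vs in per_family_except.items():
        for v in vs:
            c = candidates.get(v.vid)
            if c is None:
                candidates[v.vid] = CandidateVariant(
                    variant=v,
                    families=frozenset({fam}),
                    genes=gene_maps[fam].get(v.vid, frozenset()),
                    cadd_tier=cadd_tier(v, ann, assess, high),
                    consequence_pass=False,
                    exception=True,
                )
            else:
                c.families = c.families | {fam}
    candidate_list = annotate_cancer_genes(
        sorted(candidates.values(), key=lambda c: c.variant.key), cancer_genes
    )

    # branch B: genome-wide CADD tiers, cross-family recurrence, recurrent genes
    tiers: dict[str, str] = {}
    for vs in per_family_filtered.values():
        for v in vs:
            tiers.setdefault(v.vid, cadd_tier(v, ann, assess, high))
    cross = cross_family_variants(per_family_filtered, min_families)
    per_family_gene_hits = {
        fam: [(v, gene_maps[fam].get(v.vid, frozenset())) for v in vs]
        for fam, vs in per_family_conseq.items()
    }
    recurrent = recurrent_genes(per_family_gene_hits, blacklist, min_families)
    trace.add(
        "cross_family", union_ids(per_family_filtered), sorted(cross.keys())
    )

    branch_b = {
        "cadd_tiers": tiers,
        "cross_family": cross,
        "recurrent_genes": recurrent,
        "per_family_shared": {f: [v.vid for v in vs] for f, vs in per_family_filtered.items()},
    }
    return trace, candidate_list, branch_b
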