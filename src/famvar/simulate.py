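"""Synthetic family-cohort generator with full ground-truth bookkeeping.

Produces a desk-scale cohort mirroring the study design — four families with
two affected, sequenced women each (degree-1, degree-2 and two degree-5
pairs) plus an unrelated reference arm — with known planted candidates at
every pipeline stage: family-shared coding deleterious SNVs, one
cross-family variant, family-shared SV groups with decoys and catalogue
members, and annotation distributions for the filter cascade.

Gene dropping tracks founder-haplotype labels through each meiosis
(crossovers Poisson in genetic distance, no interference), so genotypes are
Mendelian by construction and planting a variant on a founder haplotype
guarantees the intended carriers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .compare import PatientRecord
from .io_formats import (
    VcfRow,
    write_gene_bed,
    write_genetic_map,
    write_patients_tsv,
    write_ped,
    write_pon_tsv,
    write_sv_catalogue_tsv,
    write_sv_vcf,
    write_vcf,
)
from .pedigree import Individual, Pedigree
from .variant_model import (
    AnnotatedVariant,
    BreakendPair,
    FamilyCohort,
    GeneModel,
    pad_predictor_calls,
)

__all__ = [
    "ChromSpec",
    "FamilyTemplate",
    "SimSpec",
    "GroundTruth",
    "SimulatedCohort",
    "default_spec",
    "family_template",
    "lineal_pair_template",
    "second_cousin_template",
    "simulate_founders",
    "gene_drop_labels",
    "gene_drop",
    "simulate_cohort",
    "simulate_degree_pair",
    "emit",
]

# component offsets for the documented seed fan-out:
# np.random.default_rng([seed, COMPONENT, *extra]) per independent component
_SEED_FOUNDERS = 1
_SEED_DROP = 2
_SEED_REFERENCE = 3
_SEED_ANNOT = 4
_SEED_SV = 5
_SEED_PATIENTS = 6
_SEED_PLANT = 7

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromSpec:
    name: str
    n_markers: int
    length_cm: float
    bp_spacing: int = 1000

    @property
    def length_bp(self) -> int:
        return self.n_markers * self.bp_spacing + self.bp_spacing


@dataclass
class FamilyTemplate:
    family: str
    degree: int
    individuals: list[Individual]
    affected_pair: tuple[str, str]


@dataclass
class SimSpec:
    """Full generator configuration; the seed is mandatory for reproducibility."""

    seed: int
    families: list[FamilyTemplate] = field(default_factory=list)
    n_reference: int = 33
    chroms: list[ChromSpec] = field(
        default_factory=lambda: [ChromSpec("1", 8000, 100.0), ChromSpec("2", 8000, 100.0)]
    )
    af_alpha: float = 0.2
    af_beta: float = 0.2
    fraction_rare: float = 0.1
    af_missing_rate: float = 0.03
    pon_fraction: float = 0.05
    quality_fail_rate: float = 0.02
    genes_per_chrom: int = 25
    exons_per_gene: int = 5
    exon_bp: int = 2000
    intron_bp: int = 2000
    quiet_gene_count: int = 3
    locus_flank_bp: int = 75_000
    coding_effect_probs: dict[str, float] = field(
        default_factory=lambda: {
            "nonsynonymous": 0.55,
            "synonymous": 0.25,
            "splice_region": 0.08,
            "frameshift": 0.05,
            "stop_gain": 0.04,
            "stop_loss": 0.02,
            "start_loss": 0.01,
        }
    )
    predictor_missing_rate: float = 0.05
    cadd_logistic_mid: float = 18.0
    cadd_logistic_scale: float = 3.0
    planted_cadd: float = 25.0
    planted_cross_family_cadd: float = 7.0
    n_reference_carriers_cross: int = 2
    sv_jitter_sd: float = 20.0
    sv_max_gap: int = 100
    decoys_per_sample: int = 3
    n_catalogue_svs: int = 2
    max_plant_retries: int = 200

    def __post_init__(self) -> None:
        for p in (
            self.fraction_rare,
            self.af_missing_rate,
            self.pon_fraction,
            self.quality_fail_rate,
            self.predictor_missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        total = sum(self.coding_effect_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("coding_effect_probs must sum to 1")
        if not self.families:
            self.families = [
                family_template("A", 5),
                family_template("B", 1),
                family_template("C", 2),
                family_template("D", 5),
            ]


# --------------------------------------------------------------------------
# pedigree templates


def family_template(fid: str, degree: int) -> FamilyTemplate:
    """Pedigree template with one affected pair at the requested degree.

    degree 1: mother and daughter; degree 2: aunt and niece; degree 5: two
    women whose grandfathers are full brothers (second cousins).
    """
    p = f"{fid}_"
    a1, a2 = f"{fid}1", f"{fid}2"
    if degree == 1:
        inds = [
            Individual(a2, None, None, "female", True, fid),  # mother (founder)
            Individual(p + "fa", None, None, "male", False, fid),
            Individual(a1, p + "fa", a2, "female", True, fid),  # daughter
        ]
    elif degree == 2:
        inds = [
            Individual(p + "gf", None, None, "male", False, fid),
            Individual(p + "gm", None, None, "female", False, fid),
            Individual(a2, p + "gf", p + "gm", "female", True, fid),  # aunt
            Individual(p + "mo", p + "gf", p + "gm", "female", False, fid),
            Individual(p + "sp", None, None, "male", False, fid),
            Individual(a1, p + "sp", p + "mo", "female", True, fid),  # niece
        ]
    elif degree == 3:
        # first cousins
        inds = [
            Individual(p + "gf", None, None, "male", False, fid),
            Individual(p + "gm", None, None, "female", False, fid),
            Individual(p + "m1", p + "gf", p + "gm", "female", False, fid),
            Individual(p + "m2", p + "gf", p + "gm", "female", False, fid),
            Individual(p + "s1", None, None, "male", False, fid),
            Individual(p + "s2", None, None, "male", False, fid),
            Individual(a1, p + "s1", p + "m1", "female", True, fid),
            Individual(a2, p + "s2", p + "m2", "female", True, fid),
        ]
    elif degree == 5:
        inds = [
            Individual(p + "ggf", None, None, "male", False, fid),
            Individual(p + "ggm", None, None, "female", False, fid),
            Individual(p + "b1", p + "ggf", p + "ggm", "male", False, fid),
            Individual(p + "b2", p + "ggf", p + "ggm", "male", False, fid),
            Individual(p + "s1", None, None, "female", False, fid),
            Individual(p + "s2", None, None, "female", False, fid),
            Individual(p + "p1", p + "b1", p + "s1", "female", False, fid),
            Individual(p + "p2", p + "b2", p + "s2", "male", False, fid),
            Individual(p + "q1", None, None, "male", False, fid),
            Individual(p + "q2", None, None, "female", False, fid),
            Individual(a1, p + "q1", p + "p1", "female", True, fid),
            Individual(a2, p + "p2", p + "q2", "female", True, fid),
        ]
    else:
        raise ValueError(f"no template for degree {degree}")
    return FamilyTemplate(fid, degree, inds, (a1, a2))


def lineal_pair_template(degree: int, fid: str = "L") -> FamilyTemplate:
    """Ancestor-descendant chain separated by ``degree`` meioses
    (phi = 2**(-degree-1))."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    p = f"{fid}_"
    inds = [Individual(p + "anc", None, None, "female", True, fid)]
    prev = p + "anc"
    for k in range(degree):
        spouse = f"{p}sp{k}"
        child = f"{p}c{k}"
        inds.append(Individual(spouse, None, None, "male", False, fid))
        inds.append(Individual(child, spouse, prev, "female", k == degree - 1, fid))
        prev = child
    return FamilyTemplate(fid, degree, inds, (p + "anc", prev))


def second_cousin_template(fid: str = "S") -> FamilyTemplate:
    tpl = family_template(fid, 5)
    tpl.family = fid
    return tpl


# --------------------------------------------------------------------------
# founders and gene dropping


@dataclass
class FounderData:
    """Population AFs plus founder-haplotype allele matrices per family."""

    af: dict[str, np.ndarray]  # chrom -> model AF per marker
    family_haps: dict[str, dict[str, np.ndarray]]  # family -> chrom -> (n_haps, n)
    founder_hap_ids: dict[str, dict[str, tuple[int, int]]]  # family -> iid -> (h0, h1)
    reference_haps: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> (2, n)


def _draw_afs(spec: SimSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for ch in spec.chroms:
        af = rng.beta(spec.af_alpha, spec.af_beta, size=ch.n_markers)
        af = np.clip(af, 1e-4, 1 - 1e-4)
        rare = rng.random(ch.n_markers) < spec.fraction_rare
        af[rare] = rng.uniform(1e-5, 0.001, size=int(rare.sum()))
        out[ch.name] = af
    return out


def simulate_founders(spec: SimSpec, rng: Optional[np.random.Generator] = None) -> FounderData:
    """Draw the marker AF spectrum and sample founder / reference haplotypes.

    AFs come from a Beta spectrum with a configurable fraction forced rare
    (AF <= 0.001); every haplotype is sampled binomially at its marker AF.
    """
    rng = rng or np.random.default_rng([spec.seed, _SEED_FOUNDERS])
    af = _draw_afs(spec, rng)
    family_haps: dict[str, dict[str, np.ndarray]] = {}
    founder_hap_ids: dict[str, dict[str, tuple[int, int]]] = {}
    for tpl in spec.families:
        ped = Pedigree(tpl.individuals)
        founders = ped.founders
        hap_ids = {iid: (2 * k, 2 * k + 1) for k, iid in enumerate(founders)}
        founder_hap_ids[tpl.family] = hap_ids
        family_haps[tpl.family] = {
            ch.name: (
                rng.random((2 * len(founders), ch.n_markers)) < af[ch.name]
            ).astype(np.uint8)
            for ch in spec.chroms
        }
    ref_rng = np.random.default_rng([spec.seed, _SEED_REFERENCE])
    reference_haps = {
        f"R{k + 1:02d}": {
            ch.name: (ref_rng.random((2, ch.n_markers)) < af[ch.name]).astype(np.uint8)
            for ch in spec.chroms
        }
        for k in range(spec.n_reference)
    }
    return FounderData(af, family_haps, founder_hap_ids, reference_haps)


def _meiosis(
    parent_labels: np.ndarray, cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombined gamete from a parent's (2, n) label arrays.

    Crossover count ~ Poisson(length in Morgans), positions uniform in cM,
    no interference; a 0-Morgan chromosome transmits an intact haplotype.
    """
    length_cm = float(cm[-1] - cm[0]) if cm.size else 0.0
    n_xo = rng.poisson(length_cm / 100.0)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return parent_labels[start].copy()
    xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
    phase = (start + np.searchsorted(xo, cm, side="right")) % 2
    return np.where(phase == 0, parent_labels[0], parent_labels[1])


def gene_drop_labels(
    ped: Pedigree,
    hap_ids: dict[str, tuple[int, int]],
    cm_maps: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Drop founder-haplotype labels through the pedigree.

    Returns iid -> chrom -> (2, n) arrays of founder-haplotype labels
    (row 0 = paternal, row 1 = maternal gamete).
    """
    order = sorted(ped.individuals, key=lambda i: ped._depth[i])
    labels: dict[str, dict[str, np.ndarray]] = {}
    for iid in order:
        ind = ped.individuals[iid]
        labels[iid] = {}
        for chrom, cm in cm_maps.items():
            n = cm.size
            if ped.is_founder(iid):
                if iid not in hap_ids:
                    raise KeyError(f"founder {iid} has no haplotype assignment")
                h0, h1 = hap_ids[iid]
                labels[iid][chrom] = np.stack(
                    [np.full(n, h0, dtype=np.int32), np.full(n, h1, dtype=np.int32)]
                )
            else:
                gametes = []
                for parent in (ind.father, ind.mother):
                    if parent is None:
                        raise KeyError(f"non-founder {iid} missing a parent")
                    gametes.append(_meiosis(labels[parent][chrom], cm, rng))
                labels[iid][chrom] = np.stack(gametes)
    return labels


def gene_drop(
    ped: Pedigree,
    founder_haps: dict[str, dict[str, np.ndarray]],
    cm_maps: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Phased genotypes for every pedigree member from founder haplotypes.

    ``founder_haps`` maps founder iid -> chrom -> (2, n) allele arrays.
    Genotypes are Mendelian by construction.
    """
    hap_ids = {iid: (2 * k, 2 * k + 1) for k, iid in enumerate(sorted(founder_haps))}
    labels = gene_drop_labels(ped, hap_ids, cm_maps, rng)
    matrix = {
        chrom: np.vstack([founder_haps[iid][chrom] for iid in sorted(founder_haps)])
        for chrom in cm_maps
    }
    out: dict[str, dict[str, np.ndarray]] = {}
    for iid, per_chrom in labels.items():
        out[iid] = {
            chrom: matrix[chrom][lab, np.arange(lab.shape[1])] for chrom, lab in per_chrom.items()
        }
    return out


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class PlantedVariant:
    vid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    families: list[str]
    gene: str
    effect: str
    cadd: float
    kind: str  # "branch_a" | "cross_family"
    reference_carriers: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    planted_branch_a: dict[str, PlantedVariant]  # family -> variant
    planted_cross_family: Optional[PlantedVariant]
    planted_svs: dict[str, dict]  # family -> {"sv_ids", "gene", "pos1", "pos2"}
    sv_recurrent_gene: Optional[str]
    sv_recurrent_families: list[str]
    degrees: dict[str, int]  # "A1,A2" -> degree
    quiet_genes: list[str]
    drop_attempts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["planted_branch_a"] = {
            fam: PlantedVariant(**pv) for fam, pv in data["planted_branch_a"].items()
        }
        if data.get("planted_cross_family"):
            data["planted_cross_family"] = PlantedVariant(**data["planted_cross_family"])
        return cls(**data)


@dataclass
class SimulatedCohort:
    spec: SimSpec
    cohort: FamilyCohort
    pedigree: Pedigree
    gene_models: list[GeneModel]
    variants: list[AnnotatedVariant]
    haplotypes: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> (2, n_emitted)
    genetic_map: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bp, cM)
    svs: list[BreakendPair]
    sv_catalogue: list[BreakendPair]
    pon: set[tuple[str, int, str, str]]
    patients: list[PatientRecord]
    ground_truth: GroundTruth
    labels: dict[str, dict[str, np.ndarray]]  # familial sample label mosaics

    @property
    def genome_cm(self) -> float:
        return sum(ch.length_cm for ch in self.spec.chroms)


def _make_gene_models(spec: SimSpec) -> list[GeneModel]:
    models = []
    for ch in spec.chroms:
        span = ch.length_bp
        gene_len = spec.exons_per_gene * spec.exon_bp + (spec.exons_per_gene - 1) * spec.intron_bp
        gap = max((span - 20_000) // max(spec.genes_per_chrom, 1), gene_len + 10_000)
        for k in range(spec.genes_per_chrom):
            tx_start = 10_000 + k * gap
            if tx_start + gene_len > span:
                break
            exons = []
            pos = tx_start
            for _ in range(spec.exons_per_gene):
                exons.append((pos, pos + spec.exon_bp - 1))
                pos += spec.exon_bp + spec.intron_bp
            models.append(
                GeneModel(
                    gene=f"G{ch.name}_{k:02d}",
                    chrom=ch.name,
                    strand="+" if k % 2 == 0 else "-",
                    exons=exons,
                )
            )
    return models


def _cm_positions(ch: ChromSpec) -> np.ndarray:
    return np.linspace(0.0, ch.length_cm, ch.n_markers)


def _bp_positions(ch: ChromSpec) -> np.ndarray:
    return (np.arange(ch.n_markers, dtype=np.int64) + 1) * ch.bp_spacing


def _shared_hap_mask(
    labels: dict[str, dict[str, np.ndarray]], members: Sequence[str], chrom: str, hap: int
) -> np.ndarray:
    """Markers where every member carries founder haplotype ``hap``."""
    mask = None
    for iid in members:
        lab = labels[iid][chrom]
        carry = (lab[0] == hap) | (lab[1] == hap)
        mask = carry if mask is None else (mask & carry)
    return mask


def simulate_cohort(spec: SimSpec) -> SimulatedCohort:
    """Run the full generator: founders, gene drop, planting, annotations, SVs."""
    gene_models = _make_gene_models(spec)
    founders = simulate_founders(spec)
    cm_maps = {ch.name: _cm_positions(ch) for ch in spec.chroms}
    bp_maps = {ch.name: _bp_positions(ch) for ch in spec.chroms}

    quiet = [gm for gm in gene_models if gm.chrom == spec.chroms[0].name][-spec.quiet_gene_count:] if spec.quiet_gene_count else []
    quiet_names = [gm.gene for gm in quiet]
    quiet_windows: dict[str, list[tuple[int, int]]] = {}
    for gm in quiet:
        quiet_windows.setdefault(gm.chrom, []).append(
            (gm.tx_start - spec.locus_flank_bp, gm.tx_end + spec.locus_flank_bp)
        )

    def in_quiet(chrom: str, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in quiet_windows.get(chrom, ()))

    # de-rarify markers near quiet loci so locus scans are clean negatives
    quiet_rng = np.random.default_rng([spec.seed, _SEED_ANNOT, 99])
    for ch in spec.chroms:
        for lo, hi in quiet_windows.get(ch.name, ()):
            idx = np.flatnonzero((bp_maps[ch.name] >= lo) & (bp_maps[ch.name] <= hi))
            founders.af[ch.name][idx] = quiet_rng.uniform(0.01, 0.3, size=idx.size)
            # resample haplotypes there so alleles stay consistent with AF
            for fam_haps in founders.family_haps.values():
                fam_haps[ch.name][:, idx] = (
                    quiet_rng.random((fam_haps[ch.name].shape[0], idx.size))
                    < founders.af[ch.name][idx]
                ).astype(np.uint8)
            for ref_haps in founders.reference_haps.values():
                ref_haps[ch.name][:, idx] = (
                    quiet_rng.random((2, idx.size)) < founders.af[ch.name][idx]
                ).astype(np.uint8)

    # exonic marker mask (pad excluded: plants sit strictly inside exons)
    exon_gene_at: dict[str, dict[int, str]] = {ch.name: {} for ch in spec.chroms}
    for gm in gene_models:
        if gm.gene in quiet_names:
            continue
        bp = bp_maps[gm.chrom]
        for s, e in gm.exons:
            # need pos and pos+1 inside the exon so the planted bp stays exonic
            for idx in np.flatnonzero((bp >= s) & (bp < e)):
                exon_gene_at[gm.chrom][int(idx)] = gm.gene

    # gene drop per family, with per-family retries until a planted sharing
    # path exists for all affected members
    labels: dict[str, dict[str, np.ndarray]] = {}
    planted_branch_a: dict[str, PlantedVariant] = {}
    plant_anchor: dict[str, tuple[str, int, int]] = {}  # family -> (chrom, marker, hap)
    drop_attempts: dict[str, int] = {}
    peds: dict[str, Pedigree] = {}
    for fam_idx, tpl in enumerate(spec.families):
        ped = Pedigree(tpl.individuals)
        peds[tpl.family] = ped
        hap_ids = founders.founder_hap_ids[tpl.family]
        n_haps = 2 * len(hap_ids)
        found = None
        for attempt in range(spec.max_plant_retries):
            rng = np.random.default_rng([spec.seed, _SEED_DROP, fam_idx, attempt])
            fam_labels = gene_drop_labels(ped, hap_ids, cm_maps, rng)
            members = list(tpl.affected_pair)
            hits = []
            for ch in spec.chroms:
                for hap in range(n_haps):
                    mask = _shared_hap_mask(fam_labels, members, ch.name, hap)
                    for idx in np.flatnonzero(mask):
                        if int(idx) in exon_gene_at[ch.name] and not in_quiet(
                            ch.name, int(bp_maps[ch.name][idx])
                        ):
                            hits.append((ch.name, int(idx), hap))
            if hits:
                pick_rng = np.random.default_rng([spec.seed, _SEED_PLANT, 10 + fam_idx])
                found = hits[int(pick_rng.integers(0, len(hits)))]
                labels.update({iid: fam_labels[iid] for iid in fam_labels})
                drop_attempts[tpl.family] = attempt + 1
                break
        if found is None:
            raise RuntimeError(
                f"no shared exonic founder-haplotype marker for family {tpl.family} "
                f"after {spec.max_plant_retries} gene-drop attempts"
            )
        plant_anchor[tpl.family] = found

    # cross-family plant: first two families sharing any common non-exonic marker
    fam_a, fam_b = spec.families[0].family, spec.families[1].family
    cross_anchor = None
    cross_rng = np.random.default_rng([spec.seed, _SEED_PLANT, 0])
    for ch in spec.chroms:
        share_a = np.zeros(cm_maps[ch.name].size, dtype=bool)
        best_hap_a = np.full(cm_maps[ch.name].size, -1)
        for hap in range(2 * len(founders.founder_hap_ids[fam_a])):
            m = _shared_hap_mask(labels, list(_affected(spec, fam_a)), ch.name, hap)
            best_hap_a[m & ~share_a] = hap
            share_a |= m
        share_b = np.zeros(cm_maps[ch.name].size, dtype=bool)
        best_hap_b = np.full(cm_maps[ch.name].size, -1)
        for hap in range(2 * len(founders.founder_hap_ids[fam_b])):
            m = _shared_hap_mask(labels, list(_affected(spec, fam_b)), ch.name, hap)
            best_hap_b[m & ~share_b] = hap
            share_b |= m
        both = share_a & share_b
        candidates = [
            int(i)
            for i in np.flatnonzero(both)
            if int(i) not in exon_gene_at[ch.name]
            and not in_quiet(ch.name, int(bp_maps[ch.name][i]))
        ]
        if candidates:
            idx = candidates[int(cross_rng.integers(0, len(candidates)))]
            cross_anchor = (ch.name, idx, int(best_hap_a[idx]), int(best_hap_b[idx]))
            break
    if cross_anchor is None:
        raise RuntimeError("no joint sharing marker found for the cross-family plant")

    # ------------------------------------------------------------------
    # panel assembly (base markers + planted columns), annotations
    annot_rng = np.random.default_rng([spec.seed, _SEED_ANNOT])
    samples = _affected_samples(spec) + sorted(founders.reference_haps)
    fam_of = {s: tpl.family for tpl in spec.families for s in tpl.affected_pair}

    def hap_alleles(sample: str, chrom: str) -> np.ndarray:
        if sample in fam_of:
            fam = fam_of[sample]
            lab = labels[sample][chrom]
            H = founders.family_haps[fam][chrom]
            return np.stack(
                [H[lab[0], np.arange(lab.shape[1])], H[lab[1], np.arange(lab.shape[1])]]
            )
        return founders.reference_haps[sample][chrom]

    variants: list[AnnotatedVariant] = []
    haplotypes: dict[str, dict[str, np.ndarray]] = {s: {} for s in samples}
    gmap_out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    planted_cross: Optional[PlantedVariant] = None
    tx_spans: dict[str, list[tuple[int, int, str]]] = {}
    for gm in gene_models:
        tx_spans.setdefault(gm.chrom, []).append((gm.tx_start, gm.tx_end, gm.gene))

    for ch in spec.chroms:
        chrom = ch.name
        bp = bp_maps[chrom]
        cm = cm_maps[chrom]
        af = founders.af[chrom]
        n = ch.n_markers
        allele_stack = {s: hap_alleles(s, chrom) for s in samples}

        # planted columns on this chromosome; per-family position offsets keep
        # planted vids unique even if two families anchor on the same marker
        extra: list[dict] = []
        for fam_idx, tpl in enumerate(spec.families):
            a_chrom, a_idx, a_hap = plant_anchor[tpl.family]
            if a_chrom != chrom:
                continue
            gene = exon_gene_at[chrom][a_idx]
            pos = int(bp[a_idx]) + 1 + fam_idx
            ref, alt = "G", "T"
            carriers = {}
            for s in tpl.affected_pair:
                lab = labels[s][chrom][:, a_idx]
                carriers[s] = tuple(int(l == a_hap) for l in lab)
            pv = PlantedVariant(
                vid=f"{chrom}:{pos}:{ref}:{alt}",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                families=[tpl.family],
                gene=gene,
                effect="nonsynonymous",
                cadd=spec.planted_cadd,
                kind="branch_a",
            )
            planted_branch_a[tpl.family] = pv
            extra.append(
                {
                    "pos": pos,
                    "cm": float(cm[a_idx]) + 1e-6,
                    "pv": pv,
                    "carriers": carriers,
                    "pred": ("pathogenic",) * 4 + ("benign",),
                }
            )
        if cross_anchor[0] == chrom:
            _, c_idx, hap_a, hap_b = cross_anchor
            pos = int(bp[c_idx]) + 9
            ref, alt = "C", "A"
            carriers = {}
            for fam, hap in ((fam_a, hap_a), (fam_b, hap_b)):
                for s in _affected(spec, fam):
                    lab = labels[s][chrom][:, c_idx]
                    carriers[s] = tuple(int(l == hap) for l in lab)
            ref_rng = np.random.default_rng([spec.seed, _SEED_PLANT, 1])
            ref_ids = sorted(founders.reference_haps)
            chosen = sorted(
                ref_rng.choice(len(ref_ids), size=spec.n_reference_carriers_cross, replace=False).tolist()
            )
            ref_carriers = [ref_ids[i] for i in chosen]
            for s in ref_carriers:
                carriers[s] = (1, 0)
            planted_cross = PlantedVariant(
                vid=f"{chrom}:{pos}:{ref}:{alt}",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                families=[fam_a, fam_b],
                gene="",
                effect="intergenic",
                cadd=spec.planted_cross_family_cadd,
                kind="cross_family",
                reference_carriers=ref_carriers,
            )
            extra.append(
                {
                    "pos": pos,
                    "cm": float(cm[c_idx]) + 1e-6,
                    "pv": planted_cross,
                    "carriers": carriers,
                    "pred": ("missing",) * 5,
                }
            )

        # keep polymorphic base markers only
        any_alt = np.zeros(n, dtype=bool)
        for s in samples:
            any_alt |= allele_stack[s].any(axis=0)
        keep = np.flatnonzero(any_alt)

        # per-marker annotations for kept base markers
        refs = _BASES[annot_rng.integers(0, 4, size=keep.size)]
        alts = np.array(
            [_BASES[(np.flatnonzero(_BASES == r)[0] + annot_rng.integers(1, 4)) % 4] for r in refs]
        )
        cadd_mix = annot_rng.random(keep.size) < 0.7
        cadd = np.where(
            cadd_mix,
            annot_rng.exponential(2.0, size=keep.size),
            5.0 + annot_rng.exponential(6.0, size=keep.size),
        )
        af_missing = annot_rng.random(keep.size) < spec.af_missing_rate
        qual_fail = annot_rng.random(keep.size) < spec.quality_fail_rate
        pon_flag = (af[keep] > 0.01) & (annot_rng.random(keep.size) < spec.pon_fraction)

        effect_names = list(spec.coding_effect_probs)
        effect_p = np.array([spec.coding_effect_probs[e] for e in effect_names])

        rows = []
        for j, idx in enumerate(keep.tolist()):
            pos = int(bp[idx])
            gene = exon_gene_at[chrom].get(idx, "")
            if gene:
                effect = effect_names[int(annot_rng.choice(len(effect_names), p=effect_p))]
            else:
                effect = "intergenic"
                for lo, hi, g in tx_spans.get(chrom, ()):
                    if lo <= pos <= hi:
                        effect, gene = "intronic", g
                        break
            p_path = 1.0 / (1.0 + np.exp(-(cadd[j] - spec.cadd_logistic_mid) / spec.cadd_logistic_scale))
            calls = []
            for _ in range(5):
                if annot_rng.random() < spec.predictor_missing_rate:
                    calls.append("missing")
                else:
                    calls.append("pathogenic" if annot_rng.random() < p_path else "benign")
            rows.append(
                {
                    "pos": pos,
                    "cm": float(cm[idx]),
                    "ref": str(refs[j]),
                    "alt": str(alts[j]),
                    "gene": gene,
                    "effect": effect,
                    # missing AF only plausibly affects rare alleles (common
                    # ones are always catalogued), and never in quiet locus
                    # windows, which must stay clean negatives under the
                    # missing-is-rare rule
                    "pop_af": None
                    if (af_missing[j] and af[idx] < 0.01 and not in_quiet(chrom, pos))
                    else float(af[idx]),
                    "cadd": float(cadd[j]),
                    "pred": tuple(calls),
                    "in_pon": bool(pon_flag[j]),
                    "quality_pass": not bool(qual_fail[j]),
                    "base_idx": idx,
                }
            )
        for e in extra:
            pv = e["pv"]
            rows.append(
                {
                    "pos": pv.pos,
                    "cm": e["cm"],
                    "ref": pv.ref,
                    "alt": pv.alt,
                    "gene": pv.gene,
                    "effect": pv.effect,
                    "pop_af": 0.0,
                    "cadd": pv.cadd,
                    "pred": e["pred"],
                    "in_pon": False,
                    "quality_pass": True,
                    "base_idx": None,
                    "carriers": e["carriers"],
                }
            )
        rows.sort(key=lambda r: r["pos"])

        n_out = len(rows)
        hap_out = {s: np.zeros((2, n_out), dtype=np.uint8) for s in samples}
        for col, row in enumerate(rows):
            if row["base_idx"] is not None:
                for s in samples:
                    hap_out[s][:, col] = allele_stack[s][:, row["base_idx"]]
            else:
                for s, alleles in row["carriers"].items():
                    hap_out[s][:, col] = alleles
        for s in samples:
            haplotypes[s][chrom] = hap_out[s]
        gmap_out[chrom] = (
            np.array([r["pos"] for r in rows], dtype=np.int64),
            np.array([r["cm"] for r in rows], dtype=float),
        )
        for col, row in enumerate(rows):
            genotypes = {
                s: int(hap_out[s][0, col] + hap_out[s][1, col]) for s in samples
            }
            variants.append(
                AnnotatedVariant(
                    chrom=chrom,
                    pos=row["pos"],
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    effect=row["effect"],
                    pop_af=row["pop_af"],
                    cadd_phred=row["cadd"],
                    predictor_calls=pad_predictor_calls(row["pred"]),
                    in_pon=row["in_pon"],
                    quality_pass=row["quality_pass"],
                    genotypes=genotypes,
                )
            )

    pon = {v.key for v in variants if v.in_pon}

    # ------------------------------------------------------------------
    # structural variants
    sv_rng = np.random.default_rng([spec.seed, _SEED_SV])
    svs: list[BreakendPair] = []
    planted_svs: dict[str, dict] = {}
    non_quiet_genes = [gm for gm in gene_models if gm.gene not in quiet_names]
    # two degree-5 families hit opposite ends of the same gene so one gene
    # recurs across exactly two families
    shared_gene = non_quiet_genes[len(non_quiet_genes) // 2]
    deg5_fams = [tpl.family for tpl in spec.families if tpl.degree == 5][:2]
    other_fams = [tpl.family for tpl in spec.families if tpl.family not in deg5_fams]
    gene_cycle = [gm for gm in non_quiet_genes if gm.gene != shared_gene.gene]

    def jitter() -> int:
        raw = int(round(sv_rng.normal(0.0, spec.sv_jitter_sd)))
        lim = spec.sv_max_gap - 1
        return max(-lim, min(lim, raw))

    def plant_family_del(fam: str, gene: GeneModel, left: bool) -> None:
        if left:
            p1, p2 = gene.tx_start - 500, gene.tx_start + 3000
        else:
            p1, p2 = gene.tx_end - 3000, gene.tx_end + 500
        ids = []
        for s in _affected(spec, fam):
            sv_id = f"{s}_planted"
            svs.append(
                BreakendPair(
                    sv_id=sv_id,
                    sv_type="DEL",
                    chrom1=gene.chrom,
                    pos1=p1 + jitter(),
                    orient1="+",
                    chrom2=gene.chrom,
                    pos2=p2 + jitter(),
                    orient2="-",
                    sample=s,
                )
            )
            ids.append(sv_id)
        planted_svs[fam] = {"sv_ids": ids, "gene": gene.gene, "pos1": p1, "pos2": p2}

    if len(deg5_fams) == 2:
        plant_family_del(deg5_fams[0], shared_gene, left=True)
        plant_family_del(deg5_fams[1], shared_gene, left=False)
        recurrent_gene, recurrent_fams = shared_gene.gene, sorted(deg5_fams)
    else:
        recurrent_gene, recurrent_fams = None, []
    for k, fam in enumerate(other_fams):
        plant_family_del(fam, gene_cycle[(7 * k + 3) % len(gene_cycle)], left=bool(k % 2))

    # singleton decoys, far from every planted breakpoint
    decoy_chrom = spec.chroms[-1].name
    decoy_base = spec.chroms[-1].length_bp // 2
    decoy_step = max(20 * spec.sv_max_gap, 5000)
    counter = 0
    for s in samples[: len(_affected_samples(spec))]:
        for _ in range(spec.decoys_per_sample):
            start = decoy_base + counter * decoy_step
            counter += 1
            if start + 2000 >= spec.chroms[-1].length_bp:
                break
            svs.append(
                BreakendPair(
                    sv_id=f"{s}_decoy{counter}",
                    sv_type="DEL",
                    chrom1=decoy_chrom,
                    pos1=start,
                    orient1="+",
                    chrom2=decoy_chrom,
                    pos2=start + 2000,
                    orient2="-",
                    sample=s,
                )
            )

    # catalogue SVs carried by everyone, listed in the catalogue TSV
    catalogue: list[BreakendPair] = []
    cat_chrom = spec.chroms[0].name
    cat_base = spec.chroms[0].length_bp // 3
    for k in range(spec.n_catalogue_svs):
        p1 = cat_base + k * decoy_step * 4
        p2 = p1 + 5000
        catalogue.append(
            BreakendPair(
                sv_id=f"cat{k}",
                sv_type="DEL",
                chrom1=cat_chrom,
                pos1=p1,
                orient1="+",
                chrom2=cat_chrom,
                pos2=p2,
                orient2="-",
                sample="catalogue",
                in_catalogue=True,
            )
        )
        for s in _affected_samples(spec):
            svs.append(
                BreakendPair(
                    sv_id=f"{s}_cat{k}",
                    sv_type="DEL",
                    chrom1=cat_chrom,
                    pos1=p1 + jitter(),
                    orient1="+",
                    chrom2=cat_chrom,
                    pos2=p2 + jitter(),
                    orient2="-",
                    sample=s,
                )
            )

    # ------------------------------------------------------------------
    # patients: familial arm uses the published-style defaults, reference
    # arm is drawn around a later age at diagnosis
    pat_rng = np.random.default_rng([spec.seed, _SEED_PATIENTS])
    familial_defaults = {
        "ages": [35, 36, 46, 39, 35, 60, 17, 39],
        "stages": ["IIB", "IA", "IC", "unknown", "IA", "IA", "IC", "IC"],
    }
    patients = []
    fam_samples = _affected_samples(spec)
    for k, s in enumerate(fam_samples):
        patients.append(
            PatientRecord(
                patient_id=s,
                family=fam_of[s],
                age_at_diagnosis=familial_defaults["ages"][k % 8],
                stage=familial_defaults["stages"][k % 8],
            )
        )
    for k, s in enumerate(sorted(founders.reference_haps)):
        age = float(np.clip(np.round(pat_rng.normal(51.0, 11.0)), 29, 75))
        stage = "IIIA" if k == 0 else ("IC" if k % 3 == 0 else "IA")
        patients.append(PatientRecord(patient_id=s, family="reference", age_at_diagnosis=age, stage=stage))

    all_inds = [ind for tpl in spec.families for ind in tpl.individuals]
    pedigree = Pedigree(all_inds)
    cohort = FamilyCohort(
        families={tpl.family: list(tpl.affected_pair) for tpl in spec.families},
        reference_samples=sorted(founders.reference_haps),
    )
    degrees = {
        ",".join(tpl.affected_pair): tpl.degree for tpl in spec.families
    }
    truth = GroundTruth(
        planted_branch_a=planted_branch_a,
        planted_cross_family=planted_cross,
        planted_svs=planted_svs,
        sv_recurrent_gene=recurrent_gene,
        sv_recurrent_families=recurrent_fams,
        degrees=degrees,
        quiet_genes=quiet_names,
        drop_attempts=drop_attempts,
    )
    return SimulatedCohort(
        spec=spec,
        cohort=cohort,
        pedigree=pedigree,
        gene_models=gene_models,
        variants=variants,
        haplotypes=haplotypes,
        genetic_map=gmap_out,
        svs=svs,
        sv_catalogue=catalogue,
        pon=pon,
        patients=patients,
        ground_truth=truth,
        labels={s: labels[s] for s in fam_samples},
    )


def _affected(spec: SimSpec, family: str) -> tuple[str, str]:
    for tpl in spec.families:
        if tpl.family == family:
            return tpl.affected_pair
    raise KeyError(family)


def _affected_samples(spec: SimSpec) -> list[str]:
    return [s for tpl in spec.families for s in tpl.affected_pair]


def default_spec(seed: int) -> SimSpec:
    return SimSpec(seed=seed)


# --------------------------------------------------------------------------
# small-scale pair simulation for relatedness validation


def simulate_degree_pair(
    degree: int,
    seed: int,
    n_markers_per_chrom: int = 2500,
    n_chroms: int = 2,
    chrom_cm: float = 100.0,
    af_alpha: float = 2.0,
    af_beta: float = 2.0,
    template: str = "lineal",
) -> dict:
    """Simulate one relative pair at a known degree.

    Returns genotype vectors, phased haplotypes and the cM map for the two
    designated individuals; ``template`` picks a lineal chain (any degree)
    or the second-cousin configuration (degree 5).
    """
    if template == "lineal":
        tpl = lineal_pair_template(degree)
    elif template == "second_cousin":
        if degree != 5:
            raise ValueError("second_cousin template is degree 5")
        tpl = second_cousin_template()
    elif template == "collateral":
        # two-ancestor configurations (sibs' descendants): lower realized-
        # kinship variance than a lineal chain of the same degree
        tpl = family_template("L", degree)
    else:
        raise ValueError(f"unknown template {template!r}")
    rng = np.random.default_rng([seed, degree, 11])
    ped = Pedigree(tpl.individuals)
    chrom_names = [str(k + 1) for k in range(n_chroms)]
    cm_maps = {c: np.linspace(0.0, chrom_cm, n_markers_per_chrom) for c in chrom_names}
    af = {
        c: np.clip(rng.beta(af_alpha, af_beta, size=n_markers_per_chrom), 0.05, 0.95)
        for c in chrom_names
    }
    founder_haps = {
        iid: {c: (rng.random((2, n_markers_per_chrom)) < af[c]).astype(np.uint8) for c in chrom_names}
        for iid in ped.founders
    }
    haps = gene_drop(ped, founder_haps, cm_maps, rng)
    i, j = tpl.affected_pair
    gt_i = np.concatenate([haps[i][c].sum(axis=0) for c in chrom_names]).astype(np.int8)
    gt_j = np.concatenate([haps[j][c].sum(axis=0) for c in chrom_names]).astype(np.int8)
    return {
        "pair": (i, j),
        "genotypes_i": gt_i,
        "genotypes_j": gt_j,
        "haplotypes_i": haps[i],
        "haplotypes_j": haps[j],
        "genetic_map": cm_maps,
        "genome_cm": chrom_cm * n_chroms,
    }


# --------------------------------------------------------------------------
# emission


def emit(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as mutually consistent plain-text files.

    The ground-truth sidecar is for tests and validation only; the pipeline
    never reads it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = sim.cohort.all_samples
    contigs = [(ch.name, ch.length_bp) for ch in sim.spec.chroms]

    hap_index: dict[str, dict[str, int]] = {}
    counters: dict[str, int] = {}
    rows = []
    for v in sim.variants:
        chrom = v.chrom
        col = counters.get(chrom, 0)
        counters[chrom] = col + 1
        gts = []
        for s in samples:
            h = sim.haplotypes[s][chrom][:, col]
            gts.append((int(h[0]), int(h[1])))
        info: dict = {
            "EFFECT": v.effect,
            "PRED": ",".join({"pathogenic": "P", "benign": "B", "missing": "M"}[c] for c in v.predictor_calls),
        }
        if v.pop_af is not None:
            info["POP_AF"] = v.pop_af
        if v.cadd_phred is not None:
            info["CADD"] = v.cadd_phred
        if v.gene:
            info["GENE"] = v.gene
        if v.in_pon:
            info["PON"] = True
        rows.append(
            VcfRow(chrom, v.pos, v.ref, v.alt, info, v.quality_pass, gts, phased=True)
        )
    paths = {
        "vcf": out / "cohort.vcf",
        "sv_vcf": out / "svs.vcf",
        "ped": out / "cohort.ped",
        "bed": out / "genes.bed",
        "pon": out / "pon.tsv",
        "catalogue": out / "sv_catalogue.tsv",
        "patients": out / "patients.tsv",
        "map": out / "genetic_map.tsv",
        "truth": out / "ground_truth.json",
    }
    write_vcf(rows, samples, contigs, paths["vcf"])
    write_sv_vcf(sim.svs, contigs, paths["sv_vcf"])
    write_ped(sim.pedigree, paths["ped"])
    write_gene_bed(sim.gene_models, paths["bed"])
    write_pon_tsv(sorted(sim.pon), paths["pon"])
    write_sv_catalogue_tsv(sim.sv_catalogue, paths["catalogue"])
    write_patients_tsv(sim.patients, paths["patients"])
    write_genetic_map(sim.genetic_map, paths["map"])
    sim.ground_truth.to_json(paths["truth"])
    return paths
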