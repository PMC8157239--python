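"""Readers and writers for every external format the pipeline touches.

VCF parsing is delegated to pysam; everything else (PED, BED, TSV resources,
reports, config) is plain text. Pool-of-normals and SV-catalogue resources
are consumed as TSV variant lists rather than binary databases.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
import yaml

from .compare import PatientRecord
from .pedigree import Individual, Pedigree
from .snv import CandidateVariant, FilterTrace
from .variant_model import (
    AnnotatedVariant,
    BreakendPair,
    GeneModel,
    RawRecord,
    normalize_variant,
    trim_alleles,
)

logger = logging.getLogger("famvar")

__all__ = [
    "RunConfig",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_phased_haplotypes",
    "read_ped",
    "write_ped",
    "read_sv_vcf",
    "write_sv_vcf",
    "read_gene_bed",
    "write_gene_bed",
    "read_pon_tsv",
    "write_pon_tsv",
    "read_sv_catalogue_tsv",
    "write_sv_catalogue_tsv",
    "read_patients_tsv",
    "write_patients_tsv",
    "read_genetic_map",
    "write_genetic_map",
    "write_report",
]

_DEFAULT_ALIASES = {
    "pop_af": "POP_AF",
    "cadd": "CADD",
    "gene": "GENE",
    "effect": "EFFECT",
    "pred": "PRED",
    "pon": "PON",
}

_PRED_CODE = {"pathogenic": "P", "benign": "B", "missing": "M"}
_PRED_DECODE = {v: k for k, v in _PRED_CODE.items()}


class VcfFormatError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunable thresholds plus file paths and the run seed."""

    pop_af_max: float = 0.001
    cadd_annotate: float = 5.0
    cadd_assess: float = 20.0
    cadd_highlight: float = 30.0
    predictor_min: int = 3
    exon_pad_bp: int = 10
    locus_flank_bp: int = 75_000
    sv_max_gap_bp: int = 100
    sv_bnd_flank_bp: int = 1000
    ibd_min_cm: float = 3.0
    max_degree: int = 9
    min_families: int = 2
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    locus_genes: list[str] = field(default_factory=list)
    gene_blacklist: list[str] = field(default_factory=list)
    max_background_branch_a_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pop_af_max < 1.0:
            raise ValueError("pop_af_max must be in (0, 1)")
        if not self.cadd_annotate <= self.cadd_assess <= self.cadd_highlight:
            raise ValueError("CADD thresholds must be ordered annotate <= assess <= highlight")
        for name in ("exon_pad_bp", "locus_flank_bp", "sv_max_gap_bp", "sv_bnd_flank_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# --------------------------------------------------------------------------
# SNV/indel VCF


def _info_scalar(value, k: int, n_alts: int):
    if isinstance(value, tuple):
        if len(value) == n_alts:
            return value[k]
        return value[0] if value else None
    return value


def read_vcf(
    path: str | Path,
    sample_subset: Optional[Sequence[str]] = None,
    aliases: Optional[dict[str, str]] = None,
    on_missing: str = "warn",
) -> Iterable[AnnotatedVariant]:
    """Stream normalized biallelic variants from an annotated multi-sample VCF.

    Multiallelic records are decomposed; records failing the caller FILTER
    are kept with ``quality_pass=False``. Missing required INFO keys are
    handled per ``on_missing`` ("warn" sets the annotation missing, "abort"
    raises). An unsorted file aborts.
    """
    keys = dict(_DEFAULT_ALIASES, **(aliases or {}))
    if on_missing not in {"warn", "abort"}:
        raise ValueError("on_missing must be 'warn' or 'abort'")
    vf = pysam.VariantFile(str(path))
    header_keys = set(vf.header.info.keys())
    warned: set[str] = set()
    for logical, key in keys.items():
        if key not in header_keys:
            if on_missing == "abort":
                raise VcfFormatError(f"required INFO key {key} missing from header of {path}")
            if key not in warned:
                logger.warning("INFO key %s absent from %s; setting %s to missing", key, path, logical)
                warned.add(key)
    present = {logical: key in header_keys for logical, key in keys.items()}

    def info_get(info, logical, default=None):
        # pysam raises on lookups of keys absent from the header entirely
        if not present[logical]:
            return default
        return info.get(keys[logical], default)

    samples = list(vf.header.samples)
    if sample_subset is not None:
        missing = set(sample_subset) - set(samples)
        if missing:
            raise VcfFormatError(f"samples {sorted(missing)} not in VCF {path}")
        samples = [s for s in samples if s in set(sample_subset)]
    finished_chroms: set[str] = set()
    current_chrom: Optional[str] = None
    last_pos = 0
    for rec in vf:
        if rec.chrom != current_chrom:
            if rec.chrom in finished_chroms:
                raise VcfFormatError(f"unsorted VCF: chromosome {rec.chrom} interleaved")
            if current_chrom is not None:
                finished_chroms.add(current_chrom)
            current_chrom, last_pos = rec.chrom, 0
        if rec.pos < last_pos:
            raise VcfFormatError(f"unsorted VCF at {rec.chrom}:{rec.pos}")
        last_pos = rec.pos
        alts = list(rec.alts or ())
        if not alts:
            continue
        n_alts = len(alts)
        info = rec.info
        pred_raw = info_get(info, "pred", ())
        if isinstance(pred_raw, str):
            pred_raw = (pred_raw,)
        predictor_calls = tuple(_PRED_DECODE.get(p, "missing") for p in pred_raw)
        genotypes: dict[str, Optional[tuple[int, ...]]] = {}
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                genotypes[s] = None
            else:
                genotypes[s] = tuple(gt)
        filters = list(rec.filter.keys())
        quality_pass = not filters or filters == ["PASS"]
        effect = info_get(info, "effect", "other")
        if isinstance(effect, tuple):
            effect = [e or "other" for e in effect] if len(effect) == n_alts else (effect[0] or "other")
        pop_af = info_get(info, "pop_af")
        cadd = info_get(info, "cadd")
        raw = RawRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=alts,
            record_id=rec.id or f"{rec.chrom}:{rec.pos}",
            quality_pass=quality_pass,
            genotypes=genotypes,
            gene=_info_scalar(info_get(info, "gene", ""), 0, n_alts) or "",
            effect=effect,
            pop_af=list(pop_af) if isinstance(pop_af, tuple) else pop_af,
            cadd_phred=[_info_scalar(cadd, k, n_alts) for k in range(n_alts)]
            if n_alts > 1
            else _info_scalar(cadd, 0, n_alts),
            predictor_calls=predictor_calls,
            in_pon=bool(info_get(info, "pon", False)),
        )
        yield from normalize_variant(raw)


def _fmt_info_value(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _vcf_header(samples: Sequence[str], contigs: Sequence[tuple[str, int]]) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=famvar"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FILTER=<ID=LowQual,Description="Failed caller quality filter">',
        '##INFO=<ID=POP_AF,Number=A,Type=Float,Description="Population alternate allele frequency">',
        '##INFO=<ID=CADD,Number=A,Type=Float,Description="CADD PHRED deleteriousness score">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFFECT,Number=A,Type=String,Description="Coding effect class">',
        '##INFO=<ID=PRED,Number=.,Type=String,Description="Five pathogenicity predictor calls (P/B/M)">',
        '##INFO=<ID=PON,Number=0,Type=Flag,Description="Pool-of-normals member">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    return lines


@dataclass
class VcfRow:
    """One biallelic output row; ``gts`` holds per-sample phased allele pairs
    (tuples of 0/1) or None for missing."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict
    quality_pass: bool = True
    gts: list[Optional[tuple[int, int]]] = field(default_factory=list)
    phased: bool = True


def variant_to_row(v: AnnotatedVariant, samples: Sequence[str]) -> VcfRow:
    """Lossy unphased conversion (allele counts back to diploid genotypes)."""
    gts: list[Optional[tuple[int, int]]] = []
    for s in samples:
        count = v.genotypes.get(s)
        if count is None:
            gts.append(None)
        else:
            gts.append((1, 1) if count == 2 else (0, 1) if count == 1 else (0, 0))
    info: dict = {"PRED": ",".join(_PRED_CODE[c] for c in v.predictor_calls)}
    if v.pop_af is not None:
        info["POP_AF"] = v.pop_af
    if v.cadd_phred is not None:
        info["CADD"] = v.cadd_phred
    if v.gene:
        info["GENE"] = v.gene
    info["EFFECT"] = v.effect
    if v.in_pon:
        info["PON"] = True
    return VcfRow(v.chrom, v.pos, v.ref, v.alt, info, v.quality_pass, gts, phased=False)


def write_vcf(
    rows: Iterable[VcfRow],
    samples: Sequence[str],
    contigs: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(_vcf_header(samples, contigs)) + "\n")
        for row in rows:
            parts = []
            for key, value in sorted(row.info.items()):
                if value is True:
                    parts.append(key)
                else:
                    parts.append(f"{key}={_fmt_info_value(value)}")
            info = ";".join(parts) if parts else "."
            sep = "|" if row.phased else "/"
            gts = "\t".join(
                "./." if gt is None else f"{gt[0]}{sep}{gt[1]}" for gt in row.gts
            )
            filt = "PASS" if row.quality_pass else "LowQual"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{filt}\t{info}\tGT\t{gts}\n"
            )


def read_phased_haplotypes(
    path: str | Path, sample_subset: Optional[Sequence[str]] = None
) -> dict[str, dict[str, np.ndarray]]:
    """Phased haplotypes from a pipe-separated-GT VCF.

    Returns sample -> chromosome -> (2, n_markers) uint8 arrays in record
    order. Unphased or missing genotypes abort: IBD detection requires
    complete phased input.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if sample_subset is not None:
        samples = [s for s in samples if s in set(sample_subset)]
    per_chrom: dict[str, dict[str, list[list[int]]]] = {}
    for rec in vf:
        chrom_store = per_chrom.setdefault(rec.chrom, {s: [[], []] for s in samples})
        for s in samples:
            sdata = rec.samples[s]
            gt = sdata["GT"]
            if gt is None or any(a is None for a in gt) or not sdata.phased:
                raise VcfFormatError(
                    f"unphased/missing genotype for {s} at {rec.chrom}:{rec.pos}"
                )
            chrom_store[s][0].append(min(gt[0], 1))
            chrom_store[s][1].append(min(gt[1], 1))
    return {
        s: {
            chrom: np.array(store[s], dtype=np.uint8)
            for chrom, store in per_chrom.items()
        }
        for s in samples
    }


# --------------------------------------------------------------------------
# PED


def read_ped(path: str | Path) -> Pedigree:
    """Parse a 6-column PED file (FID IID PAT MAT SEX PHENO; founders coded 0)."""
    individuals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED line has {len(fields)} columns, need 6: {line!r}")
            fid, iid, pat, mat, sex, pheno = fields[:6]
            individuals.append(
                Individual(
                    iid=iid,
                    father=None if pat == "0" else pat,
                    mother=None if mat == "0" else mat,
                    sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                    affected=pheno == "2",
                    family=fid,
                )
            )
    return Pedigree(individuals)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for iid, ind in ped.individuals.items():
            fh.write(
                "\t".join(
                    [
                        ind.family or "0",
                        iid,
                        ind.father or "0",
                        ind.mother or "0",
                        sex_code[ind.sex],
                        "2" if ind.affected else "1",
                    ]
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# SV VCF

_SV_ORIENT = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+"), "INS": ("+", "-")}


def _parse_bnd_alt(alt: str) -> tuple[str, int, str]:
    """Mate locus and local orientation from a breakend ALT string."""
    for bracket in "[]":
        if bracket in alt:
            inner = alt.split(bracket)[1]
            chrom, pos = inner.rsplit(":", 1)
            orient = "+" if alt[0] not in "[]" else "-"
            return chrom, int(pos), orient
    raise VcfFormatError(f"cannot parse BND ALT {alt!r}")


def read_sv_vcf(path: str | Path) -> list[BreakendPair]:
    """SV records as symbolic SVTYPE/END or paired BND lines with MATEID.

    Mate pairs are joined exactly once; orphan BND mates are warned about and
    dropped. Missing confidence intervals default to (0, 0). The carrying
    sample is taken from the SAMPLE INFO key when present, else from the
    single sample column.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    out: list[BreakendPair] = []
    pending: dict[str, pysam.VariantRecord] = {}

    def _ci(rec, key) -> tuple[int, int]:
        val = rec.info.get(key)
        if val is None:
            return (0, 0)
        return (int(val[0]), int(val[1]))

    def _sample(rec) -> str:
        s = rec.info.get("SAMPLE")
        if s:
            return s if isinstance(s, str) else s[0]
        for s in vcf_samples:
            gt = rec.samples[s]["GT"]
            if gt and any(a for a in gt if a):
                return s
        return vcf_samples[0] if vcf_samples else ""

    for rec in vf:
        svtype = rec.info.get("SVTYPE")
        if svtype is None:
            warnings.warn(f"record {rec.id} lacks SVTYPE; skipped")
            continue
        if svtype == "BND":
            mate_id = rec.info.get("MATEID")
            if isinstance(mate_id, tuple):
                mate_id = mate_id[0]
            if mate_id in pending:
                mate = pending.pop(mate_id)
                chrom2, pos2, orient2 = _parse_bnd_alt(rec.alts[0])
                _, _, orient1 = _parse_bnd_alt(mate.alts[0])
                out.append(
                    BreakendPair(
                        sv_id=str(mate.id),
                        sv_type="BND",
                        chrom1=mate.chrom,
                        pos1=mate.pos,
                        orient1=orient1,
                        chrom2=rec.chrom,
                        pos2=rec.pos,
                        orient2=orient2,
                        ci1=_ci(mate, "CIPOS"),
                        ci2=_ci(rec, "CIPOS"),
                        sample=_sample(mate),
                        in_catalogue=bool(mate.info.get("IN_CATALOGUE", False)),
                    )
                )
            else:
                if rec.id is None:
                    warnings.warn("BND record without ID dropped")
                    continue
                pending[rec.id] = rec
        else:
            end = rec.info.get("END", rec.stop)
            orient1, orient2 = _SV_ORIENT.get(svtype, ("+", "-"))
            out.append(
                BreakendPair(
                    sv_id=str(rec.id or f"{rec.chrom}:{rec.pos}:{svtype}"),
                    sv_type=svtype,
                    chrom1=rec.chrom,
                    pos1=rec.pos,
                    orient1=orient1,
                    chrom2=rec.chrom,
                    pos2=int(end),
                    orient2=orient2,
                    ci1=_ci(rec, "CIPOS"),
                    ci2=_ci(rec, "CIEND"),
                    sample=_sample(rec),
                    in_catalogue=bool(rec.info.get("IN_CATALOGUE", False)),
                )
            )
    for orphan in pending.values():
        warnings.warn(f"orphan BND mate {orphan.id} dropped")
    return out


def write_sv_vcf(
    svs: Sequence[BreakendPair],
    contigs: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write SVs as symbolic records (DEL/DUP/INV/INS) or BND mate pairs."""
    lines = ["##fileformat=VCFv4.2", "##source=famvar"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="CI around POS">',
        '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="CI around END">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrying sample">',
        '##INFO=<ID=IN_CATALOGUE,Number=0,Type=Flag,Description="Known-SV catalogue member">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=INS,Description="Insertion">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = []
    for sv in svs:
        flag = ";IN_CATALOGUE" if sv.in_catalogue else ""
        if sv.sv_type == "BND":
            a_id, b_id = f"{sv.sv_id}_1", f"{sv.sv_id}_2"
            alt1 = f"N[{sv.chrom2}:{sv.pos2}[" if sv.orient1 == "+" else f"]{sv.chrom2}:{sv.pos2}]N"
            alt2 = f"N[{sv.chrom1}:{sv.pos1}[" if sv.orient2 == "+" else f"]{sv.chrom1}:{sv.pos1}]N"
            body.append(
                (sv.chrom1, sv.pos1,
                 f"{sv.chrom1}\t{sv.pos1}\t{a_id}\tN\t{alt1}\t.\tPASS\t"
                 f"SVTYPE=BND;MATEID={b_id};CIPOS={sv.ci1[0]},{sv.ci1[1]};SAMPLE={sv.sample}{flag}")
            )
            body.append(
                (sv.chrom2, sv.pos2,
                 f"{sv.chrom2}\t{sv.pos2}\t{b_id}\tN\t{alt2}\t.\tPASS\t"
                 f"SVTYPE=BND;MATEID={a_id};CIPOS={sv.ci2[0]},{sv.ci2[1]};SAMPLE={sv.sample}{flag}")
            )
        else:
            body.append(
                (sv.chrom1, sv.pos1,
                 f"{sv.chrom1}\t{sv.pos1}\t{sv.sv_id}\tN\t<{sv.sv_type}>\t.\tPASS\t"
                 f"SVTYPE={sv.sv_type};END={sv.pos2};CIPOS={sv.ci1[0]},{sv.ci1[1]};"
                 f"CIEND={sv.ci2[0]},{sv.ci2[1]};SAMPLE={sv.sample}{flag}")
            )
    contig_order = {name: k for k, (name, _) in enumerate(contigs)}
    body.sort(key=lambda t: (contig_order.get(t[0], len(contig_order)), t[1]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for _, _, line in body:
            fh.write(line + "\n")


# --------------------------------------------------------------------------
# BED gene models


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Gene models from 4-column exon BED or BED12 (0-based half-open input,
    converted to 1-based closed intervals)."""
    by_gene: dict[tuple[str, str], list[tuple[int, int]]] = {}
    strands: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            key = (name, chrom)
            if len(fields) >= 12:
                strands[key] = fields[5]
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
                for size, off in zip(sizes, offsets):
                    s = start + off
                    by_gene.setdefault(key, []).append((s + 1, s + size))
            else:
                if len(fields) >= 6:
                    strands[key] = fields[5]
                by_gene.setdefault(key, []).append((start + 1, end))
    return [
        GeneModel(gene=name, chrom=chrom, strand=strands.get((name, chrom), "+"), exons=sorted(exons))
        for (name, chrom), exons in by_gene.items()
    ]


def write_gene_bed(models: Sequence[GeneModel], path: str | Path) -> None:
    """4-column exon BED (0-based half-open), one row per exon."""
    with open(path, "w") as fh:
        for gm in sorted(models, key=lambda g: (g.chrom, g.tx_start, g.gene)):
            for s, e in gm.exons:
                fh.write(f"{gm.chrom}\t{s - 1}\t{e}\t{gm.gene}\t0\t{gm.strand}\n")


# --------------------------------------------------------------------------
# TSV resources


def read_pon_tsv(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Pool-of-normals variant list (chrom, pos, ref, alt); entries are
    normalized on read so padded representations still match."""
    pon = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            npos, nref, nalt = trim_alleles(int(pos), ref, alt)
            pon.add((chrom, npos, nref, nalt))
    return pon


def write_pon_tsv(entries: Iterable[tuple[str, int, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(entries):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


_SV_TSV_HEADER = "#sv_id\tsv_type\tchrom1\tpos1\torient1\tci1_lo\tci1_hi\tchrom2\tpos2\torient2\tci2_lo\tci2_hi"


def read_sv_catalogue_tsv(path: str | Path) -> list[BreakendPair]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                BreakendPair(
                    sv_id=f[0],
                    sv_type=f[1],
                    chrom1=f[2],
                    pos1=int(f[3]),
                    orient1=f[4],
                    ci1=(int(f[5]), int(f[6])),
                    chrom2=f[7],
                    pos2=int(f[8]),
                    orient2=f[9],
                    ci2=(int(f[10]), int(f[11])),
                    sample="catalogue",
                    in_catalogue=True,
                )
            )
    return out


def write_sv_catalogue_tsv(svs: Sequence[BreakendPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_SV_TSV_HEADER + "\n")
        for sv in sorted(svs, key=lambda s: (s.chrom1, s.pos1, s.sv_id)):
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        sv.sv_id, sv.sv_type,
                        sv.chrom1, sv.pos1, sv.orient1, sv.ci1[0], sv.ci1[1],
                        sv.chrom2, sv.pos2, sv.orient2, sv.ci2[0], sv.ci2[1],
                    )
                )
                + "\n"
            )


def read_patients_tsv(path: str | Path) -> list[PatientRecord]:
    """Patients TSV: patient_id, family, age_at_diagnosis, stage[, menopausal]."""
    out = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            out.append(
                PatientRecord(
                    patient_id=f[idx["patient_id"]],
                    family=f[idx["family"]],
                    age_at_diagnosis=float(f[idx["age_at_diagnosis"]]),
                    stage=f[idx["stage"]] if "stage" in idx else "unknown",
                    menopausal=f[idx["menopausal"]] if "menopausal" in idx and f[idx["menopausal"]] else None,
                )
            )
    return out


def write_patients_tsv(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tfamily\tage_at_diagnosis\tstage\tmenopausal\n")
        for r in records:
            age = int(r.age_at_diagnosis) if float(r.age_at_diagnosis).is_integer() else r.age_at_diagnosis
            fh.write(f"{r.patient_id}\t{r.family}\t{age}\t{r.stage}\t{r.menopausal or ''}\n")


def read_genetic_map(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Genetic map TSV (chrom, pos, cM) -> chrom -> (positions, cM) arrays."""
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, cm = line.split("\t")[:3]
            store = per_chrom.setdefault(chrom, ([], []))
            store[0].append(int(pos))
            store[1].append(float(cm))
    return {
        chrom: (np.array(pos, dtype=np.int64), np.array(cm, dtype=float))
        for chrom, (pos, cm) in per_chrom.items()
    }


def write_genetic_map(
    gmap: dict[str, tuple[np.ndarray, np.ndarray]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tcM\n")
        for chrom in gmap:
            pos, cm = gmap[chrom]
            for p, c in zip(pos.tolist(), cm.tolist()):
                fh.write(f"{chrom}\t{p}\t{c:.6f}\n")


# --------------------------------------------------------------------------
# Reports


def write_report(
    trace: FilterTrace,
    candidates: Sequence[CandidateVariant],
    out_dir: str | Path,
    extras: Optional[dict] = None,
) -> dict[str, Path]:
    """Write the funnel TSV, candidates TSV, and a JSON run summary.

    Column order and row order are deterministic; re-running with identical
    inputs yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    funnel_path = out_dir / "funnel.tsv"
    with open(funnel_path, "w") as fh:
        fh.write("stage\tn_in\tn_out\tpct_retained\n")
        for name, n_in, n_out in trace.counts():
            pct = 100.0 * n_out / n_in if n_in else 0.0
            fh.write(f"{name}\t{n_in}\t{n_out}\t{pct:.1f}\n")
    cand_path = out_dir / "candidates.tsv"
    with open(cand_path, "w") as fh:
        fh.write(
            "vid\tchrom\tpos\tref\talt\tgenes\teffect\tpop_af\tcadd_phred\t"
            "n_pathogenic\tfamilies\tcancer_gene\tcadd_tier\tconsequence_pass\texception\n"
        )
        for c in sorted(candidates, key=lambda c: c.variant.key):
            v = c.variant
            fh.write(
                "\t".join(
                    [
                        v.vid, v.chrom, str(v.pos), v.ref, v.alt,
                        ",".join(sorted(c.genes)) or v.gene,
                        v.effect,
                        "" if v.pop_af is None else f"{v.pop_af:.6g}",
                        "" if v.cadd_phred is None else f"{v.cadd_phred:.6g}",
                        str(v.n_pathogenic),
                        ",".join(sorted(c.families)),
                        str(int(c.cancer_gene)),
                        c.cadd_tier,
                        str(int(c.consequence_pass)),
                        str(int(c.exception)),
                    ]
                )
                + "\n"
            )
    summary = {
        "funnel": [
            {"stage": name, "n_in": n_in, "n_out": n_out}
            for name, n_in, n_out in trace.counts()
        ],
        "n_candidates": len(candidates),
        "n_exceptions": sum(c.exception for c in candidates),
    }
    if extras:
        summary.update(extras)
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"funnel": funnel_path, "candidates": cand_path, "summary": summary_path}
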