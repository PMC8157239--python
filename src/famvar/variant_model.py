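"""Core domain types shared by every pipeline stage, plus variant normalization.

Coordinates are 1-based inclusive throughout (VCF convention). Multiallelic
records must be decomposed with :func:`normalize_variant` before any
downstream logic sees them; every :class:`AnnotatedVariant` carries exactly
one alternate allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "EFFECTS",
    "CODING_EFFECTS",
    "PREDICTOR_STATES",
    "AnnotatedVariant",
    "BreakendPair",
    "GeneModel",
    "FamilyCohort",
    "RawRecord",
    "MalformedRecordError",
    "normalize_variant",
    "trim_alleles",
    "pad_predictor_calls",
]

#: Recognised coding-effect vocabulary.
EFFECTS = frozenset(
    {
        "frameshift",
        "stop_gain",
        "stop_loss",
        "start_loss",
        "nonsynonymous",
        "synonymous",
        "splice_region",
        "intronic",
        "intergenic",
        "other",
    }
)

#: Effect classes treated as protein-truncating / automatically consequential.
CODING_EFFECTS = frozenset({"frameshift", "stop_gain", "stop_loss", "start_loss"})

PREDICTOR_STATES = ("pathogenic", "benign", "missing")

_VALID_BASES = frozenset("ACGTN")


class MalformedRecordError(ValueError):
    """Raised when a raw record carries alleles that cannot be normalized."""


def pad_predictor_calls(calls: Sequence[str]) -> tuple[str, ...]:
    """Return exactly five predictor calls, padding short vectors with ``missing``.

    The 3-of-5 pathogenicity consensus needs a fixed denominator, so absent
    predictors count as ``missing`` (which in turn counts against the
    consensus downstream).
    """
    out = []
    for c in calls[:5]:
        if c not in PREDICTOR_STATES:
            raise ValueError(f"unknown predictor call {c!r}")
        out.append(c)
    while len(out) < 5:
        out.append("missing")
    return tuple(out)


@dataclass
class AnnotatedVariant:
    """One normalized biallelic SNV/indel with genotypes and annotations.

    ``genotypes`` maps sample id to an alternate-allele count in ``{0, 1, 2}``
    or ``None`` for a missing genotype. Missing is a distinct state and is
    never coerced to homozygous reference.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: str = "other"
    pop_af: Optional[float] = None
    cadd_phred: Optional[float] = None
    predictor_calls: tuple[str, ...] = ("missing",) * 5
    in_pon: bool = False
    quality_pass: bool = True
    genotypes: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"malformed allele {allele!r} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"pop_af out of [0,1]: {self.pop_af}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be >= 0: {self.cadd_phred}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        self.predictor_calls = pad_predictor_calls(tuple(self.predictor_calls))

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized site identity used for joins (PoN, reference presence)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def n_pathogenic(self) -> int:
        return sum(c == "pathogenic" for c in self.predictor_calls)

    def carrier(self, sample: str) -> bool:
        """True iff the sample has a called genotype with >= 1 alt allele."""
        gt = self.genotypes.get(sample)
        return gt is not None and gt >= 1


@dataclass
class BreakendPair:
    """One structural variant as two oriented breakends with CIs.

    Confidence intervals are signed offsets ``(low, high)`` with
    ``low <= 0 <= high`` around each breakend position.
    """

    sv_id: str
    sv_type: str
    chrom1: str
    pos1: int
    orient1: str
    chrom2: str
    pos2: int
    orient2: str
    ci1: tuple[int, int] = (0, 0)
    ci2: tuple[int, int] = (0, 0)
    sample: str = ""
    in_catalogue: bool = False

    def __post_init__(self) -> None:
        if self.sv_type not in {"DEL", "DUP", "INV", "INS", "BND"}:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.orient1 not in "+-" or self.orient2 not in "+-":
            raise ValueError("orientations must be '+' or '-'")
        for ci in (self.ci1, self.ci2):
            if not (ci[0] <= 0 <= ci[1]):
                raise ValueError(f"confidence interval {ci} must contain 0")
        if self.sv_type != "BND":
            if self.chrom1 != self.chrom2:
                raise ValueError(f"{self.sv_type} must be intrachromosomal")
            if self.pos1 > self.pos2:
                raise ValueError(f"pos1 > pos2 for {self.sv_type} {self.sv_id}")

    def breakends(self) -> tuple[tuple[str, int, str, tuple[int, int]], ...]:
        """Both breakends in canonical order (lower chrom/pos first)."""
        a = (self.chrom1, self.pos1, self.orient1, self.ci1)
        b = (self.chrom2, self.pos2, self.orient2, self.ci2)
        return (a, b) if (a[0], a[1]) <= (b[0], b[1]) else (b, a)


@dataclass
class GeneModel:
    """A gene as a set of 1-based closed exon intervals on one chromosome."""

    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    tx_start: int = 0
    tx_end: int = 0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene} has no exons")
        self.exons = sorted(self.exons)
        if self.tx_start == 0:
            self.tx_start = self.exons[0][0]
        if self.tx_end == 0:
            self.tx_end = self.exons[-1][1]
        for s, e in self.exons:
            if s > e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"exon ({s},{e}) outside transcript span of {self.gene}")


@dataclass
class FamilyCohort:
    """Family structure of the analysis: affected, sequenced samples per family
    plus an unrelated reference arm."""

    families: dict[str, list[str]]
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam, members in self.families.items():
            if len(members) < 2:
                raise ValueError(f"family {fam} has < 2 affected samples")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"samples {sorted(overlap)} appear in multiple families")
            seen |= set(members)
        dup = seen & set(self.reference_samples)
        if dup:
            raise ValueError(f"samples {sorted(dup)} are both familial and reference")

    @property
    def family_samples(self) -> list[str]:
        return [s for members in self.families.values() for s in members]

    @property
    def all_samples(self) -> list[str]:
        return self.family_samples + list(self.reference_samples)


@dataclass
class RawRecord:
    """A minimally parsed, possibly multiallelic VCF-style record.

    ``genotypes`` maps sample id to a tuple of allele indexes (0 = ref,
    k = k-th alt) or ``None`` when uncalled. ``info`` carries per-record
    annotations; values that are per-alt lists are indexed during
    decomposition.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    record_id: str = ""
    quality_pass: bool = True
    genotypes: Mapping[str, Optional[tuple[int, ...]]] = field(default_factory=dict)
    gene: str = ""
    effect: str | list[str] = "other"
    pop_af: float | list[Optional[float]] | None = None
    cadd_phred: float | list[Optional[float]] | None = None
    predictor_calls: Sequence[str] = ()
    in_pon: bool = False


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim an allele pair: shared suffix first, then shared prefix.

    Each step keeps at least one base in both alleles; prefix removal
    advances ``pos``. This is the representation bcftools/vt converge on for
    records that need no reference-guided left shift.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _per_alt(value, k: int, n_alts: int):
    if isinstance(value, (list, tuple)):
        if len(value) != n_alts:
            raise MalformedRecordError(
                f"per-alt annotation of length {len(value)} for {n_alts} alt alleles"
            )
        return value[k]
    return value


def normalize_variant(raw: RawRecord) -> list[AnnotatedVariant]:
    """Decompose a (possibly multiallelic) record into normalized biallelic variants.

    One :class:`AnnotatedVariant` per alt allele; allele pairs are
    parsimony-trimmed and per-sample allele counts recomputed per split
    allele, so total alt dosage is conserved across the split.
    """
    if not raw.alts:
        raise MalformedRecordError(f"record {raw.record_id or raw.pos} has no alt allele")
    n_alts = len(raw.alts)
    out: list[AnnotatedVariant] = []
    for k, alt in enumerate(raw.alts):
        for allele in (raw.ref, alt):
            if not allele or not set(allele) <= _VALID_BASES:
                raise MalformedRecordError(
                    f"malformed allele {allele!r} in record "
                    f"{raw.record_id or f'{raw.chrom}:{raw.pos}'}"
                )
        pos, ref, trimmed_alt = trim_alleles(raw.pos, raw.ref, alt)
        genotypes: dict[str, Optional[int]] = {}
        for sample, gt in raw.genotypes.items():
            if gt is None:
                genotypes[sample] = None
            else:
                genotypes[sample] = sum(a == k + 1 for a in gt)
        out.append(
            AnnotatedVariant(
                chrom=raw.chrom,
                pos=pos,
                ref=ref,
                alt=trimmed_alt,
                gene=raw.gene,
                effect=_per_alt(raw.effect, k, n_alts),
                pop_af=_per_alt(raw.pop_af, k, n_alts),
                cadd_phred=_per_alt(raw.cadd_phred, k, n_alts),
                predictor_calls=pad_predictor_calls(tuple(raw.predictor_calls)),
                in_pon=raw.in_pon,
                quality_pass=raw.quality_pass,
                genotypes=genotypes,
            )
        )
    return out
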