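"""Familial-vs-reference cohort comparison: age summaries, two-sample t-test,
stage proportions, and candidate-variant presence in the reference arm."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .variant_model import AnnotatedVariant

__all__ = [
    "PatientRecord",
    "age_summary",
    "two_sample_t",
    "stage_proportion",
    "stage_beyond_I",
    "reference_presence",
]


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    family: str  # family id or "reference"
    age_at_diagnosis: float
    stage: str = "unknown"  # FIGO-like label, e.g. "IA", "IIB", or "unknown"
    menopausal: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_at_diagnosis <= 0:
            raise ValueError(f"age must be > 0, got {self.age_at_diagnosis}")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def age_summary(records: Sequence[PatientRecord]) -> dict:
    """Mean / median / range of age at diagnosis.

    Median uses the midpoint convention for even n; the rounded mean uses
    round-half-away-from-zero.
    """
    if not records:
        raise ValueError("age_summary needs at least one record")
    ages = np.array([r.age_at_diagnosis for r in records], dtype=float)
    mean = float(ages.mean())
    return {
        "n": len(records),
        "mean": mean,
        "mean_rounded": _round_half_away(mean),
        "median": float(np.median(ages)),
        "min": float(ages.min()),
        "max": float(ages.max()),
    }


def two_sample_t(
    group1: Sequence[float],
    group2: Sequence[float],
    variant: str = "welch",
) -> dict:
    """Two-sided two-sample t-test (Welch by default, Student's selectable).

    Degenerate input (zero variance in both groups) with equal means is
    reported as t = 0, p = 1 and flagged rather than raising.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in {"welch", "student"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        return {
            "t": 0.0 if equal else math.inf,
            "df": float(a.size + b.size - 2),
            "p": 1.0 if equal else 0.0,
            "variant": variant,
            "degenerate": True,
        }
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "variant": variant,
        "degenerate": False,
    }


def stage_beyond_I(record: PatientRecord) -> bool:
    """Metastatic-at-diagnosis predicate: FIGO stage beyond I.

    Unknown stage never satisfies the predicate (but stays in denominators).
    """
    stage = record.stage.strip().upper()
    if not stage or stage == "UNKNOWN":
        return False
    roman = ""
    for ch in stage:
        if ch in "IV":
            roman += ch
        else:
            break
    return roman in {"II", "III", "IV"}


def stage_proportion(
    records: Sequence[PatientRecord],
    predicate: Callable[[PatientRecord], bool] = stage_beyond_I,
) -> float:
    """Fraction of records satisfying the stage predicate; the denominator
    includes unknown-stage records."""
    if not records:
        raise ValueError("stage_proportion needs at least one record")
    return sum(bool(predicate(r)) for r in records) / len(records)


def reference_presence(
    candidates: Sequence[AnnotatedVariant],
    cohort_variants: Mapping[tuple[str, int, str, str], AnnotatedVariant],
    reference_samples: Sequence[str],
) -> dict:
    """Per-candidate reference-carrier counts plus >=1 / >=2 carrier summaries.

    ``cohort_variants`` indexes the multi-sample call set by normalized
    variant key; every reference sample must be present in the genotype
    columns of each matched record.
    """
    counts: dict[str, int] = {}
    for cand in candidates:
        rec = cohort_variants.get(cand.key)
        if rec is None:
            counts[cand.vid] = 0
            continue
        missing = [s for s in reference_samples if s not in rec.genotypes]
        if missing:
            raise KeyError(
                f"reference samples {missing} absent from genotype columns of {cand.vid}"
            )
        counts[cand.vid] = sum(rec.carrier(s) for s in reference_samples)
    return {
        "per_variant": counts,
        "n_ge1": sum(c >= 1 for c in counts.values()),
        "n_ge2": sum(c >= 2 for c in counts.values()),
    }
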