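"""Pedigree-declared kinship and degree-of-relationship classification.

Kinship coefficients are computed with the standard recursive algorithm on an
acyclic pedigree (founders unrelated and non-inbred unless the pedigree links
them); degrees follow the midpoint-in-log2 convention so that exact phi
values map back onto the printed integer degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Optional

__all__ = [
    "Individual",
    "Pedigree",
    "RelationshipDegree",
    "PedigreeCycleError",
    "degree_from_kinship",
    "all_pairwise_degrees",
    "DEGREE_SELF",
    "DEGREE_UNRELATED",
]

DEGREE_SELF = "self/MZ"
DEGREE_UNRELATED = "unrelated"


class PedigreeCycleError(ValueError):
    """An individual is (transitively) its own ancestor."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("pedigree cycle: " + " -> ".join(cycle))


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str]
    mother: Optional[str]
    sex: str = "unknown"  # "male" | "female" | "unknown"
    affected: bool = False
    family: str = ""


@dataclass(frozen=True)
class RelationshipDegree:
    pair: tuple[str, str]
    kinship_phi: float
    degree: str  # "1".."<max>", DEGREE_SELF or DEGREE_UNRELATED


class Pedigree:
    """Individuals with parent links; validates acyclicity on construction."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in self.individuals:
                raise ValueError(f"duplicate individual id {ind.iid}")
            self.individuals[ind.iid] = ind
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    raise ValueError(f"unknown parent id {parent!r} for {ind.iid}")
        self._depth: dict[str, int] = {}
        self._check_acyclic()
        self._kin_cache: dict[tuple[str, str], float] = {}

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self.individuals}

        def visit(start: str) -> None:
            # iterative DFS over parent links with an explicit stack
            stack: list[tuple[str, int]] = [(start, 0)]
            path: list[str] = []
            while stack:
                iid, state = stack.pop()
                if state == 1:
                    color[iid] = BLACK
                    self._depth[iid] = 1 + max(
                        (self._depth[p] for p in self._parents(iid)), default=-1
                    )
                    path.pop()
                    continue
                if color[iid] == BLACK:
                    continue
                if color[iid] == GRAY:
                    cycle = path[path.index(iid):] + [iid]
                    raise PedigreeCycleError(cycle)
                color[iid] = GRAY
                path.append(iid)
                stack.append((iid, 1))
                for p in self._parents(iid):
                    if color[p] != BLACK:
                        stack.append((p, 0))

        for iid in self.individuals:
            if color[iid] == WHITE:
                visit(iid)

    def _parents(self, iid: str) -> list[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.father, ind.mother) if p is not None]

    def is_founder(self, iid: str) -> bool:
        return not self._parents(iid)

    @property
    def founders(self) -> list[str]:
        return [i for i in self.individuals if self.is_founder(i)]

    @property
    def affected(self) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.affected]

    def members_of(self, family: str) -> list[str]:
        return [i for i, ind in self.individuals.items() if ind.family == family]

    def kinship(self, i: str, j: str) -> float:
        """Kinship coefficient phi(i, j).

        phi(i,i) = (1 + phi(father_i, mother_i)) / 2; for distinct i, j the
        deeper individual is expanded through its parents. Founders are
        mutually unrelated and non-inbred.
        """
        for iid in (i, j):
            if iid not in self.individuals:
                raise KeyError(f"unknown individual {iid!r}")
        return self._kin(i, j)

    def _kin(self, i: str, j: str) -> float:
        if i == j:
            ind = self.individuals[i]
            if ind.father is not None and ind.mother is not None:
                return 0.5 * (1.0 + self._kin(*sorted((ind.father, ind.mother))))
            return 0.5
        a, b = sorted((i, j))
        cached = self._kin_cache.get((a, b))
        if cached is not None:
            return cached
        # expand the individual further from the founders; guarantees the
        # other one is never a descendant of it
        lo, hi = (a, b) if self._depth[a] <= self._depth[b] else (b, a)
        parents = self._parents(hi)
        if not parents:
            phi = 0.0
        else:
            phi = sum(self._kin(p, lo) for p in parents) / 2.0
        self._kin_cache[(a, b)] = phi
        return phi


def degree_from_kinship(phi: float, max_degree: int = 9) -> str:
    """Classify a kinship coefficient into a degree label.

    Degree d covers phi in (2**(-d-1.5), 2**(-d-0.5)]; above the first
    boundary is self/MZ, at or below the last is unrelated.
    """
    if not 0.0 <= phi <= 0.5:
        raise ValueError(f"phi must be in [0, 0.5], got {phi}")
    if phi > 2.0 ** (-1.5):
        return DEGREE_SELF
    for d in range(1, max_degree + 1):
        if phi > 2.0 ** (-d - 1.5):
            return str(d)
    return DEGREE_UNRELATED


def degree_as_int(label: str, max_degree: int = 9) -> int:
    """Numeric degree for tolerance arithmetic: self/MZ = 0, unrelated = max+1."""
    if label == DEGREE_SELF:
        return 0
    if label == DEGREE_UNRELATED:
        return max_degree + 1
    return int(label)


def all_pairwise_degrees(
    ped: Pedigree,
    samples: Optional[list[str]] = None,
    max_degree: int = 9,
) -> list[RelationshipDegree]:
    """Kinship and degree for every unordered pair of the given samples.

    Pairs whose members belong to different declared families are unrelated
    by construction and are not expanded through the recursion.
    """
    ids = list(samples) if samples is not None else list(ped.individuals)
    out: list[RelationshipDegree] = []
    for i, j in combinations(ids, 2):
        fam_i = ped.individuals[i].family
        fam_j = ped.individuals[j].family
        if fam_i and fam_j and fam_i != fam_j:
            phi = 0.0
        else:
            phi = ped.kinship(i, j)
        out.append(
            RelationshipDegree(
                pair=tuple(sorted((i, j))),
                kinship_phi=phi,
                degree=degree_from_kinship(phi, max_degree=max_degree),
            )
        )
    return out
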