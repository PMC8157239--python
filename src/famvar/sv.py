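"""Structural-variant prioritization: catalogue removal, cross-sample
breakpoint-overlap grouping, family-sharing filter, gene annotation, and
cross-family gene recurrence."""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median_low
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .variant_model import BreakendPair, FamilyCohort, GeneModel

__all__ = [
    "SVGroup",
    "breakends_overlap",
    "group_svs",
    "filter_sv_catalogue",
    "family_shared_groups",
    "genes_in_sv",
    "sv_recurrent_genes",
    "chrom_dosage_check",
]


@dataclass
class SVGroup:
    """A connected component of the breakpoint-overlap graph."""

    group_id: str
    members: list[tuple[str, str]]  # (sample, sv_id), sorted
    svs: list[BreakendPair]
    sv_type: str
    consensus: tuple[tuple[str, int, str], tuple[str, int, str]]
    families: frozenset[str] = frozenset()  # set by family_shared_groups

    @property
    def samples(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.members)


def breakends_overlap(a: BreakendPair, b: BreakendPair, max_gap: int = 100) -> bool:
    """True iff two SVs share both breakpoints.

    Requires identical sv_type, and per canonically ordered breakend slot:
    same chromosome, same orientation, and intersecting CI-expanded windows
    [pos + ci_low - max_gap, pos + ci_high + max_gap].
    """
    if a.sv_type != b.sv_type:
        return False
    for (ca, pa, oa, cia), (cb, pb, ob, cib) in zip(a.breakends(), b.breakends()):
        if ca != cb or oa != ob:
            return False
        lo_a, hi_a = pa + cia[0] - max_gap, pa + cia[1] + max_gap
        lo_b, hi_b = pb + cib[0] - max_gap, pb + cib[1] + max_gap
        if hi_a < lo_b or hi_b < lo_a:
            return False
    return True


def _consensus(svs: Sequence[BreakendPair]):
    ends1 = [sv.breakends()[0] for sv in svs]
    ends2 = [sv.breakends()[1] for sv in svs]
    out = []
    for ends in (ends1, ends2):
        chrom = ends[0][0]
        orient = ends[0][2]
        pos = median_low([p for _, p, _, _ in ends])
        out.append((chrom, pos, orient))
    return tuple(out)


def group_svs(svs: Sequence[BreakendPair], max_gap: int = 100) -> list[SVGroup]:
    """Partition SVs into connected components under the overlap relation.

    Transitive: a chain a~b, b~c groups all three even when a and c do not
    overlap directly. Group ids are derived from sorted member lists, so the
    partition and the ids are invariant under input permutation.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(svs)))
    # bucket by (type, chrom of first canonical breakend) to prune comparisons
    buckets: dict[tuple[str, str], list[int]] = {}
    for idx, sv in enumerate(svs):
        buckets.setdefault((sv.sv_type, sv.breakends()[0][0]), []).append(idx)
    for bucket in buckets.values():
        for i_pos, i in enumerate(bucket):
            for j in bucket[i_pos + 1:]:
                if breakends_overlap(svs[i], svs[j], max_gap):
                    graph.add_edge(i, j)
    groups: list[SVGroup] = []
    for comp in nx.connected_components(graph):
        comp_svs = [svs[i] for i in comp]
        members = sorted((sv.sample, sv.sv_id) for sv in comp_svs)
        comp_svs.sort(key=lambda sv: (sv.sample, sv.sv_id))
        groups.append(
            SVGroup(
                group_id="",
                members=members,
                svs=comp_svs,
                sv_type=comp_svs[0].sv_type,
                consensus=_consensus(comp_svs),
            )
        )
    groups.sort(key=lambda g: g.members)
    for k, g in enumerate(groups):
        g.group_id = f"SVG{k:04d}"
    return groups


def filter_sv_catalogue(
    svs: Sequence[BreakendPair],
    catalogue: Sequence[BreakendPair],
    max_gap: int = 100,
) -> list[BreakendPair]:
    """Drop SVs flagged as catalogue members or overlapping a catalogue entry."""
    out = []
    for sv in svs:
        if sv.in_catalogue:
            continue
        if any(breakends_overlap(sv, cat, max_gap) for cat in catalogue):
            continue
        out.append(sv)
    return out


def family_shared_groups(
    groups: Sequence[SVGroup], cohort: FamilyCohort
) -> list[SVGroup]:
    """Keep groups carried by every affected member of at least one family.

    A family counts toward a group only when ALL its affected, sequenced
    samples contribute an SV to it; the carrying families are recorded on
    the surviving groups.
    """
    kept = []
    for g in groups:
        fams = frozenset(
            fam
            for fam, members in cohort.families.items()
            if set(members) <= g.samples
        )
        if fams:
            g.families = fams
            kept.append(g)
    return kept


def genes_in_sv(
    group: SVGroup, gene_models: Sequence[GeneModel], bnd_flank: int = 1000
) -> frozenset[str]:
    """Genes inside the SV region of a group (via its consensus breakends).

    Intrachromosomal DEL/DUP/INV/INS: genes whose transcript span intersects
    [pos1, pos2]. BND: genes intersecting either breakend +/- ``bnd_flank``.
    """
    (c1, p1, _), (c2, p2, _) = group.consensus
    genes = set()
    if group.sv_type != "BND" and c1 == c2:
        lo, hi = min(p1, p2), max(p1, p2)
        for gm in gene_models:
            if gm.chrom == c1 and gm.tx_start <= hi and gm.tx_end >= lo:
                genes.add(gm.gene)
    else:
        for chrom, pos in ((c1, p1), (c2, p2)):
            lo, hi = pos - bnd_flank, pos + bnd_flank
            for gm in gene_models:
                if gm.chrom == chrom and gm.tx_start <= hi and gm.tx_end >= lo:
                    genes.add(gm.gene)
    return frozenset(genes)


def sv_recurrent_genes(
    family_groups: Sequence[SVGroup],
    gene_models: Sequence[GeneModel],
    bnd_flank: int = 1000,
    min_families: int = 2,
) -> dict[str, frozenset[str]]:
    """Genes affected by family-shared SV groups in >= ``min_families`` families."""
    gene_fams: dict[str, set[str]] = {}
    for g in family_groups:
        for gene in genes_in_sv(g, gene_models, bnd_flank):
            gene_fams.setdefault(gene, set()).update(g.families)
    return {
        gene: frozenset(fams)
        for gene, fams in gene_fams.items()
        if len(fams) >= min_families
    }


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def chrom_dosage_check(
    family_groups: Sequence[SVGroup],
    dup_chrom: str = "14",
    del_chrom: str = "22",
) -> list[dict]:
    """Flag family-shared duplications on one chromosome and losses on another
    (defaults: chr14 gains, chr22 losses), reporting the families per flag
    and whether multiple families are affected."""
    flags = []
    for g in family_groups:
        chrom = _strip_chr(g.consensus[0][0])
        if (g.sv_type == "DUP" and chrom == _strip_chr(dup_chrom)) or (
            g.sv_type == "DEL" and chrom == _strip_chr(del_chrom)
        ):
            flags.append(
                {
                    "group_id": g.group_id,
                    "sv_type": g.sv_type,
                    "chrom": g.consensus[0][0],
                    "families": sorted(g.families),
                    "multiple_families": len(g.families) >= 2,
                }
            )
    return flags
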