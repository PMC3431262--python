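"""Family clustering of mature miRNAs and novelty against a known reference.

Homologous matures (at most 2 mismatches under an ungapped overlap
alignment) are joined by single linkage into family clusters. Clusters
inherit the family name of the closest known mature within the mismatch
budget; the rest are labelled fam-NNN in discovery order. Per-locus
novelty: `known-locus` when the genomic interval overlaps a known locus,
`new-homolog` when only the mature matches a known family, else `novel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import PipelineConfig
from .hairpin import MiRNALocus
from .io import normalize_seq

logger = logging.getLogger(__name__)


@dataclass
class FamilyAssignment:
    clusters: dict[str, list[str]]  # cluster/family name -> member matures
    family_of: dict[str, str]  # mature sequence -> family name
    novelty: dict[str, str] = field(default_factory=dict)  # locus name -> class


def mature_distance(a: str, b: str, max_shift: int | None = None) -> int:
    """Mismatch count of the best ungapped overlap alignment of two matures.

    Minimum over relative offsets with overlap >= min(len a, len b) - 2 of
    substitutions within the overlap plus the unaligned positions of the
    shorter sequence.
    """
    a, b = normalize_seq(a), normalize_seq(b)
    la, lb = len(a), len(b)
    short = min(la, lb)
    min_overlap = max(1, short - 2)
    best = short  # aligning nothing would cost every position of the shorter
    for off in range(-(la - min_overlap), lb - min_overlap + 1):
        # a[i] faces b[i + off]
        lo = max(0, -off)
        hi = min(la, lb - off)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        subs = sum(a[i] != b[i + off] for i in range(lo, hi))
        dist = subs + (short - overlap)
        best = min(best, dist)
    return best


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_families(matures: list[str],
                     config: PipelineConfig | None = None) -> list[list[str]]:
    """Single-linkage clusters: connected components of the <=2-mismatch graph.

    Order-invariant: members and clusters are returned deterministically
    sorted.
    """
    cfg = config or PipelineConfig()
    seqs = sorted({normalize_seq(m) for m in matures})
    uf = _UnionFind(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if mature_distance(seqs[i], seqs[j]) <= cfg.family_mismatch_max:
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(uf.find(i), []).append(s)
    return sorted(groups.values(), key=lambda g: g[0])


def assign_families(loci: list[MiRNALocus],
                    known_matures: dict[str, str] | None = None,
                    known_loci: list[tuple[str, int, int, str, str]] | None = None,
                    config: PipelineConfig | None = None,
                    new_family_prefix: str = "fam-") -> FamilyAssignment:
    """Cluster predicted matures, name families, and classify locus novelty.

    ``known_matures`` maps family name -> mature sequence (several entries
    may share a family via "name|member" ids); ``known_loci`` are
    (chrom, start, end, strand, family) intervals, 0-based half-open.
    """
    cfg = config or PipelineConfig()
    known_matures = known_matures or {}
    known_loci = known_loci or []
    known = [(fam.split("|")[0], normalize_seq(seq))
             for fam, seq in known_matures.items()]

    clusters = cluster_families([l.mature for l in loci], cfg)
    family_of: dict[str, str] = {}
    named: dict[str, list[str]] = {}
    next_new = 1
    for members in clusters:
        best: tuple[int, str] | None = None
        hits = set()
        for fam, kseq in known:
            d = min(mature_distance(m, kseq) for m in members)
            if d <= cfg.family_mismatch_max:
                hits.add(fam)
                if best is None or d < best[0]:
                    best = (d, fam)
        if best is not None:
            if len(hits) > 1:
                logger.info("cluster %s matches several known families %s; "
                            "keeping the closest (%s)", members[0], sorted(hits),
                            best[1])
            name = best[1]
        else:
            name = f"{new_family_prefix}{next_new:03d}"
            next_new += 1
        named.setdefault(name, []).extend(members)
        for m in members:
            family_of[m] = name

    novelty: dict[str, str] = {}
    known_families = {fam for fam, _ in known}
    for loc in loci:
        fam = family_of[loc.mature]
        loc.family = fam
        overlaps = any(
            c == loc.chrom and s < loc.end and loc.start < e and st == loc.strand
            for (c, s, e, st, _f) in known_loci)
        if overlaps:
            loc.novelty = "known-locus"
        elif fam in known_families:
            loc.novelty = "new-homolog"
        else:
            loc.novelty = "novel"
        novelty[loc.name] = loc.novelty
    return FamilyAssignment(clusters=named, family_of=family_of, novelty=novelty)
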