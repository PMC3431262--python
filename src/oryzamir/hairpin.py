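"""De-novo miRNA locus prediction from anchored genomic segments.

Reads mapped with a pooled count of at least 10 seed ("anchor") candidate
precursors: around every genomic hit, segments of 100-300 nt (20 nt step)
are extracted with one end 20 nt away from the anchor on either side,
folded to their minimum-free-energy structure, and kept when all five
annotation criteria hold:

1. folding free energy at most -35 kcal/mol;
2. at most 4 mismatches between the putative miRNA and miRNA*;
3. at most one asymmetric bulge in the duplex, of size at most 2 nt;
4. strand bias: sense:antisense mapped-read counts at least 5:1;
5. precise cleavage: reads in the miRNA/miRNA* regions (each extended by
   2 nt on both ends) carry at least 75% of the counts on the segment.

When several overlapping segments qualify, the one with the highest
putative-miRNA count, then lowest free energy, then shortest length is
chosen; the mature is the most abundant read on the precursor that sits in
a duplex satisfying criteria 2-3 (falling back past reads, e.g. abundant
loop fragments, that do not).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import RNA

from .config import PipelineConfig
from .genome_map import GenomicHit
from .preprocess import UniqueRead
from .simulate import revcomp

logger = logging.getLogger(__name__)


@dataclass
class Duplex:
    mirna_region: tuple[int, int]  # segment coordinates, half-open
    star_region: tuple[int, int]
    mismatches: int
    bulge_count: int
    max_bulge_size: int


@dataclass
class HairpinCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # transcribed orientation (reverse-complemented for '-')
    structure: str
    mfe: float
    anchor: UniqueRead
    anchor_hit: GenomicHit
    duplex: Duplex | None = None
    strand_ratio: float = math.nan
    cleavage_fraction: float = math.nan
    mature_count: int = 0
    sense_count: int = 0
    antisense_count: int = 0
    verdict: dict[str, bool] = field(default_factory=dict)
    fail_reason: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def valid(self) -> bool:
        return bool(self.verdict) and all(self.verdict.values())

    def to_segment(self, gstart: int, gend: int) -> tuple[int, int]:
        """Genomic half-open interval -> segment coordinates."""
        if self.strand == "+":
            return gstart - self.start, gend - self.start
        return self.end - gend, self.end - gstart

    def to_genomic(self, slo: int, shi: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.start + slo, self.start + shi
        return self.end - shi, self.end - slo


@dataclass
class MiRNALocus:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    precursor: str
    structure: str
    mfe: float
    mature: str
    star: str
    mature_start: int  # genomic
    mature_end: int
    counts: dict[str, int]
    candidate: HairpinCandidate
    family: str = ""
    novelty: str = "novel"
    biogenesis_class: str = "unvalidated"
    te_class: str | None = None


class ReadIndex:
    """Genomic hits of unique reads, queryable by containing interval."""

    def __init__(self, reads: list[UniqueRead], hits: dict[str, list[GenomicHit]]):
        by_chrom: dict[str, list[tuple[int, int, str, int, UniqueRead]]] = {}
        for read in reads:
            for h in hits.get(read.sequence, ()):
                by_chrom.setdefault(h.chrom, []).append(
                    (h.start, h.end, h.strand, read.total_count, read))
        self._data = {}
        for chrom, rows in by_chrom.items():
            rows.sort(key=lambda r: (r[0], r[1], r[2]))
            self._data[chrom] = (
                np.array([r[0] for r in rows]),
                np.array([r[1] for r in rows]),
                np.array([1 if r[2] == "+" else -1 for r in rows]),
                np.array([r[3] for r in rows]),
                [r[4] for r in rows],
            )

    def query(self, chrom: str, start: int, end: int
              ) -> list[tuple[int, int, str, int, UniqueRead]]:
        """Hits whose footprint lies entirely inside [start, end)."""
        if chrom not in self._data:
            return []
        starts, ends, strands, counts, reads = self._data[chrom]
        idx = np.nonzero((starts >= start) & (ends <= end))[0]
        return [(int(starts[i]), int(ends[i]), "+" if strands[i] > 0 else "-",
                 int(counts[i]), reads[i]) for i in idx]


def select_anchors(reads: list[UniqueRead], hits: dict[str, list[GenomicHit]],
                   config: PipelineConfig | None = None,
                   ) -> list[tuple[UniqueRead, GenomicHit]]:
    """Reads with pooled count >= anchor_min_count, one instance per hit."""
    cfg = config or PipelineConfig()
    anchors = []
    for read in reads:
        if cfg.anchor_count_per_library:
            qualifies = any(c >= cfg.anchor_min_count for c in read.counts.values())
        else:
            qualifies = read.total_count >= cfg.anchor_min_count
        if not qualifies:
            continue
        for h in hits.get(read.sequence, ()):
            anchors.append((read, h))
    return anchors


def enumerate_segments(hit: GenomicHit, chrom_length: int,
                       config: PipelineConfig | None = None
                       ) -> list[tuple[int, int]]:
    """Candidate intervals around one anchor hit (0-based half-open).

    For each side, the segment's near end sits 20 nt beyond the anchor and
    the segment extends across the anchor for 100..300 nt in 20 nt steps;
    segments clipped below 100 nt by a contig end are discarded.
    """
    cfg = config or PipelineConfig()
    lengths = range(cfg.segment_min_length, cfg.segment_max_length + 1,
                    cfg.segment_step)
    segments = []
    for L in lengths:
        left = hit.start - cfg.segment_offset
        if left >= 0 and left + L <= chrom_length and left + L >= hit.end:
            segments.append((left, left + L))
        right = hit.end + cfg.segment_offset
        if right <= chrom_length and right - L >= 0 and right - L <= hit.start:
            segments.append((right - L, right))
    if not segments:
        logger.info("anchor at %s:%d within 20 nt of both contig ends; no segments",
                    hit.chrom, hit.start)
    return sorted(set(segments))


_fold_cache: dict[str, tuple[str, float]] = {}


def fold(sequence: str) -> tuple[str, float]:
    """MFE secondary structure (dot-bracket) and free energy in kcal/mol."""
    cached = _fold_cache.get(sequence)
    if cached is None:
        structure, mfe = RNA.fold(sequence.replace("T", "U"))
        cached = _fold_cache[sequence] = (structure, round(float(mfe), 2))
    return cached


def _partner_table(structure: str) -> list[int]:
    pt = RNA.ptable(structure)
    return [pt[i + 1] - 1 for i in range(len(structure))]


def locate_duplex(structure: str, mature_region: tuple[int, int],
                  partner: list[int] | None = None) -> Duplex | None:
    """miRNA*/duplex statistics for a mature footprint on a folded segment.

    The star region spans the partners of the mature's first and last paired
    bases, shifted by 2 nt to produce the canonical 2-nt 3' overhangs.
    Symmetric internal loops count as mismatches; asymmetric unpaired runs
    count as bulges. Returns None when the mature region is entirely
    unpaired (criterion 2 then fails).
    """
    a0, a1 = mature_region
    if partner is None:
        partner = _partner_table(structure)
    n = len(partner)
    a0, a1 = max(0, a0), min(n, a1)
    paired = [p for p in range(a0, a1)
              if partner[p] >= 0 and not a0 <= partner[p] < a1]
    if not paired:
        return None
    partners = [partner[p] for p in paired]
    j_lo, j_hi = min(partners), max(partners)
    star = (min(n, j_lo + 2), min(n, j_hi + 3))

    mismatches = (paired[0] - a0) + (a1 - 1 - paired[-1])
    bulges: list[int] = []
    for (p1, p2) in zip(paired, paired[1:]):
        q1, q2 = partner[p1], partner[p2]
        gap_m = p2 - p1 - 1
        gap_s = q1 - q2 - 1
        if gap_s < 0:  # crossing partners (multiloop); treat run as mismatches
            mismatches += gap_m
            continue
        mismatches += min(gap_m, gap_s)
        if gap_m != gap_s:
            bulges.append(abs(gap_m - gap_s))
    return Duplex(mirna_region=(a0, a1), star_region=star, mismatches=mismatches,
                  bulge_count=len(bulges), max_bulge_size=max(bulges, default=0))


def has_inverted_repeat_partner(sequence: str, mature_region: tuple[int, int]
                                ) -> bool:
    """Cheap screen: can the mature footprint possibly have a miRNA* partner?

    A duplex passing criterion 2 (<= 4 mismatches, G:U pairs allowed) implies
    a near-reverse-complement of the mature elsewhere in the segment; require
    a window within len/3 mismatches of the exact reverse complement before
    spending a thermodynamic fold on the segment. Segments whose anchor lies
    in single-stranded sequence (loop fragments, contamination) are skipped.
    """
    a0, a1 = mature_region
    anchor = sequence[a0:a1]
    rc = revcomp(anchor)
    L = len(rc)
    if len(sequence) < 2 * L:
        return False
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    rcv = np.frombuffer(rc.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    mm = (windows != rcv).sum(axis=1)
    # the partner must lie outside the mature footprint itself
    lo = max(0, a0 - L + 1)
    mm[lo:a1] = L
    return int(mm.min()) <= L // 3


def evaluate_criteria(cand: HairpinCandidate, index: ReadIndex,
                      config: PipelineConfig | None = None,
                      rows: list | None = None) -> HairpinCandidate:
    """Fill in read-based statistics and the five-criterion verdict."""
    cfg = config or PipelineConfig()
    verdict = {"mfe": cand.mfe <= cfg.mfe_max}

    if cand.duplex is None:
        verdict["duplex_mismatch"] = False
        verdict["bulge"] = False
        cand.fail_reason = cand.fail_reason or "mature region unpaired"
    else:
        verdict["duplex_mismatch"] = cand.duplex.mismatches <= cfg.duplex_mismatch_max
        verdict["bulge"] = (cand.duplex.bulge_count <= cfg.bulge_max_count
                            and cand.duplex.max_bulge_size <= cfg.bulge_max_size)

    if rows is None:
        rows = index.query(cand.chrom, cand.start, cand.end)
    sense = sum(c for (_, _, s, c, _) in rows if s == cand.strand)
    anti = sum(c for (_, _, s, c, _) in rows if s != cand.strand)
    cand.sense_count, cand.antisense_count = sense, anti
    if sense == 0:
        verdict["strand_bias"] = False
        verdict["cleavage"] = False
        cand.fail_reason = cand.fail_reason or "no sense reads on segment"
        cand.verdict = verdict
        return cand

    cand.strand_ratio = math.inf if anti == 0 else sense / anti
    verdict["strand_bias"] = cand.strand_ratio >= cfg.strand_ratio_min

    if cand.duplex is not None:
        pad = cfg.cleavage_window_pad
        windows = []
        for lo, hi in (cand.duplex.mirna_region, cand.duplex.star_region):
            glo, ghi = cand.to_genomic(lo, hi)
            windows.append((glo - pad, ghi + pad))
        precise = 0
        mature_w = windows[0]
        mcount = 0
        for (s, e, strand, c, _read) in rows:
            if strand != cand.strand:
                continue
            if any(s >= wlo and e <= whi for wlo, whi in windows):
                precise += c
            if s >= mature_w[0] and e <= mature_w[1]:
                mcount += c
        cand.cleavage_fraction = precise / sense
        cand.mature_count = mcount
        verdict["cleavage"] = cand.cleavage_fraction >= cfg.cleavage_fraction_min
    else:
        verdict["cleavage"] = False
    cand.verdict = verdict
    return cand


def build_candidate(anchor: UniqueRead, hit: GenomicHit, start: int, end: int,
                    genome: dict[str, str]) -> HairpinCandidate | None:
    gseq = genome[hit.chrom][start:end]
    seq = gseq if hit.strand == "+" else revcomp(gseq)
    try:
        structure, mfe = fold(seq)
    except Exception:  # pragma: no cover - folding engine failure
        logger.warning("folding failed for segment %s:%d-%d", hit.chrom, start, end)
        return None
    cand = HairpinCandidate(chrom=hit.chrom, start=start, end=end,
                            strand=hit.strand, sequence=seq, structure=structure,
                            mfe=mfe, anchor=anchor, anchor_hit=hit)
    mat = cand.to_segment(hit.start, hit.end)
    cand.duplex = locate_duplex(structure, mat)
    return cand


def select_precursor(candidates: list[HairpinCandidate]) -> HairpinCandidate:
    """Lexicographic choice: max miRNA count, min mfe, min length, leftmost."""
    return min(candidates,
               key=lambda c: (-c.mature_count, c.mfe, c.length, c.start))


def choose_mature(cand: HairpinCandidate, index: ReadIndex,
                  config: PipelineConfig | None = None
                  ) -> tuple[UniqueRead, Duplex] | None:
    """Most abundant precursor read residing in a criteria-2/3 duplex.

    Ties in abundance break to the lexicographically smallest sequence.
    Returns None when no mapped read passes the structural requirement.
    """
    cfg = config or PipelineConfig()
    partner = _partner_table(cand.structure)
    rows = [r for r in index.query(cand.chrom, cand.start, cand.end)
            if r[2] == cand.strand]
    seen: dict[str, tuple[int, int, int]] = {}
    for (s, e, _, c, read) in rows:
        if read.sequence not in seen:
            seen[read.sequence] = (c, s, e)
    ranked = sorted(seen.items(), key=lambda kv: (-kv[1][0], kv[0]))
    for seq, (c, s, e) in ranked:
        dup = locate_duplex(cand.structure, cand.to_segment(s, e), partner)
        if dup is None:
            continue
        if (dup.mismatches <= cfg.duplex_mismatch_max
                and dup.bulge_count <= cfg.bulge_max_count
                and dup.max_bulge_size <= cfg.bulge_max_size):
            read = next(r for (_, _, _, _, r) in rows if r.sequence == seq)
            return read, dup
    return None


def _merge_groups(cands: list[HairpinCandidate]) -> list[list[HairpinCandidate]]:
    """Group valid candidates whose intervals overlap on the same strand."""
    groups: list[list[HairpinCandidate]] = []
    for key in sorted({(c.chrom, c.strand) for c in cands}):
        subset = sorted((c for c in cands if (c.chrom, c.strand) == key),
                        key=lambda c: (c.start, c.end))
        current: list[HairpinCandidate] = []
        reach = -1
        for c in subset:
            if current and c.start >= reach:
                groups.append(current)
                current = []
            current.append(c)
            reach = max(reach, c.end)
        if current:
            groups.append(current)
    return groups


def predict_loci(reads: list[UniqueRead], hits: dict[str, list[GenomicHit]],
                 genome: dict[str, str], config: PipelineConfig | None = None,
                 anchors: list[tuple[UniqueRead, GenomicHit]] | None = None,
                 eval_reads: list[UniqueRead] | None = None,
                 name_prefix: str = "mir",
                 ) -> tuple[list[MiRNALocus], list[HairpinCandidate]]:
    """Full prediction pass; returns accepted loci and all evaluated candidates.

    Anchors come from ``reads`` (the filtered read set), but the strand-bias
    and precise-cleavage criteria are judged against ``eval_reads`` - every
    mapped unique read, including reads the repeat/copy-number filters
    excluded from anchoring - so a segment cannot pass merely because its
    sense reads were filtered away.
    """
    cfg = config or PipelineConfig()
    if anchors is None:
        anchors = select_anchors(reads, hits, cfg)
    index = ReadIndex(eval_reads if eval_reads is not None else reads, hits)

    # group anchor footprints by segment so each segment is folded and its
    # reads queried once, however many anchors fall inside it
    by_segment: dict[tuple, list[tuple[UniqueRead, GenomicHit]]] = {}
    for read, hit in anchors:
        for (s, e) in enumerate_segments(hit, len(genome[hit.chrom]), cfg):
            by_segment.setdefault((hit.chrom, s, e, hit.strand), []).append(
                (read, hit))

    candidates: list[HairpinCandidate] = []
    for (chrom, s, e, strand), members in sorted(
            by_segment.items(), key=lambda kv: kv[0]):
        gseq = genome[chrom][s:e]
        seq = gseq if strand == "+" else revcomp(gseq)
        seen_fp: set[tuple[int, int]] = set()
        folded: tuple[str, float] | None = None
        rows: list | None = None
        for read, hit in members:
            if (hit.start, hit.end) in seen_fp:
                continue
            seen_fp.add((hit.start, hit.end))
            mat = (e - hit.end, e - hit.start) if strand == "-" \
                else (hit.start - s, hit.end - s)
            if not has_inverted_repeat_partner(seq, mat):
                continue
            if folded is None:
                try:
                    folded = fold(seq)
                except Exception:  # pragma: no cover - engine failure
                    logger.warning("folding failed for %s:%d-%d", chrom, s, e)
                    break
            structure, mfe = folded
            cand = HairpinCandidate(chrom=chrom, start=s, end=e, strand=strand,
                                    sequence=seq, structure=structure, mfe=mfe,
                                    anchor=read, anchor_hit=hit)
            cand.duplex = locate_duplex(structure, mat)
            if rows is None:
                rows = index.query(chrom, s, e)
            evaluate_criteria(cand, index, cfg, rows=rows)
            candidates.append(cand)

    valid = [c for c in candidates if c.valid]
    loci: list[MiRNALocus] = []
    for group in _merge_groups(valid):
        chosen = select_precursor(group)
        picked = choose_mature(chosen, index, cfg)
        if picked is None:
            logger.info("locus at %s:%d dropped: no read passes the duplex "
                        "requirement", chosen.chrom, chosen.start)
            continue
        mature_read, dup = picked
        star_lo, star_hi = dup.star_region
        star = chosen.sequence[star_lo:star_hi]
        m_glo, m_ghi = chosen.to_genomic(*dup.mirna_region)
        loci.append(MiRNALocus(
            name="", chrom=chosen.chrom, start=chosen.start, end=chosen.end,
            strand=chosen.strand, precursor=chosen.sequence,
            structure=chosen.structure, mfe=chosen.mfe,
            mature=mature_read.sequence, star=star,
            mature_start=m_glo, mature_end=m_ghi,
            counts=dict(mature_read.counts), candidate=chosen))
    loci.sort(key=lambda l: (l.chrom, l.start))
    for i, loc in enumerate(loci, start=1):
        loc.name = f"{name_prefix}{i:04d}"
    return loci, candidates
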