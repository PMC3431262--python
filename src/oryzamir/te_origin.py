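"""Transposon/repeat-derived miRNA discovery (relaxed-anchor second pass).

The first prediction pass deliberately discards reads matching annotated
repeats or mapping to more than 20 genomic positions; MITEs and other
inverted repeats can nevertheless fold into genuine miRNA precursors.
This pass re-admits exactly those excluded reads (still requiring the
anchor count of 10) and reruns the unchanged five-criterion hairpin
prediction on them, then attributes each accepted precursor to the repeat
class with the greatest genomic overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .genome_map import GenomicHit, copy_number
from .hairpin import MiRNALocus, predict_loci, select_anchors
from .io import normalize_seq
from .preprocess import UniqueRead
from .simulate import revcomp


@dataclass
class RepeatMatch:
    read: str
    repeat_id: str
    repeat_class: str
    alignment_length: int
    identity: float


def _repeat_class(repeat_id: str) -> str:
    if "class=" in repeat_id:
        return repeat_id.split("class=")[1].split("|")[0]
    return "unclassified"


def _best_diagonal_match(read: str, repeat: str, min_len: int,
                         min_identity: float) -> tuple[int, float] | None:
    """Best ungapped local alignment over all diagonals meeting both
    thresholds.

    The local alignment on each diagonal is the maximum-scoring segment
    under +1 match / -1 mismatch (so a run of exact matches does not extend
    through flanking mismatches unless later matches pay for them).
    Returns (alignment length, identity over the alignment). Exhaustive,
    intended for desk-scale repeat libraries.
    """
    n, m = len(read), len(repeat)
    best: tuple[float, int] | None = None  # (identity, length)
    for off in range(-(n - 1), m):
        lo = max(0, -off)
        hi = min(n, m - off)
        if hi - lo < min_len:
            continue
        matches = np.frombuffer(read[lo:hi].encode(), dtype=np.uint8) == \
            np.frombuffer(repeat[lo + off:hi + off].encode(), dtype=np.uint8)
        score = np.where(matches, 1, -1)
        # Kadane with segment tracking
        run = run_start = 0
        seg = (0, -1, -(10 ** 9))  # start, end, score
        for i, s in enumerate(score):
            if run <= 0:
                run, run_start = 0, i
            run += s
            if run > seg[2]:
                seg = (run_start, i, run)
        a, b, _ = seg
        length = b - a + 1
        if length < min_len:
            continue
        ident = float(matches[a:b + 1].sum()) / length
        if ident < min_identity:
            continue
        cand = (ident, length)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    return best[1], best[0]


def match_repeats(read: str, repeat_library: dict[str, str],
                  config: PipelineConfig | None = None) -> RepeatMatch | None:
    """Best repeat-library hit with alignment length >= 80% of the read and
    identity >= 80%; None when nothing qualifies (or the library is empty)."""
    cfg = config or PipelineConfig()
    seq = normalize_seq(read)
    min_len = int(np.ceil(cfg.repeat_len_frac * len(seq)))
    best: RepeatMatch | None = None
    for rid, rseq in repeat_library.items():
        rseq = normalize_seq(rseq)
        for oriented in (seq, revcomp(seq)):
            hit = _best_diagonal_match(oriented, rseq, min_len, cfg.repeat_identity)
            if hit is None:
                continue
            length, ident = hit
            cand = RepeatMatch(read=seq, repeat_id=rid,
                               repeat_class=_repeat_class(rid),
                               alignment_length=length, identity=ident)
            if best is None or (cand.identity, cand.alignment_length) > \
                    (best.identity, best.alignment_length):
                best = cand
    return best


def relaxed_anchor_set(annotation_removed: list[UniqueRead],
                       copy_removed: list[UniqueRead],
                       hits: dict[str, list[GenomicHit]],
                       repeat_library: dict[str, str] | None = None,
                       genome: dict[str, str] | None = None,
                       config: PipelineConfig | None = None,
                       ) -> list[tuple[UniqueRead, GenomicHit]]:
    """Anchors for the relaxed pass: reads the first pass excluded.

    Reads removed by the repeat annotation filter (confirmed against the
    repeat library when one is given) or by the copy-number filter, with
    pooled count >= 10 and at least one perfect genomic hit.
    """
    cfg = config or PipelineConfig()
    pool: list[UniqueRead] = []
    for read in annotation_removed:
        if read.annotation != "repeat":
            continue
        if repeat_library:
            if match_repeats(read.sequence, repeat_library, cfg) is None:
                continue
        pool.append(read)
    pool.extend(copy_removed)
    if genome is not None:
        pool.extend(
            r for r in annotation_removed
            if r.annotation != "repeat" and r not in pool
            and copy_number(r.sequence, genome, cfg.copy_number_mismatches)
            > cfg.max_copy_number)
    return select_anchors(pool, hits, cfg)


def classify_te_origin(locus: MiRNALocus,
                       repeat_annotations: list[tuple[str, int, int, str]],
                       ) -> str:
    """Repeat class with the greatest overlap with the precursor.

    Ties break to the alphabetically first class; no overlapping
    annotation gives "unclassified".
    """
    overlaps: dict[str, int] = {}
    for (chrom, start, end, cls) in repeat_annotations:
        if chrom != locus.chrom:
            continue
        ov = min(end, locus.end) - max(start, locus.start)
        if ov > 0:
            overlaps[cls] = max(overlaps.get(cls, 0), ov)
    if not overlaps:
        return "unclassified"
    return min(overlaps, key=lambda c: (-overlaps[c], c))


def predict_te_loci(annotation_removed: list[UniqueRead],
                    copy_removed: list[UniqueRead],
                    hits: dict[str, list[GenomicHit]],
                    genome: dict[str, str],
                    repeat_annotations: list[tuple[str, int, int, str]],
                    repeat_library: dict[str, str] | None = None,
                    first_pass_loci: list[MiRNALocus] | None = None,
                    eval_reads: list[UniqueRead] | None = None,
                    config: PipelineConfig | None = None,
                    ) -> list[MiRNALocus]:
    """Relaxed-anchor prediction; returns TE/repeat-derived loci only.

    All five annotation criteria still apply. Loci overlapping a
    first-pass locus are dropped so the two locus sets stay disjoint.
    """
    cfg = config or PipelineConfig()
    anchors = relaxed_anchor_set(annotation_removed, copy_removed, hits,
                                 repeat_library, genome, cfg)
    reads = sorted({id(r): r for r, _ in anchors}.values(),
                   key=lambda r: r.sequence)
    loci, _ = predict_loci(reads, hits, genome, cfg, anchors=anchors,
                           eval_reads=eval_reads, name_prefix="te-mir")
    if first_pass_loci:
        loci = [l for l in loci
                if not any(l.chrom == f.chrom and l.strand == f.strand
                           and l.start < f.end and f.start < l.end
                           for f in first_pass_loci)]
    for loc in loci:
        loc.te_class = classify_te_origin(loc, repeat_annotations)
    return loci
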