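"""Perfect-match read mapping and the genomic copy-number filter.

Mapping requires exact full-length occurrences on either strand. The
repetitiveness filter counts genomic positions where a read aligns
end-to-end with at most 2 substitutions (pigeonhole-seeded Hamming scan)
and removes reads with more than 20 such hits; removed reads are kept on a
list because the transposon/repeat pass later reuses them as anchors.

Coordinates are 0-based half-open in memory; emitted reports are 1-based
inclusive. Reads containing ambiguous bases are unmapped by definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import PipelineConfig
from .preprocess import UniqueRead
from .simulate import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicHit:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    mismatches: int = 0


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    pos = haystack.find(needle)
    while pos >= 0:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def _is_clean(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)


def map_perfect(reads: list[UniqueRead] | list[str],
                genome: dict[str, str]) -> dict[str, list[GenomicHit]]:
    """All exact full-length occurrences of each read on both strands.

    Returns {read sequence: [GenomicHit, ...]}. Reads with non-ACGT
    characters get no hits.
    """
    hits: dict[str, list[GenomicHit]] = {}
    for read in reads:
        seq = read.sequence if isinstance(read, UniqueRead) else read
        if not _is_clean(seq):
            logger.info("read with ambiguous bases left unmapped: %s", seq)
            hits[seq] = []
            continue
        found: list[GenomicHit] = []
        rc = revcomp(seq)
        for chrom, gseq in genome.items():
            for pos in _find_all(gseq, seq):
                found.append(GenomicHit(chrom, pos, pos + len(seq), "+"))
            for pos in _find_all(gseq, rc):
                found.append(GenomicHit(chrom, pos, pos + len(seq), "-"))
        hits[seq] = sorted(found, key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _hamming_positions(gseq: str, seq: str, max_mismatch: int) -> set[int]:
    """Start positions where seq aligns end-to-end with <= max_mismatch subs.

    Pigeonhole: any such alignment contains an exact occurrence of one of
    max_mismatch+1 equal pieces of the read.
    """
    L = len(seq)
    k = max_mismatch + 1
    piece = L // k
    positions: set[int] = set()
    seen: set[int] = set()
    for j in range(k):
        off = j * piece
        part = seq[off:off + piece] if j < k - 1 else seq[off:]
        for pos in _find_all(gseq, part):
            start = pos - off
            if start < 0 or start + L > len(gseq) or start in seen:
                continue
            seen.add(start)
            window = gseq[start:start + L]
            mm = sum(a != b for a, b in zip(window, seq))
            if mm <= max_mismatch:
                positions.add(start)
    return positions


def copy_number(read: str | UniqueRead, genome: dict[str, str],
                max_mismatch: int = 2) -> int:
    """Number of genomic positions (both strands) with <= max_mismatch subs."""
    seq = read.sequence if isinstance(read, UniqueRead) else read
    if not _is_clean(seq):
        return 0
    n = 0
    rc = revcomp(seq)
    for gseq in genome.values():
        n += len(_hamming_positions(gseq, seq, max_mismatch))
        n += len(_hamming_positions(gseq, rc, max_mismatch))
    return n


def copy_number_filter(reads: list[UniqueRead], genome: dict[str, str],
                       hits: dict[str, list[GenomicHit]] | None = None,
                       config: PipelineConfig | None = None,
                       ) -> tuple[list[UniqueRead], list[UniqueRead]]:
    """Remove reads with more than max_copy_number genomic hits (<=2 mismatches).

    Returns (retained, removed). Only reads with at least one perfect hit
    are examined (reads absent from the genome cannot seed precursors and
    are dropped from both lists' downstream use, but remain in `retained`
    with their empty hit lists untouched).
    """
    cfg = config or PipelineConfig()
    retained: list[UniqueRead] = []
    removed: list[UniqueRead] = []
    for read in reads:
        if hits is not None and not hits.get(read.sequence):
            retained.append(read)
            continue
        n = copy_number(read, genome, cfg.copy_number_mismatches)
        if n > cfg.max_copy_number:
            removed.append(read)
        else:
            retained.append(read)
    return retained, removed
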