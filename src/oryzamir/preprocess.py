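"""Raw-read cleaning, collapsing into unique reads, and ncRNA/repeat removal.

Only raw reads with a detectable 3' adapter are kept; the insert must fall
in the 18-30 nt window that the library's gel excision targets. Clean reads
are collapsed into unique sequences with per-library counts, then unique
reads matching annotated repeats, rRNAs, tRNAs, snRNAs, or snoRNAs are
removed before miRNA prediction (the removal list is retained: the
transposon/repeat pass reuses it as its relaxed anchor pool).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .config import PipelineConfig
from .io import normalize_seq

logger = logging.getLogger(__name__)

ANNOTATION_ORDER = ("repeat", "rRNA", "tRNA", "snRNA", "snoRNA")


@dataclass
class UniqueRead:
    """A distinct small-RNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: str = "none"

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def trim_adapter(raw_read: str, adapter: str,
                 config: PipelineConfig | None = None) -> str | None:
    """Return the insert preceding the adapter, or None for rejected reads.

    Adapter detection is an exact match of the adapter's first 8 nt at the
    leftmost occurrence. Reads with no detectable adapter, or whose insert
    is shorter than 18 nt or longer than 30 nt, are rejected.
    """
    cfg = config or PipelineConfig()
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not raw_read:
        return None
    raw = normalize_seq(raw_read)
    seed = normalize_seq(adapter)[:cfg.adapter_seed_length]
    pos = raw.find(seed)
    if pos < 0:
        return None
    insert = raw[:pos]
    if not cfg.min_read_length <= len(insert) <= cfg.max_read_length:
        return None
    return insert


def collapse_unique(reads_per_library: Mapping[str, Iterable[str]]) -> list[UniqueRead]:
    """Cluster clean reads into unique sequences, preserving per-library counts.

    Accepts either iterables of read sequences or pre-collapsed
    {sequence: count} mappings per library.
    """
    table: dict[str, UniqueRead] = {}
    for lib, reads in reads_per_library.items():
        items = reads.items() if isinstance(reads, Mapping) else ((r, 1) for r in reads)
        for seq, n in items:
            seq = normalize_seq(seq)
            rec = table.get(seq)
            if rec is None:
                rec = table[seq] = UniqueRead(seq)
            rec.counts[lib] = rec.counts.get(lib, 0) + n
    return sorted(table.values(), key=lambda r: r.sequence)


def filter_annotated(reads: list[UniqueRead],
                     annotation_sets: Mapping[str, Mapping[str, str] | Iterable[str]],
                     ) -> tuple[list[UniqueRead], list[UniqueRead]]:
    """Remove unique reads matching any annotation set; returns (kept, removed).

    A read matches when it is an exact substring of an annotation sequence
    or vice versa. Removed reads are labeled with the first matching class
    (repeat before the structural RNA classes). Missing classes are skipped
    with a warning. Counts are never altered, only records removed, so the
    operation is idempotent.
    """
    haystacks: dict[str, str] = {}
    short_annots: dict[str, list[str]] = {}
    for cls in ANNOTATION_ORDER:
        if cls not in annotation_sets:
            if annotation_sets:
                logger.warning("annotation set %r missing; skipping that class",
                               cls)
            continue
        coll = annotation_sets[cls]
        seqs = list(coll.values()) if isinstance(coll, Mapping) else list(coll)
        seqs = [normalize_seq(s) for s in seqs]
        haystacks[cls] = "#".join(seqs)
        short_annots[cls] = [s for s in seqs if len(s) <= 30]

    kept: list[UniqueRead] = []
    removed: list[UniqueRead] = []
    for read in reads:
        label = None
        for cls, hay in haystacks.items():
            if read.sequence in hay or any(a in read.sequence for a in short_annots[cls]):
                label = cls
                break
        if label is None:
            kept.append(read)
        else:
            read.annotation = label
            removed.append(read)
    return kept, removed


def clean_libraries(raw_reads_per_library: Mapping[str, Iterable[str]], adapter: str,
                    config: PipelineConfig | None = None,
                    ) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Trim + length-filter raw reads; returns per-library {seq: count} and depths.

    Library depth is the number of clean reads, the denominator used by all
    TPTM normalization downstream.
    """
    cfg = config or PipelineConfig()
    clean: dict[str, dict[str, int]] = {}
    depths: dict[str, int] = {}
    for lib, reads in raw_reads_per_library.items():
        counts: dict[str, int] = {}
        kept = 0
        for r in reads:
            insert = trim_adapter(r, adapter, cfg)
            if insert is not None:
                counts[insert] = counts.get(insert, 0) + 1
                kept += 1
        clean[lib] = counts
        depths[lib] = kept
        logger.info("library %s: %d clean reads, %d unique", lib, kept, len(counts))
    return clean, depths
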