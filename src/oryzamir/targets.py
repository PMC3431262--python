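"""miRNA target prediction by position-dependent penalty scoring.

Plant miRNAs pair their targets nearly perfectly, so candidate sites are
found by exhaustive antiparallel alignment of the mature against each
transcript (at most one bulge or gap). Alignments are scored with the
position-dependent mispair penalty system: in the general region a
mismatch, single-nucleotide bulge, or gap costs 1 and a G:U pair 0.5;
within the core region (miRNA positions 2-13 from the 5' end) penalties
double. A site is a valid target when the total penalty is at most 4 and
it has fewer than 2 bulges+gaps. Degradome reads provide cleavage
confirmation: a 5'-end pile-up opposite miRNA position 10 or 11 that is
the local maximum within the site +-20 nt and carries at least 2 reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import PipelineConfig
from .io import normalize_seq

# states per alignment column (antiparallel pairing, T treated as U)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pair_state(m: str, t: str) -> str:
    if _COMPLEMENT.get(m) == t:
        return "match"
    if (m == "G" and t == "T") or (m == "T" and t == "G"):
        return "GU"
    return "mismatch"


@dataclass
class TargetAlignment:
    mirna: str
    transcript_id: str
    site_start: int  # transcript interval covered by the alignment, half-open
    site_end: int
    # columns: (miRNA position 0-based from 5' end | None, transcript position
    # | None, state); None on the transcript side marks a miRNA bulge, None on
    # the miRNA side an extra (gapped-in) transcript base.
    columns: list[tuple[int | None, int | None, str]]
    penalty: float
    bulge_gap_count: int
    degradome: str = "untested"  # confirmed | unconfirmed | untested
    cleavage_peak: int | None = None

    @property
    def pairing_diagram(self) -> str:
        sym = {"match": "|", "GU": "o", "mismatch": " ", "bulge": "-", "gap": "-"}
        mline, pline, tline = [], [], []
        for (mi, ti, state) in self.columns:
            mline.append(self.mirna[mi] if mi is not None else "-")
            tline.append("-" if ti is None else "*")
            pline.append(sym[state])
        return "".join(mline) + "\n" + "".join(pline)


def _is_core(mirna_pos0: int, cfg: PipelineConfig) -> bool:
    return cfg.core_start <= mirna_pos0 + 1 <= cfg.core_end


def score_alignment(columns: list[tuple[int | None, int | None, str]],
                    config: PipelineConfig | None = None) -> tuple[float, int]:
    """Total penalty and bulge+gap count for an alignment's columns."""
    cfg = config or PipelineConfig()
    penalty = 0.0
    bulge_gap = 0
    for k, (mi, ti, state) in enumerate(columns):
        if state == "match":
            continue
        if state == "GU":
            base = 0.5
            pos = mi
        elif state in ("mismatch", "bulge"):
            base = 1.0
            pos = mi
        elif state == "gap":  # extra transcript base; use the next miRNA position
            base = 1.0
            nxt = next((m for (m, _, _) in columns[k + 1:] if m is not None), None)
            pos = nxt
        else:  # pragma: no cover
            raise ValueError(f"unknown pair state {state}")
        if state in ("bulge", "gap"):
            bulge_gap += 1
        if pos is not None and _is_core(pos, cfg):
            base *= 2
        penalty += base
    return penalty, bulge_gap


def _alignment_columns(mirna: str, tseq: str, t_high: int, gap_kind: str,
                       gap_pos: int) -> list[tuple[int | None, int | None, str]] | None:
    """Columns for one alignment variant; miRNA position 0 faces t_high.

    gap_kind: "none"; "mbulge" (miRNA base gap_pos unopposed); "tgap"
    (extra transcript base between miRNA positions gap_pos-1 and gap_pos).
    Returns None when the site runs off the transcript.
    """
    L = len(mirna)
    cols: list[tuple[int | None, int | None, str]] = []
    t = t_high
    for i in range(L):
        if gap_kind == "mbulge" and i == gap_pos:
            cols.append((i, None, "bulge"))
            continue
        if gap_kind == "tgap" and i == gap_pos:
            if t < 0:
                return None
            cols.append((None, t, "gap"))
            t -= 1
        if t < 0 or t >= len(tseq):
            return None
        cols.append((i, t, _pair_state(mirna[i], tseq[t])))
        t -= 1
    return cols


def _try_alignment(mirna: str, tseq: str, t_high: int, kind: str, k: int,
                   cfg: PipelineConfig, cap: float
                   ) -> tuple[list, float, int] | None:
    """Build and score one variant, aborting once the penalty exceeds cap.

    Must agree with _alignment_columns + score_alignment (property-tested).
    """
    L = len(mirna)
    cols: list[tuple[int | None, int | None, str]] = []
    penalty = 0.0
    bulge_gap = 0
    t = t_high
    for i in range(L):
        core = _is_core(i, cfg)
        if kind == "mbulge" and i == k:
            cols.append((i, None, "bulge"))
            penalty += 2.0 if core else 1.0
            bulge_gap += 1
            if penalty > cap:
                return None
            continue
        if kind == "tgap" and i == k:
            if t < 0:
                return None
            cols.append((None, t, "gap"))
            penalty += 2.0 if core else 1.0
            bulge_gap += 1
            t -= 1
        if t < 0 or t >= len(tseq):
            return None
        state = _pair_state(mirna[i], tseq[t])
        cols.append((i, t, state))
        if state == "GU":
            penalty += 1.0 if core else 0.5
        elif state == "mismatch":
            penalty += 2.0 if core else 1.0
        t -= 1
        if penalty > cap:
            return None
    return cols, penalty, bulge_gap


def find_sites(mirna: str, transcript: str, transcript_id: str = "",
               config: PipelineConfig | None = None) -> list[TargetAlignment]:
    """All candidate sites with penalty within the generous pre-filter.

    Exhaustive over transcript offsets and over placements of at most one
    bulge (unopposed miRNA base) or gap (extra transcript base). Overlapping
    variants are collapsed to the best-scoring alignment per site.
    """
    cfg = config or PipelineConfig()
    mirna = normalize_seq(mirna)
    tseq = normalize_seq(transcript)
    L = len(mirna)
    if len(tseq) < L:
        raise ValueError("transcript shorter than the miRNA")

    variants = [("none", 0)]
    variants += [("mbulge", k) for k in range(1, L - 1)]
    variants += [("tgap", k) for k in range(1, L)]

    found: list[TargetAlignment] = []
    for t_high in range(L - 2, len(tseq) + 1):
        for kind, k in variants:
            res = _try_alignment(mirna, tseq, t_high, kind, k, cfg,
                                 cfg.target_prefilter_penalty)
            if res is None:
                continue
            cols, penalty, bg = res
            tpos = [t for (_, t, _) in cols if t is not None]
            found.append(TargetAlignment(
                mirna=mirna, transcript_id=transcript_id,
                site_start=min(tpos), site_end=max(tpos) + 1,
                columns=cols, penalty=penalty, bulge_gap_count=bg))

    # keep the best alignment per overlapping site region
    found.sort(key=lambda a: (a.penalty, a.bulge_gap_count, a.site_start))
    kept: list[TargetAlignment] = []
    for aln in found:
        if any(a.site_start < aln.site_end and aln.site_start < a.site_end
               for a in kept):
            continue
        kept.append(aln)
    kept.sort(key=lambda a: a.site_start)
    return kept


def call_targets(alignments: list[TargetAlignment],
                 config: PipelineConfig | None = None) -> list[TargetAlignment]:
    """Valid targets: penalty <= 4 and fewer than 2 bulges+gaps."""
    cfg = config or PipelineConfig()
    return [a for a in alignments
            if a.penalty <= cfg.target_penalty_max
            and a.bulge_gap_count <= cfg.target_bulge_gap_max]


def degradome_profile(transcript: str, degradome_reads: Mapping[str, int]) -> np.ndarray:
    """Per-position 5'-end counts of degradome reads exactly matching the transcript."""
    tseq = normalize_seq(transcript)
    profile = np.zeros(len(tseq), dtype=int)
    for seq, n in degradome_reads.items():
        seq = normalize_seq(seq)
        pos = tseq.find(seq)
        while pos >= 0:
            profile[pos] += n
            pos = tseq.find(seq, pos + 1)
    return profile


def degradome_confirm(alignment: TargetAlignment, transcript: str,
                      degradome_reads: Mapping[str, int] | None,
                      profile: np.ndarray | None = None,
                      config: PipelineConfig | None = None) -> TargetAlignment:
    """Set the alignment's degradome status from 5'-end pile-ups.

    Confirmed when the transcript position opposite miRNA position 10 or 11
    carries a 5'-end count >= 2 that is the maximum within the aligned site
    +-20 nt.
    """
    cfg = config or PipelineConfig()
    if degradome_reads is None and profile is None:
        alignment.degradome = "untested"
        return alignment
    if profile is None:
        profile = degradome_profile(transcript, degradome_reads)

    tpos_of = {mi: ti for (mi, ti, _) in alignment.columns
               if mi is not None and ti is not None}
    canonical = [tpos_of[p] for p in (9, 10) if p in tpos_of]
    lo = max(0, alignment.site_start - cfg.degradome_window)
    hi = min(len(profile), alignment.site_end + cfg.degradome_window)
    window_max = profile[lo:hi].max() if hi > lo else 0

    alignment.degradome = "unconfirmed"
    for c in canonical:
        v = profile[c]
        if v >= cfg.degradome_min_reads and v >= window_max:
            alignment.degradome = "confirmed"
            alignment.cleavage_peak = int(c)
            break
    return alignment


def predict_targets(matures: Mapping[str, str], transcripts: Mapping[str, str],
                    degradome_reads: Mapping[str, int] | None = None,
                    config: PipelineConfig | None = None
                    ) -> list[tuple[str, TargetAlignment]]:
    """Valid targets for each mature against every transcript.

    Returns (mirna name, TargetAlignment) pairs; degradome status is filled
    in when degradome reads are supplied.
    """
    cfg = config or PipelineConfig()
    profiles = {}
    if degradome_reads is not None:
        profiles = {tid: degradome_profile(seq, degradome_reads)
                    for tid, seq in transcripts.items()}
    out: list[tuple[str, TargetAlignment]] = []
    for name, mature in matures.items():
        for tid, tseq in transcripts.items():
            if len(tseq) < len(mature):
                continue
            sites = call_targets(find_sites(mature, tseq, tid, cfg), cfg)
            for aln in sites:
                if degradome_reads is not None:
                    degradome_confirm(aln, tseq, degradome_reads,
                                      profiles.get(tid), cfg)
                out.append((name, aln))
    return out
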