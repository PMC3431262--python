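"""Biogenesis validation against Dicer/RdRP knockdown libraries.

Authentic plant miRNAs depend on a Dicer-like enzyme (DCL1 for canonical
21-nt miRNAs, DCL3 for long 24-nt miRNAs) but not on RDR2, the polymerase
of the heterochromatic siRNA pathway. A predicted miRNA is validated when,
for at least one DCL knockdown library:

1. normalized expression (TPTM, transcripts per ten million clean reads)
   reaches 50 in at least one of the four libraries (WT and the three
   knockdowns);
2. the DCL-knockdown / WT TPTM ratio is below 0.5;
3. the DCL-knockdown / RDR2-knockdown TPTM ratio is below 0.5;
4. the RDR2-knockdown / WT TPTM ratio is above 0.5.

The qualifying knockdown decides the class: DCL1 -> cmiRNA, DCL3 ->
lmiRNA; if both qualify, the mature length (21 vs 24 nt) breaks the tie,
then the smaller ratio. AGO pulldown counts are summarized into an
AGO1-family / AGO4-family predominance label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .config import PipelineConfig
from .simulate import AGO1_LIBRARIES, AGO4_LIBRARIES, BIOGENESIS_LIBRARIES


def tptm(count: int | float, depth: int, scale: float = 1e7) -> float:
    """Transcripts per ten million clean reads: count / depth * 1e7."""
    if depth <= 0:
        raise ValueError(f"library depth must be positive, got {depth}")
    return count / depth * scale


@dataclass
class ExpressionProfile:
    raw: dict[str, int]  # library -> count
    depth: dict[str, int]  # library -> total clean reads

    def tptm(self, lib: str, scale: float = 1e7) -> float:
        return tptm(self.raw.get(lib, 0), self.depth[lib], scale)


@dataclass
class ValidationEvidence:
    ratios: dict[str, float] = field(default_factory=dict)
    max_tptm: float = 0.0
    verdict: str = "unvalidated"
    qualifying: str | None = None  # dcl1 or dcl3
    reason: str = ""
    ago_predominance: str = "none"


def validate_biogenesis(profile: ExpressionProfile, mature_length: int,
                        config: PipelineConfig | None = None) -> ValidationEvidence:
    """Apply the four-condition knockdown rule; see module docstring."""
    cfg = config or PipelineConfig()
    missing = [lib for lib in BIOGENESIS_LIBRARIES if lib not in profile.depth]
    if missing:
        raise ValueError(f"missing biogenesis libraries: {missing}")
    t = {lib: profile.tptm(lib, cfg.tptm_scale) for lib in BIOGENESIS_LIBRARIES}
    ev = ValidationEvidence(max_tptm=max(t.values()))
    if ev.max_tptm < cfg.validate_tptm_min:
        ev.reason = f"max TPTM {ev.max_tptm:.1f} below {cfg.validate_tptm_min}"
        return ev
    if t["WT"] == 0:
        ev.reason = "WT expression is zero; knockdown ratios undefined"
        return ev

    rdr2_wt = t["rdr2"] / t["WT"]
    ev.ratios["rdr2/WT"] = rdr2_wt
    qualifying: list[tuple[str, float]] = []
    for dcl in ("dcl1", "dcl3"):
        r_wt = t[dcl] / t["WT"]
        ev.ratios[f"{dcl}/WT"] = r_wt
        r_rdr2 = t[dcl] / t["rdr2"] if t["rdr2"] > 0 else math.inf
        ev.ratios[f"{dcl}/rdr2"] = r_rdr2
        if (r_wt < cfg.kd_ratio_max and r_rdr2 < cfg.kd_ratio_max
                and rdr2_wt > cfg.rdr2_ratio_min):
            qualifying.append((dcl, r_wt))
    if not qualifying:
        if rdr2_wt <= cfg.rdr2_ratio_min:
            ev.reason = "RDR2-dependent (rdr2/WT ratio not above 0.5)"
        else:
            ev.reason = "no DCL knockdown reduces expression below 0.5 of WT"
        return ev

    if len(qualifying) == 2:
        preferred = "dcl1" if mature_length <= 22 else "dcl3"
        qualifying.sort(key=lambda q: (q[0] != preferred, q[1]))
    dcl, _ = qualifying[0]
    ev.qualifying = dcl
    ev.verdict = "cmiRNA" if dcl == "dcl1" else "lmiRNA"
    return ev


def ago_predominance(pulldown_counts: Mapping[str, int | float],
                     library_depths: Mapping[str, int] | None = None,
                     config: PipelineConfig | None = None) -> str:
    """AGO1-family vs AGO4-family association from pulldown count tables.

    Counts are TPTM-normalized within each library (when depths are given)
    before the two family sums are compared; equal sums - including the
    all-zero case - yield "none".
    """
    cfg = config or PipelineConfig()

    def norm(lib: str) -> float:
        c = float(pulldown_counts.get(lib, 0))
        if library_depths and library_depths.get(lib):
            return tptm(c, library_depths[lib], cfg.tptm_scale)
        return c

    ago1 = sum(norm(lib) for lib in AGO1_LIBRARIES)
    ago4 = sum(norm(lib) for lib in AGO4_LIBRARIES)
    if ago1 > ago4:
        return "AGO1-family"
    if ago4 > ago1:
        return "AGO4-family"
    return "none"
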