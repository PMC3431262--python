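"""Pipeline configuration: every analysis threshold in one place.

Defaults follow the stringent annotation criteria for plant miRNAs that the
pipeline implements: a precursor must fold at or below -35 kcal/mol, the
miRNA/miRNA* duplex may carry at most 4 mismatches and one asymmetric bulge
of at most 2 nt, reads must map with at least 5:1 strand bias, and at least
75% of segment reads must fall in the (extended) miRNA/miRNA* windows.
Expression thresholds (TPTM scale 1e7, 50 TPTM for biogenesis validation,
100 TPTM / |log2| > 1 / p <= 0.01 for stress calls) and the target-scoring
rules (penalty <= 4, fewer than 2 bulges+gaps, core positions 2-13) are
likewise configurable but default to the published values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # read cleaning
    min_read_length: int = 18
    max_read_length: int = 30
    adapter_seed_length: int = 8

    # genome mapping / repetitiveness
    max_copy_number: int = 20
    copy_number_mismatches: int = 2

    # hairpin prediction
    anchor_min_count: int = 10
    anchor_count_per_library: bool = False  # pooled across libraries by default
    segment_offset: int = 20
    segment_min_length: int = 100
    segment_max_length: int = 300
    segment_step: int = 20
    mfe_max: float = -35.0
    duplex_mismatch_max: int = 4
    bulge_max_count: int = 1
    bulge_max_size: int = 2
    strand_ratio_min: float = 5.0
    cleavage_fraction_min: float = 0.75
    cleavage_window_pad: int = 2

    # family classification
    family_mismatch_max: int = 2

    # biogenesis validation
    tptm_scale: float = 1e7
    validate_tptm_min: float = 50.0
    kd_ratio_max: float = 0.5
    rdr2_ratio_min: float = 0.5

    # differential expression
    de_tptm_min: float = 100.0
    de_log2_min: float = 1.0
    de_p_max: float = 0.01
    de_fdr: bool = False  # optional Benjamini-Hochberg on top of the raw cutoff

    # target prediction
    target_penalty_max: float = 4.0
    target_bulge_gap_max: int = 1
    target_prefilter_penalty: float = 6.0
    core_start: int = 2  # 1-based, inclusive
    core_end: int = 13
    degradome_min_reads: int = 2
    degradome_window: int = 20

    # transposon/repeat origin
    repeat_len_frac: float = 0.8
    repeat_identity: float = 0.8

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the effective parameters (changes iff any does)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
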