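"""Seeded boundary screens for the annotation thresholds.

Each screen builds a synthetic dataset that straddles one decision
boundary of the analysis (hairpin stability, duplex mismatches, strand
bias, precise cleavage, anchor abundance, genomic copy number, target
penalty, stress-call expression floor, null significance rate, knockdown
ratio), runs the corresponding pipeline stage, and measures the extreme
value the accepted/called objects actually attain. They double as the
reproducibility entry points used by scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .biogenesis import ExpressionProfile, validate_biogenesis
from .config import PipelineConfig
from .diffexpr import ac_pvalue, call_stress_regulated
from .genome_map import copy_number_filter, map_perfect
from .hairpin import select_anchors
from .pipeline import run_pipeline
from .preprocess import UniqueRead
from .simulate import (LocusSpec, SimulationConfig, generate_genome,
                       generate_libraries, generate_multicopy_genome,
                       random_seq, revcomp)
from .targets import call_targets, find_sites

STRESS = ("control", "drought", "cold", "salt")


def _screen_config(seed: int, specs: list[LocusSpec], depth: int = 20_000,
                   genome_length: int | None = None, **kw) -> SimulationConfig:
    if genome_length is None:
        genome_length = 20_000 + 600 * len(specs)
    return SimulationConfig(
        seed=seed, genome_length=genome_length, n_true_loci=len(specs),
        locus_specs=specs, n_decoys=0, n_transcripts=0,
        contamination_fraction=0.0, cleavage_noise=0.0,
        antisense_fraction=0.0, background_fraction=0.0,
        library_depths={lib: depth for lib in STRESS}, **kw)


def _predict(cfg: SimulationConfig, config: PipelineConfig | None = None):
    genome, truth = generate_genome(cfg)
    libs = generate_libraries(genome, truth, cfg)
    result = run_pipeline(libs.stress, genome, config=config,
                          last_stage="predict")
    return result, truth


def screen_accepted_mfe(seed: int) -> dict:
    """Max folding free energy among accepted candidates; loci span the
    stability boundary via arm GC content (A/U-only stems stay above
    -35 kcal/mol, GC-rich stems fall far below)."""
    gcs = np.linspace(0.0, 0.65, 30)
    specs = [LocusSpec(arm_length=27, arm_gc_fraction=float(g)) for g in gcs]
    result, _ = _predict(_screen_config(seed, specs))
    accepted = [c for c in result.candidates if c.valid]
    return {"value": max(c.mfe for c in accepted), "n": len(specs)}


def screen_duplex_mismatches(seed: int) -> dict:
    """Max miRNA/miRNA* mismatch count among accepted candidates; loci are
    built with duplex mismatch designs 0 through 8."""
    specs = [LocusSpec(arm_length=75, duplex_mismatches=k, stem_mismatches=0)
             for k in range(9)]
    result, _ = _predict(_screen_config(seed, specs))
    accepted = [c for c in result.candidates if c.valid and c.duplex]
    return {"value": max(c.duplex.mismatches for c in accepted),
            "n": len(specs)}


def screen_strand_ratio(seed: int) -> dict:
    """Min sense:antisense ratio among accepted candidates; loci carry
    antisense read fractions from 0 to 0.5."""
    fracs = np.linspace(0.0, 0.5, 9)
    specs = [LocusSpec(antisense_fraction=float(f)) for f in fracs]
    result, _ = _predict(_screen_config(seed, specs))
    accepted = [c for c in result.candidates if c.valid]
    finite = [c.strand_ratio for c in accepted if np.isfinite(c.strand_ratio)]
    return {"value": min(finite) if finite else float("inf"), "n": len(specs)}


def screen_cleavage_fraction(seed: int) -> dict:
    """Min percentage of segment counts inside the extended miRNA/miRNA*
    windows among accepted candidates; hairpin-background read fractions
    run from 0 to 0.5."""
    fracs = np.linspace(0.0, 0.5, 9)
    specs = [LocusSpec(arm_length=80, loop_length=60,
                       background_fraction=float(f)) for f in fracs]
    result, _ = _predict(_screen_config(seed, specs))
    accepted = [c for c in result.candidates if c.valid]
    return {"value": min(c.cleavage_fraction for c in accepted) * 100.0,
            "n": len(specs)}


def screen_anchor_counts(seed: int) -> dict:
    """Min pooled read count among selected anchors when locus abundances
    run from 1 to 50 expected mature reads."""
    abundances = [1, 2, 5, 8, 9, 10, 11, 15, 30, 50]
    specs = [LocusSpec(abundance=float(a), star_fraction=0.25)
             for a in abundances]
    # scale depths so one abundance unit ~ one pooled mature read
    total = sum(abundances)
    depth = max(1, round(total * (1 + 0.25) / 4))
    cfg = _screen_config(seed, specs, depth=depth)
    genome, truth = generate_genome(cfg)
    libs = generate_libraries(genome, truth, cfg)
    result = run_pipeline(libs.stress, genome, last_stage="map")
    anchors = select_anchors(result.retained, result.hits)
    return {"value": min(r.total_count for r, _ in anchors),
            "n": len(anchors)}


def screen_copy_number(seed: int) -> dict:
    """Max genomic copy number among reads retained by the repetitiveness
    filter, for reads embedded at copy numbers 1..40."""
    copies = list(range(1, 41))
    genome, reads = generate_multicopy_genome(seed, copies)
    unique = [UniqueRead(s, {"control": 10}) for s in reads]
    hits = map_perfect(unique, genome)
    retained, _removed = copy_number_filter(unique, genome, hits)
    from .genome_map import copy_number
    return {"value": max(copy_number(r.sequence, genome) for r in retained),
            "n": len(copies)}


def _site_with_penalty(rng: np.random.Generator, mature: str,
                       penalty: float) -> str:
    """Reverse-complement site carrying exactly `penalty` in general-region
    G:U pairs (0.5) and mismatches (1.0)."""
    L = len(mature)
    site = list(revcomp(mature))  # site[j] pairs mature position L-1-j
    general = [p for p in range(L) if not 2 <= p + 1 <= 13]
    general = sorted(general, reverse=True)  # start from the miRNA 3' end
    remaining = penalty
    queue = list(general)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    while remaining > 0 and queue:
        p = queue.pop(0)
        j = L - 1 - p
        base = mature[p]
        if remaining >= 1.0:
            choices = [b for b in "ACGT"
                       if b != comp[base]
                       and not (base == "G" and b == "T")
                       and not (base == "T" and b == "G")]
            site[j] = choices[rng.integers(0, len(choices))]
            remaining -= 1.0
        elif base in "GT":
            site[j] = "T" if base == "G" else "G"  # G:U pair, 0.5
            remaining -= 0.5
        else:
            continue
    if remaining > 0:
        raise ValueError(f"cannot realize penalty {penalty} for {mature}")
    return "".join(site)


def _single_imperfection_penalty(seed: int, kind: str) -> dict:
    rng = np.random.default_rng(seed)
    pos = 16  # 1-based from the miRNA 5' end; outside the 2-13 core
    mirna = None
    while mirna is None:
        cand = random_seq(rng, 21)
        if kind != "GU" or cand[pos - 1] in "GT":
            mirna = cand
    site = list(revcomp(mirna))
    j = len(mirna) - pos
    base = mirna[pos - 1]
    if kind == "GU":
        site[j] = "T" if base == "G" else "G"
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        choices = [b for b in "ACGT" if b != comp[base]
                   and not (base == "G" and b == "T")
                   and not (base == "T" and b == "G")]
        site[j] = choices[rng.integers(0, len(choices))]
    transcript = random_seq(rng, 50) + "".join(site) + random_seq(rng, 50)
    best = min(find_sites(mirna, transcript), key=lambda a: a.penalty)
    return {"value": best.penalty, "n": 1}


def screen_single_gu_penalty(seed: int) -> dict:
    """Penalty of an alignment whose only imperfection is one G:U pair
    opposite miRNA position 16 (general region)."""
    return _single_imperfection_penalty(seed, "GU")


def screen_single_mismatch_penalty(seed: int) -> dict:
    """Penalty of an alignment whose only imperfection is one non-G:U
    mismatch opposite miRNA position 16 (general region)."""
    return _single_imperfection_penalty(seed, "mismatch")


def screen_target_penalty(seed: int) -> dict:
    """Max penalty among valid target calls when embedded sites carry
    penalties 0 to 8 in 0.5 steps."""
    rng = np.random.default_rng(seed)
    # a mature with G/T in every general position so any penalty is realizable
    mature = None
    while mature is None:
        cand = random_seq(rng, 21)
        if sum(b in "GT" for p, b in enumerate(cand)
               if not 2 <= p + 1 <= 13) >= 6:
            mature = cand
    penalties = [k * 0.5 for k in range(17)]
    best = []
    for pen in penalties:
        site = _site_with_penalty(rng, mature, pen)
        transcript = random_seq(rng, 60) + site + random_seq(rng, 60)
        sites = find_sites(mature, transcript)
        valid = call_targets(sites)
        best.extend(a.penalty for a in valid)
    return {"value": max(best), "n": len(penalties)}


def screen_de_tptm_floor(seed: int) -> dict:
    """Min max(control, stress) TPTM among stress-regulation calls, for 500
    synthetic miRNAs spanning TPTM 10-1000 and fold changes 1-8."""
    rng = np.random.default_rng(seed)
    depth = 4_000_000
    n = 500
    tptm_ctrl = 10 ** rng.uniform(1, 3, size=n)  # 10..1000 TPTM
    fc = rng.uniform(1, 8, size=n)
    up = rng.random(n) < 0.5
    x = rng.poisson(tptm_ctrl * depth / 1e7)
    lam = np.where(up, tptm_ctrl * fc, tptm_ctrl / fc) * depth / 1e7
    y = rng.poisson(lam)
    counts = pd.DataFrame({
        "control": x, "drought": y, "cold": x, "salt": x},
        index=[f"m{i}" for i in range(n)])
    calls = call_stress_regulated(counts, {lib: depth for lib in STRESS})
    called = [c for c in calls if c.verdict != "unchanged"]
    return {"value": min(max(c.tptm_ctrl, c.tptm_stress) for c in called),
            "n": n}


def screen_null_pvalues(seed: int) -> dict:
    """Fraction of null (equal-proportion) count pairs significant at
    p <= 0.01; 10,000 miRNAs, depth 1e6, expected count 200 per library."""
    rng = np.random.default_rng(seed)
    n, depth, lam = 10_000, 1_000_000, 200
    x = rng.poisson(lam, size=n)
    y = rng.poisson(lam, size=n)
    pv = np.array([ac_pvalue(int(a), int(b), depth, depth)
                   for a, b in zip(x, y)])
    return {"value": float(np.mean(pv <= 0.01)), "n": n}


def screen_knockdown_ratio(seed: int) -> dict:
    """Max qualifying-DCL/WT TPTM ratio among miRNAs passing biogenesis
    validation, for 200 miRNAs with knockdown factors 0.05-1.0."""
    rng = np.random.default_rng(seed)
    n, depth = 200, 1_000_000
    out = []
    for i in range(n):
        wt_tptm = rng.uniform(20, 500)
        factor = rng.uniform(0.05, 1.0)
        length = 21 if i % 2 == 0 else 24
        wt = rng.poisson(wt_tptm * depth / 1e7)
        cognate = rng.poisson(factor * wt_tptm * depth / 1e7)
        other = rng.poisson(wt_tptm * depth / 1e7)
        rdr2 = rng.poisson(wt_tptm * depth / 1e7)
        raw = {"WT": int(wt), "rdr2": int(rdr2),
               "dcl1": int(cognate if length == 21 else other),
               "dcl3": int(cognate if length == 24 else other)}
        profile = ExpressionProfile(raw=raw,
                                    depth={k: depth for k in raw})
        ev = validate_biogenesis(profile, length)
        if ev.verdict != "unvalidated":
            out.append(ev.ratios[f"{ev.qualifying}/WT"])
    return {"value": max(out), "n": n}


def recovery_screen(seed: int, n_loci: int = 20, depth: int = 100_000,
                    genome_length: int = 200_000, noisy: bool = True,
                    ) -> dict:
    """Parameter recovery: sensitivity and precision of locus prediction
    against the simulated ground truth."""
    kw = dict(cleavage_noise=0.1, contamination_fraction=0.1,
              antisense_fraction=0.02, background_fraction=0.05) if noisy \
        else dict(cleavage_noise=0.0, contamination_fraction=0.0,
                  antisense_fraction=0.0, background_fraction=0.0)
    cfg = SimulationConfig(seed=seed, genome_length=genome_length,
                           n_true_loci=n_loci, n_decoys=20 if noisy else 0,
                           n_transcripts=0,
                           library_depths={lib: depth for lib in STRESS}, **kw)
    genome, truth = generate_genome(cfg)
    libs = generate_libraries(genome, truth, cfg)
    result = run_pipeline(libs.stress, genome,
                          annotation_sets=truth.decoys if noisy else None,
                          last_stage="predict")

    def hit(pred) -> bool:
        return any(pred.chrom == t.chrom and pred.strand == t.strand
                   and pred.start < t.end and t.start < pred.end
                   for t in truth.loci)

    found = {id(t) for t in truth.loci
             for p in result.loci
             if p.chrom == t.chrom and p.strand == t.strand
             and p.start < t.end and t.start < p.end}
    sensitivity = len(found) / len(truth.loci)
    precision = (sum(hit(p) for p in result.loci) / len(result.loci)
                 if result.loci else 0.0)
    return {"sensitivity": sensitivity, "precision": precision,
            "n": n_loci, "n_predicted": len(result.loci)}
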