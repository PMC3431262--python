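"""End-to-end orchestration: clean -> map -> predict -> classify -> report.

`run_pipeline` drives the whole analysis on in-memory objects;
`simulate_to_dir` / `load_data_dir` / `write_results` handle the on-disk
layout the CLI uses. Every run embeds the resolved configuration hash in
its manifest, and identical inputs + config + seed give identical output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .biogenesis import ExpressionProfile, ago_predominance, validate_biogenesis
from .config import PipelineConfig
from .diffexpr import DifferentialCall, call_stress_regulated, calls_to_frame
from .families import FamilyAssignment, assign_families
from .genome_map import GenomicHit, copy_number_filter, map_perfect
from .hairpin import HairpinCandidate, MiRNALocus, predict_loci
from .io import (read_count_fasta, read_fasta, read_gff3_intervals, read_tsv,
                 write_count_fasta, write_fasta, write_gff3, write_tsv)
from .preprocess import UniqueRead, collapse_unique, filter_annotated
from .simulate import (BIOGENESIS_LIBRARIES, STRESS_LIBRARIES, GroundTruth,
                       SimulatedLibraries, SimulationConfig, generate_genome,
                       generate_libraries)
from .targets import TargetAlignment, predict_targets
from .te_origin import predict_te_loci

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    depths: dict[str, int]
    unique_reads: list[UniqueRead]
    removed_annotation: list[UniqueRead]
    removed_copy: list[UniqueRead]
    retained: list[UniqueRead]
    hits: dict[str, list[GenomicHit]]
    loci: list[MiRNALocus] = field(default_factory=list)
    candidates: list[HairpinCandidate] = field(default_factory=list)
    families: FamilyAssignment | None = None
    validation: pd.DataFrame | None = None
    targets: list[tuple[str, TargetAlignment]] = field(default_factory=list)
    de_calls: list[DifferentialCall] = field(default_factory=list)
    te_loci: list[MiRNALocus] = field(default_factory=list)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-10s %6.2f s", name, t1 - t0)
    return t1


def run_pipeline(stress_libraries: Mapping[str, Mapping[str, int]],
                 genome: dict[str, str],
                 config: PipelineConfig | None = None, *,
                 annotation_sets: Mapping[str, Mapping[str, str]] | None = None,
                 biogenesis_libraries: Mapping[str, Mapping[str, int]] | None = None,
                 ago_counts: pd.DataFrame | None = None,
                 transcripts: Mapping[str, str] | None = None,
                 degradome: Mapping[str, int] | None = None,
                 known_matures: Mapping[str, str] | None = None,
                 known_loci: list[tuple[str, int, int, str, str]] | None = None,
                 repeat_annotations: list[tuple[str, int, int, str]] | None = None,
                 depths: Mapping[str, int] | None = None,
                 last_stage: str = "te_scan") -> PipelineResult:
    """Run the analysis up to ``last_stage`` (one of preprocess, map,
    predict, families, validate, targets, diffexp, te_scan)."""
    cfg = config or PipelineConfig()
    order = ["preprocess", "map", "predict", "families", "validate",
             "targets", "diffexp", "te_scan"]
    if last_stage not in order:
        raise ValueError(f"unknown stage {last_stage}")
    upto = order.index(last_stage)
    t0 = time.perf_counter()

    # preprocess: collapse into unique reads, remove annotated ncRNA/repeats
    lib_depths = dict(depths) if depths else \
        {lib: sum(c.values()) for lib, c in stress_libraries.items()}
    reads = collapse_unique(stress_libraries)
    kept, removed_annot = filter_annotated(reads, annotation_sets or {})
    result = PipelineResult(config=cfg, depths=lib_depths, unique_reads=reads,
                            removed_annotation=removed_annot, removed_copy=[],
                            retained=kept, hits={})
    t0 = _stage("preprocess", t0)
    if upto < 1:
        return result

    # map: perfect matches (all unique reads, so criteria can see the whole
    # read population), then the copy-number filter on the unannotated set
    hits = map_perfect(reads, genome)
    retained, removed_copy = copy_number_filter(kept, genome, hits, cfg)
    result.hits = hits
    result.retained = retained
    result.removed_copy = removed_copy
    t0 = _stage("map", t0)
    if upto < 2:
        return result

    loci, candidates = predict_loci(retained, hits, genome, cfg,
                                    eval_reads=reads)
    result.loci, result.candidates = loci, candidates
    t0 = _stage("predict", t0)
    if upto < 3:
        return result

    result.families = assign_families(loci, dict(known_matures or {}),
                                      known_loci, cfg)
    t0 = _stage("families", t0)
    if upto < 4:
        return result

    if biogenesis_libraries is not None:
        bio_depths = {lib: sum(c.values())
                      for lib, c in biogenesis_libraries.items()}
        rows = []
        for loc in loci:
            raw = {lib: int(biogenesis_libraries[lib].get(loc.mature, 0))
                   for lib in BIOGENESIS_LIBRARIES}
            profile = ExpressionProfile(raw=raw, depth=bio_depths)
            ev = validate_biogenesis(profile, len(loc.mature), cfg)
            if ago_counts is not None and loc.mature in ago_counts.index:
                ev.ago_predominance = ago_predominance(
                    ago_counts.loc[loc.mature].to_dict(),
                    {c: int(ago_counts[c].sum()) for c in ago_counts.columns},
                    cfg)
            loc.biogenesis_class = ev.verdict
            rows.append({"locus": loc.name, "mature": loc.mature,
                         "verdict": ev.verdict, "qualifying": ev.qualifying,
                         "max_tptm": ev.max_tptm, "reason": ev.reason,
                         "ago": ev.ago_predominance,
                         **{f"ratio_{k.replace('/', '_')}": v
                            for k, v in ev.ratios.items()}})
        result.validation = pd.DataFrame(rows)
    t0 = _stage("validate", t0)
    if upto < 5:
        return result

    if transcripts:
        matures = {loc.name: loc.mature for loc in loci}
        result.targets = predict_targets(matures, transcripts, degradome, cfg)
    t0 = _stage("targets", t0)
    if upto < 6:
        return result

    if loci:
        counts = pd.DataFrame(
            [{**{"mirna": loc.name},
              **{lib: loc.counts.get(lib, 0) for lib in STRESS_LIBRARIES}}
             for loc in loci]).set_index("mirna")
        result.de_calls = call_stress_regulated(counts, lib_depths, cfg)
    t0 = _stage("diffexp", t0)
    if upto < 7:
        return result

    # relaxed pass: reads excluded by the repeat/copy-number filters
    repeat_lib = None
    if annotation_sets and "repeat" in annotation_sets:
        coll = annotation_sets["repeat"]
        repeat_lib = dict(coll) if isinstance(coll, Mapping) else \
            {f"repeat{i}": s for i, s in enumerate(coll)}
    result.te_loci = predict_te_loci(removed_annot, removed_copy, hits,
                                     genome, repeat_annotations or [],
                                     repeat_lib, loci, eval_reads=reads,
                                     config=cfg)
    if result.te_loci:
        assign_families(result.te_loci, dict(known_matures or {}), known_loci,
                        cfg, new_family_prefix="te-fam-")
    _stage("te_scan", t0)
    return result


# ---------------------------------------------------------------------------
# on-disk layout

def simulate_to_dir(sim_config: SimulationConfig, outdir: str | Path
                    ) -> tuple[dict[str, str], GroundTruth, SimulatedLibraries]:
    """Generate a synthetic study and write it in the pipeline input layout."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(sim_config)
    libs = generate_libraries(genome, truth, sim_config)

    write_fasta(genome, out / "genome.fa")
    for lib, counts in libs.stress.items():
        write_count_fasta(counts, out / f"reads_{lib}.fa")
    for lib, counts in libs.biogenesis.items():
        write_count_fasta(counts, out / f"reads_{lib}.fa")
    write_count_fasta(libs.degradome, out / "degradome.fa")
    for cls, seqs in truth.decoys.items():
        if seqs:
            write_fasta(seqs, out / f"annot_{cls}.fa")
    if truth.repeat_library:
        write_fasta(truth.repeat_library, out / "repeat_library.fa")
    if truth.transcripts:
        write_fasta(truth.transcripts, out / "transcripts.fa")
    libs.ago.to_csv(out / "ago_counts.tsv", sep="\t")

    truth_rows = [{
        "name": l.name, "chrom": l.chrom, "start": l.start + 1, "end": l.end,
        "strand": l.strand, "mature": l.mature, "star": l.star,
        "family": l.family, "biogenesis_class": l.biogenesis_class,
        "te_class": l.te_class or "none"} for l in truth.loci]
    write_tsv(pd.DataFrame(truth_rows), out / "truth_loci.tsv",
              "coordinates 1-based inclusive")
    write_tsv(pd.DataFrame(truth.repeat_annotations,
                           columns=["chrom", "start", "end", "te_class"]),
              out / "truth_repeats.tsv", "coordinates 0-based half-open")
    write_tsv(pd.DataFrame(truth.true_targets,
                           columns=["locus", "transcript", "cleavage_pos"]),
              out / "truth_targets.tsv", "cleavage_pos 0-based")
    with open(out / "sim_config.txt", "w") as fh:
        for k, v in vars(sim_config).items():
            fh.write(f"{k}\t{v!r}\n")
    return genome, truth, libs


def load_data_dir(datadir: str | Path) -> dict:
    """Load the simulate_to_dir layout back into run_pipeline keyword form."""
    d = Path(datadir)
    if not (d / "genome.fa").exists():
        raise FileNotFoundError(f"{d}/genome.fa: no genome in data directory")
    inputs: dict = {"genome": read_fasta(d / "genome.fa")}
    inputs["stress_libraries"] = {
        lib: read_count_fasta(d / f"reads_{lib}.fa")
        for lib in STRESS_LIBRARIES if (d / f"reads_{lib}.fa").exists()}
    bio = {lib: read_count_fasta(d / f"reads_{lib}.fa")
           for lib in BIOGENESIS_LIBRARIES if (d / f"reads_{lib}.fa").exists()}
    inputs["biogenesis_libraries"] = bio or None
    annot = {}
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat"):
        p = d / f"annot_{cls}.fa"
        if p.exists():
            annot[cls] = read_fasta(p)
    if (d / "repeat_library.fa").exists():
        annot.setdefault("repeat", {}).update(read_fasta(d / "repeat_library.fa"))
    inputs["annotation_sets"] = annot
    if (d / "transcripts.fa").exists():
        inputs["transcripts"] = read_fasta(d / "transcripts.fa")
    if (d / "degradome.fa").exists():
        inputs["degradome"] = read_count_fasta(d / "degradome.fa")
    if (d / "ago_counts.tsv").exists():
        inputs["ago_counts"] = pd.read_csv(d / "ago_counts.tsv", sep="\t",
                                           index_col=0)
    if (d / "truth_repeats.tsv").exists():
        df = read_tsv(d / "truth_repeats.tsv")
        inputs["repeat_annotations"] = [
            (r.chrom, int(r.start), int(r.end), r.te_class)
            for r in df.itertuples()]
    if (d / "known_matures.fa").exists():
        inputs["known_matures"] = read_fasta(d / "known_matures.fa")
    if (d / "known_loci.gff3").exists():
        inputs["known_loci"] = [
            (c, s, e, st, i) for (c, s, e, st, i)
            in read_gff3_intervals(d / "known_loci.gff3")]
    return inputs


def write_results(result: PipelineResult, outdir: str | Path,
                  seed: int | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    all_loci = result.loci + result.te_loci
    write_gff3(
        [type("Row", (), dict(name=l.name, chrom=l.chrom, start=l.start,
                              end=l.end, strand=l.strand,
                              mature_start=l.mature_start,
                              mature_end=l.mature_end))()
         for l in all_loci], out / "loci.gff3")
    write_fasta({f"{l.name}.mature": l.mature for l in all_loci},
                out / "mature.fa")
    write_fasta({f"{l.name}.star": l.star for l in all_loci}, out / "star.fa")
    with open(out / "structures.txt", "w") as fh:
        for l in all_loci:
            fh.write(f">{l.name}\n{l.precursor}\n{l.structure} ({l.mfe})\n")

    cand_rows = [{
        "chrom": c.chrom, "start": c.start + 1, "end": c.end, "strand": c.strand,
        "anchor": c.anchor.sequence, "mfe": c.mfe,
        "duplex_mismatches": c.duplex.mismatches if c.duplex else -1,
        "bulge_count": c.duplex.bulge_count if c.duplex else -1,
        "max_bulge_size": c.duplex.max_bulge_size if c.duplex else -1,
        "strand_ratio": c.strand_ratio, "cleavage_fraction": c.cleavage_fraction,
        "valid": c.valid,
        **{f"crit_{k}": v for k, v in c.verdict.items()}}
        for c in result.candidates]
    write_tsv(pd.DataFrame(cand_rows), out / "candidates.tsv",
              "coordinates 1-based inclusive; mfe kcal/mol")

    loci_rows = [{
        "name": l.name, "chrom": l.chrom, "start": l.start + 1, "end": l.end,
        "strand": l.strand, "mature": l.mature, "star": l.star, "mfe": l.mfe,
        "family": l.family, "novelty": l.novelty,
        "biogenesis_class": l.biogenesis_class,
        "te_class": l.te_class or "none",
        **{f"count_{lib}": l.counts.get(lib, 0) for lib in STRESS_LIBRARIES}}
        for l in all_loci]
    write_tsv(pd.DataFrame(loci_rows), out / "loci.tsv",
              "coordinates 1-based inclusive; mfe kcal/mol")

    if result.validation is not None:
        write_tsv(result.validation, out / "validation.tsv",
                  "TPTM = count/depth*1e7")
    if result.targets:
        write_tsv(pd.DataFrame([{
            "mirna": name, "transcript": a.transcript_id,
            "site_start": a.site_start + 1, "site_end": a.site_end,
            "penalty": a.penalty, "bulges_gaps": a.bulge_gap_count,
            "degradome": a.degradome,
            "cleavage_peak": -1 if a.cleavage_peak is None
            else a.cleavage_peak + 1,
            "pairing": a.pairing_diagram.replace("\n", "/")}
            for name, a in result.targets]), out / "targets.tsv",
            "site coordinates 1-based inclusive")
    if result.de_calls:
        write_tsv(calls_to_frame(result.de_calls), out / "diffexp.tsv",
                  "x,y raw counts; tptm per ten million clean reads")

    manifest = {
        "tool": "oryzamir", "version": __version__,
        "config_hash": result.config.config_hash(),
        "config": result.config.to_dict(),
        "seed": seed,
        "n_unique_reads": len(result.unique_reads),
        "n_removed_annotation": len(result.removed_annotation),
        "n_removed_copy_number": len(result.removed_copy),
        "n_candidates": len(result.candidates),
        "n_loci": len(result.loci),
        "n_te_loci": len(result.te_loci),
        "n_targets": len(result.targets),
        "n_stress_calls": sum(c.verdict != "unchanged" for c in result.de_calls),
        "folding_engine": "ViennaRNA (MFE, 37 C)",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
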