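import sys
from pathlib import Path
from types import SimpleNamespace

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oryzamir.pipeline import run_pipeline
from oryzamir.simulate import SimulationConfig, generate_genome, generate_libraries

ALL_LIBS = ("control", "drought", "cold", "salt", "WT", "dcl1", "dcl3", "rdr2")


def small_mutation(seq: str, pos: int) -> str:
    repl = {"A": "C", "C": "A", "G": "T", "T": "G"}
    return seq[:pos] + repl[seq[pos]] + seq[pos + 1:]


@pytest.fixture(scope="session")
def study():
    """A mid-size noisy synthetic study shared across test modules."""
    cfg = SimulationConfig(
        seed=7, genome_length=80_000, n_true_loci=8, n_te_loci=2,
        fold_changes={(0, "drought"): 6.0, (1, "cold"): 0.15},
        library_depths={lib: 30_000 for lib in ALL_LIBS})
    genome, truth = generate_genome(cfg)
    libs = generate_libraries(genome, truth, cfg)
    return SimpleNamespace(cfg=cfg, genome=genome, truth=truth, libs=libs)


@pytest.fixture(scope="session")
def study_result(study):
    """Full pipeline output on the shared study, with a known-miRNA
    reference seeded from two truth loci (one with locus overlap, one
    mature-only homolog)."""
    truth = study.truth
    known_matures = {
        "miR100": truth.loci[0].mature,
        "miR200": small_mutation(truth.loci[1].mature, 5),
    }
    known_loci = [(truth.loci[0].chrom, truth.loci[0].start,
                   truth.loci[0].end, truth.loci[0].strand, "miR100")]
    result = run_pipeline(
        study.libs.stress, study.genome,
        annotation_sets=study.truth.decoys,
        biogenesis_libraries=study.libs.biogenesis,
        ago_counts=study.libs.ago,
        transcripts=study.truth.transcripts,
        degradome=study.libs.degradome,
        known_matures=known_matures,
        known_loci=known_loci,
        repeat_annotations=study.truth.repeat_annotations)
    return result
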