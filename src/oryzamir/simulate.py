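"""Synthetic small-RNA study generator.

Builds a random genome with embedded miRNA hairpin loci (inverted repeats
whose transcribed fold is deeply paired), MITE-like transposon hairpins,
and decoy ncRNA/repeat segments; then emits read libraries with the
statistical structure the analysis assumes:

* four stress-condition libraries (control/drought/cold/salt) whose
  per-locus expected counts scale with configured fold changes;
* four biogenesis libraries (WT and DCL1/DCL3/RDR2 knockdowns) scaled by
  knockdown factors (defaults: the cognate Dicer at 0.1, RDR2 at 1.0);
* AGO pulldown count tables (21-nt loci load AGO1a/b/c, 24-nt loci
  AGO4a/b/AGO16);
* degradome reads whose 5' ends sit exactly at programmed cleavage sites
  on synthetic transcripts.

Mature/star duplexes carry imprecise-cleavage end shifts (+-1-2 nt),
antisense leakage, and hairpin-background reads at configurable fractions.
Counts are drawn multinomially from expected proportions so each library's
total equals its configured depth exactly. Every draw comes from one
seeded numpy Generator: a fixed seed gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRESS_LIBRARIES = ("control", "drought", "cold", "salt")
BIOGENESIS_LIBRARIES = ("WT", "dcl1", "dcl3", "rdr2")
AGO1_LIBRARIES = ("AGO1a", "AGO1b", "AGO1c")
AGO4_LIBRARIES = ("AGO4a", "AGO4b", "AGO16")
DECOY_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")
TE_CLASSES = ("MITE-Stowaway", "MITE-adh", "En/Spm", "LINE1")

_BASES = np.frompyfunc(lambda i: "ACGT"[i], 1, 1)
_COMP = str.maketrans("ACGTU", "TGCAA")

# partner substitutions that cannot pair with the given base (no WC, no G:U)
_NONPAIRING = {"A": "ACG", "C": "ACT", "G": "AG", "T": "CT"}


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class LocusSpec:
    """Per-locus construction parameters; None falls back to config values."""

    mature_length: int = 21
    arm_length: int = 70
    loop_length: int = 10
    duplex_mismatches: int = 0
    duplex_wobbles: int = 2  # G:U pairs keep the stem paired but break the
    # sequence palindrome, so reads map to one strand only (as real loci do)
    stem_mismatches: int = 1
    arm_gc_fraction: float | None = None  # None -> uniform base composition;
    # low GC with a short arm yields hairpins marginal against -35 kcal/mol
    abundance: float = 1.0
    antisense_fraction: float | None = None
    background_fraction: float | None = None
    star_fraction: float = 0.25
    strand: str | None = None
    te_class: str | None = None
    fold_changes: dict = field(default_factory=dict)  # stress -> positive real
    knockdown_factor: float | None = None  # cognate Dicer kd; default 0.1
    near_miss: str | None = None  # one of mfe|duplex|strand|cleavage|abundance

    def resolved(self) -> "LocusSpec":
        """Apply the near-miss flag: violate exactly one annotation criterion."""
        import dataclasses

        spec = dataclasses.replace(self)
        if spec.near_miss == "mfe":
            # short A/U-only stem: paired and well-formed but too weak
            spec.arm_length = spec.mature_length + 5
            spec.arm_gc_fraction = 0.0
        elif spec.near_miss == "duplex":
            spec.duplex_mismatches = 6
        elif spec.near_miss == "strand":
            spec.antisense_fraction = 0.4  # sense:antisense 1.5, below 5:1
        elif spec.near_miss == "cleavage":
            spec.background_fraction = 0.4  # precise fraction 0.6, below 0.75
        elif spec.near_miss == "abundance":
            spec.abundance = 1e-4  # mature count falls under the anchor cutoff
        elif spec.near_miss is not None:
            raise ValueError(f"unknown near_miss kind: {spec.near_miss}")
        return spec


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_true_loci: int = 10
    n_te_loci: int = 0
    stem_length_range: tuple[int, int] = (60, 90)
    mature_length_choices: tuple[int, ...] = (21, 24)
    library_depths: dict = field(default_factory=dict)  # name -> read count
    fold_changes: dict = field(default_factory=dict)  # (locus_idx, stress) -> real
    knockdown_factors: dict = field(default_factory=dict)  # (locus_idx, lib) -> [0,1]
    cleavage_noise: float = 0.1
    contamination_fraction: float = 0.1
    antisense_fraction: float = 0.02
    background_fraction: float = 0.05
    n_decoys: int = 20
    n_transcripts: int = 8
    transcript_length: int = 600
    locus_specs: list[LocusSpec] | None = None

    def __post_init__(self):
        for name in ("cleavage_noise", "contamination_fraction",
                     "antisense_fraction", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for lib, d in self.library_depths.items():
            if d < 0:
                raise ValueError(f"negative depth for library {lib}")
        lo, hi = self.stem_length_range
        if hi < lo or lo < min(self.mature_length_choices):
            raise ValueError("stem_length_range must support duplex >= mature length")

    def depth(self, lib: str) -> int:
        defaults = {"degradome": 2000, "ago": 20000}
        return int(self.library_depths.get(lib, defaults.get(lib, 100_000)))


@dataclass
class TrueLocus:
    name: str
    chrom: str
    start: int  # 0-based half-open precursor interval on the genome
    end: int
    strand: str
    precursor: str  # transcribed (sense) sequence
    mature: str
    star: str
    mature_offset: int  # offset of mature within precursor
    spec: LocusSpec
    family: str = ""
    te_class: str | None = None

    @property
    def biogenesis_class(self) -> str:
        return "cmiRNA" if self.mature_length <= 22 else "lmiRNA"

    @property
    def mature_length(self) -> int:
        return len(self.mature)


@dataclass
class GroundTruth:
    loci: list[TrueLocus]
    decoys: dict[str, dict[str, str]]  # class -> {id: sequence}
    repeat_library: dict[str, str]  # consensus per TE family, class in the id
    repeat_annotations: list[tuple[str, int, int, str]]  # chrom,start,end,class
    transcripts: dict[str, str]
    true_targets: list[tuple[str, str, int]]  # locus name, transcript id, cleavage pos
    expected_counts: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SimulatedLibraries:
    stress: dict[str, dict[str, int]]
    biogenesis: dict[str, dict[str, int]]
    ago: pd.DataFrame  # rows = locus matures, columns = AGO libraries
    degradome: dict[str, int]
    depths: dict[str, int]


def build_hairpin(rng: np.random.Generator, spec: LocusSpec
                  ) -> tuple[str, str, str, int]:
    """Construct one stem-loop precursor; returns (precursor, mature, star, offset).

    The precursor is arm + loop + reverse-complement(arm) with the requested
    number of non-pairing substitutions placed opposite the mature (duplex
    mismatches) and elsewhere in the stem (stem mismatches). The star is the
    partner region shifted to leave the canonical 2-nt 3' overhangs.
    """
    m, A, G = spec.mature_length, spec.arm_length, spec.loop_length
    if A < m + 4:
        # short-stem loci (near-miss mfe) still need room for the mature
        A = m + 4
    if spec.arm_gc_fraction is None:
        arm = random_seq(rng, A)
    else:
        gc = spec.arm_gc_fraction
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        arm = "".join("ACGT"[k] for k in rng.choice(4, size=A, p=probs))
    i = int(rng.integers(4, max(5, A - m - 4))) if A - m - 4 > 4 else 2
    i = min(i, A - m)
    loop = random_seq(rng, G)
    precursor = list(arm + loop + revcomp(arm))
    P = len(precursor)

    def mutate_partner(pos: int) -> None:
        partner = P - 1 - pos
        base = precursor[pos]
        choices = _NONPAIRING[base]
        precursor[partner] = choices[rng.integers(0, len(choices))]

    # G:U wobbles: pair structurally, differ in sequence. One in each half of
    # the mature so every +-2 nt cleavage variant still maps to one strand.
    wobbled: set[int] = set()
    if spec.duplex_wobbles > 0:
        halves = [range(i + 4, i + m // 2), range(i + m // 2, i + m - 4)]
        for k in range(spec.duplex_wobbles):
            cands = [p for p in halves[k % 2]
                     if precursor[p] in "GT" and p not in wobbled]
            if not cands:
                cands = [p for p in range(i + 3, i + m - 3)
                         if precursor[p] in "GT" and p not in wobbled]
            if not cands:
                break
            p = cands[rng.integers(0, len(cands))]
            precursor[P - 1 - p] = "T" if precursor[p] == "G" else "G"
            wobbled.add(p)

    # duplex mismatches: interior mature positions, spaced >= 3 apart
    interior = [p for p in range(i + 3, i + m - 3) if p not in wobbled]
    n_mm = min(spec.duplex_mismatches, len(interior) // 3)
    if n_mm:
        picks = interior[:: max(1, len(interior) // n_mm)][:n_mm]
        for p in picks:
            mutate_partner(p)
    # stem mismatches outside the duplex footprint
    outside = [p for p in range(2, A - 2) if p < i - 4 or p > i + m + 3]
    n_sm = min(spec.stem_mismatches, len(outside) // 4)
    if n_sm and outside:
        for p in rng.choice(outside, size=n_sm, replace=False):
            mutate_partner(int(p))
    seq = "".join(precursor)
    mature = seq[i:i + m]
    star_lo = P - (i + m) + 2
    star = seq[star_lo:star_lo + m]
    return seq, mature, star, i


def _default_specs(cfg: SimulationConfig, rng: np.random.Generator) -> list[LocusSpec]:
    specs = []
    lo, hi = cfg.stem_length_range
    for k in range(cfg.n_true_loci):
        specs.append(LocusSpec(
            mature_length=int(rng.choice(cfg.mature_length_choices)),
            arm_length=int(rng.integers(lo, hi + 1)),
            abundance=float(rng.uniform(0.5, 2.0)),
        ))
    for k in range(cfg.n_te_loci):
        specs.append(LocusSpec(
            mature_length=int(rng.choice(cfg.mature_length_choices)),
            arm_length=int(rng.integers(max(lo, 55), hi + 1)),
            abundance=float(rng.uniform(0.5, 2.0)),
            te_class=TE_CLASSES[k % len(TE_CLASSES)],
        ))
    return specs


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], GroundTruth]:
    """Build the synthetic genome and its ground truth.

    Returns ({chrom: sequence}, GroundTruth). Raises ValueError when
    genome_length cannot hold the requested loci and decoys.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.locus_specs
    if specs is None:
        specs = _default_specs(config, rng)
    specs = [s.resolved() for s in specs]
    for idx, s in enumerate(specs):
        for (li, stress), fc in config.fold_changes.items():
            if li == idx:
                s.fold_changes.setdefault(stress, fc)
        for (li, lib), kf in config.knockdown_factors.items():
            if li == idx and lib in ("dcl1", "dcl3"):
                s.knockdown_factor = kf if s.knockdown_factor is None else s.knockdown_factor

    # TE family consensus: the whole element is the inverted repeat, so one
    # full hairpin per family is built once and reused verbatim by its copies
    # (a MITE's terminal inverted repeats make the entire element fold back)
    consensus: dict[str, tuple[str, str, str, int]] = {}
    for s in specs:
        if s.te_class and s.te_class not in consensus:
            consensus[s.te_class] = build_hairpin(rng, s)

    inserts: list[tuple[str, object]] = []  # (kind, payload)
    loci: list[TrueLocus] = []
    for idx, s in enumerate(specs):
        if s.te_class:
            seq, mature, star, i = consensus[s.te_class]
        else:
            seq, mature, star, i = build_hairpin(rng, s)
        strand = s.strand or ("+" if rng.random() < 0.5 else "-")
        loc = TrueLocus(name=f"locus{idx:03d}", chrom="chr1", start=-1, end=-1,
                        strand=strand, precursor=seq, mature=mature, star=star,
                        mature_offset=i, spec=s, te_class=s.te_class)
        loci.append(loc)
        inserts.append(("locus", loc))

    decoys: dict[str, dict[str, str]] = {c: {} for c in DECOY_CLASSES}
    for k in range(config.n_decoys):
        cls = DECOY_CLASSES[k % len(DECOY_CLASSES)]
        name = f"{cls}_{k:03d}"
        seq = random_seq(rng, int(rng.integers(80, 200)))
        decoys[cls][name] = seq
        inserts.append(("decoy", (name, seq)))

    margin = 60
    total = sum(len(x[1].precursor) if x[0] == "locus" else len(x[1][1])
                for x in inserts)
    needed = total + (len(inserts) + 1) * margin
    if needed > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small for requested loci "
            f"and decoys (need >= {needed})")

    free = config.genome_length - needed
    gaps = rng.multinomial(free, np.ones(len(inserts) + 1) / (len(inserts) + 1)) \
        if inserts else np.array([free])
    parts: list[str] = []
    pos = 0
    repeat_annotations: list[tuple[str, int, int, str]] = []

    order = list(range(len(inserts)))
    rng.shuffle(order)
    for slot, j in enumerate(order):
        gap = int(gaps[slot]) + margin
        parts.append(random_seq(rng, gap))
        pos += gap
        kind, payload = inserts[j]
        if kind == "locus":
            loc = payload
            gseq = loc.precursor if loc.strand == "+" else revcomp(loc.precursor)
            loc.start, loc.end = pos, pos + len(gseq)
            parts.append(gseq)
            if loc.te_class:
                repeat_annotations.append(("chr1", loc.start, loc.end, loc.te_class))
            pos += len(gseq)
        else:
            name, seq = payload
            parts.append(seq)
            pos += len(seq)
    parts.append(random_seq(rng, int(gaps[-1]) + margin if inserts else config.genome_length))
    genome = {"chr1": "".join(parts)}

    repeat_library = {f"{cls.replace('/', '_')}_consensus|class={cls}": seq
                      for cls, (seq, *_rest) in consensus.items()}
    # repeat-class decoys also go to the repeat library used for read filtering
    for cls, (seq, *_rest) in consensus.items():
        decoys["repeat"][f"{cls.replace('/', '_')}_consensus"] = seq

    transcripts: dict[str, str] = {}
    true_targets: list[tuple[str, str, int]] = []
    n_tx = min(config.n_transcripts, len(loci))
    for t in range(n_tx):
        loc = loci[t]
        tlen = config.transcript_length
        tseq = random_seq(rng, tlen)
        m = len(loc.mature)
        q = int(rng.integers(50, tlen - m - 50))
        tseq = tseq[:q] + revcomp(loc.mature) + tseq[q + m:]
        tid = f"tx{t:03d}"
        transcripts[tid] = tseq
        # cleavage opposite miRNA position 10 (1-based from the miRNA 5' end)
        true_targets.append((loc.name, tid, q + m - 10))

    truth = GroundTruth(loci=loci, decoys=decoys, repeat_library=repeat_library,
                        repeat_annotations=repeat_annotations,
                        transcripts=transcripts, true_targets=true_targets)
    for loc in truth.loci:
        gslice = genome[loc.chrom][loc.start:loc.end]
        expected = loc.precursor if loc.strand == "+" else revcomp(loc.precursor)
        assert gslice == expected, "truth locus does not match genome"
    return genome, truth


def _shift_distribution(noise: float) -> list[tuple[int, float]]:
    if noise <= 0:
        return [(0, 1.0)]
    return [(0, 1 - noise), (-1, 0.3 * noise), (1, 0.3 * noise),
            (-2, 0.2 * noise), (2, 0.2 * noise)]


def _locus_species(loc: TrueLocus, cfg: SimulationConfig) -> list[tuple[str, float, str]]:
    """Read species for one locus: (sequence, weight within locus, kind).

    kind in {mature, star, background, antisense}. Weights sum to 1.
    """
    s = loc.spec
    alpha = s.antisense_fraction if s.antisense_fraction is not None else cfg.antisense_fraction
    beta = s.background_fraction if s.background_fraction is not None else cfg.background_fraction
    sigma = s.star_fraction
    P, i, m = len(loc.precursor), loc.mature_offset, len(loc.mature)
    shifts = _shift_distribution(cfg.cleavage_noise)

    species: list[tuple[str, float, str]] = []
    sense = 1.0 - alpha
    w_mature = sense * (1 - beta) / (1 + sigma)
    w_star = sense * (1 - beta) * sigma / (1 + sigma)
    star_lo = P - (i + m) + 2

    def end_shifted(lo: int, hi: int, weight: float, kind: str) -> None:
        combos = []
        for s5, p5 in shifts:
            for s3, p3 in shifts:
                a, b = lo + s5, hi + s3
                if a < 0 or b > P or not (18 <= b - a <= 30):
                    continue
                combos.append((a, b, p5 * p3))
        z = sum(p for *_, p in combos)
        for a, b, p in combos:
            species.append((loc.precursor[a:b], weight * p / z, kind))

    end_shifted(i, i + m, w_mature, "mature")
    end_shifted(star_lo, min(star_lo + m, P), w_star, "star")

    if beta > 0:
        lo, hi = i + m + 3, star_lo - 3
        if hi - lo >= 21:
            n_bg = 4
            step = (hi - lo - 21) // max(1, n_bg - 1) if n_bg > 1 else 1
            starts = [lo + k * max(1, step) for k in range(n_bg)]
            starts = [min(x, hi - 21) for x in starts]
            for x in dict.fromkeys(starts):
                species.append((loc.precursor[x:x + 21], sense * beta / len(set(starts)),
                                "background"))
        else:  # tight loop: reuse the loop center
            x = max(0, (P - 21) // 2)
            species.append((loc.precursor[x:x + 21], sense * beta, "background"))
    if alpha > 0:
        species.append((revcomp(loc.mature), alpha, "antisense"))
    return species


def _knockdown_factor(loc: TrueLocus, lib: str) -> float:
    kd = loc.spec.knockdown_factor if loc.spec.knockdown_factor is not None else 0.1
    if lib == "WT" or lib == "rdr2":
        return 1.0
    cognate = "dcl1" if loc.biogenesis_class == "cmiRNA" else "dcl3"
    return kd if lib == cognate else 1.0


def generate_libraries(genome: dict[str, str], truth: GroundTruth,
                       config: SimulationConfig) -> SimulatedLibraries:
    """Sample all read libraries from the ground truth; see module docstring."""
    rng = np.random.default_rng(config.seed + 1)
    loci = truth.loci
    locus_species = [_locus_species(loc, config) for loc in loci]
    abundances = np.array([loc.spec.abundance for loc in loci], dtype=float)

    # decoy fragment species (fixed set, deterministic under the seed)
    decoy_frags: list[tuple[str, float]] = []
    all_decoys = [(name, seq) for cls in truth.decoys.values() for name, seq in cls.items()]
    cont = config.contamination_fraction
    if cont > 0 and all_decoys:
        per = cont / (1 - cont) * abundances.sum() / (3 * len(all_decoys))
        for name, seq in all_decoys:
            for _ in range(3):
                L = int(rng.integers(20, 25))
                x = int(rng.integers(0, max(1, len(seq) - L)))
                decoy_frags.append((seq[x:x + L], per))

    z_control = abundances.sum() + sum(w for _, w in decoy_frags)

    def sample(lib: str, locus_weights: np.ndarray) -> tuple[dict[str, int], np.ndarray]:
        depth = config.depth(lib)
        if depth == 0:
            warnings.warn(f"library {lib} has depth 0; emitting empty library")
            return {}, np.zeros(len(loci))
        seqs: list[str] = []
        weights: list[float] = []
        owner: list[int] = []
        for idx, spp in enumerate(locus_species):
            for seq, w, _kind in spp:
                seqs.append(seq)
                weights.append(w * locus_weights[idx])
                owner.append(idx)
        for seq, w in decoy_frags:
            seqs.append(seq)
            weights.append(w)
            owner.append(-1)
        w = np.asarray(weights)
        counts = rng.multinomial(depth, w / w.sum())
        lib_counts: dict[str, int] = {}
        for seq, n in zip(seqs, counts):
            if n:
                lib_counts[seq] = lib_counts.get(seq, 0) + int(n)
        expected = depth * locus_weights / z_control
        return lib_counts, expected

    stress: dict[str, dict[str, int]] = {}
    depths: dict[str, int] = {}
    for lib in STRESS_LIBRARIES:
        fc = np.array([loc.spec.fold_changes.get(lib, 1.0) for loc in loci]) \
            if lib != "control" else np.ones(len(loci))
        stress[lib], truth.expected_counts[lib] = sample(lib, abundances * fc)
        depths[lib] = sum(stress[lib].values())

    biogenesis: dict[str, dict[str, int]] = {}
    for lib in BIOGENESIS_LIBRARIES:
        kf = np.array([_knockdown_factor(loc, lib) for loc in loci])
        # explicit per-locus overrides from the config win over defaults
        for (idx, l), v in config.knockdown_factors.items():
            if l == lib and 0 <= idx < len(kf):
                kf[idx] = v
        biogenesis[lib], truth.expected_counts[lib] = sample(lib, abundances * kf)
        depths[lib] = sum(biogenesis[lib].values())

    ago_libs = AGO1_LIBRARIES + AGO4_LIBRARIES
    ago_counts = np.zeros((len(loci), len(ago_libs)), dtype=int)
    for i, loc in enumerate(loci):
        target = AGO1_LIBRARIES if loc.biogenesis_class == "cmiRNA" else AGO4_LIBRARIES
        for lib in target:
            j = ago_libs.index(lib)
            ago_counts[i, j] = rng.poisson(loc.spec.abundance * 1000)
    ago = pd.DataFrame(ago_counts, index=[loc.mature for loc in loci], columns=ago_libs)

    degradome: dict[str, int] = {}
    deg_species: list[tuple[str, float]] = []
    for locus_name, tid, cpos in truth.true_targets:
        tseq = truth.transcripts[tid]
        deg_species.append((tseq[cpos:cpos + 20], 20.0))
    for tid, tseq in truth.transcripts.items():
        for _ in range(5):
            x = int(rng.integers(0, len(tseq) - 20))
            deg_species.append((tseq[x:x + 20], 1.0))
    if deg_species:
        w = np.array([x[1] for x in deg_species])
        counts = rng.multinomial(config.depth("degradome"), w / w.sum())
        for (seq, _), n in zip(deg_species, counts):
            if n:
                degradome[seq] = degradome.get(seq, 0) + int(n)

    return SimulatedLibraries(stress=stress, biogenesis=biogenesis, ago=ago,
                              degradome=degradome, depths=depths)


def generate_multicopy_genome(seed: int, copy_numbers: list[int],
                              read_length: int = 21, spacing: int = 40
                              ) -> tuple[dict[str, str], list[str]]:
    """Genome embedding one distinct read verbatim per requested copy number.

    Utility for exercising the repetitiveness filter: returns the genome and
    the list of embedded read sequences (reads[k] occurs copy_numbers[k]
    times).
    """
    rng = np.random.default_rng(seed)
    reads = [random_seq(rng, read_length) for _ in copy_numbers]
    parts = []
    for read, n in zip(reads, copy_numbers):
        for _ in range(n):
            parts.append(random_seq(rng, spacing))
            parts.append(read)
    parts.append(random_seq(rng, spacing))
    rng.shuffle(parts)
    return {"chr1": "".join(parts)}, reads
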