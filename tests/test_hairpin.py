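"""Hairpin prediction: segments, folding, duplex location, criteria, selection."""

import math

import numpy as np
import pytest

from oryzamir.genome_map import GenomicHit, map_perfect
from oryzamir.hairpin import (Duplex, HairpinCandidate, ReadIndex, choose_mature,
                              enumerate_segments, evaluate_criteria, fold,
                              has_inverted_repeat_partner, locate_duplex,
                              predict_loci, select_anchors, select_precursor)
from oryzamir.preprocess import UniqueRead, collapse_unique
from oryzamir.simulate import (LocusSpec, SimulationConfig, build_hairpin,
                               generate_genome, generate_libraries, random_seq,
                               revcomp)


class TestAnchors:
    def _reads(self, counts):
        return [UniqueRead(f"{'ACGT' * 5}{i % 4}".replace("0", "A")
                           .replace("1", "C").replace("2", "G")
                           .replace("3", "T"), c)
                for i, c in enumerate(counts)]

    def test_pooled_count_boundary_at_10(self):
        r10 = UniqueRead("A" * 21, {"control": 4, "drought": 6})
        r9 = UniqueRead("C" * 21, {"control": 9})
        hits = {r10.sequence: [GenomicHit("c", 0, 21, "+")],
                r9.sequence: [GenomicHit("c", 50, 71, "+")]}
        anchors = select_anchors([r10, r9], hits)
        assert [a.sequence for a, _ in anchors] == [r10.sequence]

    def test_one_anchor_instance_per_genomic_hit(self):
        read = UniqueRead("G" * 21, {"control": 12})
        hits = {read.sequence: [GenomicHit("c", 0, 21, "+"),
                                GenomicHit("c", 99, 120, "-")]}
        anchors = select_anchors([read], hits)
        assert len(anchors) == 2


class TestSegments:
    def test_mid_chromosome_anchor_yields_22_segments(self):
        segs = enumerate_segments(GenomicHit("c", 5000, 5021, "+"), 10_000)
        assert len(segs) == 22
        lengths = sorted({e - s for s, e in segs})
        assert lengths == list(range(100, 301, 20))

    def test_every_segment_contains_the_anchor(self):
        hit = GenomicHit("c", 5000, 5021, "+")
        for s, e in enumerate_segments(hit, 10_000):
            assert s <= hit.start and e >= hit.end

    def test_contig_edge_clips_one_side(self):
        segs = enumerate_segments(GenomicHit("c", 50, 71, "+"), 10_000)
        left = [s for s in segs if s[0] == 30]
        assert len(left) == 11  # left-anchored family intact
        assert len(segs) < 22  # right-anchored family partly clipped

    def test_anchor_pinned_at_both_ends_gives_nothing(self):
        assert enumerate_segments(GenomicHit("c", 10, 31, "+"), 45) == []


class TestFold:
    def test_homopolymer_has_no_pairs_and_zero_energy(self):
        structure, mfe = fold("A" * 150)
        assert set(structure) == {"."}
        assert mfe == 0.0

    def test_perfect_inverted_repeat_folds_deeply(self):
        rng = np.random.default_rng(0)
        arm = random_seq(rng, 60)
        structure, mfe = fold(arm + random_seq(rng, 10) + revcomp(arm))
        assert mfe < -35.0

    def test_structure_is_balanced(self):
        rng = np.random.default_rng(1)
        arm = random_seq(rng, 40)
        structure, _ = fold(arm + "AAAA" + revcomp(arm))
        depth = 0
        for c in structure:
            depth += {"(": 1, ")": -1}.get(c, 0)
            assert depth >= 0
        assert depth == 0


def _stem_partner(n=100, mature=(10, 31), star_lo=50):
    """Partner table for a clean antiparallel duplex of the mature region."""
    partner = [-1] * n
    a0, a1 = mature
    top = star_lo + (a1 - a0) - 1 + 20  # arbitrary upper partner index
    for k, i in enumerate(range(a0, a1)):
        j = top - k
        partner[i] = j
        partner[j] = i
    return partner


class TestLocateDuplex:
    def test_fully_paired_duplex_has_no_mismatches_or_bulges(self):
        partner = _stem_partner()
        d = locate_duplex("." * 100, (10, 31), partner)
        assert (d.mismatches, d.bulge_count, d.max_bulge_size) == (0, 0, 0)
        j = [partner[i] for i in range(10, 31)]
        assert d.star_region == (min(j) + 2, max(j) + 3)

    def test_symmetric_internal_loop_counts_as_mismatch(self):
        partner = _stem_partner()
        i = 15
        j = partner[i]
        partner[i] = partner[j] = -1
        d = locate_duplex("." * 100, (10, 31), partner)
        assert d.mismatches == 1 and d.bulge_count == 0

    def test_asymmetric_run_counts_as_bulge_with_its_size(self):
        partner = [-1] * 120
        # mature 10..30; star side skips 2 extra bases mid-helix
        top = 90
        for k, i in enumerate(range(10, 16)):
            partner[i], partner[top - k] = top - k, i
        for k, i in enumerate(range(16, 31)):
            j = top - 5 - 2 - 1 - k  # 2-nt asymmetric insertion on the star
            partner[i], partner[j] = j, i
        d = locate_duplex("." * 120, (10, 31), partner)
        assert d.mismatches == 0
        assert (d.bulge_count, d.max_bulge_size) == (1, 2)

    def test_unpaired_mature_region_is_undefined(self):
        assert locate_duplex("." * 100, (10, 31), [-1] * 100) is None

    def test_unpaired_duplex_ends_count_as_mismatches(self):
        partner = _stem_partner()
        for i in (10, 11, 30):  # fray both helix ends
            j = partner[i]
            partner[i] = partner[j] = -1
        d = locate_duplex("." * 100, (10, 31), partner)
        assert d.mismatches == 3


def _candidate(mfe=-40.0, duplex=None):
    anchor = UniqueRead("A" * 21, {"l": 50})
    return HairpinCandidate(
        chrom="c", start=0, end=100, strand="+", sequence="A" * 100,
        structure="." * 100, mfe=mfe, anchor=anchor,
        anchor_hit=GenomicHit("c", 20, 41, "+"),
        duplex=duplex or Duplex((20, 41), (58, 81), 0, 0, 0))


def _index(rows):
    """rows: (seq, start, end, strand, count)"""
    reads, hits = [], {}
    for (seq, s, e, strand, c) in rows:
        r = UniqueRead(seq, {"l": c})
        reads.append(r)
        hits.setdefault(seq, []).append(GenomicHit("c", s, e, strand))
    return ReadIndex(reads, hits)


class TestCriteria:
    def test_all_pass_at_their_exact_boundaries(self):
        # ratio exactly 5.0 and cleavage exactly 0.75 both pass; mfe -35 passes
        idx = _index([("A" * 21, 20, 41, "+", 60),
                      ("C" * 21, 40, 58, "+", 20),
                      ("G" * 21, 50, 71, "-", 16)])
        cand = evaluate_criteria(_candidate(mfe=-35.0), idx)
        assert cand.strand_ratio == 5.0
        assert cand.cleavage_fraction == 0.75
        assert cand.valid

    def test_mfe_just_above_threshold_fails(self):
        idx = _index([("A" * 21, 20, 41, "+", 60)])
        cand = evaluate_criteria(_candidate(mfe=-34.9), idx)
        assert cand.verdict["mfe"] is False and not cand.valid

    def test_duplex_mismatch_and_bulge_boundaries(self):
        idx = _index([("A" * 21, 20, 41, "+", 60)])
        ok = evaluate_criteria(
            _candidate(duplex=Duplex((20, 41), (58, 81), 4, 1, 2)), idx)
        assert ok.verdict["duplex_mismatch"] and ok.verdict["bulge"]
        bad = evaluate_criteria(
            _candidate(duplex=Duplex((20, 41), (58, 81), 5, 2, 3)), idx)
        assert not bad.verdict["duplex_mismatch"] and not bad.verdict["bulge"]

    def test_no_antisense_reads_gives_infinite_ratio_and_passes(self):
        idx = _index([("A" * 21, 20, 41, "+", 60)])
        cand = evaluate_criteria(_candidate(), idx)
        assert math.isinf(cand.strand_ratio) and cand.verdict["strand_bias"]

    def test_no_reads_on_segment_fails_with_reason(self):
        cand = evaluate_criteria(_candidate(), _index([]))
        assert not cand.valid and "no sense reads" in cand.fail_reason

    def test_adding_antisense_reads_never_rescues_strand_bias(self):
        base = [("A" * 21, 20, 41, "+", 60)]
        ratios = []
        for anti in (0, 10, 13, 50):
            rows = base + ([("G" * 21, 50, 71, "-", anti)] if anti else [])
            cand = evaluate_criteria(_candidate(), _index(rows))
            ratios.append(cand.strand_ratio)
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))


class TestSelection:
    def _stub(self, count, mfe, length, start=0):
        c = _candidate(mfe=mfe)
        c.mature_count = count
        c.start, c.end = start, start + length
        return c

    def test_highest_mature_count_wins(self):
        a, b = self._stub(100, -40, 120), self._stub(90, -80, 100)
        assert select_precursor([a, b]) is a

    def test_mfe_breaks_count_ties(self):
        a, b = self._stub(50, -40, 120), self._stub(50, -50, 150)
        assert select_precursor([a, b]) is b

    def test_shortest_length_breaks_remaining_ties(self):
        a, b = self._stub(50, -40, 120), self._stub(50, -40, 100)
        assert select_precursor([a, b]) is b


@pytest.fixture(scope="module")
def designed_locus():
    rng = np.random.default_rng(11)
    spec = LocusSpec(arm_length=70, loop_length=30)
    precursor, mature, star, i = build_hairpin(rng, spec)
    pad = random_seq(rng, 150)
    genome = {"c": pad + precursor + random_seq(rng, 150)}
    offset = len(pad)
    return genome, precursor, mature, star, i, offset


class TestChooseMature:
    def _run(self, genome, precursor, offset, rows):
        reads = collapse_unique({"l": rows})
        hits = map_perfect(reads, genome)
        index = ReadIndex(reads, hits)
        seq = precursor
        structure, mfe = fold(seq)
        anchor = reads[0]
        cand = HairpinCandidate(
            chrom="c", start=offset, end=offset + len(seq), strand="+",
            sequence=seq, structure=structure, mfe=mfe, anchor=anchor,
            anchor_hit=hits[anchor.sequence][0])
        return choose_mature(cand, index)

    def test_most_abundant_structurally_valid_read_is_mature(self, designed_locus):
        genome, precursor, mature, star, i, offset = designed_locus
        rows = {mature: 50, star: 12}
        picked = self._run(genome, precursor, offset, rows)
        assert picked is not None and picked[0].sequence == mature

    def test_abundant_loop_read_is_skipped_for_next_valid(self, designed_locus):
        genome, precursor, mature, star, i, offset = designed_locus
        arm = 70  # matches the fixture's LocusSpec
        loop_read = precursor[arm + 4:arm + 25]  # single-stranded loop
        rows = {loop_read: 100, mature: 50}
        picked = self._run(genome, precursor, offset, rows)
        assert picked is not None and picked[0].sequence == mature

    def test_abundance_ties_break_lexicographically(self, designed_locus):
        genome, precursor, mature, star, i, offset = designed_locus
        rows = {mature: 50, star: 50}
        picked = self._run(genome, precursor, offset, rows)
        assert picked[0].sequence == min(mature, star)


class TestPrefilter:
    def test_hairpin_segment_passes_and_random_segment_fails(self):
        rng = np.random.default_rng(3)
        arm = random_seq(rng, 60)
        hairpin = arm + random_seq(rng, 12) + revcomp(arm)
        assert has_inverted_repeat_partner(hairpin, (5, 26))
        assert not has_inverted_repeat_partner(random_seq(rng, 150), (5, 26))


@pytest.fixture(scope="module")
def mini():
    cfg = SimulationConfig(
        seed=21, genome_length=25_000, n_true_loci=3, n_decoys=0,
        n_transcripts=0, cleavage_noise=0.0, contamination_fraction=0.0,
        antisense_fraction=0.0, background_fraction=0.0,
        library_depths={lib: 8_000 for lib in
                        ("control", "drought", "cold", "salt")})
    genome, truth = generate_genome(cfg)
    libs = generate_libraries(genome, truth, cfg)
    reads = collapse_unique(libs.stress)
    hits = map_perfect(reads, genome)
    return genome, truth, reads, hits


class TestEndToEnd:
    def test_zero_noise_recovers_every_locus_exactly(self, mini):
        genome, truth, reads, hits = mini
        loci, _ = predict_loci(reads, hits, genome)
        assert {l.mature for l in loci} == {t.mature for t in truth.loci}
        for pred in loci:
            t = next(t for t in truth.loci if t.mature == pred.mature)
            assert pred.strand == t.strand
            assert pred.start < t.end and t.start < pred.end

    def test_verdicts_invariant_under_read_ordering(self, mini):
        genome, truth, reads, hits = mini
        loci_fwd, _ = predict_loci(list(reads), hits, genome)
        loci_rev, _ = predict_loci(list(reads)[::-1], hits, genome)
        key = lambda l: (l.chrom, l.start, l.end, l.strand, l.mature)
        assert sorted(map(key, loci_fwd)) == sorted(map(key, loci_rev))

    def test_star_has_two_nt_three_prime_overhang_geometry(self, mini):
        genome, truth, reads, hits = mini
        loci, _ = predict_loci(reads, hits, genome)
        for pred in loci:
            t = next(t for t in truth.loci if t.mature == pred.mature)
            assert pred.star == t.star
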