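"""Target prediction: penalty scoring, site search, degradome confirmation."""

import numpy as np
import pytest

from oracles import naive_target_scan, rc
from oryzamir.simulate import random_seq
from oryzamir.targets import (call_targets, degradome_confirm, find_sites,
                              score_alignment)

MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def _perfect_site_transcript(mirna, rng=None, flank=40):
    rng = rng or np.random.default_rng(0)
    return random_seq(rng, flank) + rc(mirna) + random_seq(rng, flank)


def _site_columns(mirna, mutate=None):
    """Columns of the ungapped perfect alignment, optionally with one
    position's state replaced: mutate = (miRNA pos 1-based, state)."""
    cols = [(i, 100 - i, "match") for i in range(len(mirna))]
    if mutate:
        pos, state = mutate
        cols[pos - 1] = (pos - 1, 100 - (pos - 1), state)
    return cols


class TestScoring:
    def test_perfect_complementarity_scores_zero(self):
        assert score_alignment(_site_columns(MIRNA)) == (0.0, 0)

    def test_single_gu_outside_core_scores_half(self):
        penalty, bg = score_alignment(_site_columns(MIRNA, (16, "GU")))
        assert (penalty, bg) == (0.5, 0)

    def test_single_mismatch_outside_core_scores_one(self):
        penalty, _ = score_alignment(_site_columns(MIRNA, (16, "mismatch")))
        assert penalty == 1.0

    def test_core_mismatch_is_doubled(self):
        penalty, _ = score_alignment(_site_columns(MIRNA, (5, "mismatch")))
        assert penalty == 2.0

    def test_core_gu_is_doubled_to_one(self):
        penalty, _ = score_alignment(_site_columns(MIRNA, (7, "GU")))
        assert penalty == 1.0

    def test_moving_a_lone_mismatch_into_the_core_doubles_it(self):
        general, _ = score_alignment(_site_columns(MIRNA, (15, "mismatch")))
        core, _ = score_alignment(_site_columns(MIRNA, (13, "mismatch")))
        assert core == 2 * general

    def test_bulge_counts_toward_bulge_gap_total(self):
        penalty, bg = score_alignment(_site_columns(MIRNA, (16, "bulge")))
        assert (penalty, bg) == (1.0, 1)


class TestFindSites:
    def test_exact_reverse_complement_gives_one_perfect_site(self):
        tx = _perfect_site_transcript(MIRNA)
        sites = find_sites(MIRNA, tx)
        perfect = [s for s in sites if s.penalty == 0.0]
        assert len(perfect) == 1
        assert perfect[0].site_start == 40
        assert perfect[0].site_end == 40 + len(MIRNA)

    def test_random_transcript_yields_no_candidate_sites(self):
        rng = np.random.default_rng(10)
        hits = [s for _ in range(5)
                for s in find_sites(random_seq(rng, 21), random_seq(rng, 400))]
        valid = call_targets(hits)
        assert len(valid) == 0

    def test_supersets_brute_force_ungapped_scan(self):
        rng = np.random.default_rng(2)
        mirna = random_seq(rng, 21)
        tx = random_seq(rng, 300) + rc(mirna) + random_seq(rng, 100)
        oracle_hits = {t for t, pen in naive_target_scan(mirna, tx)
                       if pen <= 6.0}
        ours = find_sites(mirna, tx)
        our_highs = set()
        for a in ours:
            tpos = [t for (_, t, _) in a.columns if t is not None]
            our_highs.add(max(tpos))
        # every brute-force hit region is covered by a reported site
        for t_high in oracle_hits:
            assert any(a.site_start <= t_high < a.site_end + 2 for a in ours)

    def test_reported_penalties_rescore_identically(self):
        rng = np.random.default_rng(3)
        mirna = random_seq(rng, 21)
        tx = _perfect_site_transcript(mirna, rng)
        tx = tx[:45] + "A" + tx[45:]  # perturb to force gapped variants
        for aln in find_sites(mirna, tx):
            assert score_alignment(aln.columns) == \
                (aln.penalty, aln.bulge_gap_count)

    def test_single_bulged_site_is_found_with_one_gap(self):
        rng = np.random.default_rng(4)
        mirna = random_seq(rng, 21)
        site = rc(mirna)
        bulged = site[:10] + "A" + site[10:]  # extra transcript base
        tx = random_seq(rng, 50) + bulged + random_seq(rng, 50)
        sites = find_sites(mirna, tx)
        best = min(sites, key=lambda a: a.penalty)
        assert best.bulge_gap_count == 1
        assert best.penalty <= 2.0

    def test_transcript_shorter_than_mirna_is_an_error(self):
        with pytest.raises(ValueError):
            find_sites(MIRNA, "ACGT")


class TestCalling:
    def _aln(self, penalty, bg=0):
        from oryzamir.targets import TargetAlignment
        return TargetAlignment(mirna=MIRNA, transcript_id="t",
                               site_start=0, site_end=21, columns=[],
                               penalty=penalty, bulge_gap_count=bg)

    def test_penalty_boundary_four_is_valid(self):
        assert call_targets([self._aln(4.0)]) != []

    def test_penalty_above_four_is_invalid(self):
        assert call_targets([self._aln(4.5)]) == []

    def test_two_bulges_invalid_even_with_low_penalty(self):
        assert call_targets([self._aln(3.0, bg=2)]) == []


class TestDegradome:
    def _setup(self, peak_offset=0, peak_count=30, background=0):
        rng = np.random.default_rng(5)
        mirna = random_seq(rng, 21)
        tx = _perfect_site_transcript(mirna, rng, flank=60)
        aln = next(a for a in find_sites(mirna, tx) if a.penalty == 0.0)
        # canonical cleavage: transcript base opposite miRNA position 10
        tpos = {mi: ti for (mi, ti, _) in aln.columns}
        cleavage = tpos[9] + peak_offset
        reads = {}
        if peak_count:
            reads[tx[cleavage:cleavage + 20]] = peak_count
        if background:
            for i in range(20, len(tx) - 20, 11):
                seq = tx[i:i + 20]
                reads[seq] = reads.get(seq, 0) + background
        return aln, tx, reads

    def test_peak_at_canonical_position_confirms(self):
        aln, tx, reads = self._setup()
        assert degradome_confirm(aln, tx, reads).degradome == "confirmed"

    def test_uniform_background_without_peak_is_unconfirmed(self):
        aln, tx, reads = self._setup(peak_count=0, background=2)
        assert degradome_confirm(aln, tx, reads).degradome == "unconfirmed"

    def test_peak_three_nt_off_canonical_is_unconfirmed(self):
        aln, tx, reads = self._setup(peak_offset=3)
        assert degradome_confirm(aln, tx, reads).degradome == "unconfirmed"

    def test_no_degradome_data_is_untested(self):
        aln, tx, _ = self._setup()
        assert degradome_confirm(aln, tx, None).degradome == "untested"

    def test_peak_below_two_reads_is_unconfirmed(self):
        aln, tx, reads = self._setup(peak_count=1)
        assert degradome_confirm(aln, tx, reads).degradome == "unconfirmed"


class TestOnSyntheticStudy:
    def test_true_targets_recovered_and_confirmed(self, study, study_result):
        truth = study.truth
        name_of = {l.mature: l.name for l in truth.loci}
        pred_by_locus = {}
        loci_names = {l.name: l.mature for l in study_result.loci}
        for name, aln in study_result.targets:
            pred_by_locus.setdefault((loci_names[name], aln.transcript_id),
                                     aln)
        for locus_name, tid, cleavage in truth.true_targets:
            t = next(l for l in truth.loci if l.name == locus_name)
            key = (t.mature, tid)
            if t.mature not in {l.mature for l in study_result.loci}:
                continue  # locus itself not predicted (filtered as TE)
            assert key in pred_by_locus
            aln = pred_by_locus[key]
            assert aln.penalty <= 4.0
            assert aln.degradome == "confirmed"
            assert aln.cleavage_peak == cleavage
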