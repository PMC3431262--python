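# Methods

## Scope and model

`oryzamir` re-implements, at desk scale, a plant small-RNA analysis that
annotates miRNA loci de novo from sequenced reads and then characterizes
them: family membership, biogenesis class against Dicer/RdRP knockdown
libraries, penalty-scored targets with degradome confirmation, exact
count-based stress-regulation calls, and a relaxed second pass for
transposon/repeat-derived loci. A first-class synthetic-data generator
produces genomes, read libraries, and ground truth with the statistical
structure the analysis assumes, so every stage is testable end to end
without external downloads.

## Locus prediction

Unique reads (collapsed from clean 18-30 nt reads, with reads matching
annotated repeats/rRNA/tRNA/snRNA/snoRNA removed, mapped to the genome by
perfect match, and purged of reads with more than 20 genomic hits at up
to 2 substitutions) seed precursor candidates when their pooled count
reaches 10. Around every anchor hit, segments with one end 20 nt beyond
the anchor on either side and lengths 100-300 nt (step 20) are folded to
their minimum-free-energy structure; a candidate is accepted when all
five criteria hold:

1. MFE <= -35 kcal/mol;
2. <= 4 miRNA/miRNA* duplex mismatches;
3. <= 1 asymmetric bulge, of size <= 2 nt;
4. sense:antisense mapped counts >= 5:1;
5. reads in the miRNA and miRNA* regions (each padded 2 nt) carry >= 75%
   of the segment's counts.

Overlapping accepted segments on a strand merge into one locus; the
precursor is chosen by highest putative-miRNA count, then lowest MFE,
then shortest length, then leftmost start. The mature is the most
abundant precursor read residing in a duplex satisfying criteria 2-3
(ties break to the lexicographically smaller sequence); the star spans
the partners of the mature's terminal paired bases shifted to the
canonical 2-nt 3' overhangs.

Numerical and procedural choices:

* **Folding engine.** ViennaRNA MFE folding at 37 °C, default parameters,
  MFE structure only. Thermodynamic engines differ by ~1-2 kcal/mol on
  these segments, small against the -35 threshold; the engine is recorded
  in the run manifest.
* **Segment sides.** "One end 20 nt away on one side" is ambiguous; both
  sides are enumerated (a superset), and precursor selection collapses
  duplicates.
* **Duplex accounting.** Symmetric internal loops count as mismatches;
  an asymmetric unpaired run counts as one bulge of its excess length;
  unpaired duplex ends count as mismatches; a mature footprint that pairs
  only within itself (or not at all) fails criterion 2 outright.
* **Criterion denominators.** Strand bias uses read multiplicities, with
  zero antisense reads counting as an infinite (passing) ratio. The
  precise-cleavage denominator is restricted to sense-strand reads;
  antisense reads are judged by criterion 4. Both criteria are evaluated
  against *every* mapped unique read, including reads the repeat and
  copy-number filters excluded from anchoring — otherwise a segment whose
  sense reads were filtered away would spuriously pass strand bias on its
  surviving antisense reads.
* **Inverted-repeat pre-screen.** Before folding, a segment must contain
  a window within len/3 mismatches of the anchor's exact reverse
  complement. Any duplex that could pass criterion 2 (<= 4 mismatches,
  G:U pairs allowed) implies such a window; the margin (7 of 21)
  accommodates several wobbles. This skips folding of segments anchored
  in single-stranded sequence (loop fragments, contamination) and is the
  main reason the pipeline runs at desk scale. Heavily G:U-paired duplexes
  beyond that margin would be missed; the screen is a heuristic, not part
  of the annotation criteria.
* **Anchor pooling.** The count>=10 anchor rule pools the four stress
  libraries; a per-library mode is available
  (`anchor_count_per_library`).

## Families and novelty

Mature distance is the minimum, over ungapped overlap alignments with
overlap >= min(len)-2, of substitutions plus unaligned shorter-sequence
positions; families are single-linkage components of the <=2-mismatch
graph. A cluster inherits the family of the closest known mature within
2 mismatches, otherwise a sequential `fam-NNN` label (members sorted
deterministically first). Locus novelty: `known-locus` on genomic
overlap with a known locus, `new-homolog` on mature similarity only,
else `novel`.

## Biogenesis validation

Expression is normalized to TPTM (count/depth x 1e7). A locus validates
when max TPTM over WT and the three knockdowns is >= 50 and, for at
least one DCL knockdown, DCL/WT < 0.5, DCL/RDR2 < 0.5, and RDR2/WT
> 0.5 (conditions 2-3 must hold for the same DCL library). Class follows
the qualifying knockdown (DCL1 -> cmiRNA, DCL3 -> lmiRNA); when both
qualify, mature length (21 vs 24 nt) decides, then the smaller ratio.
Zero WT expression leaves ratios undefined and the locus unvalidated
(conservative). AGO predominance compares within-library-normalized
AGO1a/b/c and AGO4a/b/AGO16 sums; equality (including all-zero) is
"none".

## Target prediction

Sites are found by exhaustive antiparallel alignment of the mature
against each transcript with at most one bulge (unopposed miRNA base) or
gap (extra transcript base), pre-filtered at penalty <= 6 with early
abort. Penalties: mismatch/bulge/gap 1, G:U 0.5, doubled at miRNA
positions 2-13 (1-based from the 5' end; a core G:U therefore costs 1).
An extra transcript base is charged at the following miRNA position's
region. Valid targets have penalty <= 4 and fewer than 2 bulges+gaps.
Degradome confirmation requires a 5'-end pile-up of >= 2 reads at the
transcript position opposite miRNA position 10 or 11 that is the maximum
within the site +-20 nt; the full category system of dedicated degradome
tools is out of scope.

## Differential expression

For counts x, y in libraries of depth N1, N2 the Audic-Claverie mass
p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)) — algebraically
NB(r = x+1, p = N1/(N1+N2)) — is summed directly in log space for both
inclusive tails; the smaller tail is doubled and capped at 1. (With
inclusive tails the p-value is not exactly symmetric under swapping the
two libraries at equal depths — the tails shift by one point mass; tests
assert the true factor-2 agreement.) Tails below float resolution clamp
to the smallest positive double. A miRNA is called stress-regulated when
max TPTM >= 100 in either library, |log2 ratio| > 1 (strict), and
p <= 0.01; no multiple-testing correction by default (Benjamini-Hochberg
behind a flag). For the ratio only, a zero count is replaced by one
read's TPTM in that library; both-zero pairs are excluded.

## Transposon/repeat pass

Reads excluded from the first pass by the repeat filter (confirmed
against the repeat library by the best ungapped local alignment —
maximum-scoring segment at +1/-1 — with alignment length >= 80% of the
read and identity >= 80% over the alignment) or by the copy-number
filter (> 20 hits at <= 2 mismatches) become anchors for a second,
otherwise unchanged prediction pass. Accepted loci take the class of the
repeat annotation with greatest precursor overlap (ties: larger overlap,
then alphabetical); loci overlapping a first-pass locus on the same
strand are dropped, so the two sets are disjoint.

## Synthetic data generator

The generator emulates: four stress libraries (control/drought/cold/
salt) whose per-locus expectations scale with configured fold changes;
four biogenesis libraries (WT, dcl1, dcl3, rdr2) scaled by knockdown
factors (cognate Dicer 0.1, RDR2 1.0 by default); AGO pulldown count
tables (21-nt loci load AGO1a/b/c, 24-nt loci AGO4a/b/AGO16); and
degradome reads, 20 nt on the transcript sense strand starting exactly
at the programmed cleavage site (opposite miRNA position 10).

Hairpin loci are stem-loops: arm + loop + reverse-complement arm, with
configurable arm length (default 60-90 nt), loop (10 nt), mature 21 or
24 nt. Two G:U wobbles (one per mature half) keep the stem paired while
breaking the sequence palindrome, so locus reads map to a single strand
as real loci do; designed duplex mismatches substitute non-pairing bases
opposite the mature; stem mismatches sit outside the duplex. Arm GC
content is adjustable — A/U-only short stems give hairpins marginal
against the -35 kcal/mol threshold. A `near_miss` flag builds loci
violating exactly one named criterion for boundary tests. MITE-like
loci reuse one full-element consensus hairpin per family (the element's
terminal inverted repeats are the stem), which also populates the repeat
library and the genomic repeat annotation.

Reads are drawn multinomially from expected species proportions, so each
library's total equals its configured depth exactly. Species per locus:
mature and star with independent +-1-2 nt end shifts at the configured
cleavage-noise rate (P(0)=1-noise, P(+-1)=0.3 noise, P(+-2)=0.2 noise),
loop-background reads at fixed positions, antisense copies of the
mature, and ncRNA/repeat decoy fragments as contamination. Expected
per-locus counts are defined as rates against a fixed control-library
normalization, so configured fold changes and knockdown factors are
reproduced exactly in expectation even though sampled library
compositions renormalize (a real compositional effect the tests
tolerate). Defaults: depth 1e5 reads/library, cleavage noise 0.1,
contamination 0.1, antisense 0.02, background 0.05, star:mature 0.25 —
chosen as typical of deeply sequenced plant small-RNA libraries in which
the exact mature dominates its isoforms and structural ncRNA
contamination survives gel excision at the few-percent level.

What the generator does *not* emulate: sequencing error and quality
scores, realistic chromosome composition (background is i.i.d. uniform),
multi-locus families with divergent copies, GU-rich natural duplexes,
expression-dependent star ratios. Passing tests therefore demonstrate
algorithmic correctness under the stated statistical assumptions, not
performance on real libraries.

## Problem sizes and determinism

Tests and the reproduction script run on 20-200 kb genomes with up to 30
loci and 1e5-read libraries — sizes chosen so a full run completes in
minutes on one core while every boundary is still exercised on both
sides. All randomness flows from a single integer seed per run
(numpy Generator); fixed seeds give byte-identical genomes, libraries,
and results. The boundary screens (`oryzamir.screens`) isolate one
criterion each by switching other noise sources off; the parameter-
recovery screen uses the full default noise model.

## Known limitations

* The repeat/ncRNA read filter is exact substring containment; the
  fraction of reads it removes on real data depends on the annotation
  sets and is not calibrated here.
* The inverted-repeat pre-screen can skip duplexes with more than ~7
  combined wobbles/mismatches against the exact reverse complement.
* Loci closer than one segment length can merge into a single locus.
* The target-site search is exhaustive and quadratic; it is meant for
  desk-scale transcript sets, not whole transcriptomes.
* Degradome confirmation implements only the canonical-position peak
  test, not transcript-abundance-normalized categories.
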