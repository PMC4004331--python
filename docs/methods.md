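# Methods

This note documents the models, rules and numerical choices implemented in
`gutcrispr`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Coordinates and sequences

All intervals are 0-based half-open on the contig plus strand; GFF3,
BLAST tabular and the prediction-exchange TSV are converted at the I/O
boundary and nowhere else. Sequences are upper-case over {A,C,G,T,N}. `N`
never counts as a match in any comparison — including `N` vs `N` — which
makes every mismatch count conservative. Spacer identity questions
(uniqueness, sharing) use the canonical form min(s, revcomp(s)), because
cassette strand is frequently unknown; a strand-sensitive convention would
split counts for unoriented cassettes arbitrarily.

## Cassette calling

**Merging.** Predictions on one contig are grouped single-linkage when
their array intervals reciprocally overlap ≥50 %. The defining prediction
of a candidate is the member with the most repeat copies (ties: longest
array, then leftmost); union intervals are kept only for bookkeeping,
since averaging would blur repeat boundaries.

**The three rules.** Rule 1 accepts candidates reported by CRT,
CRISPRFinder and PILER-CR simultaneously. Rule 2 accepts one- or
two-program candidates with a cas gene within the adjacency window
(default 2,000 nt between the gene and the array interval, either side,
any strand; "adjacent" has no published numeric window, and typical cas
loci sit directly beside their arrays, so 2 kb is generous but still
local). Rule 3 accepts remaining candidates whose repeat consensus falls
in the same repeat cluster as an accepted cassette, iterated to a fixed
point so chains of similarity resolve. Rules are assigned with priority
1 > 2 > 3 and the filter is monotone in the cas annotations: adding a cas
gene can only grow the accepted set.

**Completeness.** A cassette is *complete* when at least 100 nt of
non-cassette sequence flank it on both sides; 100 nt is the same flank
constant the pseudospacer fallback rule uses, and completeness gates the
orientation-dependent position test.

**Built-in detector.** `detect_arrays_builtin` chains exact 16-mer seed
repeats at admissible periods (repeat 21–48 nt, spacer gap 20–80 nt,
≥3 copies) and extends each chain to the maximal repeat shared by all
copies. It exists so that synthetic end-to-end runs need no external
detector; it assumes near-exact repeat copies and is not a substitute for
the dedicated programs on real data, where the simulated-detector path
(`emit_detector_predictions`) or ingested predictions should be used.

## Repeat clustering and orientation

Two consensus repeats are linked when a word-seeded ungapped local
alignment on either strand reaches ≥50 % identity over a span covering
≥50 % of the longer sequence, with word size 15 (the BLASTCLUST parameter
set `-L 0.5 -S 50 -W 15` read as length-coverage 0.5, identity 50 %,
word 15; the identity reading of `-S` is an interpretation — score-based
similarity is the alternative). Extension uses +1/−2 match/mismatch
scoring, appropriate for short near-equal-length repeats; the test suite
bounds this heuristic with an exhaustive seed-and-extend oracle. Clusters
are connected components (single linkage), invariant to input order.

Orientation proceeds in two stages. A cassette with a cas gene in the
adjacency window takes its leader at the end nearest the cas locus — the
weakest defensible reading of "proper orientation", since the original
rule is not defined numerically; a strict mode additionally requires the
gene to be transcribed toward the cassette. Unoriented cluster members
then inherit orientation from oriented members by comparing repeat strand
(forward vs reverse-complement alignment score); conflicting evidence
leaves a cassette unoriented rather than guessing. Orientation is
idempotent, and serials renumber as n+1−i for right-leader cassettes.

cas system types use the signature mapping cas3→I, cas9→II, cas10→III;
cas1/cas2 are universal and uninformative, and conflicting signatures
yield `unclassified` with the evidence listed.

## Protospacer discovery

The default matcher is exact: every window at full spacer length on both
strands, mismatches ≤4 over the entire length. It is implemented with
pigeonhole seeding (a window within m mismatches must contain one of m+1
query chunks exactly), which is provably equivalent to the naive scan —
the suite verifies this against a quadruple-loop oracle on randomized
planted instances. This removes the word-size edge artifact that seeded
aligners have on short queries; BLAST tabular ingest plus full-length
extension is retained for interoperability, with gapped raw hits rejected
(mismatch-over-full-length is an ungapped notion) and extensions that
would run past a contig end rejected rather than truncated.

Windows overlapping any accepted-or-candidate cassette interval are never
counted as protospacers (this includes each spacer's own locus); rejected
candidates are masked too, since they may be genuine arrays that merely
failed the program-consensus test.

**Repeat-contamination filter.** For each hit, the repeat consensus of
the spacer's cassette is scanned against the hit's target contig with a
mismatch budget of ⌈0.15 × repeat length⌉ (~the 4/27 ratio of the spacer
threshold; no published constant exists). A repeat match on the same
contig (outside known cassette intervals) marks the hit as a likely
undetected cassette and fails it; only passing hits are *reliable*.

**Pseudospacer null.** Each spacer is replaced by a random same-length
fragment drawn uniformly from the cassette-free part of its own contig;
when both non-cassette flanks of the contig are shorter than 100 nt the
fragment comes from a random cassette-free contig of the same individual.
Pseudospacer hits to the very window the fragment was drawn from are
discarded as self-matches. Each surviving pair is then checked for
gene-homology context: the pseudospacer's flanks, at the repeat length of
its cassette, are scanned against the pair's target with the same 15 %
budget, and any flank match discards the pair. A flank truncated by a
contig end is used if at least half the repeat length remains, else
treated as non-matching (a shorter fragment cannot support a reliable
match decision).

**PAM scan.** Reliable hits are grouped by repeat cluster; for each group
and flank side the 10-nt flanks are anchored at the protospacer boundary
and per-position information content is computed as 2 − H bits with the
first-order small-sample correction 3/(2·ln2·n) subtracted by default.
The correction matters: a 2-of-3 majority column already carries 1.08 raw
bits, so uncorrected tiny groups fabricate motifs. A motif is reported
only when ≥2 consecutive positions each reach 1.0 bit and the group has
≥3 flanks. On unstructured synthetic data the expected report is "no
reliable PAM" everywhere; isolated all-identical columns in groups of
exactly 3 hits can still slip through, so motifs from minimal groups
should be treated as suggestive only.

## Permutation statistics

All Monte-Carlo p-values use the plain fraction k/n of as-or-more-extreme
permutations (ties inclusive, hence conservative); the (k+1)/(n+1)
variant is available on every result object. All draws derive from an
explicit seed.

**Position test.** Eligible cassettes are complete, oriented, and carry
≥1 flagged spacer. The statistic is the sum of serial-from-leader over
flagged spacers; the null redraws each cassette's flagged positions
uniformly without replacement, keeping the per-cassette flag count fixed.
Lower tail for targeting spacers (recent acquisitions sit near the
leader), upper tail for shared spacers (older material drifts to the
trailer). Exact small-case enumeration and calibration studies (power
≥95 % under leader-biased planting; type-I error 5 % ± 1.5 points under
unbiased planting) back the implementation; the calibration replicates
draw flags with the community generator's own placement rule without
rendering sequences, which leaves the statistic's inputs unchanged while
making 1,000 replicates affordable.

**Sharing test.** The assignment vector cassette→individual is permuted
(per-individual cassette counts are automatically preserved); the
statistic counts distinct canonical spacer sequences present in ≥2
individuals. Note the synthetic generator plants sharing by copying
sequences *across* individuals, so the planted observed count is the
maximum achievable and the lower-tail p is 1 by construction; depletion
of sharing (the interesting real-data direction) would need within-
individual duplication structure the generator does not emulate.

**CMH test.** Strata are individuals; each spacer–protospacer *pair* (not
unique spacer) is classified per stratum. Degenerate strata (a zero
margin) contribute nothing to either sum. Both the uncorrected and the
0.5-continuity-corrected forms are implemented; the implementation is
verified against R's `mantelhaen.test` on frozen cases. The permutation
null shuffles the multiset of protospacer-individual labels over pairs,
which leaves every stratum's margins invariant — so only the summed
diagonal count varies, and the permuted statistic is recomputed from that
count against fixed expectation and variance terms (an exact algebraic
shortcut, unit-tested against full recomputation).

**Majority-foreign count.** Over individuals whose spacers have ≥1 pair,
those whose foreign-protospacer pairs strictly outnumber same-individual
pairs; reported with both denominators (eligible individuals and the
whole cohort) since the choice is ambiguous.

## Synthetic communities

Defaults: 12 individuals × 6 bacterial contigs (6–12 kb) + 2 phage
contigs (5–10 kb); 30 cassettes (repeats 24–48 nt, spacers 25–70 nt, 4–12
spacers each); 60 planted protospacer instances with mismatch
distribution {0: .35, 1: .2, 2: .15, 3: .1, 4: .1, 5: .1} (mass above the
threshold deliberately exercises the 4-mismatch boundary); 5 % of spacers
copied into another individual's cassette; leader bias 0.5 (planted
serial ∝ e^−0.5·serial); half the cassettes get a cas locus within 500 nt
of the leader end. Sizes are chosen so a desk-scale run finishes in
seconds while every statistic has enough events to be testable.

Background sequence is i.i.d. uniform ACGT, so chance full-length
≤4-mismatch matches at spacer length ≥25 have probability ~10⁻⁹ per
window and the truth manifest accounts for every recovered feature.
Phage contigs never carry cassettes, keeping protospacer space disjoint
from cassette space. At most one cassette is planted per contig —
distinct arrays are not observed to share an assembled contig, and a lone
cas locus then orients its own array unambiguously. Repeat copies within
an array are exact by default. Decoy regions (tandem repeats and
periodic low-complexity units at realistic 25–40 nt gaps) are recorded as
negative examples; the simulated detectors report them with per-program
rates (CRT and PILER-CR high, CRISPRFinder low), so a decoy occasionally
achieves three-program agreement and is accepted — correctly, since the
filter is program-based.

What the generator does **not** emulate: realistic phage genome
architecture, GC content and k-mer composition of gut genomes, read-level
artifacts or assembly errors, repeat degeneracy within arrays (available
as an option but off by default), and within-individual spacer
duplication. Passing tests therefore demonstrate correctness of the
machinery under the stated planting model, not detector performance on
real gut assemblies.

## Cohort manifests

The three dataset manifests bundled under `src/gutcrispr/data/cohorts/`
describe the combined 139-individual cohort (124 + 13 + 2). The 13-member
cohort uses the individual identifiers named in the source study's
results (F1T, F2W, F2X, F2Y, INA, INB, INE, INM, INR) completed with
placeholder ids to the stated family structure (two families of 3 and 4,
six unrelated); the 124-member cohort uses generated ids (HMP001–HMP124)
as no per-individual identifiers are published.

## Known limitations

- The exhaustive matcher cannot reproduce the exact hit lists of a
  BLASTN-based search whose word size and E-value cutoff are unknown; it
  is a superset at the stated mismatch threshold.
- The taxonomy rule engine formalises a partly manual curation protocol
  and may diverge from expert judgment on edge cases (ties, mixed ranks).
- The repeat-link heuristic (seeded extension) can in principle miss a
  qualifying low-identity alignment whose score-maximal core is shorter
  than the coverage requirement; the DP oracle in the tests bounds this
  on the length/divergence regimes that matter for 24–48 nt repeats.
- Golden-number checks that require the study's supplementary
  per-individual pair matrix run only when that table is supplied (see
  README); the statistics they exercise are fully unit-tested against
  independent oracles regardless.
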