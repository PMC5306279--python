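# Methods

## Coordinate contract

All coordinates are 1-based inclusive on the forward strand of each replicon,
the convention of GFF3 and of published genomic positions. Antisense
transcripts are strand `-` intervals on the same axis; sequences are
reverse-complemented only when nucleotide strings are extracted. BED6 I/O
converts to/from 0-based half-open at the file boundary and nowhere else.
Fragment lengths between a TSS and a 3′ end are inclusive (|end − start| + 1);
this is the only convention that reproduces both published fragment lengths
(122 nt and 83 nt) from their genomic end positions, and it is applied
consistently to interval lengths everywhere.

## Preprocessing

Adapter trimming is exact prefix matching: the read is truncated at the
leftmost position where a prefix of the 3′ adapter (≥ 5 nt) matches and runs
to the read's end, or where the full adapter occurs. Exact matching is chosen
over error-tolerant alignment because it is deterministic and checkable
against a brute-force oracle; sequencing kits differ and no published
algorithm is being reproduced. A consequence worth knowing: trimming is not
strictly idempotent — a transcript whose genomic sequence happens to end in
the adapter's first ≥ 5 nt is indistinguishable from an adapter-bearing read
(probability 4⁻⁵ ≈ 10⁻³ per read for the 5-nt minimum), exactly as in
production trimmers. Downstream, the unification tolerance absorbs such
rare end clips.

Read filters: length ≥ 18 nt, then mean Phred ≥ 20, checked in that order so
the rejection report partitions the input ("short" takes precedence). The
28–200 nt size selection of the wet protocol happens on a gel before
sequencing, so no upper length bound is applied to reads; oversize handling
is a flag on transcript units (> 310 nt) instead of a drop.

## Exact-match test mapper

A seed-table index (14-mer seeds over the forward strands) reports every
exact full-length occurrence of a read or its reverse complement; `N` never
matches. A read is *uniquely aligned* iff its total occurrence count across
both strands of all replicons is one, independent of the reporting cap.
This mapper exists so synthetic scenarios run with no external aligner;
mismatch/indel alignment is deliberately out of scope and real libraries
enter as SAM, where the end coordinate is derived from reference-consuming
CIGAR operations (M, D, =, X) and uniqueness from one-record-per-read-id.

## Unification

Within each (replicon, strand), alignments are grouped by exact interval;
groups are ordered by descending multiplicity, ties by leftmost start then
shortest. Sweeping that order, each unabsorbed group seeds a unit and absorbs
every remaining group whose 5′ AND 3′ ends lie within `end_tolerance`
(default 5 nt, per end, separately configurable for the 3′ side — setting the
3′ tolerance very large emulates 5′-anchored merging for dRNA-Seq-style
data). The unit keeps the seed's coordinates: the most abundant boundary is
the best estimate of the TSS/terminus, and min/max spans would grow with
depth. The canonical ordering makes the greedy result invariant under input
permutation; with tolerance 0 units are exactly the distinct intervals.
`read_count` sums absorbed uniquely-aligned reads, `total_count` all absorbed
reads, so both are conserved quantities.

## Classification

One category per unit, first matching rule wins:
rRNA (any-strand overlap) > tRNA (any-strand) > sense-ORF (overlap ≥ 50 % of
the unit's length, configurable) > antisense-ORF (≥ 1 nt) > 5′ LR > IGR.
Structural-RNA contamination must dominate because those reads are removable
background, and antisense must outrank IGR so asRNAs partially overlapping an
ORF are not lost. The sense rule's 50 % floor keeps short 5′ leaders that
brush a start codon from being swallowed as ORF reads. The 5′ LR window is
the 300 nt immediately upstream of the annotated gene start, strand-aware and
inclusive of position start−1 (the annotation carries no UTRs); membership is
by intersection, with a strict-containment switch exposed. Antisense targets
are the maximal-overlap opposite-strand ORF, ties to the leftmost; 5′ LR
associates with the nearest downstream gene. Candidates are AS/IGR/LR5 units
with ≥ 10 uniquely aligned reads (inclusive threshold).

## Differential calling

Matching is greedy one-to-one in descending overlap fraction
(|intersection| / shorter unit length — symmetric and forgiving to boundary
jitter; a reciprocal-overlap option exists), requiring the same replicon and
strand and overlap ≥ 10 %. Greedy one-to-one rather than many-to-many keeps
the summary counts interpretable: each unit contributes to at most one call.
The ratio is HL/NL on raw unique-read counts; "≥ 10 reads under NL or HL" is
read as max(NL, HL) ≥ 10. A matched pair with a zero side is reported as
library-unique rather than an infinite ratio. Counts-per-million
normalization is opt-in (`normalize=True` with library sizes) since raw
read counts are the reported currency. Calls are symmetric: swapping the
libraries maps up↔down and unique_NL↔unique_HL exactly, which the tests
assert. No statistical test is layered on top — the method is a pure
threshold filter and adding one would change what it measures.

## Length statistics

The Gaussian is fitted by sample moments (mean; sd with the n−1 denominator)
rather than least squares on a histogram: moments are bin-width independent
and agree with maximum likelihood up to the variance denominator. The
histogram (default 10-nt bins) is descriptive output only. The replicon
breakdown reports per-replicon counts and a chromosome-vs-plasmids rollup.

## asRNA/target analysis

The antisense map expresses an asRNA in target-CDS coordinates with position
1 at the first base of the start codon counted along the target's strand.
Ends overhanging the CDS clamp to the boundary with `fully_contained=False`;
the reported `length` is always the asRNA's own inclusive length. The motif
scanner expands IUPAC degenerate codes to character classes and reports all
(overlapping) hits via a look-ahead regular expression; DNA input is treated
as its RNA transcript. The RNase E consensus `RAUUW` is provided as a named
shortcut; completeness (all hits, not just the first) is the safer library
contract even when a single site is of interest.

## Synthetic scenarios

The generator emulates the study design at desk scale: a random 200-kb
chromosome plus four 10-kb plasmids (uniform i.i.d. DNA), 75 ORFs, 4 tRNAs
and 2 rRNAs, and 90 planted candidates (60 asRNA / 20 IGR / 10 5′ LR,
preserving the strong asRNA dominance of real cyanobacterial candidate
sets). Placements sit on a block layout with 450-nt gaps and built-in
clearances — asRNAs strictly inside ORF bodies, 5′ LR units strictly inside
their gene's 300-nt window, IGR units > 300 nt from any feature — so every
planted unit has an unambiguous class under the classifier's own rules
(asserted as a cross-module contract test). Candidate-bearing placements go
to a plasmid with probability 0.11, the megaplasmid share reported for NL
conditions.

Unit lengths are drawn from Normal(146, 55) truncated to [18, 310] nt, the
NL-like candidate length distribution. DE statuses are assigned by floor
rounding of the configured fractions (defaults 0.15 up, 0.45 down, 0.15
NL-unique, 0.10 HL-unique, remainder unchanged — approximating the reported
up:down:unique proportions). `depth_per_unit` (default 50 reads) is the
expected coverage in a DE unit's *lower* condition, with the higher condition
at `de_fold` (default 4) times that; anchoring the lower side keeps
down-regulated units above the 10-read candidate floor under Poisson noise,
mirroring how detectable DE pairs look in real candidate sets. Counts are
rounded expectations by default — the noiseless setting under which planted
truth must be recovered exactly — with Poisson sampling as the
`poisson_counts` switch.

Reads are exact genome substrings of the unit interval (reverse-complemented
for strand `-`): a 60 % majority at the exact interval plus 40 % with 0–2 nt
end jitter, so unification sees realistic boundary variation while the exact
interval remains the most abundant (seed) boundary. Each read carries the 3′
adapter (Illumina small-RNA adapter by default, echoed in the manifest) and
uniform Phred-35 qualities. The instrument read length defaults to 350 nt so
reads span the gel-selected ≤ 310-nt size range and unit boundaries are
directly observable; when a unit exceeds the read length, 5′-anchored reads
are emitted instead. Background reads (20–45 nt) are sampled sense-strand
from rRNA/tRNA/ORF features at read fractions 0.27/0.25/0.22, the
NL category breakdown. A per-base error knob exists (default 0 — the exact
mapper then suffices; error-bearing reads require an external aligner).

What the generator does *not* emulate: sequencing errors and quality decay,
GC/ligation bias, rRNA processing intermediates, operon structure and
overlapping genes, and multi-mapping repeats. Passing tests therefore
demonstrate the correctness of the pipeline's logic under its stated
contracts, not robustness to real-library artifacts; on real data the
mapping and trimming stages should come from production tools.

## Problem sizes and determinism

The default scenario (~39 k NL + ~22 k HL reads on a 240-kb genome) runs the
full pipeline in a few seconds; test and acceptance workloads were sized to
stay at that desk scale while keeping every statistical check at the sample
sizes the fitted parameters refer to (n = 5,261 and 3,380 for the length
fits). All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seed and config produce byte-identical
scenario files.

## Known limitations

- Exact-match mapping and exact adapter matching make the built-in stages
  unsuitable for error-bearing real reads (by design; supply SAM).
- The unification contract is a defined greedy procedure, not a
  reconstruction of any particular published implementation; its parameters
  (per-end tolerance) are exposed rather than inferred.
- Classification depends entirely on the supplied annotation; unannotated
  genes surface as IGR candidates.
- The differential filter has no replicate or variance model; calls are
  threshold statements about two libraries, not hypothesis tests.
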