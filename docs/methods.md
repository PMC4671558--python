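# Methods

## The problem and the model

Short-read assemblers cannot phase repeats longer than their reads, so a
draft microbial assembly breaks at every long repeat and may additionally
contain N-gaps (unknown sequence inside scaffolded contigs) and chimeric
joins (false adjacencies). Corrected long reads — kilobase-scale reads with
residual error on the order of 10⁻⁴ — span such repeats. `asmpatch` treats
the draft contigs as trusted sequence, the long reads as long-range
evidence, and joins contigs only where that evidence is unambiguous under
explicit uniqueness margins. The output is always concrete sequence: gaps
are replaced by voted read sequence and junctions are tiled from reads,
never padded with `N`.

## Alignment layer

All stages share one alignment contract: local alignments with 0-based
half-open coordinates, both strands, minus-strand hits stored with both
intervals on the forward strands plus a strand flag, and
`identity = matches / alignment columns` (indels count as columns).

The aligner is a seed-and-extend design for the high-identity regime this
tool operates in (draft contigs and corrected reads, ≥~90 % identity):
exact k-mer anchors (k = 15 by default) are grouped by diagonal (±40 bp,
tolerating the rare indels of corrected reads), chained along the query
(gaps ≤ 400 bp between anchors), extended outward under +1/−3 scoring with
a 50-point x-drop so extension cannot tunnel through unrelated sequence,
and finally realigned globally with edlib to obtain exact columns,
identity, and ragged-end trimming. Hyper-repetitive seeds (>200
occurrences) are dropped. Anchoring can in principle miss alignments whose
identity is so low that no 15-mer survives intact; at the ≥90 % identity
floors used here the probability of an anchor-free 200-bp overlap is
negligible, and the test suite pins behaviour against an exact-DP oracle
on small instances rather than against any particular backend.

A hit is a proper **dovetail** when it reaches within `max_overhang`
(default 50 bp) of exactly one end of each sequence, on strand-consistent
ends (suffix-to-prefix on `+`, like-end-to-like-end on `-`), with at least
`min_overlap` (default 200 bp) aligned columns. **Containment** of A in B
is the unioned fraction of A covered by hits to B together with the
alignment-length-weighted identity; both must strictly exceed 0.95 for A
to be considered redundant. The overhang, overlap and per-stage identity
floors (0.95 contig-vs-contig, 0.90 when a read is involved) are not fixed
by the published procedure; they are exposed in `PatchConfig`.

## Stage 1 — modification

*Gap filling.* A gap is a maximal N-run; gaps whose 100-bp flank is
truncated or contains `N` are skipped. Flanks are searched in each long
read exactly first, then by alignment at ≥90 % identity (edlib infix
search) — corrected reads rarely need the fallback, raw ones do. The gap
is replaced only when the most frequent inter-flank sequence occurs at
least 3 times (the ">2" rule) and strictly more often than the runner-up;
a tie has no unique maximum and leaves the gap untouched. Gaps are
processed right-to-left so coordinates stay valid, and every replacement
is logged (interval, votes, length).

*Zero-coverage splitting* (only when raw short reads are given). Reads are
mapped to the gap-filled contigs at every placement achieving their
minimal edit distance, so reads tied across repeat copies contribute depth
at all best placements and repeats do not become false zero-coverage
holes. The default placement threshold is 0 edits: the short reads serve
as binary evidence of support, and a read that does not match exactly is
not evidence (raise `max_read_edits` for error-prone read sets — at the
default the mapper reduces to exact multi-placement seeding). Two kinds of
unsupported position are cut: maximal zero-depth base runs are excised
(their bases have no evidence), and *bonds* between adjacent bases that no
single read spans are cut without removing bases. The bond rule matters
because a false junction can appear "covered" when one read ends exactly
at it and another starts exactly on it; only span coverage distinguishes a
supported position from a coincidence of read boundaries. Positions inside
the terminal `1 %` of the contig are exempt — coverage tapers to zero at
sequence ends for purely geometric reasons — and split products shorter
than 50 bp are discarded. All events are logged so the original contig can
be reconstructed from kept + discarded + excised intervals.

## Stage 2 — selection

When a genome size is supplied, reads are first subset to the longest ones
whose cumulative length reaches 15× the genome size (the read crossing the
threshold is included); otherwise all reads enter the pool. Selection is
greedy longest-first (ties broken by id): the longest remaining sequence
becomes a representative, every remaining sequence >95 %-contained in it
(both conditions strict) is removed and recorded in the delineation map,
and the process repeats. Only removed-vs-representative containment is
recorded; chains collapse to the final representative. The invariants
|representatives| + |delineated| = |input| and idempotence on the
representative set are asserted by tests.

## Stage 3 — connection

The driver runs: (a) strict bridging to a fixpoint, re-aligning the pool
after every application round so connected products can chain; (b) repeat
estimation; (c) easy bridging to a fixpoint; (d) rescue of delineated
reads followed by easy bridging; (e) direct merging of reciprocal-unique
dovetails; then (b)–(d) repeat until an iteration changes nothing.

*Strict bridging.* Every pool sequence is a candidate bridge. At each of
its two ends the end-overlaps are ranked by length; the best must be at
least 1.25-fold the second best (inclusive), both ends must resolve, to
two distinct targets, at least one of which plays the contig role.
Connected products inherit the contig role — they contain contig content
and the procedure explicitly reuses them as candidates. Self-resolving
bridges (circularisation) are logged and skipped; circular closure is out
of scope.

*Application order and geometry.* Bridges apply longest-bridge-first
within a round; a bridge whose record or targets were already consumed is
skipped and the next round re-evaluates. Geometry is resolved in the
bridge-forward frame: the left target is oriented to end at the junction,
the right to start at it; disjoint target alignments on the bridge insert
the intervening bridge substring, overlapping ones trim the overlap from
the shorter target once. Unaligned overhangs (≤ 50 bp) at junctions are
dropped as unsupported. Every product records a tile layout
(source id, interval, strand) whose concatenation reproduces the product
byte-exactly — the traceability invariant the tests assert on every run.

*Repeat bound and easy bridging.* The maximal repeat is the longest
alignment in the pool's all-vs-all self-alignment that is neither a
dovetail nor part of a containment pair, including non-trivial self hits
(internal and inverted duplications) — a conservative reading that raises
the easy-bridge gate. A read qualifies for easy bridging iff it is longer
than this bound and each end has exactly one contig partner, the two
partners distinct; overlaps to other reads do not disqualify a candidate
(the ambiguity that matters is between target contigs). Rescued delineated
reads pass through the same gates. The final merge joins two sequences
directly when their dovetail is longer than the repeat bound, unique by
the same 1.25-fold margin at both ends, and reciprocal (each end's unique
best is the other) — preventing repeat-induced star merges.

Unused reads are evidence, not assembly content: they are dropped from the
output (a config flag emits them to a side file). Termination is
guaranteed because every applied join removes at least one sequence from
the pool. Tie-breaks are fixed everywhere (overlap length desc, identity
desc, id lexicographic), so identical inputs and configuration produce
byte-identical outputs.

## Synthetic scenarios

The generator emulates the target data regime, with defaults that define
the reference study conditions: a 200-kb uniform-random genome; three 4-kb
repeat families, two copies each, mutated by substitutions to 98 %
identity and placed ≥12 kb apart (so inter-repeat contigs are well longer
than the bridging reads' overlap needs); the draft cut at every repeat
copy with repeat interiors withheld (what a short-read assembler cannot
resolve); one 300-bp N-gap masked mid-contig; one chimera concatenating
two non-adjacent fragments; 15X long reads with normal lengths
(mean 8 kb, sd 1.5 kb, truncated at 500 bp), uniform starts and strands,
and substitutions/indels each at 10⁻⁴ per base; and 20X error-free 100-bp
single-end short reads drawn uniformly from the genome, which guarantees
zero span-coverage at false junctions by construction. All randomness
derives from one seed through fixed per-component child streams
(NumPy `SeedSequence`), so adding reads never perturbs the genome.

What the generator does **not** model: raw long-read error profiles
(~15 % CLR error), quality values, GC/coverage bias, tandem or nested
repeats, plasmids and circular replicons. Passing tests therefore show the
algorithmic machinery is correct under the stated regime, not that the
tool is robust to uncorrected reads or heavily biased libraries.

The mis-join checker asserts two properties against the true genome: every
layout-tile junction, with 200 bp of context per side, must occur in the
genome (either strand) within 20 edits, and every output sequence must be
collinear with a single genomic locus within an edit budget of 1 % of its
length + 100 (covering repeat-copy divergence and read errors at inserted
junctions).

## Problem sizes and numerical choices

The test suite runs the reference scenario once (~40 s on one core) and
uses 40–60-kb variants of the same conditions for pipeline, determinism
and CLI checks; oracle-equivalence tests use 50 constructed pools of up to
~20 sequences ≤5 kb and 500 random dovetail geometries. Degenerate inputs
are defined: empty alignments return empty results, an empty bridge list
leaves the pool unchanged, a gap with insufficient votes is left in place,
a pool of one sequence is its own representative, and degenerate bridge
geometry (trim exceeding a target's aligned span) skips the bridge with a
log entry rather than emitting truncated sequence.

## Known limitations

* Circular genomes are not closed; a self-bridge is detected and logged.
* Gap filling takes the most-voted inter-flank string verbatim; no
  consensus polishing is applied inside filled gaps or at junctions, so
  single read errors can enter the output (the corrected-read error rate
  bounds this at ~10⁻⁴).
* Repeat-size estimation sees only the pool's internal evidence; a repeat
  family absent from contigs and unsampled by reads is invisible to the
  easy-bridge gate.
* The coverage mapper is designed for the exact-evidence regime; for
  error-prone short reads, raise `max_read_edits` and expect junction
  penetration of up to that many bases.
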