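# asmpatch

Upgrade draft microbial genome assemblies using corrected long reads.

Short-read assemblies of microbial genomes are routinely left in dozens of
pieces by long repeats and uneven coverage. Corrected PacBio long reads
(CPBLRs) — kilobase-scale reads whose residual error has been reduced to
~0.01 % by short-read or unitig correction — carry exactly the long-range
information needed to finish such drafts. `asmpatch` consumes a draft
assembly plus CPBLRs (and optionally raw short reads) and improves the
assembly in three stages:

1. **Assembly modification.** Every run of `N` inside a contig is a gap.
   The 100-bp flanks of each gap are located in the long reads; reads
   containing both flanks span the gap, and the gap is replaced by the
   inter-flank sequence that occurs most often — only if it occurs more
   than twice and strictly beats the runner-up. If raw short reads are
   supplied they are mapped back to the gap-filled contigs and contigs are
   split wherever a position has no read support (zero coverage, including
   base-to-base junctions no read spans), except within the terminal 1 % of
   the contig; split products shorter than 50 bp are discarded. This
   removes chimeric joins.
2. **Representative selection.** Contigs and the longest 15X of the CPBLRs
   (when a genome size is given) are pooled. The longest sequence is taken
   as a representative; every sequence whose major portion (>95 % alignment
   rate *and* >95 % identity) is found in it is removed, remembering which
   representative absorbed ("delineated") it. Repeat until the pool is
   empty. Run with `--mode redundancy_only` this stage alone de-duplicates
   an over-assembled draft.
3. **Iterative connection.** Representatives are self-aligned all-vs-all
   and proper end-to-end (dovetail) overlaps are classified. *Strict
   bridging* joins two sequences through a third whose best end overlap at
   each end is at least 1.25-fold longer than the second best (unique by
   margin), with at least one target a contig. After strict bridging, the
   maximal repeat size is estimated from the remaining non-dovetail,
   non-containment alignments; *easy bridging* then joins exactly two
   contigs through a CPBLR longer than that bound with one clean partner
   per end. Delineated reads are rescued as bridging candidates before
   their unusable representative is discarded, reciprocal-unique dovetails
   longer than the repeat bound are merged directly, and the easy-bridging
   loop repeats until nothing changes. Joins insert real read sequence —
   never `N` — and trim target overlaps once.

Every output sequence carries a layout of source tiles, so each base traces
back to an input contig or read.

## Worked example

The built-in scenario generator simulates the regime the tool targets:
a 200-kb genome with three 4-kb repeat families (two copies each, 98 %
identity) that fragment the draft into seven contigs, one 300-bp N-gap,
one chimeric mis-join, 15X long reads (mean 8 kb, 10⁻⁴ error) and 20X
error-free 100-bp short reads:

```python
from asmpatch import SimScenario, write_scenario
paths = write_scenario(SimScenario(seed=1), "demo")
```

```bash
asmpatch --assembly demo/draft.fasta --long-reads demo/cpblr.fasta \
         --reads demo/reads.fastq --genome-size 200000 -o demo/out
```

prints

```
6 -> 1 sequences; N50 29460 -> 200001
```

i.e. the six draft records (the chimera fuses two of the seven fragments)
are rebuilt into a single 200-kb sequence: the gap was filled with the
exact masked sequence, the chimera was split at its unsupported junction,
and the repeat-broken fragments were re-connected by bridging reads with
zero mis-joins against the simulation truth (`demo/out/` contains the
patched FASTA, an AGP-like layout, join and delineation logs, before/after
statistics and a replayable manifest).

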