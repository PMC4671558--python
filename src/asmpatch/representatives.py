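"""Stage 2 — representative sequence selection (redundancy removal).

Contigs and corrected long reads are pooled; the longest sequence is taken
as a representative and every pooled sequence whose major portion
(>95 % alignment rate *and* >95 % identity) is found in it is removed.
The longest survivor is selected next, and so on until the pool is empty.
Removed ("delineated") sequences remember which representative absorbed
them — they can be re-instated later as bridging candidates.

When a genome size is known the long reads are first subset to the longest
15X so selection does not wade through redundant coverage.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

from .alignment import align, containment
from .sequence_io import SeqRecord

log = logging.getLogger("asmpatch")


@dataclasses.dataclass
class RepresentativeSet:
    representatives: list[SeqRecord]          # in selection order
    delineated: dict[str, str]                # removed id -> representative id
    removed_records: dict[str, SeqRecord]     # full records of removed seqs
    table: list[tuple[str, str, float, float]]  # id, rep id, rate, identity


def subset_cpblrs(cpblrs: Sequence[SeqRecord],
                  genome_size: int | None = None,
                  depth_factor: float = 15.0) -> list[SeqRecord]:
    """The longest reads summing to ``depth_factor`` times the genome size.

    Without a genome size all reads are kept.  Reads are taken longest
    first until the cumulative length first reaches the threshold (the
    read crossing it is included); if the total falls short, all are kept.
    """
    if genome_size is None:
        return list(cpblrs)
    if genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    target = depth_factor * genome_size
    ordered = sorted(cpblrs, key=lambda r: (-r.length, r.id))
    out: list[SeqRecord] = []
    acc = 0
    for r in ordered:
        out.append(r)
        acc += r.length
        if acc >= target:
            break
    return out


def select_representatives(sequences: Sequence[SeqRecord],
                           rate_thresh: float = 0.95,
                           ident_thresh: float = 0.95,
                           min_aln_len: int = 100,
                           aln_min_identity: float = 0.90,
                           kmer_size: int = 15) -> RepresentativeSet:
    """Greedy longest-first selection with containment-based removal.

    Both containment conditions are strict: a sequence is removed only if
    its alignment rate and weighted identity against the current
    representative both exceed their thresholds.
    """
    if not sequences:
        raise ValueError("select_representatives requires a non-empty pool")
    ids = {r.id for r in sequences}
    if len(ids) != len(sequences):
        raise ValueError("duplicate ids in selection pool")
    remaining = sorted(sequences, key=lambda r: (-r.length, r.id))
    reps: list[SeqRecord] = []
    delineated: dict[str, str] = {}
    removed_records: dict[str, SeqRecord] = {}
    table: list[tuple[str, str, float, float]] = []
    while remaining:
        rep = remaining.pop(0)
        reps.append(rep)
        if not remaining:
            break
        hits = align(remaining, [rep], min_len=min_aln_len,
                     min_identity=aln_min_identity, k=kmer_size)
        by_query: dict[str, list] = {}
        for h in hits:
            by_query.setdefault(h.qid, []).append(h)
        survivors: list[SeqRecord] = []
        for seq in remaining:
            c = containment(seq, rep, by_query.get(seq.id, ()))
            if c.alignment_rate > rate_thresh and c.identity > ident_thresh:
                delineated[seq.id] = rep.id
                removed_records[seq.id] = seq
                table.append((seq.id, rep.id, c.alignment_rate, c.identity))
            else:
                survivors.append(seq)
        remaining = survivors
    log.info("representative selection: %d representatives, %d removed",
             len(reps), len(delineated))
    return RepresentativeSet(reps, delineated, removed_records, table)


def delineation_tsv(repset: RepresentativeSet) -> str:
    rows = ["removed_id\trepresentative_id\talignment_rate\tidentity"]
    for rid, rep, rate, ident in repset.table:
        rows.append(f"{rid}\t{rep}\t{rate:.4f}\t{ident:.4f}")
    return "\n".join(rows) + "\n"
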