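"""Sequence ingest/egress and basic assembly statistics.

FASTA/FASTQ reading is delegated to Biopython; this module adds the
pipeline's normalisation rules (uppercase, ``U``→``T``, non-ACGTN → ``N``),
origin tagging (draft contig vs corrected long read) and deterministic FASTA
output ordering.
"""

from __future__ import annotations

import dataclasses
import enum
import gzip
import logging
import re
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger("asmpatch")

_VALID = set("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class Origin(str, enum.Enum):
    contig = "contig"
    cpblr = "cpblr"


@dataclasses.dataclass
class SeqRecord:
    """A named nucleotide sequence with an origin tag.

    ``origin`` distinguishes draft-assembly contigs from corrected PacBio
    long reads (CPBLRs); it is fixed at ingest and carried through every
    stage so bridging rules can tell the two apart.
    """

    id: str
    seq: str
    origin: Origin

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass
class AssemblyStats:
    n_contigs: int
    total_length: int
    largest: int
    n50: int
    n_per_100kbp: float


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: IO[str]) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("file is neither FASTA nor FASTQ (first char %r)" % first)


def normalize_seq(raw: str) -> tuple[str, int]:
    """Uppercase, map U→T, replace any other non-ACGTN character with N.

    Returns the normalised sequence and the count of characters mapped to N.
    """
    s = raw.upper().replace("U", "T")
    n_mapped = 0
    if _NON_ACGTN.search(s):
        n_mapped = sum(1 for c in s if c not in _VALID)
        s = _NON_ACGTN.sub("N", s)
    return s, n_mapped


def read_sequences(path: str | Path, origin: Origin | str) -> list[SeqRecord]:
    """Read a FASTA or FASTQ file (optionally gzipped) into tagged records.

    Sequences are uppercased, ``U`` mapped to ``T`` and other non-ACGTN
    characters mapped to ``N`` (counted and logged).  Empty records are
    dropped with a warning; duplicate ids are fatal.
    """
    origin = Origin(origin)
    try:
        handle = _open_maybe_gzip(path)
    except OSError as e:
        raise RuntimeError(f"cannot read sequence file {path}: {e}") from e
    records: list[SeqRecord] = []
    seen: dict[str, int] = {}
    mapped_total = 0
    with handle:
        fmt = _sniff_format(handle)
        for idx, rec in enumerate(SeqIO.parse(handle, fmt)):
            seq, mapped = normalize_seq(str(rec.seq))
            mapped_total += mapped
            if not seq:
                log.warning("dropping empty record %r in %s", rec.id, path)
                continue
            if rec.id in seen:
                raise RuntimeError(
                    f"duplicate sequence id {rec.id!r} in {path} "
                    f"(records #{seen[rec.id]} and #{idx})")
            seen[rec.id] = idx
            records.append(SeqRecord(rec.id, seq, origin))
    if mapped_total:
        log.warning("%d non-ACGTN characters mapped to N while reading %s",
                    mapped_total, path)
    return records


def write_assembly(records: Sequence[SeqRecord], path: str | Path) -> None:
    """Write records as 80-column FASTA, longest first (id breaks ties)."""
    if not records:
        raise RuntimeError("refusing to write an empty assembly")
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    with open(path, "wt") as out:
        for rec in ordered:
            out.write(f">{rec.id}\n")
            for i in range(0, rec.length, 80):
                out.write(rec.seq[i:i + 80] + "\n")


def assembly_stats(records: Sequence[SeqRecord]) -> AssemblyStats:
    """N50 and friends, mirroring the usual draft-assembly report columns."""
    if not records:
        raise ValueError("assembly_stats requires at least one record")
    lengths = sorted((r.length for r in records), reverse=True)
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc >= half:
            n50 = L
            break
    n_count = sum(r.seq.count("N") for r in records)
    return AssemblyStats(
        n_contigs=len(lengths),
        total_length=total,
        largest=lengths[0],
        n50=n50,
        n_per_100kbp=1e5 * n_count / total,
    )


def stats_tsv(rows: Iterable[tuple[str, AssemblyStats]]) -> str:
    """Render labelled stats as a TSV block (header + one row per label)."""
    out = ["label\tn_contigs\ttotal_length\tlargest\tn50\tn_per_100kbp"]
    for label, s in rows:
        out.append(f"{label}\t{s.n_contigs}\t{s.total_length}\t{s.largest}"
                   f"\t{s.n50}\t{s.n_per_100kbp:.2f}")
    return "\n".join(out) + "\n"
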