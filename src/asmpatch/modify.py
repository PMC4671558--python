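"""Stage 1 — assembly modification: gap filling and zero-coverage splitting.

Any run of ``N`` inside a contig defines a gap.  The 100-bp sequences
flanking a gap are searched in the corrected long reads; reads containing
both flanks in a consistent orientation span the gap, and the inter-flank
substring they carry is a candidate replacement.  The most frequent
candidate wins if it occurs more than twice and strictly beats the
runner-up (a tie has no unique maximum, so nothing is done).

When raw short reads are supplied they are mapped onto the gap-filled
contigs and contigs are split at zero-coverage positions — evidence-free
bases are excised — except inside the terminal 1 % of the contig, where
coverage drops off for purely geometric reasons.  Split products shorter
than 50 bp are discarded.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .sequence_io import Origin, SeqRecord, read_sequences, revcomp

log = logging.getLogger("asmpatch")


@dataclasses.dataclass
class Gap:
    contig_id: str
    start: int            # 0-based half-open interval of the maximal N-run
    end: int
    left_flank: str
    right_flank: str
    short_flank: bool     # flank truncated or contains N -> skipped by filling


@dataclasses.dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray     # per-base read depth, length == contig length
    # reads spanning the bond between base i and i+1 (length L-1); a bond
    # with zero spanning reads is an evidence-free junction even when both
    # flanking bases are covered by reads that end/start exactly there
    bond_depth: np.ndarray | None = None


@dataclasses.dataclass
class FillEvent:
    contig_id: str
    start: int
    end: int
    votes: int
    n_spanning: int
    replacement_len: int


@dataclasses.dataclass
class SplitEvent:
    contig_id: str
    kind: str             # "excise" | "keep" | "discard"
    start: int            # interval in the original contig
    end: int
    segment_id: str = ""


# ------------------------------------------------------------------- gaps

def find_gaps(contig: SeqRecord, flank_len: int = 100) -> list[Gap]:
    """One Gap per maximal N-run, with its flanking anchor sequences.

    Runs whose available flank is shorter than ``flank_len`` or whose flank
    itself contains ``N`` (adjacent gaps closer than one flank) are marked
    ``short_flank`` and are skipped by :func:`fill_gaps`.
    """
    gaps: list[Gap] = []
    seq = contig.seq
    i = seq.find("N")
    while i != -1:
        j = i
        while j < len(seq) and seq[j] == "N":
            j += 1
        left = seq[max(0, i - flank_len):i]
        right = seq[j:j + flank_len]
        short = (len(left) < flank_len or len(right) < flank_len
                 or "N" in left or "N" in right)
        gaps.append(Gap(contig.id, i, j, left, right, short))
        i = seq.find("N", j)
    return gaps


def _find_flank(flank: str, read: str, max_edits: int) -> list[tuple[int, int]]:
    """All occurrences of a flank in a read: exact first, edlib fallback."""
    occ: list[tuple[int, int]] = []
    p = read.find(flank)
    while p != -1:
        occ.append((p, p + len(flank)))
        p = read.find(flank, p + 1)
    if occ or max_edits <= 0:
        return occ
    res = edlib.align(flank, read, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return []
    return [(s, e + 1) for s, e in res["locations"]]


def _spanning_insert(gap: Gap, read_seq: str, max_edits: int) -> str | None:
    """The inter-flank substring a read carries across a gap, if it spans."""
    for oriented in (read_seq, revcomp(read_seq)):
        lefts = _find_flank(gap.left_flank, oriented, max_edits)
        if not lefts:
            continue
        rights = _find_flank(gap.right_flank, oriented, max_edits)
        if not rights:
            continue
        # nearest right-flank occurrence downstream of a left-flank one
        best: tuple[int, int] | None = None
        for _, le in lefts:
            for rs, _ in rights:
                if rs >= le and (best is None or rs - le < best[1] - best[0]):
                    best = (le, rs)
        if best is not None:
            return oriented[best[0]:best[1]]
    return None


def fill_gaps(contig: SeqRecord, gaps: Sequence[Gap],
              cpblrs: Sequence[SeqRecord], min_votes: int = 3,
              flank_identity: float = 0.90
              ) -> tuple[SeqRecord, list[FillEvent]]:
    """Replace each gap's N-run by the consensus inter-flank sequence.

    A gap is filled only when the most frequent candidate occurs at least
    ``min_votes`` times and strictly more often than the runner-up.  Gaps
    are processed right-to-left so earlier coordinates stay valid.
    """
    seq = contig.seq
    events: list[FillEvent] = []
    for gap in sorted(gaps, key=lambda g: -g.start):
        if gap.short_flank:
            continue
        max_edits = int(round(len(gap.left_flank) * (1 - flank_identity)))
        votes: Counter[str] = Counter()
        for read in cpblrs:
            ins = _spanning_insert(gap, read.seq, max_edits)
            if ins is not None and "N" not in ins:
                votes[ins] += 1
        if not votes:
            continue
        ranked = votes.most_common(2)
        top_seq, top_n = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0
        if top_n >= min_votes and top_n > runner:
            seq = seq[:gap.start] + top_seq + seq[gap.end:]
            events.append(FillEvent(contig.id, gap.start, gap.end,
                                    top_n, sum(votes.values()), len(top_seq)))
    return SeqRecord(contig.id, seq, contig.origin), events


# --------------------------------------------------------------- coverage

def _read_stream(paths: Sequence[str | Path]) -> Iterable[str]:
    for p in paths:
        for rec in read_sequences(p, Origin.cpblr):
            yield rec.seq


def compute_coverage(contigs: Sequence[SeqRecord],
                     read_files: Sequence[str | Path],
                     max_edits: int = 2, seed_k: int = 21
                     ) -> dict[str, CoverageProfile]:
    """Per-base depth of short reads over the contigs.

    Each read is placed at every position achieving its minimal edit
    distance (<= ``max_edits``), on either strand; reads tied across
    repeat copies therefore contribute depth at all best placements.
    Paired-end files are consumed as independent single-end streams.
    """
    reads = list(_read_stream(read_files))
    k = min([seed_k] + [len(r) for r in reads]) if reads else seed_k
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ci, contig in enumerate(contigs):
        s = contig.seq
        for p in range(len(s) - k + 1):
            km = s[p:p + k]
            if "N" not in km:
                index[km].append((ci, p))
    diffs = [np.zeros(c.length + 1, dtype=np.int64) for c in contigs]
    bond_diffs = [np.zeros(c.length, dtype=np.int64) for c in contigs]
    for read in reads:
        L = len(read)
        placements: dict[tuple[int, int], int] = {}
        best = max_edits + 1
        for oriented in (read, revcomp(read)):
            seed_offs = sorted({0, max(0, L // 2 - k // 2), L - k})
            cand: set[tuple[int, int]] = set()
            for off in seed_offs:
                for ci, p in index.get(oriented[off:off + k], ()):
                    cand.add((ci, p - off))
            for ci, start in cand:
                cseq = contigs[ci].seq
                lo = max(0, start - max_edits)
                hi = min(len(cseq), start + L + max_edits)
                if hi - lo < L:
                    continue
                window = cseq[lo:hi]
                if window[start - lo:start - lo + L] == oriented:
                    d, span = 0, (start, start + L)
                else:
                    res = edlib.align(oriented, window, mode="HW",
                                      task="locations", k=max_edits)
                    if res["editDistance"] < 0:
                        continue
                    d = res["editDistance"]
                    s0, e0 = res["locations"][0]
                    span = (lo + s0, lo + e0 + 1)
                key = (ci, span[0])
                if d < best:
                    best = d
                    placements = {key: span[1]}
                elif d == best:
                    placements.setdefault(key, span[1])
        for (ci, s0), e0 in placements.items():
            diffs[ci][s0] += 1
            diffs[ci][e0] -= 1
            if e0 - s0 >= 2:
                bond_diffs[ci][s0] += 1
                bond_diffs[ci][e0 - 1] -= 1
    return {c.id: CoverageProfile(c.id, np.cumsum(d[:-1]),
                                  np.cumsum(b[:-1]))
            for c, d, b in zip(contigs, diffs, bond_diffs)}


# ----------------------------------------------------------------- splits

def split_zero_coverage(contig: SeqRecord, profile: CoverageProfile,
                        end_fraction: float = 0.01, min_segment: int = 50
                        ) -> tuple[list[SeqRecord], list[SplitEvent]]:
    """Excise zero-depth runs and cut evidence-free bonds.

    Zero-depth base runs are excised (the bases have no read support);
    bonds that no read spans are cut without removing bases — a false
    junction can sit between two covered bases when reads end exactly at
    it on both sides.  Runs/bonds lying entirely within the terminal
    windows of ``floor(end_fraction * length)`` bp are exempt; remaining
    pieces shorter than ``min_segment`` are discarded (and logged).
    """
    depth = profile.depth
    if depth.shape[0] != contig.length:
        raise ValueError("coverage profile does not match contig length")
    L = contig.length
    win = int(end_fraction * L)
    zero = depth == 0
    padded = np.concatenate([[False], zero, [False]])
    starts = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)[0]
    ends = np.nonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)[0]
    cut_runs = [(int(s), int(e)) for s, e in zip(starts, ends)
                if not (e <= win or s >= L - win)]
    events = [SplitEvent(contig.id, "excise", s, e) for s, e in cut_runs]
    if profile.bond_depth is not None:
        covered = np.zeros(L, dtype=bool)
        for s, e in cut_runs:
            covered[s:e] = True
        for i in np.nonzero(profile.bond_depth == 0)[0]:
            p = int(i) + 1  # cut point between base i and i+1
            if p <= win or p >= L - win:
                continue
            if covered[p - 1] or covered[p]:
                continue  # already separated by an excised run
            cut_runs.append((p, p))
            events.append(SplitEvent(contig.id, "cut", p, p))
    if not cut_runs:
        return [contig], []
    cut_runs.sort()
    pieces: list[tuple[int, int]] = []
    prev = 0
    for s, e in cut_runs:
        pieces.append((prev, s))
        prev = e
    pieces.append((prev, L))
    out: list[SeqRecord] = []
    n = 0
    for s, e in pieces:
        if e - s < min_segment:
            events.append(SplitEvent(contig.id, "discard", s, e))
            continue
        n += 1
        seg_id = f"{contig.id}_p{n}"
        events.append(SplitEvent(contig.id, "keep", s, e, seg_id))
        out.append(SeqRecord(seg_id, contig.seq[s:e], contig.origin))
    return out, events


def modify_assembly(contigs: Sequence[SeqRecord],
                    cpblrs: Sequence[SeqRecord],
                    read_files: Sequence[str | Path] | None = None,
                    flank_len: int = 100, min_votes: int = 3,
                    flank_identity: float = 0.90, end_fraction: float = 0.01,
                    min_segment: int = 50, max_read_edits: int = 2,
                    split: bool = True
                    ) -> tuple[list[SeqRecord], list[FillEvent], list[SplitEvent]]:
    """Run stage 1: fill gaps in every contig, then (optionally) split.

    Splitting runs only when short-read files are provided, and maps the
    reads against the *gap-filled* contigs.
    """
    filled: list[SeqRecord] = []
    fill_events: list[FillEvent] = []
    for contig in contigs:
        gaps = find_gaps(contig, flank_len)
        rec, ev = fill_gaps(contig, gaps, cpblrs, min_votes, flank_identity)
        filled.append(rec)
        fill_events.extend(ev)
    if not read_files or not split:
        return filled, fill_events, []
    profiles = compute_coverage(filled, read_files, max_read_edits)
    out: list[SeqRecord] = []
    split_events: list[SplitEvent] = []
    for contig in filled:
        segs, ev = split_zero_coverage(contig, profiles[contig.id],
                                       end_fraction, min_segment)
        out.extend(segs)
        split_events.extend(ev)
    return out, fill_events, split_events
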