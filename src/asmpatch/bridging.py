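"""Stage 3 — iterative connection of representative sequences.

Representatives are self-aligned all-vs-all and their proper dovetail
(end-to-end) overlaps drive three joining mechanisms:

* **strict bridging** — a sequence bridges two targets when, at each of its
  ends, the best end-overlap is at least 1.25-fold longer than the second
  best (unique by margin) and at least one target is a contig;
* **easy bridging** — a long read longer than the estimated maximal repeat
  bridges exactly two contigs, one clean partner per end;
* **end merging** — two sequences sharing a reciprocal-best dovetail longer
  than the maximal repeat are joined directly.

Reads removed during representative selection ("delineated") are rescued
as easy-bridging candidates before their representative is discarded.
Every join records a layout of source tiles so each output base traces to
an input base.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Sequence

from .alignment import AlignmentHit, EndOverlap, align, classify_end_overlap, containment
from .config import PatchConfig
from .sequence_io import Origin, SeqRecord, revcomp

log = logging.getLogger("asmpatch")

End = Literal["head", "tail"]


@dataclasses.dataclass
class Tile:
    source_id: str
    start: int        # interval on the source's forward strand
    end: int
    strand: str       # '+' or '-'


@dataclasses.dataclass
class ConnectedSequence(SeqRecord):
    layout: list[Tile] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class BridgeSide:
    target_id: str
    target_end: End
    overlap: EndOverlap       # a = bridge (query of .hit), b = target


@dataclasses.dataclass
class Bridge:
    bridge_id: str
    bridge_record: SeqRecord
    left: BridgeSide          # at the bridge's head
    right: BridgeSide         # at the bridge's tail
    mode: str                 # "strict" | "easy"


@dataclasses.dataclass
class RepeatEstimate:
    max_repeat: int


@dataclasses.dataclass
class JoinEvent:
    mode: str                 # strict | easy | rescue | merge
    bridge_id: str
    left_target: str
    left_end: End
    right_target: str
    right_end: End
    new_id: str
    trim: int                 # bp trimmed when targets overlapped
    insert_len: int           # bridge bp inserted between targets


# ----------------------------------------------------------------- layout

def layout_of(rec: SeqRecord) -> list[Tile]:
    if isinstance(rec, ConnectedSequence):
        return rec.layout
    return [Tile(rec.id, 0, rec.length, "+")]


def _flip_tiles(tiles: Sequence[Tile]) -> list[Tile]:
    return [Tile(t.source_id, t.start, t.end, "-" if t.strand == "+" else "+")
            for t in reversed(tiles)]


def slice_layout(rec: SeqRecord, start: int, end: int, flip: bool) -> list[Tile]:
    """Tiles covering [start, end) of ``rec`` viewed in the given orientation."""
    tiles = _flip_tiles(layout_of(rec)) if flip else layout_of(rec)
    out: list[Tile] = []
    off = 0
    for t in tiles:
        tl = t.end - t.start
        lo, hi = max(start, off), min(end, off + tl)
        if lo < hi:
            a, b = lo - off, hi - off
            if t.strand == "+":
                out.append(Tile(t.source_id, t.start + a, t.start + b, "+"))
            else:
                out.append(Tile(t.source_id, t.end - b, t.end - a, "-"))
        off += tl
    return out


def reconstruct(tiles: Sequence[Tile], sources: dict[str, str]) -> str:
    """Concatenate layout tiles back into a sequence (traceability check)."""
    parts = []
    for t in tiles:
        sub = sources[t.source_id][t.start:t.end]
        parts.append(sub if t.strand == "+" else revcomp(sub))
    return "".join(parts)


# ------------------------------------------------------- end-overlap table

def collect_end_overlaps(hits: Sequence[AlignmentHit],
                         lengths: dict[str, int],
                         max_overhang: int, min_overlap: int
                         ) -> dict[tuple[str, End], list[EndOverlap]]:
    """Best dovetail per (sequence end, partner end), sorted for uniqueness.

    Self overlaps (circularity signals) are excluded; hits are taken from
    the query side, so an all-vs-all alignment yields both directions.
    """
    best: dict[tuple[str, End, str, End], EndOverlap] = {}
    for h in hits:
        if h.qid == h.sid:
            continue
        eo = classify_end_overlap(h, lengths[h.qid], lengths[h.sid],
                                  max_overhang, min_overlap)
        if eo is None:
            continue
        key = (eo.a_id, eo.a_end, eo.b_id, eo.b_end)
        prev = best.get(key)
        if prev is None or (eo.overlap_len, eo.identity) > (
                prev.overlap_len, prev.identity):
            best[key] = eo
    ends: dict[tuple[str, End], list[EndOverlap]] = {}
    for (aid, aend, _, _), eo in best.items():
        ends.setdefault((aid, aend), []).append(eo)
    for lst in ends.values():
        lst.sort(key=lambda e: (-e.overlap_len, -e.identity, e.b_id, e.b_end))
    return ends


def is_contig_role(rec: SeqRecord) -> bool:
    """Connected sequences inherit the contig role for bridging rules."""
    return rec.origin == Origin.contig or isinstance(rec, ConnectedSequence)


def _unique_choice(cands: list[EndOverlap], uniq_ratio: float
                   ) -> EndOverlap | None:
    """The best end-overlap if it clears the uniqueness margin."""
    if not cands:
        return None
    if len(cands) == 1:
        return cands[0]
    if cands[0].overlap_len >= uniq_ratio * cands[1].overlap_len:
        return cands[0]
    return None


# --------------------------------------------------------- strict bridging

def find_strict_bridges(pool: Sequence[SeqRecord], cfg: PatchConfig
                        ) -> list[Bridge]:
    """Bridges whose two end-overlaps are unique by the 1.25-fold margin.

    Every pool sequence is a candidate bridge; a bridge is emitted iff both
    of its ends resolve uniquely, to two distinct targets, at least one of
    which plays the contig role.
    """
    recs = {r.id: r for r in pool}
    hits = align(pool, pool, min_len=cfg.min_overlap,
                 min_identity=cfg.cpblr_min_identity, k=cfg.kmer_size)
    lengths = {r.id: r.length for r in pool}
    ends = collect_end_overlaps(hits, lengths, cfg.max_overhang,
                                cfg.min_overlap)
    bridges: list[Bridge] = []
    for r in pool:
        head = _unique_choice(ends.get((r.id, "head"), []), cfg.uniq_ratio)
        tail = _unique_choice(ends.get((r.id, "tail"), []), cfg.uniq_ratio)
        if head is None or tail is None:
            continue
        if head.b_id == tail.b_id:
            log.info("self-circularising bridge %s -> %s skipped",
                     r.id, head.b_id)
            continue
        t1, t2 = recs[head.b_id], recs[tail.b_id]
        if not (is_contig_role(t1) or is_contig_role(t2)):
            continue
        bridges.append(Bridge(r.id, r,
                              BridgeSide(head.b_id, head.b_end, head),
                              BridgeSide(tail.b_id, tail.b_end, tail),
                              "strict"))
    return bridges


# ----------------------------------------------------------- easy bridging

def find_easy_bridges(cpblr_pool: Sequence[SeqRecord],
                      contig_pool: Sequence[SeqRecord],
                      max_repeat: int, cfg: PatchConfig) -> list[Bridge]:
    """Reads longer than the repeat bound that cleanly join two contigs.

    A read qualifies iff each of its ends overlaps exactly one contig,
    the two partners are distinct, and the read outsizes every repeat.
    """
    cands = [r for r in cpblr_pool if r.length > max_repeat]
    if not cands or not contig_pool:
        return []
    hits = align(cands, contig_pool, min_len=cfg.min_overlap,
                 min_identity=cfg.cpblr_min_identity, k=cfg.kmer_size)
    lengths = {r.id: r.length for r in cands}
    lengths.update({r.id: r.length for r in contig_pool})
    ends = collect_end_overlaps(hits, lengths, cfg.max_overhang,
                                cfg.min_overlap)
    bridges: list[Bridge] = []
    for r in cands:
        head = ends.get((r.id, "head"), [])
        tail = ends.get((r.id, "tail"), [])
        head_partners = {e.b_id for e in head}
        tail_partners = {e.b_id for e in tail}
        if len(head_partners) != 1 or len(tail_partners) != 1:
            continue
        if head_partners == tail_partners:
            continue
        bridges.append(Bridge(r.id, r,
                              BridgeSide(head[0].b_id, head[0].b_end, head[0]),
                              BridgeSide(tail[0].b_id, tail[0].b_end, tail[0]),
                              "easy"))
    return bridges


# ------------------------------------------------------------- application

def _oriented_interval(s: int, e: int, length: int, flip: bool
                       ) -> tuple[int, int]:
    return (length - e, length - s) if flip else (s, e)


def _apply_one(bridge: Bridge, recs: dict[str, SeqRecord], new_id: str
               ) -> tuple[ConnectedSequence, JoinEvent] | None:
    """Merge bridge + two targets into one ConnectedSequence.

    Geometry is resolved in the bridge-forward frame: the left target is
    oriented to end at the junction, the right target to start at it.  If
    the two target alignments on the bridge are disjoint the intervening
    bridge sequence is inserted; if they overlap, the overlap is trimmed
    from the shorter target.
    """
    r = bridge.bridge_record
    t1 = recs[bridge.left.target_id]
    t2 = recs[bridge.right.target_id]
    hl, hr = bridge.left.overlap.hit, bridge.right.overlap.hit
    r1e = hl.qend
    r2s = hr.qstart
    flip_l = bridge.left.overlap.b_end == "head"    # left target must end at junction
    flip_r = bridge.right.overlap.b_end == "tail"   # right target must start there
    _, t1e = _oriented_interval(hl.sstart, hl.send, t1.length, flip_l)
    t2s, t2e = _oriented_interval(hr.sstart, hr.send, t2.length, flip_r)
    t1_seq = revcomp(t1.seq) if flip_l else t1.seq
    t2_seq = revcomp(t2.seq) if flip_r else t2.seq
    if r1e <= r2s:
        trim = 0
        insert = r.seq[r1e:r2s]
        seq = t1_seq[:t1e] + insert + t2_seq[t2s:]
        tiles = (slice_layout(t1, 0, t1e, flip_l)
                 + slice_layout(r, r1e, r2s, False)
                 + slice_layout(t2, t2s, t2.length, flip_r))
    else:
        trim = r1e - r2s
        insert = ""
        if t1.length <= t2.length:
            cut = t1e - trim
            if cut <= 0 or t2s >= t2e:
                return None
            seq = t1_seq[:cut] + t2_seq[t2s:]
            tiles = (slice_layout(t1, 0, cut, flip_l)
                     + slice_layout(t2, t2s, t2.length, flip_r))
        else:
            start = t2s + trim
            if start >= t2e:
                return None
            seq = t1_seq[:t1e] + t2_seq[start:]
            tiles = (slice_layout(t1, 0, t1e, flip_l)
                     + slice_layout(t2, start, t2.length, flip_r))
    if not seq:
        return None
    new = ConnectedSequence(new_id, seq, Origin.contig, tiles)
    ev = JoinEvent(bridge.mode, bridge.bridge_id,
                   bridge.left.target_id, bridge.left.overlap.b_end,
                   bridge.right.target_id, bridge.right.overlap.b_end,
                   new_id, trim, len(insert))
    return new, ev


class _Joiner:
    """Names connected sequences and accumulates the join log."""

    def __init__(self) -> None:
        self.counter = 0
        self.events: list[JoinEvent] = []

    def next_id(self) -> str:
        self.counter += 1
        return f"join_{self.counter}"


def apply_bridges(bridges: Sequence[Bridge], pool: dict[str, SeqRecord],
                  joiner: _Joiner) -> tuple[list[ConnectedSequence], set[str]]:
    """Apply one round of bridges, longest bridge first.

    A bridge is applied only while its record and both targets are still
    unconsumed; applied joins remove three sequences from the pool and the
    products are added back afterwards (chains grow on the next round,
    when the pool is re-aligned).
    """
    consumed: set[str] = set()
    new_seqs: list[ConnectedSequence] = []
    for b in sorted(bridges, key=lambda b: (-b.bridge_record.length,
                                            b.bridge_id)):
        if (b.bridge_id in consumed
                or b.left.target_id in consumed
                or b.right.target_id in consumed
                or b.left.target_id not in pool
                or b.right.target_id not in pool):
            log.debug("bridge %s skipped: end already consumed", b.bridge_id)
            continue
        res = _apply_one(b, pool, joiner.next_id())
        if res is None:
            log.debug("bridge %s skipped: degenerate geometry", b.bridge_id)
            continue
        new, ev = res
        consumed.update({b.bridge_id, b.left.target_id, b.right.target_id})
        pool.pop(b.bridge_id, None)   # rescued bridges live outside the pool
        del pool[b.left.target_id]
        del pool[b.right.target_id]
        new_seqs.append(new)
        joiner.events.append(ev)
    for n in new_seqs:
        pool[n.id] = n
    return new_seqs, consumed


# -------------------------------------------------------- repeat estimate

def estimate_max_repeat(pool: Sequence[SeqRecord], cfg: PatchConfig
                        ) -> RepeatEstimate:
    """Longest alignment that is neither a dovetail nor a containment.

    Inter-sequence repeat hits and non-trivial self hits (internal or
    inverted duplications) both count; the estimate gates easy bridging
    and final end merging.
    """
    if not pool:
        return RepeatEstimate(0)
    hits = align(pool, pool, min_len=cfg.min_aln_len,
                 min_identity=cfg.cpblr_min_identity, k=cfg.kmer_size)
    recs = {r.id: r for r in pool}
    by_pair: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        by_pair.setdefault((h.qid, h.sid), []).append(h)
    contained: set[tuple[str, str]] = set()
    for (qid, sid), pair_hits in by_pair.items():
        if qid == sid:
            continue
        c = containment(recs[qid], recs[sid], pair_hits)
        if c.alignment_rate > cfg.rate_thresh and c.identity > cfg.ident_thresh:
            contained.add((qid, sid))
    max_repeat = 0
    for h in hits:
        if h.qid == h.sid:
            max_repeat = max(max_repeat, h.aln_len)
            continue
        if (h.qid, h.sid) in contained or (h.sid, h.qid) in contained:
            continue
        if classify_end_overlap(h, recs[h.qid].length, recs[h.sid].length,
                                cfg.max_overhang, cfg.min_overlap) is not None:
            continue
        max_repeat = max(max_repeat, h.aln_len)
    return RepeatEstimate(max_repeat)


# ------------------------------------------------------------------ rescue

def rescue_delineated(unused_cpblrs: Sequence[SeqRecord],
                      delineated: dict[str, str],
                      removed_records: dict[str, SeqRecord],
                      contig_pool: Sequence[SeqRecord],
                      max_repeat: int, cfg: PatchConfig) -> list[Bridge]:
    """Easy-bridge candidates among reads absorbed by unusable reads.

    Before an unused representative read is discarded, the reads it
    delineated in stage 2 get one chance to bridge under the same gates.
    """
    unused_ids = {r.id for r in unused_cpblrs}
    cands = [removed_records[rid]
             for rid, rep in delineated.items()
             if rep in unused_ids
             and removed_records[rid].origin == Origin.cpblr]
    if not cands:
        return []
    bridges = find_easy_bridges(cands, contig_pool, max_repeat, cfg)
    for b in bridges:
        b.mode = "rescue"
    return bridges


# ------------------------------------------------------------ end merging

def _merge_pair(x: SeqRecord, y: SeqRecord, eo: EndOverlap, new_id: str
                ) -> tuple[ConnectedSequence, JoinEvent]:
    """Join two sequences across a reciprocal dovetail (overlap kept once)."""
    h = eo.hit
    flip_x = eo.a_end == "head"
    flip_y = eo.b_end == "tail"
    _, xe = _oriented_interval(h.qstart, h.qend, x.length, flip_x)
    _, ye = _oriented_interval(h.sstart, h.send, y.length, flip_y)
    x_seq = revcomp(x.seq) if flip_x else x.seq
    y_seq = revcomp(y.seq) if flip_y else y.seq
    seq = x_seq[:xe] + y_seq[ye:]
    tiles = (slice_layout(x, 0, xe, flip_x)
             + slice_layout(y, ye, y.length, flip_y))
    new = ConnectedSequence(new_id, seq, Origin.contig, tiles)
    ev = JoinEvent("merge", "-", x.id, eo.a_end, y.id, eo.b_end,
                   new_id, eo.overlap_len, 0)
    return new, ev


def merge_end_overlaps(pool: dict[str, SeqRecord], max_repeat: int,
                       cfg: PatchConfig, joiner: _Joiner) -> int:
    """Merge reciprocal-best dovetails longer than the repeat bound.

    Rounds repeat (re-aligning the shrinking pool) until no merge applies;
    returns the number of merges performed.
    """
    merged_total = 0
    while True:
        seqs = list(pool.values())
        if len(seqs) < 2:
            return merged_total
        hits = align(seqs, seqs, min_len=max(cfg.min_overlap, max_repeat + 1),
                     min_identity=cfg.cpblr_min_identity, k=cfg.kmer_size)
        lengths = {r.id: r.length for r in seqs}
        ends = collect_end_overlaps(hits, lengths, cfg.max_overhang,
                                    cfg.min_overlap)
        cands: list[EndOverlap] = []
        for (aid, aend), lst in ends.items():
            eo = _unique_choice(lst, cfg.uniq_ratio)
            if eo is None or eo.overlap_len <= max_repeat:
                continue
            back = _unique_choice(ends.get((eo.b_id, eo.b_end), []),
                                  cfg.uniq_ratio)
            if back is None or (back.b_id, back.b_end) != (aid, aend):
                continue  # not reciprocal unique best
            if aid < eo.b_id:   # each reciprocal pair once
                cands.append(eo)
        cands.sort(key=lambda e: (-e.overlap_len, e.a_id))
        used: set[tuple[str, End]] = set()
        applied = 0
        for eo in cands:
            if ((eo.a_id, eo.a_end) in used or (eo.b_id, eo.b_end) in used
                    or eo.a_id not in pool or eo.b_id not in pool
                    or eo.a_id == eo.b_id):
                continue
            new, ev = _merge_pair(pool[eo.a_id], pool[eo.b_id], eo,
                                  joiner.next_id())
            used.update({(eo.a_id, eo.a_end), (eo.b_id, eo.b_end),
                         (eo.a_id, "head"), (eo.a_id, "tail"),
                         (eo.b_id, "head"), (eo.b_id, "tail")})
            del pool[eo.a_id]
            del pool[eo.b_id]
            pool[new.id] = new
            joiner.events.append(ev)
            applied += 1
        merged_total += applied
        if applied == 0:
            return merged_total


# ----------------------------------------------------------------- driver

def iterative_connect(repset, cfg: PatchConfig
                      ) -> tuple[list[SeqRecord], list[JoinEvent],
                                 list[SeqRecord]]:
    """Drive stage 3 to a fixpoint.

    (a) strict bridging iteratively; (b) repeat-size estimation; (c) easy
    bridging iteratively; (d) delineated-read rescue + easy bridging;
    (e) reciprocal end merging; (f) repeat (b)-(d) until an iteration
    changes nothing.  Returns (final sequences, join log, unused reads).
    """
    pool: dict[str, SeqRecord] = {r.id: r for r in repset.representatives}
    joiner = _Joiner()

    def strict_to_fixpoint() -> None:
        while True:
            bridges = find_strict_bridges(list(pool.values()), cfg)
            new, _ = apply_bridges(bridges, pool, joiner)
            if not new:
                return

    def easy_round(bridges: Sequence[Bridge]) -> bool:
        new, _ = apply_bridges(bridges, pool, joiner)
        return bool(new)

    def easy_phase() -> bool:
        changed = False
        while True:
            est = estimate_max_repeat(list(pool.values()), cfg)
            cpblrs = [r for r in pool.values() if not is_contig_role(r)]
            contigs = [r for r in pool.values() if is_contig_role(r)]
            if not easy_round(find_easy_bridges(cpblrs, contigs,
                                                est.max_repeat, cfg)):
                break
            changed = True
        while True:
            est = estimate_max_repeat(list(pool.values()), cfg)
            cpblrs = [r for r in pool.values() if not is_contig_role(r)]
            contigs = [r for r in pool.values() if is_contig_role(r)]
            bridges = rescue_delineated(cpblrs, repset.delineated,
                                        repset.removed_records, contigs,
                                        est.max_repeat, cfg)
            if not easy_round(bridges):
                break
            changed = True
        return changed

    strict_to_fixpoint()
    easy_phase()
    est = estimate_max_repeat(list(pool.values()), cfg)
    contig_pool = {r.id: r for r in pool.values() if is_contig_role(r)}
    for rid in contig_pool:
        del pool[rid]
    merge_end_overlaps(contig_pool, est.max_repeat, cfg, joiner)
    pool.update(contig_pool)
    while easy_phase():
        pass
    final = [r for r in pool.values() if is_contig_role(r)]
    unused = [r for r in pool.values() if not is_contig_role(r)]
    if unused:
        log.info("%d unused long reads dropped from the assembly", len(unused))
    final.sort(key=lambda r: (-r.length, r.id))
    return final, joiner.events, unused


def joins_tsv(events: Sequence[JoinEvent]) -> str:
    rows = ["mode\tbridge_id\tleft_target\tleft_end\tright_target"
            "\tright_end\tnew_id\ttrim\tinsert_len"]
    for e in events:
        rows.append(f"{e.mode}\t{e.bridge_id}\t{e.left_target}\t{e.left_end}"
                    f"\t{e.right_target}\t{e.right_end}\t{e.new_id}"
                    f"\t{e.trim}\t{e.insert_len}")
    return "\n".join(rows) + "\n"


def layout_tsv(records: Sequence[SeqRecord]) -> str:
    """AGP-like component table: one row per layout tile per output sequence."""
    rows = ["object\tobject_start\tobject_end\tcomponent\tcomponent_start"
            "\tcomponent_end\torientation"]
    for rec in records:
        off = 0
        for t in layout_of(rec):
            tl = t.end - t.start
            rows.append(f"{rec.id}\t{off}\t{off + tl}\t{t.source_id}"
                        f"\t{t.start}\t{t.end}\t{t.strand}")
            off += tl
    return "\n".join(rows) + "\n"
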