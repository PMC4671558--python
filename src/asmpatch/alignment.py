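"""Local alignment layer: anchor-based aligner, containment, dovetail calls.

Every later stage (gap spanning, redundancy removal, bridging) consumes the
same three primitives defined here:

* :func:`align` — all local alignments between two sequence sets, both
  strands, as :class:`AlignmentHit` records.  The aligner is an exact k-mer
  anchor / diagonal-chain front end with base-level refinement by edlib;
  it targets the high-identity regime of draft contigs and corrected long
  reads (residual error well below a few percent).
* :func:`containment` — fraction of an inner sequence covered by its
  alignments to an outer sequence (interval union), with length-weighted
  identity.
* :func:`classify_end_overlap` — decides whether a hit is a proper dovetail
  (suffix-to-prefix after strand normalisation, small overhangs) and which
  end of each sequence participates.

Coordinates are 0-based half-open throughout; minus-strand hits keep both
intervals on the forward strands of their sequences with a strand flag.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Sequence

import edlib
import numpy as np

from .sequence_io import SeqRecord, revcomp

Strand = Literal["+", "-"]
End = Literal["head", "tail"]


@dataclasses.dataclass
class AlignmentHit:
    qid: str
    sid: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: Strand
    aln_len: int        # alignment columns (matches + mismatches + gaps)
    identity: float     # matches / columns


@dataclasses.dataclass
class EndOverlap:
    a_id: str
    b_id: str
    a_end: End
    b_end: End
    overlap_len: int
    identity: float
    strand: Strand
    a_overhang: int
    b_overhang: int
    hit: "AlignmentHit | None" = None   # underlying alignment (join geometry)


@dataclasses.dataclass
class ContainmentResult:
    inner_id: str
    outer_id: str
    alignment_rate: float
    identity: float


# ---------------------------------------------------------------- encoding

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_values(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer value of every k-mer plus the positions of N-free windows."""
    n = enc.size
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    x = enc.astype(np.int64)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.int64)
    for j in range(k):
        vals = vals * 4 + np.minimum(x[j:j + m], 3)
    is_n = (enc == 4).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    clean = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(clean)[0]
    return vals[pos], pos


class _SubjectIndex:
    """Sorted global k-mer table over a set of subject sequences."""

    def __init__(self, subjects: Sequence[SeqRecord], k: int, max_occ: int):
        self.k = k
        self.max_occ = max_occ
        self.ids = [r.id for r in subjects]
        self.enc = {r.id: _encode(r.seq) for r in subjects}
        vals_all, pos_all, sid_all = [], [], []
        for i, r in enumerate(subjects):
            v, p = _kmer_values(self.enc[r.id], k)
            vals_all.append(v)
            pos_all.append(p)
            sid_all.append(np.full(v.size, i, dtype=np.int64))
        vals = np.concatenate(vals_all) if vals_all else np.empty(0, np.int64)
        order = np.argsort(vals, kind="stable")
        self.vals = vals[order]
        self.pos = (np.concatenate(pos_all)[order]
                    if pos_all else np.empty(0, np.int64))
        self.sidx = (np.concatenate(sid_all)[order]
                     if sid_all else np.empty(0, np.int64))

    def anchors(self, qvals: np.ndarray, qpos: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(subject index, query pos, subject pos) for every shared k-mer."""
        if qvals.size == 0 or self.vals.size == 0:
            z = np.empty(0, np.int64)
            return z, z, z
        lo = np.searchsorted(self.vals, qvals, side="left")
        hi = np.searchsorted(self.vals, qvals, side="right")
        cnt = hi - lo
        cnt = np.where(cnt > self.max_occ, 0, cnt)  # drop hyper-repetitive seeds
        total = int(cnt.sum())
        if total == 0:
            z = np.empty(0, np.int64)
            return z, z, z
        q_rep = np.repeat(qpos, cnt)
        starts = np.repeat(lo, cnt)
        offsets = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        g = starts + offsets
        return self.sidx[g], q_rep, self.pos[g]


# ------------------------------------------------------------- chain/refine

_BAND = 40          # diagonal tolerance within one chained block
_CHAIN_GAP = 400    # max anchor spacing along the query within one block


def _chain_blocks(qp: np.ndarray, sp: np.ndarray, k: int
                  ) -> list[tuple[int, int, int, int]]:
    """Greedy diagonal chaining of anchors into candidate blocks."""
    diag = qp - sp
    order = np.lexsort((qp, diag))
    diag_s, qp_s, sp_s = diag[order], qp[order], sp[order]
    blocks: list[tuple[int, int, int, int]] = []
    brk = np.nonzero(np.diff(diag_s) > _BAND)[0] + 1
    for grp in np.split(np.arange(diag_s.size), brk):
        q_g, s_g = qp_s[grp], sp_s[grp]
        o2 = np.argsort(q_g, kind="stable")
        q_g, s_g = q_g[o2], s_g[o2]
        brk2 = np.nonzero(np.diff(q_g) > _CHAIN_GAP)[0] + 1
        for chunk in np.split(np.arange(q_g.size), brk2):
            qs, qe = int(q_g[chunk[0]]), int(q_g[chunk[-1]]) + k
            ss, se = int(s_g[chunk].min()), int(s_g[chunk].max()) + k
            blocks.append((qs, qe, ss, se))
    return blocks


_XDROP = 50


def _ext_len(a: np.ndarray, b: np.ndarray) -> int:
    """Diagonal extension length: best prefix under +1/-3 scoring, with an
    x-drop cutoff so extension cannot tunnel through unrelated sequence."""
    if a.size == 0:
        return 0
    m = (a == b) & (a != 4)
    score = np.where(m, 1, -3).cumsum()
    runmax = np.maximum.accumulate(score)
    dropped = np.nonzero(runmax - score > _XDROP)[0]
    if dropped.size:
        score = score[:dropped[0]]
    if score.size == 0 or score.max() <= 0:
        return 0
    return int(score.argmax()) + 1


def _extend_exact(qe_arr: np.ndarray, se_arr: np.ndarray,
                  qs: int, qe: int, ss: int, se: int
                  ) -> tuple[int, int, int, int]:
    """Extend a block outward along the diagonal, past isolated mismatches."""
    L = min(qs, ss)
    if L:
        ext = _ext_len(qe_arr[qs - L:qs][::-1], se_arr[ss - L:ss][::-1])
        qs -= ext
        ss -= ext
    R = min(qe_arr.size - qe, se_arr.size - se)
    if R:
        ext = _ext_len(qe_arr[qe:qe + R], se_arr[se:se + R])
        qe += ext
        se += ext
    return qs, qe, ss, se


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _refine(qseq: str, sseq: str, qs: int, qe: int, ss: int, se: int
            ) -> tuple[int, int, int, int, int, float] | None:
    """Global-align the block with edlib; trim ragged ends; score identity."""
    res = edlib.align(qseq[qs:qe], sseq[ss:se], mode="NW", task="path")
    cigar = res.get("cigar")
    if not cigar:
        return None
    ops = _cigar_ops(cigar)
    # trim non-matching runs at the extremities (indel/mismatch overhangs)
    while ops and ops[0][1] != "=":
        n, op = ops.pop(0)
        if op in ("=", "X", "I"):
            qs += n
        if op in ("=", "X", "D"):
            ss += n
    while ops and ops[-1][1] != "=":
        n, op = ops.pop()
        if op in ("=", "X", "I"):
            qe -= n
        if op in ("=", "X", "D"):
            se -= n
    if not ops:
        return None
    cols = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    return qs, qe, ss, se, cols, matches / cols


def _dedupe(blocks: list[tuple[int, int, int, int]]
            ) -> list[tuple[int, int, int, int]]:
    """Collapse blocks whose query AND subject intervals largely coincide."""
    blocks = sorted(blocks, key=lambda b: -(b[1] - b[0]))
    kept: list[tuple[int, int, int, int]] = []
    for b in blocks:
        qs, qe, ss, se = b
        redundant = False
        for qs2, qe2, ss2, se2 in kept:
            qo = min(qe, qe2) - max(qs, qs2)
            so = min(se, se2) - max(ss, ss2)
            if qo > 0.8 * (qe - qs) and so > 0.8 * (se - ss):
                redundant = True
                break
        if not redundant:
            kept.append(b)
    return kept


def align(queries: Sequence[SeqRecord], subjects: Sequence[SeqRecord],
          min_len: int = 100, min_identity: float = 0.9,
          k: int = 15, max_occ: int = 200) -> list[AlignmentHit]:
    """All local alignments between queries and subjects, both strands.

    Trivial full-length self-identity hits (same id) are excluded; other
    self-hits (internal repeats, inverted duplications) are reported.
    Output order is deterministic: (qid, sid, strand, qstart).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not queries or not subjects:
        return []
    index = _SubjectIndex(subjects, k, max_occ)
    hits: list[AlignmentHit] = []
    for q in queries:
        q_fwd = _encode(q.seq)
        for strand in ("+", "-"):
            qseq = q.seq if strand == "+" else revcomp(q.seq)
            qenc = q_fwd if strand == "+" else _encode(qseq)
            qvals, qpos = _kmer_values(qenc, k)
            sidx, qp, sp = index.anchors(qvals, qpos)
            if sidx.size == 0:
                continue
            for si in np.unique(sidx):
                s_id = index.ids[si]
                mask = sidx == si
                qp_i, sp_i = qp[mask], sp[mask]
                if q.id == s_id and strand == "+":
                    keep = qp_i != sp_i  # skip the trivial identity diagonal
                    qp_i, sp_i = qp_i[keep], sp_i[keep]
                    if qp_i.size == 0:
                        continue
                senc = index.enc[s_id]
                raw = _chain_blocks(qp_i, sp_i, k)
                ext = [_extend_exact(qenc, senc, *b) for b in raw]
                for qs, qe, ss, se in _dedupe(ext):
                    if min(qe - qs, se - ss) < min_len:
                        continue
                    ref = _refine(qseq, _decode_cache(index, s_id),
                                  qs, qe, ss, se)
                    if ref is None:
                        continue
                    qs2, qe2, ss2, se2, cols, ident = ref
                    if cols < min_len or ident < min_identity:
                        continue
                    if min(qe2 - qs2, se2 - ss2) < 1:
                        continue
                    if strand == "+":
                        h_qs, h_qe = qs2, qe2
                    else:  # map back to the query's forward strand
                        h_qs, h_qe = q.length - qe2, q.length - qs2
                    if (q.id == s_id and strand == "+"
                            and h_qs == ss2 and h_qe == se2):
                        continue
                    hits.append(AlignmentHit(q.id, s_id, h_qs, h_qe,
                                             ss2, se2, strand, cols, ident))
    hits.sort(key=lambda h: (h.qid, h.sid, h.strand, h.qstart, h.sstart))
    return hits


_DECODE = np.array(list("ACGTN"))


def _decode_cache(index: _SubjectIndex, sid: str) -> str:
    cache = getattr(index, "_seq_cache", None)
    if cache is None:
        cache = index._seq_cache = {}
    if sid not in cache:
        cache[sid] = "".join(_DECODE[index.enc[sid]])
    return cache[sid]


# ------------------------------------------------------------- containment

def containment(inner: SeqRecord, outer: SeqRecord,
                hits: Iterable[AlignmentHit]) -> ContainmentResult:
    """How much of ``inner`` is found in ``outer``.

    ``alignment_rate`` is the unioned fraction of inner covered by hits of
    this pair (inner as query); ``identity`` is the alignment-length-weighted
    mean identity of those hits.
    """
    ivs: list[tuple[int, int]] = []
    wsum = 0.0
    lsum = 0
    for h in hits:
        if h.qid != inner.id or h.sid != outer.id:
            continue
        ivs.append((h.qstart, h.qend))
        wsum += h.identity * h.aln_len
        lsum += h.aln_len
    if not ivs:
        return ContainmentResult(inner.id, outer.id, 0.0, 0.0)
    ivs.sort()
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return ContainmentResult(inner.id, outer.id,
                             covered / inner.length, wsum / lsum)


# --------------------------------------------------------------- dovetails

def classify_end_overlap(hit: AlignmentHit, a_len: int, b_len: int,
                         max_overhang: int = 50, min_overlap: int = 200
                         ) -> EndOverlap | None:
    """Classify a hit as a proper dovetail, or return None.

    A dovetail must reach within ``max_overhang`` of exactly one end of each
    sequence on strand-consistent ends: suffix-to-prefix on ``+``,
    like-end-to-like-end on ``-``.  Containment-shaped hits (alignment
    internal to one sequence, or a whole sequence inside the overhang
    margin) are rejected.
    """
    if hit.aln_len < min_overlap:
        return None
    a_head, a_tail = hit.qstart, a_len - hit.qend
    b_head, b_tail = hit.sstart, b_len - hit.send
    if hit.strand == "+":
        cases = [("tail", "head", a_tail, b_head, a_head, b_tail),
                 ("head", "tail", a_head, b_tail, a_tail, b_head)]
    else:
        cases = [("tail", "tail", a_tail, b_tail, a_head, b_head),
                 ("head", "head", a_head, b_head, a_tail, b_tail)]
    for a_end, b_end, da, db, ra, rb in cases:
        if (da <= max_overhang and db <= max_overhang
                and ra > max_overhang and rb > max_overhang):
            return EndOverlap(hit.qid, hit.sid, a_end, b_end,
                              hit.aln_len, hit.identity, hit.strand,
                              da, db, hit)
    return None


def hits_tsv(hits: Iterable[AlignmentHit]) -> str:
    """Debug dump of hits as a tab-separated overlap table."""
    rows = ["qid\tsid\tqstart\tqend\tsstart\tsend\tstrand\taln_len\tidentity"]
    for h in hits:
        rows.append(f"{h.qid}\t{h.sid}\t{h.qstart}\t{h.qend}\t{h.sstart}"
                    f"\t{h.send}\t{h.strand}\t{h.aln_len}\t{h.identity:.4f}")
    return "\n".join(rows) + "\n"
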