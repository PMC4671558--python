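"""Independent reference implementations used only by the test suite.

These deliberately take different routes from the package: exact DP local
alignment via Biopython's PairwiseAligner, a geometric enumeration for
dovetail classification, and greedy redundancy removal over containment
relations known analytically from instance construction.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

from asmpatch.sequence_io import Origin, SeqRecord, revcomp


# ------------------------------------------------- exact DP local aligner

def dp_local_block(a: str, b: str) -> tuple[int, int, int, int]:
    """Best local alignment block (exact DP): (astart, aend, bstart, bend)."""
    aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                    mismatch_score=-3, open_gap_score=-5,
                                    extend_gap_score=-5)
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    return (int(blocks_a[0][0]), int(blocks_a[-1][1]),
            int(blocks_b[0][0]), int(blocks_b[-1][1]))


# ----------------------------------------- geometric dovetail enumeration

def classify_oracle(qstart: int, qend: int, sstart: int, send: int,
                    strand: str, aln_len: int, a_len: int, b_len: int,
                    max_overhang: int, min_overlap: int
                    ) -> tuple[str, str] | None:
    """Dovetail decision by enumerating end-distance conditions."""
    if aln_len < min_overlap:
        return None
    near_a_head = qstart <= max_overhang
    near_a_tail = a_len - qend <= max_overhang
    near_b_head = sstart <= max_overhang
    near_b_tail = b_len - send <= max_overhang
    if near_a_head == near_a_tail or near_b_head == near_b_tail:
        return None  # reaches zero or both ends of one sequence
    a_end = "head" if near_a_head else "tail"
    b_end = "head" if near_b_head else "tail"
    consistent = (a_end != b_end) if strand == "+" else (a_end == b_end)
    return (a_end, b_end) if consistent else None


# ------------------------------- constructed redundancy-removal instances

def build_containment_instance(rng: np.random.Generator
                               ) -> tuple[list[SeqRecord], list[str],
                                          dict[str, str]]:
    """A random pool whose containment structure is known by construction.

    Backbones are long random sequences; each extra sequence is either a
    lightly mutated substring of a backbone (contained: rate 1.0, identity
    ~0.99), a half-substring/half-random chimera (alignment rate ~0.5) or
    a heavily mutated substring (identity ~0.88) — only the first kind is
    removable at the >95 %/>95 % thresholds.  Returns the pool, the
    expected representatives in selection order, and the expected
    delineation map.
    """
    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    def mutate(s: str, rate: float) -> str:
        out = list(s)
        n_mut = int(round(len(s) * rate))
        for p in rng.choice(len(s), size=n_mut, replace=False):
            out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4)))
                            % 4]
        return "".join(out)

    n_backbones = int(rng.integers(2, 5))
    backbones = []
    for i in range(n_backbones):
        L = int(rng.integers(3000, 5001)) - i  # distinct lengths
        backbones.append(SeqRecord(f"bb{i}", rand_seq(L), Origin.contig))
    pool: list[SeqRecord] = list(backbones)
    expected_delineated: dict[str, str] = {}
    survivors: list[SeqRecord] = []
    n_extra = int(rng.integers(4, 17))
    for j in range(n_extra):
        bb = backbones[int(rng.integers(0, n_backbones))]
        L = int(rng.integers(500, 2500))
        start = int(rng.integers(0, bb.length - L + 1))
        sub = bb.seq[start:start + L]
        kind = int(rng.integers(0, 3))
        if kind == 0:  # contained
            s = mutate(sub, float(rng.uniform(0, 0.01)))
            if rng.random() < 0.5:
                s = revcomp(s)
            rec = SeqRecord(f"cont{j}", s, Origin.cpblr)
            expected_delineated[rec.id] = bb.id
        elif kind == 1:  # half real, half noise
            s = sub[:L // 2] + rand_seq(L - L // 2)
            rec = SeqRecord(f"part{j}", s, Origin.cpblr)
            survivors.append(rec)
        else:  # diverged beyond the identity threshold
            s = mutate(sub, 0.12)
            rec = SeqRecord(f"div{j}", s, Origin.cpblr)
            survivors.append(rec)
        pool.append(rec)
    reps = sorted(backbones, key=lambda r: (-r.length, r.id)) + sorted(
        survivors, key=lambda r: (-r.length, r.id))
    return pool, [r.id for r in reps], expected_delineated


# ---------------------------------------------------------- brute-force N50

def n50_bruteforce(lengths: list[int]) -> int:
    """Largest L with sum(lengths >= L) covering at least half the total."""
    total = sum(lengths)
    best = min(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = L
            break
    return best
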