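import re

import numpy as np
import pytest

from asmpatch.modify import (CoverageProfile, compute_coverage, fill_gaps,
                             find_gaps, modify_assembly, split_zero_coverage)
from asmpatch.sequence_io import revcomp
from asmpatch.synthetic import write_fastq
from conftest import contig, cpblr, rand_seq


# ----------------------------------------------------------------- gaps

def test_no_gap_in_clean_sequence():
    assert find_gaps(contig("c", "ACGT")) == []


def test_single_gap_with_flanks():
    c = contig("c", "AAAA" + "NNN" + "CCCC")
    gaps = find_gaps(c, flank_len=4)
    assert len(gaps) == 1
    g = gaps[0]
    assert (g.start, g.end) == (4, 7)
    assert g.left_flank == "AAAA" and g.right_flank == "CCCC"
    assert not g.short_flank


def test_short_flank_marked():
    gaps = find_gaps(contig("c", "AA" + "NN" + "CCCC"), flank_len=4)
    assert gaps[0].short_flank
    # adjacent gaps closer than a flank contaminate each other's flank
    gaps = find_gaps(contig("c", "A" * 10 + "N" + "AA" + "N" + "A" * 10),
                     flank_len=4)
    assert all(g.short_flank for g in gaps)


def test_gap_intervals_match_scan_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(20, 300))
        seq = list(rand_seq(rng, n))
        for _ in range(int(rng.integers(0, 4))):
            s = int(rng.integers(0, n))
            e = min(n, s + int(rng.integers(1, 20)))
            seq[s:e] = "N" * (e - s)
        seq = "".join(seq)
        got = [(g.start, g.end) for g in find_gaps(contig("c", seq))]
        exp = [(m.start(), m.end()) for m in re.finditer("N+", seq)]
        assert got == exp


# ------------------------------------------------------------- gap fill

def _gap_setup(rng):
    left = rand_seq(rng, 100)
    right = rand_seq(rng, 100)
    c = contig("c", rand_seq(rng, 50) + left + "N" * 6 + right
               + rand_seq(rng, 50))
    return c, left, right


def test_three_votes_fill_beats_one_dissent(rng):
    c, left, right = _gap_setup(rng)
    reads = [cpblr(f"r{i}", left + "ATGCTA" + right) for i in range(3)]
    reads.append(cpblr("d", left + "GGCGGC" + right))
    out, events = fill_gaps(c, find_gaps(c), reads)
    assert "ATGCTA" in out.seq and "N" not in out.seq
    assert events[0].votes == 3 and events[0].n_spanning == 4


def test_two_votes_insufficient(rng):
    c, left, right = _gap_setup(rng)
    reads = [cpblr(f"r{i}", left + "ATGCTA" + right) for i in range(2)]
    out, events = fill_gaps(c, find_gaps(c), reads)
    assert out.seq == c.seq and events == []


def test_tie_has_no_unique_maximum(rng):
    c, left, right = _gap_setup(rng)
    reads = ([cpblr(f"a{i}", left + "ATGCTA" + right) for i in range(3)]
             + [cpblr(f"b{i}", left + "TTTTTT" + right) for i in range(3)])
    out, events = fill_gaps(c, find_gaps(c), reads)
    assert out.seq == c.seq and events == []


def test_reverse_strand_reads_count(rng):
    c, left, right = _gap_setup(rng)
    reads = [cpblr(f"r{i}", revcomp(left + "ATGCTA" + right))
             for i in range(3)]
    out, _ = fill_gaps(c, find_gaps(c), reads)
    assert "ATGCTA" in out.seq


def test_simulated_gap_restored_exactly(rng):
    genome = rand_seq(rng, 20_000)
    start = 9_850
    truth = genome[start:start + 300]
    c = contig("c", genome[:start] + "N" * 300 + genome[start + 300:])
    reads = [cpblr(f"r{i}", genome[start - 2000 + i * 170:
                                   start + 2300 + i * 170])
             for i in range(10)]
    out, events = fill_gaps(c, find_gaps(c), reads)
    assert out.seq == genome
    assert events[0].replacement_len == 300
    assert truth in out.seq


def test_fill_never_increases_n_count(rng):
    c, left, right = _gap_setup(rng)
    reads = [cpblr(f"r{i}", left + "AT" + right) for i in range(5)]
    out, _ = fill_gaps(c, find_gaps(c), reads)
    assert out.seq.count("N") <= c.seq.count("N")


# ------------------------------------------------------------- coverage

def test_unaligned_reads_give_zero_profile(tmp_path, rng):
    c = contig("c", rand_seq(rng, 200))
    fq = tmp_path / "r.fq"
    write_fastq([cpblr("r", rand_seq(rng, 50))], fq)
    prof = compute_coverage([c], [fq])
    assert prof["c"].depth.sum() == 0


def test_single_read_interval(tmp_path, rng):
    c = contig("c", rand_seq(rng, 20))
    fq = tmp_path / "r.fq"
    write_fastq([cpblr("r", c.seq[5:15])], fq)
    depth = compute_coverage([c], [fq])["c"].depth
    assert list(depth) == [0] * 5 + [1] * 10 + [0] * 5


def test_repeat_read_counts_all_best_placements(tmp_path, rng):
    block = rand_seq(rng, 60)
    c = contig("c", block + rand_seq(rng, 100) + block)
    fq = tmp_path / "r.fq"
    write_fastq([cpblr("r", block[10:50])], fq)
    depth = compute_coverage([c], [fq])["c"].depth
    assert depth[20] == 1 and depth[180] == 1  # both copies covered


def test_uniform_coverage_matches_expectation(tmp_path, rng):
    c = contig("c", rand_seq(rng, 5000))
    n = 1000  # 20X at 100 bp
    reads = []
    for i in range(n):
        s = int(rng.integers(0, 4901))
        seq = c.seq[s:s + 100]
        reads.append(cpblr(f"r{i}", seq if rng.random() < 0.5
                           else revcomp(seq)))
    fq = tmp_path / "r.fq"
    write_fastq(reads, fq)
    depth = compute_coverage([c], [fq])["c"].depth
    interior = depth[200:-200]
    assert 15 < interior.mean() < 25
    assert depth[0] <= depth[2500]  # ends taper


# --------------------------------------------------------------- splits

def test_positive_profile_unchanged(rng):
    c = contig("c", rand_seq(rng, 300))
    segs, ev = split_zero_coverage(c, CoverageProfile("c", np.ones(300)))
    assert segs == [c] and ev == []


def test_terminal_zero_run_exempt(rng):
    c = contig("c", rand_seq(rng, 1000))
    depth = np.ones(1000)
    depth[996:] = 0  # last 0.4% < 1% window
    segs, ev = split_zero_coverage(c, CoverageProfile("c", depth))
    assert segs == [c]


def test_interior_run_excised_and_small_piece_discarded(rng):
    c = contig("c", rand_seq(rng, 1000))
    depth = np.ones(1000)
    depth[400:430] = 0
    depth[470:500] = 0
    segs, ev = split_zero_coverage(c, CoverageProfile("c", depth))
    assert [s.length for s in segs] == [400, 500]
    assert [s.id for s in segs] == ["c_p1", "c_p2"]
    assert segs[0].seq == c.seq[:400] and segs[1].seq == c.seq[500:]
    discards = [e for e in ev if e.kind == "discard"]
    assert [(e.start, e.end) for e in discards] == [(430, 470)]


def test_split_conservation(rng):
    """Kept + discarded + excised intervals tile the original contig."""
    for _ in range(50):
        L = int(rng.integers(200, 2000))
        c = contig("c", rand_seq(rng, L))
        depth = rng.integers(0, 3, L)
        segs, ev = split_zero_coverage(c, CoverageProfile("c", depth))
        if not ev:
            assert segs == [c]
            continue
        ivs = sorted((e.start, e.end) for e in ev)
        assert ivs[0][0] == 0 and ivs[-1][1] == L
        assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))
        kept = {(e.start, e.end): e.segment_id for e in ev
                if e.kind == "keep"}
        for s in segs:
            iv = next(k for k, v in kept.items() if v == s.id)
            assert c.seq[iv[0]:iv[1]] == s.seq


def test_mismatched_profile_rejected(rng):
    c = contig("c", rand_seq(rng, 100))
    with pytest.raises(ValueError):
        split_zero_coverage(c, CoverageProfile("c", np.ones(99)))


# -------------------------------------------------------------- stage 1

def test_modify_assembly_without_reads_skips_splitting(rng):
    c, left, right = _gap_setup(rng)
    reads = [cpblr(f"r{i}", left + "ATGCTA" + right) for i in range(3)]
    out, fills, splits = modify_assembly([c], reads, None)
    assert len(out) == 1 and "N" not in out[0].seq
    assert len(fills) == 1 and splits == []
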