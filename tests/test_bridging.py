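import numpy as np
import pytest

from asmpatch.bridging import (ConnectedSequence, apply_bridges,
                               estimate_max_repeat, find_easy_bridges,
                               find_strict_bridges, iterative_connect,
                               layout_of, merge_end_overlaps, reconstruct,
                               rescue_delineated, slice_layout, _Joiner)
from asmpatch.config import PatchConfig
from asmpatch.representatives import RepresentativeSet, select_representatives
from asmpatch.sequence_io import Origin, SeqRecord, revcomp
from conftest import contig, cpblr, rand_seq

CFG = PatchConfig()


def _sources(*records):
    return {r.id: r.seq for r in records}


# ----------------------------------------------------- strict uniqueness

def _margin_pool(rng, second_len):
    """Bridge R: head overlaps contig A by 1000 bp and a decoy by
    ``second_len``; tail overlaps contig B by 1000 bp uniquely."""
    r = rand_seq(rng, 3000)
    a = contig("A", rand_seq(rng, 2000) + r[:1000])
    decoy = contig("D", rand_seq(rng, 2000) + r[:second_len])
    b = contig("B", r[-1000:] + rand_seq(rng, 2000))
    return [a, decoy, b, cpblr("R", r)]


def test_margin_rejects_close_secondary(rng):
    bridges = find_strict_bridges(_margin_pool(rng, 900), CFG)
    assert bridges == []  # 1000 < 1.25 x 900


def test_margin_accepts_clear_secondary(rng):
    bridges = find_strict_bridges(_margin_pool(rng, 700), CFG)
    assert len(bridges) == 1
    b = bridges[0]
    assert b.bridge_id == "R" and b.mode == "strict"
    assert {b.left.target_id, b.right.target_id} == {"A", "B"}


def test_margin_boundary_is_accepted(rng):
    # 1000 == 1.25 x 800 exactly: "at least 1.25-fold" is inclusive
    assert len(find_strict_bridges(_margin_pool(rng, 800), CFG)) == 1


def test_no_end_overlaps_no_bridges(rng):
    pool = [contig(f"c{i}", rand_seq(rng, 1000)) for i in range(3)]
    assert find_strict_bridges(pool, CFG) == []


def test_both_cpblr_targets_rejected(rng):
    r = rand_seq(rng, 3000)
    pool = [cpblr("X", rand_seq(rng, 2000) + r[:1000]),
            cpblr("Y", r[-1000:] + rand_seq(rng, 2000)),
            cpblr("R", r)]
    assert find_strict_bridges(pool, CFG) == []


# ------------------------------------------------------- bridge geometry

def test_bridge_fills_gap_between_targets(rng):
    g = rand_seq(rng, 22_000)
    a = contig("A", g[:10_000])
    b = contig("B", g[12_000:])
    r = cpblr("R", g[9_000:13_000])
    pool = {x.id: x for x in (a, b, r)}
    bridges = find_strict_bridges(list(pool.values()), CFG)
    assert len(bridges) == 1
    joiner = _Joiner()
    new, consumed = apply_bridges(bridges, pool, joiner)
    assert consumed == {"A", "B", "R"}
    assert len(new) == 1 and new[0].seq == g
    assert joiner.events[0].insert_len == 2000
    assert reconstruct(new[0].layout, _sources(a, b, r)) == g


def test_overlapping_targets_trimmed_once(rng):
    g = rand_seq(rng, 20_000)
    a = contig("A", g[:10_000])
    b = contig("B", g[9_500:])
    r = cpblr("R", g[8_000:11_000])
    pool = {x.id: x for x in (a, b, r)}
    bridges = find_strict_bridges(list(pool.values()), CFG)
    assert len(bridges) == 1
    joiner = _Joiner()
    new, _ = apply_bridges(bridges, pool, joiner)
    assert new[0].seq == g  # sum - overlap, trim applied once
    assert joiner.events[0].trim == 500


def test_reverse_oriented_target_handled(rng):
    g = rand_seq(rng, 22_000)
    a = contig("A", g[:10_000])
    b = contig("B", revcomp(g[12_000:]))
    r = cpblr("R", g[9_000:13_000])
    pool = {x.id: x for x in (a, b, r)}
    bridges = find_strict_bridges(list(pool.values()), CFG)
    assert len(bridges) == 1
    new, _ = apply_bridges(bridges, pool, _Joiner())
    assert new[0].seq in (g, revcomp(g))
    assert reconstruct(new[0].layout, _sources(a, b, r)) == new[0].seq


def test_empty_bridge_list_leaves_pool(rng):
    pool = {f"c{i}": contig(f"c{i}", rand_seq(rng, 500)) for i in range(3)}
    new, consumed = apply_bridges([], pool, _Joiner())
    assert new == [] and consumed == set() and len(pool) == 3


def test_consumed_end_skips_second_bridge(rng):
    g = rand_seq(rng, 40_000)
    a = contig("A", g[:10_000])
    b = contig("B", g[12_000:22_000])
    r1 = cpblr("R1", g[9_000:13_000])
    r2 = cpblr("R2", g[9_500:12_500])  # same junction, shorter bridge
    pool = {x.id: x for x in (a, b, r1, r2)}
    bridges = find_strict_bridges(list(pool.values()), CFG)
    joiner = _Joiner()
    new, consumed = apply_bridges(bridges, pool, joiner)
    assert len(new) == 1  # the longer bridge won; the other was skipped
    assert joiner.events[0].bridge_id == "R1"


# -------------------------------------------------------- repeat bound

def test_unrelated_sequences_have_no_repeat(rng):
    pool = [contig(f"c{i}", rand_seq(rng, 3000)) for i in range(3)]
    assert estimate_max_repeat(pool, CFG).max_repeat == 0


def test_planted_interspersed_repeat_measured(rng):
    rep = rand_seq(rng, 3000)
    a = contig("A", rand_seq(rng, 2000) + rep + rand_seq(rng, 2000))
    b = contig("B", rand_seq(rng, 1500) + rep + rand_seq(rng, 2500))
    est = estimate_max_repeat([a, b], CFG).max_repeat
    assert est == pytest.approx(3000, abs=60)


def test_inverted_self_repeat_measured(rng):
    block = rand_seq(rng, 2000)
    s = contig("S", rand_seq(rng, 1000) + block + rand_seq(rng, 1000)
               + revcomp(block) + rand_seq(rng, 1000))
    est = estimate_max_repeat([s], CFG).max_repeat
    assert est == pytest.approx(2000, abs=60)


def test_pure_dovetail_not_a_repeat(rng):
    g = rand_seq(rng, 10_000)
    a = contig("A", g[:6_000])
    b = contig("B", g[5_000:])
    assert estimate_max_repeat([a, b], CFG).max_repeat == 0


# --------------------------------------------------------- easy bridging

def _easy_setup(rng):
    g = rand_seq(rng, 24_000)
    a = contig("A", g[:10_000])
    b = contig("B", g[14_000:])
    r = cpblr("R", g[9_000:15_000])  # 6 kb spanning the 4-kb gap
    return a, b, r


def test_easy_bridge_found(rng):
    a, b, r = _easy_setup(rng)
    bridges = find_easy_bridges([r], [a, b], max_repeat=3000, cfg=CFG)
    assert len(bridges) == 1 and bridges[0].mode == "easy"


def test_easy_bridge_length_gate(rng):
    a, b, r = _easy_setup(rng)
    assert find_easy_bridges([r], [a, b], max_repeat=6000, cfg=CFG) == []


def test_easy_bridge_ambiguous_end_rejected(rng):
    a, b, r = _easy_setup(rng)
    decoy = contig("C", rand_seq(rng, 5000) + a.seq[-1000:])
    assert find_easy_bridges([r], [a, b, decoy], max_repeat=3000,
                             cfg=CFG) == []


# --------------------------------------------------------------- rescue

def test_delineated_read_recovers_bridge(rng):
    a, b, rd = _easy_setup(rng)
    rd = cpblr("RD", rd.seq)
    rp = cpblr("RP", rd.seq + rand_seq(rng, 1000))  # ambiguous second end
    delineated = {"RD": "RP"}
    removed = {"RD": rd}
    bridges = rescue_delineated([rp], delineated, removed, [a, b],
                                max_repeat=3000, cfg=CFG)
    assert len(bridges) == 1
    assert bridges[0].bridge_id == "RD" and bridges[0].mode == "rescue"


def test_empty_delineation_map_rescues_nothing(rng):
    a, b, r = _easy_setup(rng)
    assert rescue_delineated([r], {}, {}, [a, b], 0, CFG) == []


def test_rescued_candidate_shorter_than_repeat_rejected(rng):
    a, b, rd = _easy_setup(rng)
    rp = cpblr("RP", rd.seq + rand_seq(rng, 1000))
    bridges = rescue_delineated([rp], {"RD": "RP"}, {"RD": cpblr("RD", rd.seq)},
                                [a, b], max_repeat=len(rd.seq), cfg=CFG)
    assert bridges == []


# ------------------------------------------------------------ end merge

def test_long_dovetail_merged_with_conservation(rng):
    g = rand_seq(rng, 15_000)
    a = contig("A", g[:10_000])
    b = contig("B", g[5_000:])
    pool = {"A": a, "B": b}
    joiner = _Joiner()
    n = merge_end_overlaps(pool, max_repeat=3000, cfg=CFG, joiner=joiner)
    assert n == 1 and len(pool) == 1
    merged = next(iter(pool.values()))
    assert merged.seq == g  # sum - overlap
    assert reconstruct(merged.layout, _sources(a, b)) == g


def test_short_dovetail_gated_by_repeat_bound(rng):
    g = rand_seq(rng, 18_000)
    a = contig("A", g[:10_000])
    b = contig("B", g[8_000:])
    pool = {"A": a, "B": b}
    assert merge_end_overlaps(pool, max_repeat=3000, cfg=CFG,
                              joiner=_Joiner()) == 0
    assert len(pool) == 2


def test_ambiguous_star_overlap_not_merged(rng):
    x = rand_seq(rng, 4000)
    a = contig("A", rand_seq(rng, 6000) + x)
    b = contig("B", x + rand_seq(rng, 6000))
    c = contig("C", x + rand_seq(rng, 6000))
    pool = {"A": a, "B": b, "C": c}
    assert merge_end_overlaps(pool, max_repeat=1000, cfg=CFG,
                              joiner=_Joiner()) == 0


# ----------------------------------------------------- layout machinery

def test_slice_layout_roundtrip(rng):
    src = contig("s", rand_seq(rng, 500))
    flipped = slice_layout(src, 100, 400, flip=True)
    assert reconstruct(flipped, _sources(src)) == revcomp(src.seq)[100:400]
    nested = ConnectedSequence("j", revcomp(src.seq)[100:400], Origin.contig,
                               flipped)
    again = slice_layout(nested, 50, 250, flip=True)
    assert reconstruct(again, _sources(src)) == revcomp(nested.seq)[50:250]


# ----------------------------------------------------------- the driver

def test_driver_without_cpblrs_is_identity(rng):
    contigs = [contig(f"c{i}", rand_seq(rng, 2000)) for i in range(3)]
    reps = RepresentativeSet(contigs, {}, {}, [])
    final, events, unused = iterative_connect(reps, CFG)
    assert sorted(r.id for r in final) == ["c0", "c1", "c2"]
    assert events == [] and unused == []


def test_driver_chains_multiple_junctions(rng):
    g = rand_seq(rng, 60_000)
    cuts = [0, 15_000, 30_000, 45_000, 60_000]
    contigs = [contig(f"c{i}", g[cuts[i]:cuts[i + 1]]) for i in range(4)]
    reads = [cpblr(f"r{i}", g[c - 3000:c + 3000])
             for i, c in enumerate(cuts[1:-1])]
    reps = select_representatives(contigs + reads)
    final, events, unused = iterative_connect(reps, CFG)
    assert len(final) == 1
    assert final[0].seq == g
    assert len(final) <= len(reps.representatives)  # free ends decreased
    sources = _sources(*contigs, *reads)
    assert reconstruct(layout_of(final[0]), sources) == final[0].seq
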