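"""Synthetic study scenarios with known ground truth.

Emulates the data regime the patching pipeline targets: a microbial-scale
genome with a few multi-kb repeat families, a draft assembly fragmented at
every repeat copy (short-read assemblers cannot phase long repeats), planted
N-gaps and optional chimeric joins, kb-scale corrected long reads with very
low residual error (~0.01 %), and uniform error-free short reads whose only
zero-coverage positions are engineered false junctions.

All randomness flows from one seed through per-component child streams, so
adding reads to a scenario never perturbs its genome.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from .sequence_io import Origin, SeqRecord, revcomp

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SimScenario:
    """Study conditions for one synthetic run.

    Defaults describe the reference scenario: a 200-kb genome carrying
    three 4-kb repeat families with two copies each at 98 % identity
    (fragmenting the draft into seven contigs), one 300-bp N-gap, one
    chimeric join, 15X long reads of mean 8 kb with 1e-4 error, and 20X
    error-free 100-bp short reads.
    """

    seed: int = 0
    genome_len: int = 200_000
    repeat_specs: tuple[tuple[int, int, float], ...] = (
        (4000, 2, 0.98), (4000, 2, 0.98), (4000, 2, 0.98))
    n_gap_specs: tuple[tuple[int, int], ...] = ((0, 300),)
    chimera_specs: tuple[tuple[int, int], ...] = ((2, 5),)
    cpblr_depth: float = 15.0
    cpblr_len_mean: float = 8000.0
    cpblr_len_sd: float = 1500.0
    cpblr_error: float = 1e-4
    short_read_len: int = 100
    short_depth: float = 20.0
    short_error: float = 0.0
    min_locus_gap: int = 12_000   # spacing between repeat loci (clean contigs)

    def __post_init__(self) -> None:
        for r in (self.cpblr_error, self.short_error):
            if not 0 <= r <= 1:
                raise ValueError("error rates must be in [0, 1]")
        if self.cpblr_depth < 0 or self.short_depth < 0:
            raise ValueError("depths must be >= 0")
        for length, copies, ident in self.repeat_specs:
            if length >= self.genome_len:
                raise ValueError("repeat length must be < genome length")
            if not 0 < ident <= 1 or copies < 1:
                raise ValueError("bad repeat spec")

    def _child_rng(self, component: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(component,))
        return np.random.default_rng(ss)


@dataclasses.dataclass
class TruthTable:
    genome: str
    repeat_loci: list[tuple[int, int, int]]          # family, start, end
    contig_placements: dict[str, tuple[int, int]]    # draft id -> genome interval
    gap_truth: dict[str, list[tuple[int, int, str]]] # contig -> (start, end, seq)
    chimeras: list[tuple[str, str, str, int]]        # id, left, right, junction
    cpblr_placements: dict[str, tuple[int, int, str]]
    adjacency: list[str]                             # contig ids along the genome

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("genome")
        return json.dumps(d, indent=1)


def _random_genome(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _mutate_subs(rng: np.random.Generator, arr: np.ndarray,
                 identity: float) -> np.ndarray:
    """Substitute bases to reach the target identity (positions exact count)."""
    out = arr.copy()
    n_mut = int(round(len(arr) * (1 - identity)))
    if n_mut == 0:
        return out
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def simulate_genome(scenario: SimScenario
                    ) -> tuple[str, TruthTable]:
    """Uniform background with planted, mutually non-overlapping repeats."""
    rng = scenario._child_rng(0)
    g = _random_genome(rng, scenario.genome_len)
    loci: list[tuple[int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    margin = scenario.min_locus_gap
    for fam, (length, copies, ident) in enumerate(scenario.repeat_specs):
        master = _random_genome(rng, length)
        for _ in range(copies):
            placed = False
            for _attempt in range(10_000):
                pos = int(rng.integers(margin,
                                       scenario.genome_len - length - margin))
                if all(pos + length + margin <= s or pos >= e + margin
                       for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise RuntimeError("could not place repeats without overlap; "
                                   "reduce repeat load or min_locus_gap")
            copy = _mutate_subs(rng, master, ident)
            g[pos:pos + length] = copy
            occupied.append((pos, pos + length))
            loci.append((fam, pos, pos + length))
    loci.sort(key=lambda t: t[1])
    genome = "".join(_BASES[g])
    truth = TruthTable(genome, loci, {}, {}, [], {}, [])
    return genome, truth


def fragment_assembly(genome: str, truth: TruthTable, scenario: SimScenario
                      ) -> tuple[list[SeqRecord], TruthTable]:
    """Cut the genome at every repeat locus; plant gaps and chimeras.

    Repeat interiors are withheld from the draft (the short-read assembler
    could not have resolved them); N-gaps mask contig interiors per spec;
    chimeric contigs concatenate the designated non-adjacent pieces.
    """
    bounds = [0]
    for _, s, e in truth.repeat_loci:
        bounds.extend([s, e])
    bounds.append(len(genome))
    contigs: list[SeqRecord] = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = bounds[i], bounds[i + 1]
        cid = f"contig_{len(contigs)}"
        contigs.append(SeqRecord(cid, genome[s:e], Origin.contig))
        truth.contig_placements[cid] = (s, e)
        truth.adjacency.append(cid)
    for ci, gap_len in scenario.n_gap_specs:
        c = contigs[ci]
        if gap_len >= c.length - 2_000:
            raise ValueError("gap does not fit in contig")
        start = (c.length - gap_len) // 2
        true_seq = c.seq[start:start + gap_len]
        seq = c.seq[:start] + "N" * gap_len + c.seq[start + gap_len:]
        contigs[ci] = SeqRecord(c.id, seq, Origin.contig)
        truth.gap_truth.setdefault(c.id, []).append((start, start + gap_len,
                                                     true_seq))
    if scenario.chimera_specs:
        joined: list[SeqRecord] = []
        consumed: set[int] = set()
        for i, j in scenario.chimera_specs:
            a, b = contigs[i], contigs[j]
            cid = f"chimera_{i}_{j}"
            joined.append(SeqRecord(cid, a.seq + b.seq, Origin.contig))
            truth.chimeras.append((cid, a.id, b.id, a.length))
            consumed.update((i, j))
        contigs = [c for k, c in enumerate(contigs)
                   if k not in consumed] + joined
    return contigs, truth


def _apply_read_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitutions and single-base indels, each at the given per-base rate."""
    if rate == 0:
        return seq
    arr = list(seq)
    L = len(arr)
    n_sub = rng.binomial(L, rate)
    n_ins = rng.binomial(L, rate)
    n_del = rng.binomial(L, rate)
    for p in rng.choice(L, size=min(n_sub, L), replace=False):
        arr[p] = "ACGT"[(("ACGT".index(arr[p])) + int(rng.integers(1, 4))) % 4]
    for p in sorted(rng.choice(L, size=min(n_del, L), replace=False),
                    reverse=True):
        del arr[int(p)]
    for p in sorted(rng.choice(max(len(arr), 1), size=min(n_ins, len(arr)),
                               replace=False), reverse=True):
        arr.insert(int(p), "ACGT"[int(rng.integers(0, 4))])
    return "".join(arr)


def simulate_cpblrs(genome: str, scenario: SimScenario, truth: TruthTable
                    ) -> list[SeqRecord]:
    """Corrected long reads: uniform starts, truncated-normal lengths."""
    rng = scenario._child_rng(1)
    G = len(genome)
    if scenario.cpblr_depth == 0:
        return []
    n = max(1, int(round(scenario.cpblr_depth * G / scenario.cpblr_len_mean)))
    reads: list[SeqRecord] = []
    for i in range(n):
        L = int(round(rng.normal(scenario.cpblr_len_mean,
                                 scenario.cpblr_len_sd)))
        L = max(500, min(L, G))
        start = int(rng.integers(0, G - L + 1))
        raw = genome[start:start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _apply_read_errors(rng, raw, scenario.cpblr_error)
        if strand == "-":
            seq = revcomp(seq)
        rid = f"read_{i}"
        reads.append(SeqRecord(rid, seq, Origin.cpblr))
        truth.cpblr_placements[rid] = (start, start + L, strand)
    return reads


def simulate_short_reads(genome: str, scenario: SimScenario
                         ) -> list[SeqRecord]:
    """Uniform single-end short reads drawn from the true genome.

    Error-free by default: splitting tests need placement truth, not noise.
    Because reads come from real loci only, engineered false junctions in
    the draft receive zero coverage by construction.
    """
    rng = scenario._child_rng(2)
    G = len(genome)
    L = scenario.short_read_len
    if scenario.short_depth == 0:
        return []
    n = int(round(scenario.short_depth * G / L))
    reads: list[SeqRecord] = []
    for i in range(n):
        start = int(rng.integers(0, G - L + 1))
        seq = genome[start:start + L]
        seq = _apply_read_errors(rng, seq, scenario.short_error)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SeqRecord(f"sr_{i}", seq, Origin.cpblr))
    return reads


def simulate_scenario(scenario: SimScenario
                      ) -> tuple[list[SeqRecord], list[SeqRecord],
                                 list[SeqRecord], TruthTable]:
    """(draft contigs, long reads, short reads, truth) for a scenario."""
    genome, truth = simulate_genome(scenario)
    contigs, truth = fragment_assembly(genome, truth, scenario)
    cpblrs = simulate_cpblrs(genome, scenario, truth)
    shorts = simulate_short_reads(genome, scenario)
    return contigs, cpblrs, shorts, truth


# ------------------------------------------------------------------ files

def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    with open(path, "wt") as out:
        for r in records:
            out.write(f">{r.id}\n")
            for i in range(0, r.length, 80):
                out.write(r.seq[i:i + 80] + "\n")


def write_fastq(records: Sequence[SeqRecord], path: str | Path) -> None:
    with open(path, "wt") as out:
        for r in records:
            out.write(f"@{r.id}\n{r.seq}\n+\n{'I' * r.length}\n")


def write_scenario(scenario: SimScenario, outdir: str | Path
                   ) -> dict[str, Path]:
    """Materialise a scenario as draft/reads/truth files for CLI runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, cpblrs, shorts, truth = simulate_scenario(scenario)
    paths = {
        "draft": outdir / "draft.fasta",
        "cpblr": outdir / "cpblr.fasta",
        "reads": outdir / "reads.fastq",
        "truth": outdir / "truth.json",
    }
    write_fasta(contigs, paths["draft"])
    write_fasta(cpblrs, paths["cpblr"])
    write_fastq(shorts, paths["reads"])
    paths["truth"].write_text(truth.to_json())
    return paths


# --------------------------------------------------------- misjoin checks

def _infix_distance(needle: str, haystack: str, k: int) -> int:
    """Min edit distance of needle (either strand) as an infix; -1 if > k."""
    best = -1
    for s in (needle, revcomp(needle)):
        res = edlib.align(s, haystack, mode="HW", k=k)
        d = res["editDistance"]
        if d >= 0 and (best < 0 or d < best):
            best = d
    return best


def count_misjoins(records: Sequence[SeqRecord], genome: str,
                   junction_window: int = 200, junction_k: int = 20) -> int:
    """Adjacencies in the output that do not exist in the true genome.

    Two complementary checks: every layout-tile junction, taken with
    ``junction_window`` bp of context on each side, must occur in the
    genome (either strand) within ``junction_k`` edits; and every output
    sequence as a whole must be collinear with one genomic locus (edit
    distance within an error budget scaled to its length).  Sequences
    shorter than the junction window are checked whole.
    """
    from .bridging import layout_of
    misjoins = 0
    for rec in records:
        tiles = layout_of(rec)
        offsets = []
        off = 0
        for t in tiles[:-1]:
            off += t.end - t.start
            offsets.append(off)
        for off in offsets:
            lo = max(0, off - junction_window)
            hi = min(rec.length, off + junction_window)
            if _infix_distance(rec.seq[lo:hi], genome, junction_k) < 0:
                misjoins += 1
        budget = int(0.01 * rec.length) + 100
        if _infix_distance(rec.seq, genome, budget) < 0:
            misjoins += 1
    return misjoins
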