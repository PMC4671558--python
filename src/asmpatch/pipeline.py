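"""Pipeline orchestration: modification → selection → connection.

`run_patch` wires the three stages together, honours the run mode
(``full``, ``redundancy_only``, ``no_split``) and writes the output
directory: the patched FASTA, an AGP-like layout, join/delineation logs,
before/after statistics and a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from .bridging import JoinEvent, iterative_connect, joins_tsv, layout_tsv
from .config import Mode, PatchConfig
from .modify import FillEvent, SplitEvent, modify_assembly
from .representatives import (RepresentativeSet, delineation_tsv,
                              select_representatives, subset_cpblrs)
from .sequence_io import (AssemblyStats, Origin, SeqRecord, assembly_stats,
                          read_sequences, stats_tsv, write_assembly)

log = logging.getLogger("asmpatch")


@dataclasses.dataclass
class RunResult:
    outdir: Path
    final: list[SeqRecord]
    stats_before: AssemblyStats
    stats_after: AssemblyStats
    fill_events: list[FillEvent]
    split_events: list[SplitEvent]
    join_events: list[JoinEvent]
    repset: RepresentativeSet
    pool: dict[str, SeqRecord]      # stage-2 pool (layout tile sources)
    unused_cpblrs: list[SeqRecord]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_patch(assembly: str | Path, cpblrs: str | Path,
              reads: Sequence[str | Path] | None = None,
              genome_size: int | None = None,
              config: PatchConfig | None = None,
              outdir: str | Path = "patch_out") -> RunResult:
    """Upgrade a draft assembly with corrected long reads.

    ``reads`` (optional raw short-read files) enable zero-coverage
    splitting; ``genome_size`` enables the longest-15X read subset.
    """
    cfg = config or PatchConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = read_sequences(assembly, Origin.contig)
    if not contigs:
        raise RuntimeError("stage input: draft assembly contains no sequences")
    long_reads = read_sequences(cpblrs, Origin.cpblr)
    stats_before = assembly_stats(contigs)

    # stage 1 — gap filling always; splitting only with reads and full mode
    split = cfg.mode == Mode.full and bool(reads)
    try:
        modified, fill_events, split_events = modify_assembly(
            contigs, long_reads, reads if split else None,
            flank_len=cfg.flank_len, min_votes=cfg.min_votes,
            flank_identity=cfg.flank_identity, end_fraction=cfg.end_fraction,
            min_segment=cfg.min_segment, max_read_edits=cfg.max_read_edits,
            split=split)
    except Exception as e:
        raise RuntimeError(f"[modification] {e}") from e

    # stage 2 — representative selection over contigs + (subset) reads
    try:
        subset = subset_cpblrs(long_reads, genome_size, cfg.depth_factor)
        pool_records = list(modified) + subset
        repset = select_representatives(
            pool_records, cfg.rate_thresh, cfg.ident_thresh,
            cfg.min_aln_len, cfg.cpblr_min_identity, cfg.kmer_size)
    except Exception as e:
        raise RuntimeError(f"[selection] {e}") from e

    # stage 3 — iterative connection (skipped in redundancy-only mode)
    join_events: list[JoinEvent] = []
    unused: list[SeqRecord] = []
    if cfg.mode == Mode.redundancy_only:
        final = [r for r in repset.representatives
                 if r.origin == Origin.contig]
        if not final:
            final = list(repset.representatives)
        unused = [r for r in repset.representatives
                  if r.origin == Origin.cpblr]
    else:
        try:
            final, join_events, unused = iterative_connect(repset, cfg)
        except Exception as e:
            raise RuntimeError(f"[connection] {e}") from e
        if not final:   # pool was reads only; fall back to representatives
            final = list(repset.representatives)
    stats_after = assembly_stats(final)

    pool = {r.id: r for r in pool_records}
    _write_outputs(outdir, cfg, assembly, cpblrs, reads, genome_size,
                   final, stats_before, stats_after, fill_events,
                   split_events, join_events, repset, unused)
    log.info("run complete: %d -> %d sequences (%s)", stats_before.n_contigs,
             stats_after.n_contigs, cfg.mode.value)
    return RunResult(outdir, final, stats_before, stats_after, fill_events,
                     split_events, join_events, repset, pool, unused)


def _write_outputs(outdir: Path, cfg: PatchConfig, assembly, cpblrs, reads,
                   genome_size, final, before, after, fill_events,
                   split_events, join_events, repset, unused) -> None:
    write_assembly(final, outdir / "patched.fasta")
    (outdir / "layout.tsv").write_text(layout_tsv(
        sorted(final, key=lambda r: (-r.length, r.id))))
    (outdir / "joins.tsv").write_text(joins_tsv(join_events))
    (outdir / "delineated.tsv").write_text(delineation_tsv(repset))
    (outdir / "stats.tsv").write_text(stats_tsv(
        [("before", before), ("after", after)]))
    mods = ["kind\tcontig\tstart\tend\tdetail"]
    for e in fill_events:
        mods.append(f"fill\t{e.contig_id}\t{e.start}\t{e.end}"
                    f"\tvotes={e.votes}/{e.n_spanning},len={e.replacement_len}")
    for e in split_events:
        mods.append(f"{e.kind}\t{e.contig_id}\t{e.start}\t{e.end}"
                    f"\t{e.segment_id}")
    (outdir / "modifications.tsv").write_text("\n".join(mods) + "\n")
    if cfg.keep_unused_cpblrs and unused:
        write_assembly(unused, outdir / "unused_cpblrs.fasta")
    manifest = {
        "config": cfg.to_dict(),
        "inputs": {
            "assembly": {"path": str(assembly), "sha256": _sha256(assembly)},
            "cpblrs": {"path": str(cpblrs), "sha256": _sha256(cpblrs)},
            "reads": [{"path": str(p), "sha256": _sha256(p)}
                      for p in (reads or [])],
            "genome_size": genome_size,
        },
        "counters": {
            "gaps_filled": len(fill_events),
            "splits": sum(1 for e in split_events if e.kind == "excise"),
            "removed_redundant": len(repset.delineated),
            "joins": {m: sum(1 for e in join_events if e.mode == m)
                      for m in ("strict", "easy", "rescue", "merge")},
            "unused_cpblrs": len(unused),
        },
        "stats": {"before": dataclasses.asdict(before),
                  "after": dataclasses.asdict(after)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_from_manifest(manifest: str | Path, outdir: str | Path) -> RunResult:
    """Replay a run from its manifest (inputs must be where it says)."""
    m = json.loads(Path(manifest).read_text())
    cfg = PatchConfig.from_dict(m["config"])
    inp = m["inputs"]
    reads = [r["path"] for r in inp.get("reads", [])] or None
    return run_patch(inp["assembly"]["path"], inp["cpblrs"]["path"], reads,
                     inp.get("genome_size"), cfg, outdir)
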