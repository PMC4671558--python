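"""Run configuration for the assembly-patching pipeline.

Every numeric constant of the method lives here so that a run is fully
described by one :class:`PatchConfig` (plus inputs and seed).  Defaults follow
the published procedure: 100-bp gap flanks, a ``>2`` vote rule for gap
replacement, a <1 % terminal exemption and 50-bp discard cutoff for
zero-coverage splitting, a 15X longest-read subset, ``>95 %`` containment
thresholds for representative selection, and the 1.25-fold uniqueness margin
for strict bridging.  Alignment-layer defaults (minimum overlap, maximum
dovetail overhang, per-stage identity floors) are not fixed by the published
description and are exposed for tuning.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Any, Mapping


class Mode(str, enum.Enum):
    """Pipeline mode.

    ``full``            — modification, selection and bridging.
    ``redundancy_only`` — selection only; emit non-redundant contigs, no joins.
    ``no_split``        — full pipeline but never split at zero coverage.
    """

    full = "full"
    redundancy_only = "redundancy_only"
    no_split = "no_split"


@dataclasses.dataclass
class PatchConfig:
    # stage 1 — assembly modification
    flank_len: int = 100          # bp of gap-flanking sequence used to anchor spanning reads
    min_votes: int = 3            # minimum identical inter-flank sequences ("> 2")
    flank_identity: float = 0.90  # fallback alignment identity for flank matching
    end_fraction: float = 0.01    # terminal window exempt from splitting (<1 % contig length)
    min_segment: int = 50         # discard split segments smaller than this (bp)
    max_read_edits: int = 0       # max edit distance for a short-read placement
                                  # (0: a placement is evidence only if exact;
                                  #  raise for error-prone read sets)

    # stage 2 — representative selection
    depth_factor: float = 15.0    # take the longest 15X of reads when genome size known
    rate_thresh: float = 0.95     # containment alignment-rate threshold (strict >)
    ident_thresh: float = 0.95    # containment identity threshold (strict >)

    # stage 3 — iterative connection
    uniq_ratio: float = 1.25      # best end-overlap must be >= ratio * second best
    min_overlap: int = 200        # minimum dovetail overlap length (bp)
    max_overhang: int = 50        # max unaligned bp beyond a dovetail toward the end

    # alignment layer
    kmer_size: int = 15
    contig_min_identity: float = 0.95   # contig-vs-contig alignments
    cpblr_min_identity: float = 0.90    # alignments involving long reads
    min_aln_len: int = 100              # discard alignment blocks shorter than this

    # run control
    mode: Mode = Mode.full
    seed: int = 0
    threads: int = 1
    keep_unused_cpblrs: bool = False    # emit unused long reads to a side file

    def __post_init__(self) -> None:
        if self.uniq_ratio <= 1:
            raise ValueError("uniq_ratio must be > 1")
        for name in ("rate_thresh", "ident_thresh", "flank_identity",
                     "contig_min_identity", "cpblr_min_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("flank_len", "min_segment", "min_overlap", "max_overhang",
                     "min_aln_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.end_fraction < 1:
            raise ValueError("end_fraction must be in [0, 1)")
        if isinstance(self.mode, str):
            self.mode = Mode(self.mode)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["mode"] = self.mode.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PatchConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
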