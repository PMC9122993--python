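"""Amplicon indel profiling: per-read edit calls aggregated to indel rate,
signed size distribution and motif-disruption fraction.

Reads are sampled (up to a cap, default 50,000), aligned to the amplicon
reference by the k-mer-anchored edit-op caller, and each aligned read
contributes once to the indel rate (any insertion or deletion counts). The
size distribution bins indel reads by net signed size — inserted bases
minus deleted bases — so a pure 7 nt deletion lands in bin −7 and a +1
insertion in bin +1. Motif disruption (e.g. of the GATAA element in the
BCL11A erythroid enhancer) is, by default, the fraction of all analyzed
reads carrying a deletion overlapping the motif interval or an insertion
strictly inside it; mismatch-counting is opt-in. The denominator choice
(all analyzed reads, not indel reads only) is recorded in the profile
metadata.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import DELETION, INSERTION, MISMATCH, EditOpSet, call_edit_ops
from .errors import ConfigError, UndefinedRateError

__all__ = ["AmpliconReference", "IndelProfile", "subsample_reads",
           "call_reads", "indel_rate", "size_distribution",
           "motif_disruption", "profile_reads"]

READ_CAP = 50_000


@dataclass(frozen=True)
class AmpliconReference:
    """Amplicon reference sequence, optionally with a motif interval.

    ``motif_interval`` is a 0-based half-open [start, end) slice, e.g.
    the GATAA element; when ``motif`` is given it must equal the sequence
    at that interval.
    """

    name: str
    sequence: str
    motif_interval: tuple[int, int] | None = None
    motif: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.motif_interval is not None:
            s, e = self.motif_interval
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError("motif interval outside reference bounds")
            if self.motif is not None and self.sequence[s:e] != self.motif.upper():
                raise ValueError(
                    f"reference at {s}:{e} is {self.sequence[s:e]}, "
                    f"not the declared motif {self.motif}")


@dataclass
class IndelProfile:
    n_total_reads: int
    n_sampled: int
    n_aligned: int
    n_indel_reads: int
    indel_rate: float
    size_bins: dict[int, float]
    motif_disruption_fraction: float | None = None
    metadata: dict = field(default_factory=dict)


def subsample_reads(reads: list, cap: int = READ_CAP, seed: int = 0) -> list:
    """Uniform sample without replacement of at most ``cap`` reads.

    Input order is preserved; the same seed reproduces the same sample.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(reads) <= cap:
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=cap, replace=False))
    return [reads[i] for i in idx]


def call_reads(reads: list[tuple[str, str]], ref: AmpliconReference, *,
               k: int = 10) -> list[EditOpSet]:
    """Call edit operations for (read_id, sequence) pairs."""
    return [call_edit_ops(seq, ref.sequence, rid, k=k) for rid, seq in reads]


def indel_rate(callsets: list[EditOpSet]) -> float:
    """Fraction of aligned reads carrying >= 1 insertion or deletion."""
    aligned = [c for c in callsets if c.aligned]
    if not aligned:
        raise UndefinedRateError("no aligned reads")
    return sum(c.has_indel for c in aligned) / len(aligned)


def size_distribution(callsets: list[EditOpSet]) -> dict[int, float]:
    """Signed-size histogram over indel reads (fractions sum to 1).

    Negative sizes are net deletions, positive net insertions; a read with
    both is binned once by its net size.
    """
    sizes = Counter(c.net_indel_size for c in callsets
                    if c.aligned and c.has_indel)
    total = sum(sizes.values())
    return {s: n / total for s, n in sorted(sizes.items())}


def _disrupts(ops: EditOpSet, start: int, end: int,
              count_mismatches: bool) -> bool:
    for op in ops.ops:
        if op.kind == DELETION:
            if op.ref_position < end and op.ref_position + op.length > start:
                return True
        elif op.kind == INSERTION:
            if start < op.ref_position < end:
                return True
        elif count_mismatches and op.kind == MISMATCH:
            if op.ref_position < end and op.ref_position + op.length > start:
                return True
    return False


def motif_disruption(callsets: list[EditOpSet], ref: AmpliconReference, *,
                     count_mismatches: bool = False) -> float:
    """Fraction of analyzed (aligned) reads whose alignment disrupts the
    motif interval: a deletion overlapping it, an insertion strictly
    inside it, or (optionally) a mismatch within it."""
    if ref.motif_interval is None:
        raise ConfigError("reference has no motif_interval")
    start, end = ref.motif_interval
    aligned = [c for c in callsets if c.aligned]
    if not aligned:
        raise UndefinedRateError("no aligned reads")
    return sum(_disrupts(c, start, end, count_mismatches)
               for c in aligned) / len(aligned)


def profile_reads(reads: list[tuple[str, str]], ref: AmpliconReference, *,
                  cap: int = READ_CAP, seed: int = 0,
                  k: int = 10) -> IndelProfile:
    """End-to-end profile: subsample, call, aggregate."""
    sampled = subsample_reads(reads, cap=cap, seed=seed)
    callsets = call_reads(sampled, ref, k=k)
    aligned = [c for c in callsets if c.aligned]
    if not aligned:
        raise UndefinedRateError("no aligned reads")
    n_indel = sum(c.has_indel for c in aligned)
    profile = IndelProfile(
        n_total_reads=len(reads),
        n_sampled=len(sampled),
        n_aligned=len(aligned),
        n_indel_reads=n_indel,
        indel_rate=n_indel / len(aligned),
        size_bins=size_distribution(callsets) if n_indel else {},
        metadata={"read_cap": cap, "seed": seed, "anchor_k": k,
                  "n_unaligned": len(callsets) - len(aligned),
                  "motif_denominator": "all_analyzed_reads"},
    )
    if ref.motif_interval is not None:
        profile.motif_disruption_fraction = motif_disruption(callsets, ref)
    return profile
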