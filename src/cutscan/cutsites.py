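"""Cut-site reconstruction from sequenced in vitro cleavage products.

A staggered double-strand break leaves 5' or 3' overhangs, so the two
strands' nicks sit at different positions. Sequencing the 5' and 3' cut
products of untreated reactions reports the non-template-strand (NTS) and
template-strand (TS) nicks respectively; treating the products with mung
bean nuclease (which blunts overhangs) before sequencing exposes the
*additional* nicks — 5' products then report the TS, 3' products the NTS.
Combining the four (treated x end-type) arms yields the full per-strand
cut-site distribution.

Positions are reported protospacer-relative: position 1 is the
PAM-proximal protospacer base, increasing PAM-distal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

__all__ = ["FragmentRead", "SubstrateAnnotation", "CutSiteDistribution",
           "assign_cut_strand", "to_protospacer_coord",
           "from_protospacer_coord", "build_distribution"]

TS = "TS"
NTS = "NTS"

#: (treated, end_type) -> strand whose nick the product reports
STRAND_ASSIGNMENT = {
    (False, "5prime_product"): NTS,
    (False, "3prime_product"): TS,
    (True, "5prime_product"): TS,
    (True, "3prime_product"): NTS,
}


@dataclass(frozen=True)
class FragmentRead:
    end_type: str            # 5prime_product | 3prime_product
    treated: bool            # mung bean nuclease treated
    junction: int            # 0-based coordinate on the substrate
    count: int = 1

    def __post_init__(self):
        if self.end_type not in ("5prime_product", "3prime_product"):
            raise ValueError(f"unknown end_type {self.end_type!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class SubstrateAnnotation:
    """PAM and protospacer placement on the linear substrate."""

    length: int
    proto_start: int         # 0-based half-open protospacer interval
    proto_end: int
    proto_strand: str = "+"  # strand carrying the protospacer sequence

    def __post_init__(self):
        if not (0 <= self.proto_start < self.proto_end <= self.length):
            raise ValueError("protospacer outside substrate")
        if self.proto_strand not in ("+", "-"):
            raise ValueError("proto_strand must be + or -")


@dataclass
class CutSiteDistribution:
    """Per-strand protospacer-relative cut-position fractions."""

    ts: dict[int, float] = field(default_factory=dict)
    nts: dict[int, float] = field(default_factory=dict)
    partial: bool = False    # True when an arm contributed no reads
    metadata: dict = field(default_factory=dict)

    def strand(self, label: str) -> dict[int, float]:
        return self.ts if label == TS else self.nts

    def mode(self, label: str) -> int | None:
        d = self.strand(label)
        if not d:
            return None
        top = max(d.values())
        return min(p for p, f in d.items() if f == top)


def assign_cut_strand(read: FragmentRead) -> str:
    """Strand reported by a cut product, per the treated x end-type rule."""
    return STRAND_ASSIGNMENT[(read.treated, read.end_type)]


def to_protospacer_coord(junction: int, sub: SubstrateAnnotation) -> int:
    """Substrate coordinate -> protospacer-relative position.

    Position 1 is the PAM-proximal protospacer base; values increase
    PAM-distal. For a plus-strand protospacer with a 5' PAM the proximal
    base is ``proto_start``.
    """
    if sub.proto_strand == "+":
        return junction - sub.proto_start + 1
    return sub.proto_end - junction


def from_protospacer_coord(pos: int, sub: SubstrateAnnotation) -> int:
    """Inverse of :func:`to_protospacer_coord`."""
    if sub.proto_strand == "+":
        return pos + sub.proto_start - 1
    return sub.proto_end - pos


def build_distribution(reads: list[FragmentRead],
                       sub: SubstrateAnnotation) -> CutSiteDistribution:
    """Merge treated and untreated arms into per-strand distributions.

    Each arm (treated / untreated) is normalized to its own read total
    before merging, so unequal sequencing depth between arms does not
    reweight the pattern; per-strand fractions are then renormalized to
    sum to 1. Junctions outside the substrate are rejected and tallied.
    """
    arm_totals: dict[bool, int] = defaultdict(int)
    rejected = 0
    kept: list[FragmentRead] = []
    for r in reads:
        if not 0 <= r.junction < sub.length:
            rejected += 1
            continue
        kept.append(r)
        arm_totals[r.treated] += r.count

    # integer counts per (strand, arm, position) so the merge is exactly
    # order-independent; arm weights applied afterwards in sorted order
    counts: dict[tuple[str, bool, int], int] = defaultdict(int)
    for r in kept:
        strand = assign_cut_strand(r)
        pos = to_protospacer_coord(r.junction, sub)
        counts[(strand, r.treated, pos)] += r.count
    weights: dict[str, dict[int, float]] = {TS: defaultdict(float),
                                            NTS: defaultdict(float)}
    for (strand, treated, pos), c in sorted(counts.items()):
        weights[strand][pos] += c / arm_totals[treated]

    dist = CutSiteDistribution(
        partial=len(arm_totals) < 2,
        metadata={"n_rejected": rejected,
                  "arm_normalization": "equal per-arm",
                  "position_convention":
                      "1 = PAM-proximal protospacer base, increasing "
                      "PAM-distal"})
    for label in (TS, NTS):
        total = sum(weights[label].values())
        if total > 0:
            dist.strand(label).update(
                {p: w / total for p, w in sorted(weights[label].items())})
    return dist
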