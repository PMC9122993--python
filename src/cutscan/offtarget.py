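"""In silico off-target prediction and MLE background correction.

Prediction scans the genome for PAM occurrences on both strands; the
spacer-length window adjacent to each PAM (with up to ``max_ed`` extra
flank so indel alignments can be scored) is aligned to the spacer with a
PAM-anchored Levenshtein alignment, and candidates within ``max_ed``
edits are ranked by ascending edit distance (ties by genomic order).

Targeted-sequencing indel counts at candidate sites are corrected for
background sequencing/PCR error under a two-sample binomial mixture:
treated reads carry an indel with probability q = b + p(1 - b), where b
is the background rate estimated from a matched untreated control
(b-hat = k0/n0) and p is the true editing rate. The maximum-likelihood
estimate with the plug-in background is

    p_hat = clip((k/n - b_hat) / (1 - b_hat), 0, 1)

A site is called detected when p_hat exceeds the limit of detection
(default 0.2%).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .errors import DegenerateControlError
from .seqs import find_iupac, revcomp
from .ttiss import GuideSpec, extract_pam

__all__ = ["OffTargetCandidate", "OffTargetEstimate", "scan_genome",
           "mle_background_correct", "detection_call", "LOD"]

LOD = 0.002


@dataclass(frozen=True)
class OffTargetCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    edit_distance: int
    rank: int = 0
    is_on_target: bool = False


@dataclass
class OffTargetEstimate:
    candidate: OffTargetCandidate
    k: int
    n: int
    k0: int
    n0: int
    corrected_rate: float
    detected: bool


def scan_genome(genome: dict[str, str], guide: GuideSpec, *,
                max_ed: int = 6) -> list[OffTargetCandidate]:
    """Rank every PAM-adjacent site within ``max_ed`` edits of the spacer.

    The spacer alignment is anchored at the PAM-proximal protospacer end
    and may extend up to ``max_ed`` bases further PAM-distal to absorb
    indels. Candidates are sorted by ascending edit distance, then
    genomic order; the best placement per PAM occurrence is kept.
    """
    spacer = guide.spacer.upper()
    if len(spacer) > max(len(s) for s in genome.values()):
        raise ValueError("spacer longer than every contig")
    L = len(spacer)
    plen = len(guide.pam)
    out = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for strand in ("+", "-"):
            pattern = guide.pam if strand == "+" else revcomp(guide.pam)
            for pos in find_iupac(pattern, seq):
                # the protospacer window sits 3' of a 5' PAM on the
                # protospacer strand; translate to forward coordinates
                pam_left = (strand, guide.pam_side) in (
                    ("+", "5prime"), ("-", "3prime"))
                if pam_left:
                    lo = pos + plen
                    hi = min(len(seq), lo + L + max_ed)
                else:
                    hi = pos
                    lo = max(0, hi - L - max_ed)
                if hi - lo < L - max_ed:
                    continue
                window = seq[lo:hi]
                oriented = window if strand == "+" else revcomp(window)
                # PAM-proximal end of the oriented reading
                proximal_at_start = guide.pam_side == "5prime"
                if proximal_at_start:
                    res = edlib.align(spacer, oriented, mode="SHW",
                                      task="locations", k=max_ed)
                else:
                    res = edlib.align(spacer[::-1], oriented[::-1],
                                      mode="SHW", task="locations", k=max_ed)
                dist = res["editDistance"]
                if dist < 0:
                    continue
                span = res["locations"][0][1] + 1
                if pam_left:
                    gs, ge = lo, lo + span
                else:
                    gs, ge = hi - span, hi
                proto = seq[gs:ge] if strand == "+" else revcomp(seq[gs:ge])
                pam_seq = extract_pam(seq, gs, ge, strand, guide)
                on = (guide.on_target is not None
                      and guide.on_target == (chrom, gs) and dist == 0)
                out.append(OffTargetCandidate(chrom, gs, ge, strand, proto,
                                              pam_seq, dist,
                                              is_on_target=on))
    out.sort(key=lambda c: (c.edit_distance, c.chrom, c.start, c.strand))
    return [OffTargetCandidate(c.chrom, c.start, c.end, c.strand,
                               c.protospacer, c.pam, c.edit_distance,
                               rank=i + 1, is_on_target=c.is_on_target)
            for i, c in enumerate(out)]


def mle_background_correct(k: int, n: int, k0: int, n0: int) -> float:
    """MLE of the editing rate under the binomial background mixture.

    ``k``/``n`` are indel and total reads in the treated sample,
    ``k0``/``n0`` in the untreated control. Monotone non-decreasing in
    ``k`` and clipped to [0, 1].
    """
    if not (0 <= k <= n and 0 <= k0 <= n0 and n >= 1 and n0 >= 1):
        raise ValueError("need 0 <= k <= n, 0 <= k0 <= n0, n, n0 >= 1")
    b = k0 / n0
    if b >= 1.0:
        raise DegenerateControlError("control indel rate is 1")
    p = (k / n - b) / (1.0 - b)
    return min(1.0, max(0.0, p))


def detection_call(corrected_rate: float, lod: float = LOD) -> bool:
    """Detected iff the corrected rate exceeds the limit of detection."""
    return corrected_rate > lod


def estimate_sites(counts: list[tuple[OffTargetCandidate, int, int, int, int]],
                   *, lod: float = LOD) -> list[OffTargetEstimate]:
    """Correct and call a batch of (candidate, k, n, k0, n0) records."""
    out = []
    for cand, k, n, k0, n0 in counts:
        p = mle_background_correct(k, n, k0, n0)
        out.append(OffTargetEstimate(cand, k, n, k0, n0, p,
                                     detection_call(p, lod)))
    return out
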