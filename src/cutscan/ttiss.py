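"""Tag-integration site sequencing (TTISS) off-target discovery.

A double-stranded oligodeoxynucleotide (dsODN) tag integrates at nuclease
double-strand breaks; sequencing outward from the tag yields read pairs
whose read1 begins with the dsODN primer followed by the genomic junction.
The pipeline applies, in order:

* primer/quality filtering and truncation to 25 bp (forward) / 15 bp
  (reverse) of genomic sequence;
* paired alignment with a maximum fragment length of 1000 bp and PCR
  duplicate marking (identical outer coordinates and strand);
* 100 bp window calling requiring >= 2 unique (non-duplicate) reads;
* cut-site prediction from the junction coordinate distribution (modal
  coordinate; ties resolved toward both-strand support, then leftmost);
* guide matching: best protospacer-like substring within Levenshtein
  distance 6 of the spacer, on either strand, in the padded window;
* site filters: matched-sequence cut site within 8 bp of the predicted
  cut, an IUPAC-matching PAM (NTTN, 5' of the protospacer for Cas12i),
  and no overlap with negative-control windows.

The built-in aligner (exact 15-mer seed + near-exact extension) suits the
synthetic genomes used for validation; externally produced SAM alignments
can be ingested instead for real genomes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from .seqs import iupac_match, mean_phred, revcomp

__all__ = ["GuideSpec", "ReadPair", "TrimmedPair", "PairAlignment",
           "GenomicWindow", "TtissSite", "TtissReport", "GenomeIndex",
           "filter_and_trim", "align_pairs", "mark_duplicates",
           "call_windows", "predict_cut_site", "match_guide",
           "apply_site_filters", "summarize", "run_ttiss",
           "alignments_from_sam"]

WINDOW_SIZE = 100
MIN_UNIQUE_READS = 2
MAX_FRAGMENT = 1000
MAX_EDIT_DISTANCE = 6
MAX_CUT_OFFSET = 8
TRIM_FORWARD = 25
TRIM_REVERSE = 15


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA spacer with its PAM requirement.

    ``pam_side`` is the side of the PAM relative to the protospacer on the
    protospacer strand (5prime for Cas12i's NTTN, 3prime for SpCas9's
    NGG). ``cut_offset`` places the nuclease cut relative to the
    PAM-proximal protospacer end (nt); Cas12i cleaves PAM-distal.
    ``on_target`` optionally pins the programmed locus as (chrom, start)
    of the protospacer.
    """

    guide_id: str
    spacer: str
    pam: str = "NTTN"
    pam_side: str = "5prime"
    cut_offset: int = 24
    on_target: tuple[str, int] | None = None

    def __post_init__(self):
        if set(self.spacer.upper()) - set("ACGT"):
            raise ValueError("spacer must be over A/C/G/T")
        if self.pam_side not in ("5prime", "3prime"):
            raise ValueError("pam_side must be 5prime or 3prime")


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass(frozen=True)
class TrimmedPair:
    pair_id: str
    fwd: str   # 25 bp genomic, dsODN side
    rev: str   # 15 bp genomic, distal side


@dataclass
class PairAlignment:
    pair_id: str
    chrom: str
    junction: int      # dsODN integration coordinate, 0-based
    strand: str        # strand the forward read extends along
    frag_start: int
    frag_end: int      # half-open
    is_duplicate: bool = False


@dataclass
class GenomicWindow:
    chrom: str
    start: int
    end: int
    unique_read_count: int
    junctions: list[tuple[int, str]] = field(default_factory=list)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class TtissSite:
    window: GenomicWindow
    predicted_cut: int
    matched_sequence: str
    edit_distance: int
    pam_sequence: str
    strand: str
    proto_start: int
    proto_end: int
    match_cut: int
    guide_id: str
    is_on_target: bool = False


@dataclass
class TtissReport:
    guide_id: str
    sites: list[TtissSite]
    on_target_read_fraction: float
    n_off_targets: int
    metadata: dict = field(default_factory=dict)


def filter_and_trim(pairs: list[ReadPair], dsodn_primer: str, *,
                    min_mean_quality: float = 20.0,
                    trim_fwd: int = TRIM_FORWARD,
                    trim_rev: int = TRIM_REVERSE
                    ) -> tuple[list[TrimmedPair], Counter]:
    """Keep pairs whose read1 starts with the dsODN primer; trim and QC.

    Returns the trimmed pairs and a tally of rejection reasons.
    """
    if not dsodn_primer:
        raise ValueError("dsODN primer must be non-empty")
    out: list[TrimmedPair] = []
    tally: Counter = Counter()
    plen = len(dsodn_primer)
    for p in pairs:
        if not p.seq1.startswith(dsodn_primer):
            tally["no_primer"] += 1
            continue
        g1, q1 = p.seq1[plen:], p.qual1[plen:]
        if len(g1) < trim_fwd or len(p.seq2) < trim_rev:
            tally["too_short"] += 1
            continue
        g1, q1 = g1[:trim_fwd], q1[:trim_fwd]
        g2, q2 = p.seq2[:trim_rev], p.qual2[:trim_rev]
        if mean_phred(q1) < min_mean_quality or mean_phred(q2) < min_mean_quality:
            tally["low_quality"] += 1
            continue
        out.append(TrimmedPair(p.pair_id, g1, g2))
        tally["kept"] += 1
    return out, tally


class GenomeIndex:
    """Exact k-mer index over a genome for seed-and-extend pair placement."""

    def __init__(self, genome: dict[str, str], k: int = 15):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i:i + k]].append((chrom, i))

    def locate(self, seq: str) -> list[tuple[str, int]]:
        """Positions where ``seq`` occurs exactly (seeded by its first k-mer)."""
        if len(seq) < self.k:
            return []
        hits = []
        for chrom, pos in self.index.get(seq[:self.k], ()):
            if self.genome[chrom][pos:pos + len(seq)] == seq:
                hits.append((chrom, pos))
        return hits


def align_pairs(pairs: list[TrimmedPair], index: GenomeIndex, *,
                max_fragment: int = MAX_FRAGMENT
                ) -> tuple[list[PairAlignment], Counter]:
    """Place trimmed pairs on the genome; keep proper pairs only.

    The forward read anchors the dsODN junction; the reverse read must
    map in the opposite orientation within ``max_fragment`` bp. Duplicates
    are marked afterwards with :func:`mark_duplicates`.
    """
    out: list[PairAlignment] = []
    tally: Counter = Counter()
    for p in pairs:
        placements = []
        for chrom, pos in index.locate(p.fwd):          # junction on + strand
            rc2 = revcomp(p.rev)
            for c2, p2 in index.locate(rc2):
                end = p2 + len(p.rev)
                if c2 == chrom and pos < end and end - pos <= max_fragment:
                    placements.append(PairAlignment(p.pair_id, chrom, pos,
                                                    "+", pos, end))
        rc1 = revcomp(p.fwd)
        for chrom, pos in index.locate(rc1):            # junction on - strand
            junction = pos + len(p.fwd)
            for c2, p2 in index.locate(p.rev):
                if c2 == chrom and p2 < junction and junction - p2 <= max_fragment:
                    placements.append(PairAlignment(p.pair_id, chrom, junction,
                                                    "-", p2, junction))
        if len(placements) == 1:
            out.append(placements[0])
            tally["mapped"] += 1
        elif not placements:
            tally["unmapped"] += 1
        else:
            tally["ambiguous"] += 1
    mark_duplicates(out)
    return out, tally


def mark_duplicates(alignments: list[PairAlignment]) -> None:
    """Mark PCR duplicates: identical outer coordinates and strand.

    Idempotent; the set of unique fragments is invariant to input order.
    """
    seen: set[tuple] = set()
    for aln in sorted(alignments, key=lambda a: (a.chrom, a.frag_start,
                                                 a.frag_end, a.strand,
                                                 a.pair_id)):
        key = (aln.chrom, aln.frag_start, aln.frag_end, aln.strand)
        aln.is_duplicate = key in seen
        seen.add(key)


def call_windows(alignments: list[PairAlignment], *,
                 window_size: int = WINDOW_SIZE,
                 min_unique: int = MIN_UNIQUE_READS) -> list[GenomicWindow]:
    """Fixed-width windows with >= ``min_unique`` unique reads.

    Junctions of unique (non-duplicate) reads are clustered per
    chromosome; within a cluster the maximum-support window is emitted
    greedily, so overlapping candidates merge into the best-supported one.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for a in alignments:
        if not a.is_duplicate:
            by_chrom[a.chrom].append((a.junction, a.strand))
    windows: list[GenomicWindow] = []
    for chrom in sorted(by_chrom):
        juncs = sorted(by_chrom[chrom])
        # split into clusters separated by > window_size
        clusters: list[list[tuple[int, str]]] = [[]]
        for j in juncs:
            if clusters[-1] and j[0] - clusters[-1][-1][0] > window_size:
                clusters.append([])
            clusters[-1].append(j)
        for cluster in clusters:
            remaining = list(cluster)
            while len(remaining) >= min_unique:
                best_start, best_members = None, []
                positions = [j for j, _ in remaining]
                for j, _ in remaining:
                    start = j - window_size // 2
                    members = [x for x in remaining
                               if start <= x[0] < start + window_size]
                    if len(members) > len(best_members):
                        best_start, best_members = start, members
                if len(best_members) < min_unique:
                    break
                lo = max(0, best_start)
                windows.append(GenomicWindow(chrom, lo, lo + window_size,
                                             len(best_members),
                                             sorted(best_members)))
                remaining = [x for x in remaining if x not in best_members]
    return windows


def predict_cut_site(window: GenomicWindow) -> int:
    """Modal junction coordinate; ties prefer both-strand support, then
    the leftmost coordinate."""
    counts = Counter(j for j, _ in window.junctions)
    strands = defaultdict(set)
    for j, s in window.junctions:
        strands[j].add(s)
    top = max(counts.values())
    candidates = [j for j, c in counts.items() if c == top]
    both = [j for j in candidates if len(strands[j]) == 2]
    pool = both if both else candidates
    return min(pool)


def _match_candidates(region: str, region_start: int, spacer: str,
                      strand: str, max_ed: int,
                      guide: GuideSpec) -> list[tuple]:
    """Raw protospacer matches of ``spacer`` in ``region`` on one strand."""
    target = region if strand == "+" else revcomp(region)
    res = edlib.align(spacer, target, mode="HW", task="locations", k=max_ed)
    if res["editDistance"] < 0:
        return []
    out = []
    for loc_start, loc_end in res["locations"]:
        if strand == "+":
            gs = region_start + loc_start
            ge = region_start + loc_end + 1
            cut = gs + guide.cut_offset if guide.pam_side == "5prime" \
                else ge - guide.cut_offset
        else:
            ge = region_start + len(region) - loc_start
            gs = region_start + len(region) - (loc_end + 1)
            cut = ge - guide.cut_offset if guide.pam_side == "5prime" \
                else gs + guide.cut_offset
        out.append((res["editDistance"], gs, ge, cut, strand))
    return out


def extract_pam(genome_seq: str, gs: int, ge: int, strand: str,
                guide: GuideSpec) -> str:
    """PAM bases adjacent to a protospacer placement, on its strand."""
    n = len(guide.pam)
    if guide.pam_side == "5prime":
        if strand == "+":
            lo, hi = gs - n, gs
        else:
            lo, hi = ge, ge + n
    else:
        if strand == "+":
            lo, hi = ge, ge + n
        else:
            lo, hi = gs - n, gs
    if lo < 0 or hi > len(genome_seq):
        return ""
    seq = genome_seq[lo:hi]
    return seq if strand == "+" else revcomp(seq)


def match_guide(window: GenomicWindow, genome: dict[str, str],
                guide: GuideSpec, *, max_ed: int = MAX_EDIT_DISTANCE,
                predicted_cut: int | None = None) -> TtissSite | None:
    """Best guide-like sequence in the padded window, either strand.

    Ties break by smaller edit distance, then proximity of the match's
    implied cut site to the predicted cut, then leftmost coordinate.
    """
    seq = genome[window.chrom].upper()
    spacer = guide.spacer.upper()
    pad = len(spacer) + max_ed + len(guide.pam)
    lo = max(0, window.start - pad)
    hi = min(len(seq), window.end + pad)
    region = seq[lo:hi]
    if predicted_cut is None:
        predicted_cut = predict_cut_site(window)
    cands = []
    for strand in ("+", "-"):
        cands.extend(_match_candidates(region, lo, spacer, strand, max_ed,
                                       guide))
    if not cands:
        return None
    dist, gs, ge, cut, strand = min(
        cands, key=lambda c: (c[0], abs(c[3] - predicted_cut), c[1], c[4]))
    matched = seq[gs:ge] if strand == "+" else revcomp(seq[gs:ge])
    pam_seq = extract_pam(seq, gs, ge, strand, guide)
    on = (guide.on_target is not None
          and guide.on_target == (window.chrom, gs)
          and dist == 0) or (guide.on_target is None and dist == 0)
    return TtissSite(window, predicted_cut, matched, dist, pam_seq, strand,
                     gs, ge, cut, guide.guide_id, on)


def apply_site_filters(site: TtissSite,
                       negative_control_windows: list[tuple[str, int, int]] = (),
                       *, max_offset: int = MAX_CUT_OFFSET,
                       pam_pattern: str | None = None
                       ) -> tuple[bool, str | None]:
    """Keep/drop a candidate site; returns (keep, drop_reason)."""
    if abs(site.match_cut - site.predicted_cut) > max_offset:
        return False, "cut_offset"
    pattern = pam_pattern if pam_pattern is not None else "NTTN"
    if not iupac_match(pattern, site.pam_sequence):
        return False, "bad_pam"
    for chrom, start, end in negative_control_windows:
        if site.window.overlaps(chrom, start, end):
            return False, "negative_control"
    return True, None


def summarize(sites: list[TtissSite], guide_id: str,
              metadata: dict | None = None) -> TtissReport:
    """Per-guide report: on-target unique-read fraction, off-target count.

    The denominator is the unique reads of retained sites only; the
    unique-read definition (non-duplicate fragments) is recorded in the
    report metadata.
    """
    total = sum(s.window.unique_read_count for s in sites)
    on = sum(s.window.unique_read_count for s in sites if s.is_on_target)
    meta = {"unique_read_definition": "non-duplicate fragments",
            "denominator": "retained sites only"}
    meta.update(metadata or {})
    return TtissReport(guide_id, sites,
                       on / total if total else 0.0,
                       sum(not s.is_on_target for s in sites), meta)


def run_ttiss(pairs: list[ReadPair], genome: dict[str, str],
              guide: GuideSpec, dsodn_primer: str, *,
              negative_control_windows: list[tuple[str, int, int]] = (),
              min_mean_quality: float = 20.0,
              max_fragment: int = MAX_FRAGMENT,
              window_size: int = WINDOW_SIZE,
              min_unique: int = MIN_UNIQUE_READS,
              max_ed: int = MAX_EDIT_DISTANCE,
              max_offset: int = MAX_CUT_OFFSET) -> TtissReport:
    """End-to-end TTISS analysis on raw read pairs."""
    trimmed, trim_tally = filter_and_trim(pairs, dsodn_primer,
                                          min_mean_quality=min_mean_quality)
    index = GenomeIndex(genome)
    alignments, align_tally = align_pairs(trimmed, index,
                                          max_fragment=max_fragment)
    windows = call_windows(alignments, window_size=window_size,
                           min_unique=min_unique)
    retained, dropped = [], Counter()
    for w in windows:
        cut = predict_cut_site(w)
        site = match_guide(w, genome, guide, max_ed=max_ed,
                           predicted_cut=cut)
        if site is None:
            dropped["no_guide_match"] += 1
            continue
        keep, reason = apply_site_filters(
            site, negative_control_windows, max_offset=max_offset,
            pam_pattern=guide.pam)
        if keep:
            retained.append(site)
        else:
            dropped[reason] += 1
    return summarize(retained, guide.guide_id,
                     {"trim": dict(trim_tally), "align": dict(align_tally),
                      "dropped_windows": dict(dropped),
                      "n_windows": len(windows)})


def alignments_from_sam(path: str, *, max_fragment: int = MAX_FRAGMENT
                        ) -> list[PairAlignment]:
    """Ingest externally produced paired alignments from a SAM file.

    Read1 carries the dsODN junction at its 5' end. SAM's 1-based
    coordinates are converted to the 0-based half-open convention used
    internally. Duplicates are (re)marked here.
    """
    import pysam

    out: list[PairAlignment] = []
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if (not rec.is_read1 or rec.is_unmapped or rec.mate_is_unmapped
                    or rec.is_secondary or rec.is_supplementary
                    or not rec.is_proper_pair):
                continue
            tlen = abs(rec.template_length)
            if tlen == 0 or tlen > max_fragment:
                continue
            if rec.is_reverse:
                junction = rec.reference_end
                frag_start, frag_end = junction - tlen, junction
                strand = "-"
            else:
                junction = rec.reference_start
                frag_start, frag_end = junction, junction + tlen
                strand = "+"
            out.append(PairAlignment(rec.query_name, rec.reference_name,
                                     junction, strand, frag_start, frag_end))
    mark_duplicates(out)
    return out
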