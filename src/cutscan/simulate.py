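"""Synthetic-data generators with known ground truth.

Every generator emulates the statistical structure of one pipeline input
— plate fluorescence endpoints with planted variant effects, amplicon
reads with target-dependent deletion spectra, dsODN-tagged read pairs
from planted integration sites, and genomes with planted PAM-adjacent
off-targets at known edit distances — and returns a :class:`TruthRecord`
describing exactly what was planted, so downstream checks compare
pipeline output to generator truth rather than to constants.

A single global seed fans out to independent per-generator streams via
``numpy``'s ``SeedSequence``, so each dataset can be regenerated
independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import edlib

from .errors import GenerationError
from .indels import AmpliconReference
from .seqs import revcomp
from .ttiss import GuideSpec, ReadPair

__all__ = ["TruthRecord", "module_rng", "random_genome", "gen_plate",
           "gen_amplicon_reads", "gen_ttiss", "gen_offtarget_genome",
           "PlantedSite", "TtissSimulation", "DEFAULT_DSODN"]

# Stable stream ids so each generator draws from an independent stream of
# the same global seed.
_STREAMS = {"plate": 1, "amplicon": 2, "ttiss": 3, "offtarget": 4,
            "genome": 5, "protein": 6}

#: dsODN primer prefix used by the paired-read generator.
DEFAULT_DSODN = "GTTTAATTGAGTTGTCATATGT"

BASES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Ground truth serialized alongside every generated dataset."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str, **kw)


def module_rng(seed: int, stream: str) -> np.random.Generator:
    """Per-generator random stream fanned out from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, _STREAMS[stream]]))


def random_genome(length: int, seed: int, *, chrom: str = "chr1",
                  stream: str = "genome") -> dict[str, str]:
    """Uniform-composition random genome (GC bias out of scope)."""
    rng = module_rng(seed, stream)
    return {chrom: "".join(rng.choice(BASES, size=length))}


def random_protein(length: int, seed: int) -> str:
    from .seqs import AMINO_ACIDS
    rng = module_rng(seed, "protein")
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------- plates

def gen_plate(n_variants: int = 200, n_wt_controls: int = 20,
              hit_fraction: float = 0.05, hit_effect: float = 3.0,
              noise_cv: float = 5.0, n_reps: int = 3,
              n_targets: int = 2, plate_id: str = "P1",
              seed: int = 0) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate one screening plate (long-format fluorescence table).

    Wild-type controls deplete at ratio ~1; a ``hit_fraction`` of the
    test variants carries a multiplicative depletion effect
    ``hit_effect`` (> 1 = stronger depletion). Replicate noise is
    multiplicative with coefficient of variation ``noise_cv`` percent.
    GFP/RFP endpoints are back-computed so every well realizes its ratio
    well above the 60 rfu floor. Defaults mirror the screen conditions:
    three replicates per variant in 384-well-style plates with a shared
    set of wild-type controls, two GFP targets.
    """
    rng = module_rng(seed, "plate")
    n_hits = int(round(hit_fraction * n_variants))
    hit_ids = sorted(rng.choice(n_variants, size=n_hits, replace=False))
    variants = [f"V{i:04d}" for i in range(n_variants)]
    controls = [f"WT{i:03d}" for i in range(n_wt_controls)]
    hits = {variants[i] for i in hit_ids}

    rows = []
    base = 1000.0
    for target in [f"GFP{t + 1}" for t in range(n_targets)]:
        for vid in controls + variants:
            true_ratio = hit_effect if vid in hits else 1.0
            for rep in range(1, n_reps + 1):
                ratio = true_ratio * max(
                    0.05, 1.0 + rng.normal(0.0, noise_cv / 100.0))
                # non-target arm: GFP unaffected; target arm: GFP depleted
                for kind, gfp in (("non_target", base * ratio),
                                  ("target", base)):
                    rows.append((plate_id, vid, rep, kind, target,
                                 gfp, base))
    records = pd.DataFrame(rows, columns=["plate_id", "variant_id",
                                          "replicate", "guide_kind",
                                          "target_id", "gfp_rfu",
                                          "rfp_rfu"])
    truth = TruthRecord(
        "plate", seed,
        params=dict(n_variants=n_variants, n_wt_controls=n_wt_controls,
                    hit_fraction=hit_fraction, hit_effect=hit_effect,
                    noise_cv=noise_cv, n_reps=n_reps, n_targets=n_targets,
                    plate_id=plate_id),
        planted=dict(hits=sorted(hits), wt_controls=controls))
    return records, truth


# -------------------------------------------------------------- amplicons

def gen_amplicon_reads(ref: AmpliconReference, n_reads: int,
                       indel_rate: float, size_spectrum: dict[int, float],
                       *, cut_site: int | None = None,
                       subst_error: float = 0.002,
                       motif_disrupt_fraction: float | None = None,
                       seed: int = 0
                       ) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Simulate amplicon reads with planted indels at the cut region.

    Each read carries a planted indel with probability ``indel_rate``;
    the signed size is drawn from ``size_spectrum`` (negative =
    deletion), emulating the target-dependent 5-20 nt deletion spectra
    characteristic of Cas12i editing, plus uniform substitution noise.
    With ``motif_disrupt_fraction`` set (requires ``ref.motif_interval``),
    that fraction of indel reads carries a deletion overlapping the
    motif and the rest are placed clear of it.
    """
    total = sum(size_spectrum.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("size spectrum fractions must sum to 1")
    rng = module_rng(seed, "amplicon")
    seq = ref.sequence
    cut = cut_site if cut_site is not None else len(seq) // 2
    sizes = np.array(sorted(size_spectrum))
    probs = np.array([size_spectrum[s] for s in sizes], float)
    probs = probs / probs.sum()

    reads, planted_sizes, planted_disrupt = [], [], []
    for i in range(n_reads):
        read = seq
        size = 0
        disrupt = False
        if rng.random() < indel_rate:
            size = int(rng.choice(sizes, p=probs))
            if size < 0:
                d = -size
                if motif_disrupt_fraction is not None:
                    ms, me = ref.motif_interval
                    disrupt = rng.random() < motif_disrupt_fraction
                    if disrupt:   # deletion overlapping the motif
                        start = int(rng.integers(max(0, ms - d + 1),
                                                 min(me, len(seq) - d) ))
                    else:         # deletion wholly clear of the motif
                        left_ok = ms - d >= 1
                        if left_ok and (me + d >= len(seq) - 1
                                        or rng.random() < 0.5):
                            start = int(rng.integers(0, ms - d))
                        else:
                            start = int(rng.integers(me + 1,
                                                     len(seq) - d))
                else:
                    lo = max(0, cut - d)
                    hi = min(cut, len(seq) - d)
                    start = int(rng.integers(lo, hi + 1))
                read = seq[:start] + seq[start + d:]
            else:
                ins = "".join(rng.choice(BASES, size=size))
                read = seq[:cut] + ins + seq[cut:]
        if subst_error > 0:
            arr = np.array(list(read))
            mask = rng.random(len(arr)) < subst_error
            for j in np.flatnonzero(mask):
                arr[j] = rng.choice([b for b in "ACGT" if b != arr[j]])
            read = "".join(arr)
        reads.append((f"read{i:06d}", read))
        planted_sizes.append(size)
        planted_disrupt.append(disrupt)

    n_indel = sum(1 for s in planted_sizes if s != 0)
    truth = TruthRecord(
        "amplicon", seed,
        params=dict(n_reads=n_reads, indel_rate=indel_rate,
                    size_spectrum={str(k): v for k, v in
                                   size_spectrum.items()},
                    subst_error=subst_error, cut_site=cut,
                    motif_disrupt_fraction=motif_disrupt_fraction),
        planted=dict(sizes=planted_sizes,
                     n_indel_reads=n_indel,
                     indel_fraction=n_indel / n_reads if n_reads else 0.0,
                     disrupt_fraction=(sum(planted_disrupt) / n_reads
                                       if n_reads else 0.0)))
    return reads, truth


# ----------------------------------------------------------------- ttiss

@dataclass
class PlantedSite:
    """A planted integration locus for the TTISS generator."""

    edit_distance: int
    read_count: int
    pam: str = "ATTC"            # concrete NTTN realization
    is_negative_control: bool = False
    # filled in by the generator:
    proto_start: int = -1
    cut: int = -1
    sequence: str = ""


@dataclass
class TtissSimulation:
    genome: dict[str, str]
    pairs: list[ReadPair]
    guide: GuideSpec
    sites: list[PlantedSite]
    negative_control_windows: list[tuple[str, int, int]]
    truth: TruthRecord


def _mutate_to_distance(spacer: str, d: int,
                        rng: np.random.Generator) -> str:
    """A sequence at anchored edit distance exactly ``d`` from spacer."""
    if d == 0:
        return spacer
    for _ in range(200):
        s = list(spacer)
        # interior substitutions keep the anchored distance well-defined
        pos = rng.choice(np.arange(2, len(s) - 2), size=d, replace=False)
        for p in pos:
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        cand = "".join(s)
        res = edlib.align(spacer, cand, mode="SHW", k=d)
        if res["editDistance"] == d:
            return cand
    raise GenerationError(f"could not realize edit distance {d}")


def gen_ttiss(guide: GuideSpec, planted: list[PlantedSite], *,
              genome_length: int = 100_000,
              dsodn: str = DEFAULT_DSODN,
              n_noise_singletons: int = 200,
              primerless_fraction: float = 0.0,
              genomic_read1: int = 40, read2_len: int = 18,
              seed: int = 0, chrom: str = "chr1") -> TtissSimulation:
    """Simulate a TTISS experiment on a random genome.

    Planted sites receive a concrete PAM plus a spacer-like sequence at
    the requested edit distance; their cut site follows the guide's
    ``cut_offset``. Each site emits ``read_count`` unique read pairs
    (distinct fragment lengths, junctions at the cut on both strands).
    Noise singletons are placed pairwise farther apart than the window
    width so they never reach the 2-read threshold; negative-control
    sites are generated like real sites but returned as control windows.
    """
    rng = module_rng(seed, "ttiss")
    genome = random_genome(genome_length, seed, chrom=chrom,
                           stream="ttiss")
    seq = list(genome[chrom])
    spacer = guide.spacer.upper()
    L = len(spacer)

    # place planted loci and noise junctions with generous spacing
    n_loci = len(planted)
    needed = n_loci + n_noise_singletons
    spacing = (genome_length - 2500) // max(needed, 1)
    if spacing < 150:  # must exceed window width so singletons stay alone
        raise GenerationError("genome too short for requested plants")
    positions = rng.permutation(
        np.arange(1000, genome_length - 1500, spacing))[:needed]
    site_pos, noise_pos = positions[:n_loci], positions[n_loci:]

    for site, pos in zip(planted, site_pos):
        proto = _mutate_to_distance(spacer, site.edit_distance, rng)
        start = int(pos)
        pam = site.pam
        seq[start - len(pam):start] = list(pam)
        seq[start:start + L] = list(proto)
        site.proto_start = start
        site.cut = start + guide.cut_offset
        site.sequence = proto
    genome = {chrom: "".join(seq)}
    gseq = genome[chrom]

    pairs: list[ReadPair] = []
    pid = 0

    def emit(junction: int, strand: str, frag_len: int):
        nonlocal pid
        if strand == "+":
            g1 = gseq[junction:junction + genomic_read1]
            end = junction + frag_len
            g2 = revcomp(gseq[end - read2_len:end])
        else:
            g1 = revcomp(gseq[junction - genomic_read1:junction])
            start = junction - frag_len
            g2 = gseq[start:start + read2_len]
        primer = dsodn
        if primerless_fraction and rng.random() < primerless_fraction:
            primer = "".join(rng.choice(BASES, size=len(dsodn)))
        seq1 = primer + g1
        pairs.append(ReadPair(f"pair{pid:06d}", seq1, "I" * len(seq1),
                              g2, "I" * len(g2)))
        pid += 1

    for site in planted:
        frag_lens = 120 + 7 * np.arange(site.read_count)
        for i, fl in enumerate(frag_lens):
            emit(site.cut, "+" if i % 2 == 0 else "-", int(fl))
    for pos in noise_pos:
        emit(int(pos), "+", int(rng.integers(150, 400)))

    neg_windows = [(chrom, s.cut - 50, s.cut + 50)
                   for s in planted if s.is_negative_control]
    real = [s for s in planted if not s.is_negative_control]
    total_reads = sum(s.read_count for s in real)
    on_share = sum(s.read_count for s in real if s.edit_distance == 0)
    truth = TruthRecord(
        "ttiss", seed,
        params=dict(genome_length=genome_length, dsodn=dsodn,
                    n_noise_singletons=n_noise_singletons,
                    primerless_fraction=primerless_fraction,
                    guide=guide.guide_id),
        planted=dict(
            sites=[dict(proto_start=s.proto_start, cut=s.cut,
                        edit_distance=s.edit_distance,
                        read_count=s.read_count, pam=s.pam,
                        negative_control=s.is_negative_control)
                   for s in planted],
            on_target_read_share=(on_share / total_reads
                                  if total_reads else 0.0)))
    return TtissSimulation(genome, pairs, guide, planted, neg_windows,
                           truth)


# ------------------------------------------------------------- offtarget

def gen_offtarget_genome(guide: GuideSpec, distances: list[int], *,
                         genome_length: int = 100_000, max_ed: int = 6,
                         concrete_pam: str = "ATTC", seed: int = 0,
                         chrom: str = "chr1"
                         ) -> tuple[dict[str, str], TruthRecord]:
    """Random genome with PAM-adjacent sites planted at exact distances.

    Each requested Levenshtein distance is realized next to a concrete
    PAM and verified by anchored alignment before the genome is returned.
    The default NTTN realization ``ATTC`` is chosen because no shifted
    overlap of it re-creates the PAM pattern, which would otherwise
    plant spurious near-distance candidates. The distance-0 plant is the
    programmed on-target.
    """
    if any(d > max_ed for d in distances):
        raise GenerationError("requested distance exceeds max_ed")
    rng = module_rng(seed, "offtarget")
    genome = random_genome(genome_length, seed, chrom=chrom,
                           stream="offtarget")
    seq = list(genome[chrom])
    spacer = guide.spacer.upper()
    L = len(spacer)
    spacing = max(400, genome_length // (len(distances) + 2))
    planted = []
    for i, d in enumerate(sorted(distances)):
        start = 500 + i * spacing
        if start + L + 10 > genome_length:
            raise GenerationError("genome too short for requested plants")
        pam = concrete_pam
        # verify the anchored distance in genomic context (flank slack
        # included), retrying the mutation if the flank shortens it
        for _ in range(100):
            proto = _mutate_to_distance(spacer, d, rng)
            window = proto + "".join(seq[start + L:start + L + max_ed])
            res = edlib.align(spacer, window, mode="SHW", k=max_ed)
            if res["editDistance"] == d:
                break
        else:
            raise GenerationError(
                f"could not realize edit distance {d} in context")
        seq[start - len(pam):start] = list(pam)
        seq[start:start + L] = list(proto)
        planted.append(dict(start=start, distance=d, pam=pam,
                            sequence=proto))
    genome = {chrom: "".join(seq)}
    truth = TruthRecord(
        "offtarget_genome", seed,
        params=dict(genome_length=genome_length, distances=distances,
                    guide=guide.guide_id),
        planted=dict(sites=planted))
    return genome, truth
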