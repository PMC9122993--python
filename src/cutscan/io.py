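"""Readers and writers for the text formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM through pysam, tables through
pandas. Coordinates are 0-based half-open internally; BED is native
0-based, SAM is converted on ingest (see :mod:`cutscan.ttiss`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .ttiss import ReadPair

__all__ = ["read_fasta", "write_fasta", "read_fastq", "write_fastq",
           "read_fastq_pairs", "write_fastq_pairs", "read_bed",
           "write_bed", "read_tsv", "write_tsv", "write_json"]

_IUPAC_DNA = set("ACGTNRYSWKMBDHV")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence mapping."""
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - _IUPAC_DNA
            if bad:
                raise ParseError(
                    f"record {rec.id!r}: non-IUPAC characters {sorted(bad)}")
        # second pass kept trivial: SeqIO already validated structure
        out = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(path), "fasta")}
    except ValueError as exc:
        raise ParseError(str(exc)) from exc
    return out


def write_fasta(path: str | Path, seqs: dict[str, str],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, sequence, quality-string) records from a FASTQ file."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = "".join(chr(q + 33)
                            for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq).upper(), quals
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_fastq(path: str | Path,
                records: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ParseError(
                    f"record {rid!r}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq_pairs(path1: str | Path,
                     path2: str | Path) -> list[ReadPair]:
    """Load paired FASTQ files into :class:`~cutscan.ttiss.ReadPair`s."""
    r1 = list(read_fastq(path1))
    r2 = list(read_fastq(path2))
    if len(r1) != len(r2):
        raise ParseError(
            f"unpaired files: {len(r1)} vs {len(r2)} records")
    return [ReadPair(a[0], a[1], a[2], b[1], b[2])
            for a, b in zip(r1, r2)]


def write_fastq_pairs(path1: str | Path, path2: str | Path,
                      pairs: list[ReadPair]) -> None:
    write_fastq(path1, [(p.pair_id, p.seq1, p.qual1) for p in pairs])
    write_fastq(path2, [(p.pair_id, p.seq2, p.qual2) for p in pairs])


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: (chrom, start, end, name) per interval."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("fewer than 3 BED fields", line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}",
                                 line=lineno) from exc
            if start < 0 or end < start:
                raise ParseError(f"bad interval {start}-{end}", line=lineno)
            name = fields[3] if len(fields) > 3 else ""
            out.append((fields[0], start, end, name))
    return out


def write_bed(path: str | Path,
              intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(str(exc)) from exc


def write_tsv(path: str | Path, frame: pd.DataFrame,
              provenance: dict | None = None) -> None:
    """Write a TSV, optionally preceded by '#'-prefixed provenance lines."""
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
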