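"""Small DNA sequence helpers: complementing, IUPAC pattern matching.

Coordinates are 0-based half-open throughout the toolkit.
"""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True when ``seq`` satisfies the IUPAC ``pattern`` base-for-base."""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern.upper(), seq.upper()):
        allowed = IUPAC.get(p)
        if allowed is None or s not in allowed:
            return False
    return True


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into a regex over {A,C,G,T}."""
    parts = []
    for p in pattern.upper():
        allowed = IUPAC.get(p)
        if allowed is None:
            raise ValueError(f"not an IUPAC code: {p!r}")
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile("".join(parts))


def find_iupac(pattern: str, seq: str) -> list[int]:
    """All (overlapping) start positions of an IUPAC pattern in ``seq``."""
    rx = re.compile(f"(?=({iupac_regex(pattern).pattern}))")
    return [m.start() for m in rx.finditer(seq.upper())]


def mean_phred(qualities: str) -> float:
    """Mean Phred score of a Sanger-encoded quality string."""
    if not qualities:
        return 0.0
    return sum(ord(q) - 33 for q in qualities) / len(qualities)
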