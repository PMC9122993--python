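"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain-Python dynamic
programming and straight-line arithmetic, kept simple enough to verify by
eye.
"""

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def levenshtein(a, b):
    """Plain full-matrix edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j - 1] + (a[i - 1] != b[j - 1]),
                         cur[j - 1] + 1, prev[j] + 1)
        prev = cur
    return prev[n]


def best_substring_distance(query, text):
    """Min Levenshtein distance of ``query`` to any substring of ``text``
    (semi-global: free start and end in the text), one strand."""
    m, n = len(query), len(text)
    prev = [0] * (n + 1)          # free start in text
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j - 1] + (query[i - 1] != text[j - 1]),
                         cur[j - 1] + 1, prev[j] + 1)
        prev = cur
    return min(prev)              # free end in text


def best_substring_distance_both_strands(query, text):
    return min(best_substring_distance(query, text),
               best_substring_distance(query, rc(text)))


def prefix_anchored_distance(query, text):
    """Min edit distance of ``query`` to any *prefix* of ``text``
    (alignment pinned at text position 0, free end)."""
    m, n = len(query), len(text)
    prev = list(range(n + 1))
    best = prev[0] + m            # degenerate: empty prefix
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j - 1] + (query[i - 1] != text[j - 1]),
                         cur[j - 1] + 1, prev[j] + 1)
        prev = cur
    return min(prev)


IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
         "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
         "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


def pam_positions(pattern, seq):
    """All start positions where ``seq`` matches the IUPAC pattern."""
    plen = len(pattern)
    out = []
    for i in range(len(seq) - plen + 1):
        if all(seq[i + k] in IUPAC[pattern[k]] for k in range(plen)):
            out.append(i)
    return out


def brute_scan(genome, spacer, pam, max_ed):
    """Every PAM-adjacent candidate within ``max_ed`` anchored edits,
    both strands, as a set of (chrom, pam_pos, strand, distance).

    Mirrors the definition: the spacer alignment starts immediately 3'
    of a 5' PAM on the protospacer strand and may extend up to
    ``max_ed`` bases beyond spacer length.

    The adjacency coordinate identifying each candidate is the forward
    coordinate of the PAM-proximal protospacer end: window start for "+",
    window end for "-".
    """
    L = len(spacer)
    found = set()
    for chrom, seq in genome.items():
        for pos in pam_positions(pam, seq):
            window = seq[pos + len(pam):pos + len(pam) + L + max_ed]
            if len(window) >= L - max_ed:
                d = prefix_anchored_distance(spacer, window)
                if d <= max_ed:
                    found.add((chrom, pos + len(pam), "+", d))
        rseq = rc(seq)
        for pos in pam_positions(pam, rseq):
            window = rseq[pos + len(pam):pos + len(pam) + L + max_ed]
            if len(window) >= L - max_ed:
                d = prefix_anchored_distance(spacer, window)
                if d <= max_ed:
                    found.add((chrom, len(seq) - pos - len(pam), "-", d))
    return found


def zscore_chain(control_ratios, variant_ratios):
    """Straight-line recomputation of the plate-statistics chain.

    ``control_ratios``: 2-D array (controls x replicates);
    ``variant_ratios``: 1-D array of one variant's replicate ratios.
    """
    flat = np.asarray(control_ratios, float).ravel()
    mu = flat.sum() / flat.size
    sigma = np.sqrt(((flat - mu) ** 2).sum() / flat.size)
    v = np.asarray(variant_ratios, float)
    n_reps = np.asarray(control_ratios).shape[1]
    return (v.sum() / v.size - mu) / (sigma / np.sqrt(n_reps))


def grid_mle(k, n, k0, n0, grid_step=1e-4):
    """Grid-search maximizer of the binomial mixture likelihood in p."""
    b = k0 / n0
    p = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    q = np.clip(b + p * (1.0 - b), 1e-12, 1 - 1e-12)
    loglik = k * np.log(q) + (n - k) * np.log1p(-q)
    return float(p[int(np.argmax(loglik))])


def cigar_indel_totals(cigar):
    """(inserted, deleted) base totals from an edlib cigar string."""
    ins = dele = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "I":
                ins += int(num)
            elif ch == "D":
                dele += int(num)
            num = ""
    return ins, dele
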