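"""Edit-operation calling between a read and a reference sequence.

The engine combines exact k-mer anchoring with unit-cost dynamic-programming
alignment of the unanchored interior, the strategy used throughout amplicon
indel profiling here:

1. k-mers that occur exactly once in both the read and the reference are
   collected as candidate anchors;
2. the highest-count mutually consistent anchor chain is selected;
3. stretches between consecutive anchors (and the two flanks) are resolved
   by a full Needleman–Wunsch-style DP with unit mismatch and unit
   per-base indel cost;
4. when no anchors exist the whole read falls back to the full DP, and the
   read is declared unaligned if the resulting edit distance exceeds a
   fraction of its length.

Tie-breaking in the DP traceback prefers diagonal moves, then deletions,
then insertions, which left-aligns gaps inside homopolymers; a final
left-shift pass normalizes indels that straddle anchor boundaries.
Coordinates are 0-based on the reference; an insertion's ``ref_position``
is the reference index *before which* the bases are inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EditOp", "EditOpSet", "global_align", "call_edit_ops"]

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass
class EditOp:
    kind: str
    ref_position: int
    length: int
    inserted_sequence: str = ""


@dataclass
class EditOpSet:
    """Ordered edit operations for one read against one reference."""

    read_id: str
    ops: list[EditOp] = field(default_factory=list)
    aligned: bool = True

    @property
    def total_inserted(self) -> int:
        return sum(o.length for o in self.ops if o.kind == INSERTION)

    @property
    def total_deleted(self) -> int:
        return sum(o.length for o in self.ops if o.kind == DELETION)

    @property
    def has_indel(self) -> bool:
        return any(o.kind in (INSERTION, DELETION) for o in self.ops)

    @property
    def net_indel_size(self) -> int:
        """Signed per-read indel size: inserted bases minus deleted bases."""
        return self.total_inserted - self.total_deleted


def _dp_align(read: str, ref: str) -> list[str]:
    """Unit-cost global alignment path.

    Returns a move string over {'M' diagonal, 'D' ref-gap-in-read
    (deletion), 'I' read-gap-in-ref (insertion)} read left to right.
    """
    m, n = len(read), len(ref)
    if m == 0:
        return ["D"] * n
    if n == 0:
        return ["I"] * m
    # D[i][j]: edit distance read[:i] vs ref[:j]
    prevs: list[list[int]] = [list(range(n + 1))]
    for i in range(1, m + 1):
        row = [i] + [0] * n
        prev = prevs[-1]
        ri = read[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (ri != ref[j - 1])
            dele = row[j - 1] + 1
            ins = prev[j] + 1
            row[j] = min(sub, dele, ins)
        prevs.append(row)
    # traceback: prefer diagonal, then deletion (left), then insertion (up)
    moves: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        cur = prevs[i][j]
        if i > 0 and j > 0 and prevs[i - 1][j - 1] + (read[i - 1] != ref[j - 1]) == cur:
            moves.append("M")
            i -= 1
            j -= 1
        elif j > 0 and prevs[i][j - 1] + 1 == cur:
            moves.append("D")
            j -= 1
        else:
            moves.append("I")
            i -= 1
    moves.reverse()
    return moves


def _ops_from_moves(moves: list[str], read: str, ref: str,
                    read_off: int = 0, ref_off: int = 0) -> list[EditOp]:
    ops: list[EditOp] = []
    i, j = read_off, ref_off
    for mv in moves:
        if mv == "M":
            kind = MATCH if read[i] == ref[j] else MISMATCH
            if ops and ops[-1].kind == kind and mv == "M":
                ops[-1].length += 1
            else:
                ops.append(EditOp(kind, j, 1))
            i += 1
            j += 1
        elif mv == "D":
            if ops and ops[-1].kind == DELETION and ops[-1].ref_position + ops[-1].length == j:
                ops[-1].length += 1
            else:
                ops.append(EditOp(DELETION, j, 1))
            j += 1
        else:  # insertion
            if ops and ops[-1].kind == INSERTION and ops[-1].ref_position == j:
                ops[-1].length += 1
                ops[-1].inserted_sequence += read[i]
            else:
                ops.append(EditOp(INSERTION, j, 1, read[i]))
            i += 1
    return ops


def _merge_ops(ops: list[EditOp]) -> list[EditOp]:
    merged: list[EditOp] = []
    for op in ops:
        if merged:
            last = merged[-1]
            if (op.kind == last.kind and op.kind in (MATCH, MISMATCH)
                    and last.ref_position + last.length == op.ref_position):
                last.length += op.length
                continue
            if (op.kind == last.kind == DELETION
                    and last.ref_position + last.length == op.ref_position):
                last.length += op.length
                continue
            if (op.kind == last.kind == INSERTION
                    and last.ref_position == op.ref_position):
                last.length += op.length
                last.inserted_sequence += op.inserted_sequence
                continue
        merged.append(EditOp(op.kind, op.ref_position, op.length,
                             op.inserted_sequence))
    return merged


def _left_align(ops: list[EditOp], ref: str) -> list[EditOp]:
    """Shift indels leftward through flanking matches (homopolymer norm)."""
    ops = [EditOp(o.kind, o.ref_position, o.length, o.inserted_sequence)
           for o in ops]
    for idx, op in enumerate(ops):
        if op.kind not in (DELETION, INSERTION) or idx == 0:
            continue
        prev = ops[idx - 1]
        if prev.kind != MATCH:
            continue
        shift = 0
        if op.kind == DELETION:
            p, L = op.ref_position, op.length
            while (shift < prev.length
                   and ref[p - 1 - shift] == ref[p + L - 1 - shift]):
                shift += 1
        else:
            p = op.ref_position
            seq = op.inserted_sequence
            while shift < prev.length and seq[-1] == ref[p - 1]:
                seq = ref[p - 1] + seq[:-1]
                p -= 1
                shift += 1
            op.inserted_sequence = seq
        if shift == 0:
            continue
        op.ref_position -= shift
        prev.length -= shift
        nxt = ops[idx + 1] if idx + 1 < len(ops) else None
        if nxt is not None and nxt.kind == MATCH:
            nxt.ref_position -= shift
            nxt.length += shift
        else:
            tail_pos = op.ref_position + (op.length if op.kind == DELETION else 0)
            ops.insert(idx + 1, EditOp(MATCH, tail_pos, shift))
    return _merge_ops([o for o in ops if o.length > 0])


def global_align(read: str, ref: str) -> list[EditOp]:
    """Full-DP edit operations of ``read`` against ``ref`` (left-aligned)."""
    moves = _dp_align(read, ref)
    return _left_align(_merge_ops(_ops_from_moves(moves, read, ref)), ref)


def _anchors(read: str, ref: str, k: int) -> list[tuple[int, int]]:
    def unique_kmers(s: str) -> dict[str, int]:
        seen: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if km in seen:
                dup.add(km)
            else:
                seen[km] = i
        for km in dup:
            del seen[km]
        return seen

    rk = unique_kmers(read)
    fk = unique_kmers(ref)
    return sorted((rpos, fk[km]) for km, rpos in rk.items() if km in fk)


def _chain(anchors: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Longest mutually consistent anchor chain (O(n^2) DP)."""
    n = len(anchors)
    if n == 0:
        return []
    best = [1] * n
    back = [-1] * n
    for b in range(n):
        rb, pb = anchors[b]
        for a in range(b):
            ra, pa = anchors[a]
            same_diag = (rb - ra) == (pb - pa) and rb > ra
            apart = rb >= ra + k and pb >= pa + k
            if (same_diag or apart) and best[a] + 1 > best[b]:
                best[b] = best[a] + 1
                back[b] = a
    end = max(range(n), key=best.__getitem__)
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = back[end]
    chain.reverse()
    return chain


def call_edit_ops(read: str, ref: str, read_id: str = "", *, k: int = 10,
                  max_dist_frac: float = 0.3) -> EditOpSet:
    """Call edit operations for one read against an amplicon reference.

    Parameters
    ----------
    read, ref
        DNA over {A,C,G,T,N}; the read is assumed to span the reference
        (amplicon sequencing).
    k
        Anchor k-mer length.
    max_dist_frac
        When anchoring fails entirely, the full-DP fallback alignment is
        accepted only if its edit distance is at most this fraction of the
        read length; otherwise the read is reported unaligned.
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    ref = ref.upper()
    if read == ref:
        return EditOpSet(read_id, [EditOp(MATCH, 0, len(ref))])

    chain = _chain(_anchors(read, ref, k), k)
    if not chain:
        ops = global_align(read, ref)
        dist = sum(o.length for o in ops if o.kind != MATCH)
        if dist > max_dist_frac * len(read):
            return EditOpSet(read_id, [], aligned=False)
        return EditOpSet(read_id, ops)

    # collapse same-diagonal overlapping/adjacent anchors into exact blocks
    blocks: list[tuple[int, int, int]] = []  # (read_start, ref_start, length)
    for r, p in chain:
        if blocks:
            br, bp, bl = blocks[-1]
            if (r - br) == (p - bp) and r <= br + bl:
                blocks[-1] = (br, bp, r - br + k)
                continue
        blocks.append((r, p, k))

    moves: list[str] = []
    ri = pi = 0
    for br, bp, bl in blocks:
        moves.extend(_dp_align(read[ri:br], ref[pi:bp]))
        moves.extend("M" * bl)
        ri, pi = br + bl, bp + bl
    moves.extend(_dp_align(read[ri:], ref[pi:]))
    ops = _left_align(_merge_ops(_ops_from_moves(moves, read, ref)), ref)
    return EditOpSet(read_id, ops)
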