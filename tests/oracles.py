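"""Independent reference implementations used only as test oracles.

These deliberately avoid the library code paths they check: the motif oracle
is a per-window, per-position set-membership check; the alignment oracles
score alignments directly (one by exhaustive generation of every alignment,
one by memoized recursion over edit operations with affine gap costs).
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def naive_scan(seq: str, elements: list[tuple[str, set[str]]]) -> list[int]:
    """1-based match starts of a fixed-width motif by direct window checks.

    ``elements`` is a list of ("wildcard"|"set", residues) pairs.
    """
    seq = seq.upper()
    w = len(elements)
    starts = []
    for s in range(len(seq) - w + 1):
        ok = True
        for k, (kind, residues) in enumerate(elements):
            ch = seq[s + k]
            if kind == "wildcard":
                continue
            if ch not in residues:
                ok = False
                break
        if ok:
            starts.append(s + 1)
    return starts


def affine_score_recursive(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal global affine-gap score by memoized recursion over edit ops.

    A gap run of length L costs gap_open + (L-1)*gap_extend. Substitution
    scores come from BLOSUM62.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(_BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if prev == "D" else gap_open
            options.append(-cost + best(i + 1, j, "D"))
        if j < len(b):  # gap in a
            cost = gap_extend if prev == "I" else gap_open
            options.append(-cost + best(i, j + 1, "I"))
        return max(options)

    return float(best(0, 0, "-"))


def affine_score_enumerated(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal score by generating and scoring every alignment explicitly.

    Exponential; only usable for very short sequences. Validates the
    memoized oracle above.
    """

    def alignments(i: int, j: int):
        if i == len(a) and j == len(b):
            yield []
            return
        if i < len(a) and j < len(b):
            for rest in alignments(i + 1, j + 1):
                yield ["M"] + rest
        if i < len(a):
            for rest in alignments(i + 1, j):
                yield ["D"] + rest
        if j < len(b):
            for rest in alignments(i, j + 1):
                yield ["I"] + rest

    def score(ops: list[str]) -> float:
        total = 0.0
        i = j = 0
        prev = "-"
        for op in ops:
            if op == "M":
                total += _BLOSUM62[a[i], b[j]]
                i += 1
                j += 1
            else:
                total -= gap_extend if prev == op else gap_open
                if op == "D":
                    i += 1
                else:
                    j += 1
            prev = op
        return total

    return max(score(ops) for ops in alignments(0, 0))
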