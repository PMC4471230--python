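"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementation: the
mapper oracle is a character-by-character sliding scan, and the aligner
oracle is a plain three-matrix affine DP with free end gaps.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_map(read_seq: str, genome_seq: str, bound: int, circular: bool = True):
    """All (start, strand, mismatches) with Hamming distance <= bound."""
    hits = set()
    n = len(genome_seq)
    hay = genome_seq + genome_seq if circular else genome_seq
    L = len(read_seq)
    if L > n:
        return hits
    starts = range(n) if circular else range(n - L + 1)
    for strand, s in (("+", read_seq), ("-", rc(read_seq))):
        for i in starts:
            window = hay[i : i + L]
            m = sum(a != b or a == "N" or b == "N" for a, b in zip(window, s))
            if m <= bound:
                hits.add((i, strand, m))
    return hits


MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -4, -1  # first gap char: -5

NEG = float("-inf")


def affine_global_score(a: str, b: str) -> float:
    """Optimal end-free affine global alignment score (no traceback)."""
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading end gap
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + GAP_OPEN + GAP_EXTEND, X[i - 1][j] + GAP_EXTEND
            )
            Y[i][j] = max(
                M[i][j - 1] + GAP_OPEN + GAP_EXTEND, Y[i][j - 1] + GAP_EXTEND
            )
    # free trailing end gaps: best over last row / last column
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m] if i else NEG)
    for j in range(m + 1):
        best = max(best, M[n][j], Y[n][j] if j else NEG)
    return best


def score_alignment(row_a: str, row_b: str) -> float:
    """Score a gapped alignment under the same scheme (end gaps free)."""
    cols = list(zip(row_a, row_b))
    # strip end-gap columns
    lo, hi = 0, len(cols)
    while lo < hi and ("-" in cols[lo]):
        lo += 1
    while hi > lo and ("-" in cols[hi - 1]):
        hi -= 1
    score = 0.0
    in_gap = None
    for x, y in cols[lo:hi]:
        if x == "-" or y == "-":
            which = "x" if x == "-" else "y"
            if in_gap != which:
                score += GAP_OPEN
            score += GAP_EXTEND
            in_gap = which
        else:
            score += MATCH if x == y else MISMATCH
            in_gap = None
    return score
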