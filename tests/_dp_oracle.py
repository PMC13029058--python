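"""Independent affine-gap alignment oracle (Gotoh recurrences, score only).

Written against the BLAST gap convention — a gap of length k costs
open + k*extend — and kept deliberately separate from the package's
alignment implementation so score comparisons are a dual-route check.
"""

NEG = float("-inf")

ALPHABET = "ACDE"  # 4-letter reduced protein alphabet for exhaustive tests


def oracle_score(a, b, match, mismatch, gap_open, gap_extend, mode):
    go = gap_open + gap_extend  # cost of the first gap column
    ge = gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    if mode == "global":
        for i in range(1, n + 1):
            X[i][0] = -(go + ge * (i - 1))
        for j in range(1, m + 1):
            Y[0][j] = -(go + ge * (j - 1))
    best_local = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if mode == "local":
                prev = max(prev, 0.0)
            M[i][j] = s + prev
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
            best_local = max(best_local, M[i][j])
    if mode == "local":
        return best_local
    return max(M[n][m], X[n][m], Y[n][m])
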