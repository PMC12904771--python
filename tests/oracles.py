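"""Independent reference implementations used only as test oracles.

These deliberately avoid the production code paths: the local-alignment
oracle maximizes an affine-gap *global* alignment over every substring
pair, and the metric oracle is plain confusion-matrix arithmetic.
"""

from __future__ import annotations

import math


def global_affine_score(a, b, score, gap_open, gap_extend):
    """Optimal global affine-gap alignment score of two index sequences.

    A gap of length g costs gap_open + g * gap_extend. Returns -inf when
    one side is empty and the other is not... no: gaps may cover it.
    """
    n, m = len(a), len(b)
    neg = -math.inf
    # M: last column is a match; X: gap consuming b; Y: gap consuming a
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        Y[i][0] = -(gap_open + gap_extend * i)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score[a[i - 1]][b[j - 1]] if not hasattr(score, "shape") \
                else score[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          X[i][j - 1] - gap_extend)
            Y[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          Y[i - 1][j] - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def local_alignment_score_oracle(a, b, score, gap_open, gap_extend):
    """Best local score = max over all substring pairs of the global
    affine score, floored at 0 (the empty alignment)."""
    best = 0.0
    n, m = len(a), len(b)
    for i1 in range(n):
        for i2 in range(i1 + 1, n + 1):
            sub_a = a[i1:i2]
            for j1 in range(m):
                for j2 in range(j1 + 1, m + 1):
                    s = global_affine_score(sub_a, b[j1:j2], score,
                                            gap_open, gap_extend)
                    if s > best:
                        best = s
    return best


def metrics_oracle(tp, tn, fp, fn):
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    return acc, prec, rec, mcc
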