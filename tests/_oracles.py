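"""Independent brute-force oracles used to cross-check the numeric kernels.

These deliberately share no code with the implementations they verify.
"""

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_ks_d(a, b):
    """Two-sample KS statistic by scanning every pooled value as an ECDF
    evaluation point and taking the largest gap."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    points = np.concatenate([a, b])
    return max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in points)


def enumerate_best_score(a, b, gap_open=10.0, gap_extend=0.5, end_free=True):
    """Optimal global alignment score by exhaustively enumerating every
    alignment (as a column list) and scoring it directly: affine gap runs
    cost gap_open + (k-1)*gap_extend, terminal runs free when ``end_free``."""

    def alignments(i, j):
        if i == len(a) and j == len(b):
            yield []
            return
        if i < len(a) and j < len(b):
            for rest in alignments(i + 1, j + 1):
                yield [(a[i], b[j])] + rest
        if i < len(a):
            for rest in alignments(i + 1, j):
                yield [(a[i], "-")] + rest
        if j < len(b):
            for rest in alignments(i, j + 1):
                yield [("-", b[j])] + rest

    def score(cols):
        total = 0.0
        for row in (0, 1):
            run, start, runs = 0, 0, []
            for k, col in enumerate(cols):
                if col[row] == "-":
                    if run == 0:
                        start = k
                    run += 1
                else:
                    if run:
                        runs.append((start, run))
                    run = 0
            if run:
                runs.append((start, run))
            for s, length in runs:
                if end_free and (s == 0 or s + length == len(cols)):
                    continue
                total -= gap_open + (length - 1) * gap_extend
        for x, y in cols:
            if x != "-" and y != "-":
                total += BLOSUM62[x][y]
        return total

    return max(score(cols) for cols in alignments(0, 0))
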