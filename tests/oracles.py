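"""Independent straight-line oracles used by unit and acceptance tests.

Everything here is written with explicit Python loops and stays deliberately
separate from the package implementation it is used to check.
"""

import math

import numpy as np


def loop_matmul(a, b):
    ra, ca = len(a), len(a[0])
    cb = len(b[0])
    out = [[0.0] * cb for _ in range(ra)]
    for i in range(ra):
        for j in range(cb):
            acc = 0.0
            for k in range(ca):
                acc += a[i][k] * b[k][j]
            out[i][j] = acc
    return out


def loop_apply(mat, func):
    return [[func(x) for x in row] for row in mat]


def loop_encode(A, X, W0, W1):
    hidden = loop_apply(loop_matmul(loop_matmul(A, X), W0), lambda x: max(x, 0.0))
    return loop_apply(loop_matmul(loop_matmul(A, hidden), W1), math.tanh)


def loop_decode(A, Z, W2, W3):
    def sigmoid(x):
        return 1.0 / (1.0 + math.exp(-x))

    hidden = loop_apply(loop_matmul(loop_matmul(A, Z), W2), lambda x: max(x, 0.0))
    return loop_apply(loop_matmul(loop_matmul(A, hidden), W3), sigmoid)


def loop_softmax_rows(mat):
    out = []
    for row in mat:
        top = max(row)
        exps = [math.exp(x - top) for x in row]
        total = sum(exps)
        out.append([e / total for e in exps])
    return out


def loop_forward(Am, Ad, Y, weights, alpha, d, divisor):
    """The full composed pipeline, explicit loops end to end."""
    Yt = [list(col) for col in zip(*Y)]
    Zm = loop_encode(Am, Y, weights["m_w0"], weights["m_w1"])
    Zd = loop_encode(Ad, Yt, weights["d_w0"], weights["d_w1"])
    Fm = loop_decode(Am, Zm, weights["m_w2"], weights["m_w3"])
    Fd = loop_decode(Ad, Zd, weights["d_w2"], weights["d_w3"])
    m, n = len(Y), len(Y[0])
    F = [
        [alpha * Fm[i][j] + (1.0 - alpha) * Fd[j][i] for j in range(n)]
        for i in range(m)
    ]
    logits = [
        [
            sum(Zm[i][k] * Zd[j][k] for k in range(d)) / divisor
            for j in range(n)
        ]
        for i in range(m)
    ]
    P = loop_softmax_rows(logits)
    T = [[P[i][j] * F[i][j] for j in range(n)] for i in range(m)]
    return {
        "Zm": np.array(Zm),
        "Zd": np.array(Zd),
        "Fm": np.array(Fm),
        "Fd": np.array(Fd),
        "F": np.array(F),
        "T": np.array(T),
    }


def pairwise_auroc(labels, scores):
    """Rank statistic: P(score+ > score-) + P(tie)/2 by full enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def direct_mcc(tp, fp, tn, fn):
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom
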