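"""Independent brute-force oracles used to check the package's computations.

Everything here is deliberately written from first principles (textbook
formulas, exhaustive enumeration, loops) and shares no code with the package
under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_direct(x, y) -> float:
    """Textbook Pearson correlation: covariance over product of deviations."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def qstar_direct(W: np.ndarray, labels) -> float:
    """Direct summation of the asymmetric signed modularity over all pairs."""
    n = W.shape[0]
    labels = list(labels)
    wp = [[max(W[i][j], 0.0) if i != j else 0.0 for j in range(n)] for i in range(n)]
    wn = [[max(-W[i][j], 0.0) if i != j else 0.0 for j in range(n)] for i in range(n)]
    vp = sum(sum(row) for row in wp)
    vn = sum(sum(row) for row in wn)
    sp = [sum(row) for row in wp]
    sn = [sum(row) for row in wn]
    qp = qn = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            # diagonal carries no weight (wp/wn are 0 there) but keeps its
            # expected-weight term
            if vp > 0:
                qp += (wp[i][j] - sp[i] * sp[j] / vp) / vp
            if vn > 0:
                qn += (wn[i][j] - sn[i] * sn[j] / vn) / vn
    if vp + vn == 0:
        return 0.0
    return qp - (vn / (vp + vn)) * qn


def set_partitions(n: int):
    """All set partitions of range(n) as label lists (restricted growth strings)."""

    def rec(prefix, max_label):
        i = len(prefix)
        if i == n:
            yield list(prefix)
            return
        for lab in range(max_label + 2):
            yield from rec(prefix + [lab], max(max_label, lab))

    yield from rec([], -1)


def best_partition_exhaustive(W: np.ndarray):
    """Globally optimal Q* over every set partition (feasible for n <= 8)."""
    best_q = -np.inf
    best = None
    n = W.shape[0]
    # precompute the per-pair summand once; enumeration then sums over pairs
    wp = np.where(W > 0, W, 0.0).astype(float)
    wn = np.where(W < 0, -W, 0.0).astype(float)
    np.fill_diagonal(wp, 0.0)
    np.fill_diagonal(wn, 0.0)
    vp, vn = wp.sum(), wn.sum()
    sp, sn = wp.sum(1), wn.sum(1)
    term = np.zeros((n, n))
    if vp > 0:
        term += (wp - np.outer(sp, sp) / vp) / vp
    if vn > 0:
        term -= (vn / (vp + vn)) * (wn - np.outer(sn, sn) / vn) / vn
    for labels in set_partitions(n):
        lab = np.asarray(labels)
        q = term[lab[:, None] == lab[None, :]].sum()
        if q > best_q:
            best_q = q
            best = labels
    return best_q, best


def zscores_direct(W: np.ndarray, labels) -> np.ndarray:
    """Two-pass within-module degree z-scores (population sd)."""
    n = W.shape[0]
    labels = list(labels)
    kappa = []
    for i in range(n):
        kappa.append(sum(W[i][j] for j in range(n) if j != i and labels[j] == labels[i]))
    z = [0.0] * n
    for lab in set(labels):
        members = [i for i in range(n) if labels[i] == lab]
        if len(members) < 2:
            continue
        m = sum(kappa[i] for i in members) / len(members)
        var = sum((kappa[i] - m) ** 2 for i in members) / len(members)
        sd = math.sqrt(var)
        if sd > 0:
            for i in members:
                z[i] = (kappa[i] - m) / sd
    return np.asarray(z)


def ranksum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments (tie-free)."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    na = len(a)
    n = len(pooled)
    w_obs = sum(ranks[v] for v in a)
    ew = na * (n + 1) / 2.0
    dev = abs(w_obs - ew)
    hits = total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        total += 1
        if abs(sum(combo) - ew) >= dev - 1e-12:
            hits += 1
    return hits / total


def ols_line(x, y):
    """Straight-line fit by explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.array([[x.size, x.sum()], [x.sum(), (x * x).sum()]])
    rhs = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, rhs)
    return slope, intercept


def pair_count_agreement(a, b) -> float:
    """Adjusted agreement between two labelings by explicit pair counting."""
    a = list(a)
    b = list(b)
    n = len(a)
    n00 = n01 = n10 = n11 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa:
                n10 += 1
            elif sb:
                n01 += 1
            else:
                n00 += 1
    total = n * (n - 1) / 2
    sum_a = n11 + n10
    sum_b = n11 + n01
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def chi2_2x2(sa, ta, sb, tb):
    """Pearson chi-squared statistic for a 2x2 table, no continuity correction."""
    obs = [[sa, ta - sa], [sb, tb - sb]]
    tot = ta + tb
    col = [sa + sb, (ta - sa) + (tb - sb)]
    rowt = [ta, tb]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rowt[i] * col[j] / tot
            stat += (obs[i][j] - e) ** 2 / e
    return stat
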