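"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written as plain loops/enumeration,
sharing no code path with the package.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up, via the explicit definition."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


def ks_permutation_p(x, y):
    """Exact two-sample KS p by enumerating all label splits of the pool."""
    pooled = list(x) + list(y)
    nx = len(x)

    def ks_d(a, b):
        pts = sorted(set(a) | set(b))
        d = 0.0
        for t in pts:
            fa = sum(v <= t for v in a) / len(a)
            fb = sum(v <= t for v in b) / len(b)
            d = max(d, abs(fa - fb))
        return d

    d_obs = ks_d(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if ks_d(a, b) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def auc_pair_count(scores, labels):
    """AUC as concordant-pair fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def mannwhitney_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by label enumeration (no ties)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(a, b):
        return sum(1.0 if ai > bj else (0.5 if ai == bj else 0.0)
                   for ai in a for bj in b)

    mu = nx * len(y) / 2.0
    obs = abs(u_stat(x, y) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - mu) >= obs - 1e-12:
            count += 1
    return count / total


def tmm_reference(counts, trim_m=0.30, trim_a=0.05):
    """Step-by-step TMM reimplementation (plain loops, rank trimming)."""
    counts = np.asarray(counts, float)
    nlib = counts.sum(axis=0)
    # reference column: 75th-percentile CPM closest to the mean
    f75 = [np.quantile(counts[:, j] / nlib[j], 0.75) for j in range(counts.shape[1])]
    ref = int(np.argmin([abs(f - np.mean(f75)) for f in f75]))
    logf = []
    for j in range(counts.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        Ms, As, ws = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / nlib[j], r / nlib[ref]
                Ms.append(math.log2(po / pr))
                As.append(0.5 * math.log2(po * pr))
                ws.append((nlib[j] - o) / (nlib[j] * o)
                          + (nlib[ref] - r) / (nlib[ref] * r))
        n = len(Ms)
        order_m = sorted(range(n), key=lambda i: Ms[i])
        order_a = sorted(range(n), key=lambda i: As[i])
        rank_m = [0] * n
        rank_a = [0] * n
        for pos, i in enumerate(order_m):
            rank_m[i] = pos + 1
        for pos, i in enumerate(order_a):
            rank_a[i] = pos + 1
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += Ms[i] / ws[i]
                den += 1.0 / ws[i]
        logf.append(num / den if den else 0.0)
    factors = np.array([2.0 ** f for f in logf])
    return factors / np.exp(np.mean(np.log(factors)))


def fcm_multistart_best_objective(X, c, m, n_restarts=5000, n_iter=60, seed=0):
    """Best fuzzy c-means objective over many random restarts.

    Textbook update equations written directly (no log-domain tricks);
    centroids initialized at random point pairs with jitter.
    """
    X = np.asarray(X, float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    best = np.inf
    for _ in range(n_restarts):
        idx = rng.choice(n, size=c, replace=False)
        V = X[idx] + rng.normal(0, 1e-3, (c, X.shape[1]))
        for _ in range(n_iter):
            d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (m - 1.0))
            U = inv / inv.sum(axis=1, keepdims=True)
            Um = U ** m
            V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = np.maximum(((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2), 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        J = ((U ** m) * d2).sum()
        best = min(best, J)
    return best


def levenshtein(a, b):
    """Plain dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
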