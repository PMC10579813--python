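"""Independent brute-force oracles used to cross-check the library.

Everything here is written as plain loops straight from the definitions and
shares no code with the package. Slow on purpose; only run on tiny inputs.
"""

from __future__ import annotations

import math

import numpy as np


# --- sample similarity and the relief weight update -----------------------


def oracle_pcc(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((x[i] - mx) ** 2 for i in range(n))) * math.sqrt(
        sum((y[i] - my) ** 2 for i in range(n))
    )
    if den == 0:
        raise ZeroDivisionError
    return num / den


def oracle_similarity(x, y, epsilon=1e-6, floor=0.5) -> float:
    try:
        rho = oracle_pcc(x, y)
    except ZeroDivisionError:
        return floor
    rho = min(rho, 1.0 - epsilon)
    if rho < -1.0:
        rho = -1.0
    return 1.0 / (1.0 - rho)


def oracle_update_weights(X, Y, k, epsilon=1e-6, floor=0.5) -> np.ndarray:
    """Term-by-term transcription of the relief weight update.

    For every probe t (visited once each): subtract the similarity-weighted
    mean feature difference to the top-k same-label-set neighbors, add for
    every absent class C the prior-weighted mean difference to the top-k
    neighbors carrying C.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    n, f = X.shape
    m = Y.shape[1]
    priors = [sum(Y[i, c] for i in range(n)) / n for c in range(m)]
    fmin = [min(X[i, p] for i in range(n)) for p in range(f)]
    fmax = [max(X[i, p] for i in range(n)) for p in range(f)]

    S = [[oracle_similarity(X[i], X[j], epsilon, floor) for j in range(n)] for i in range(n)]

    def d(p, i, j):
        rng = fmax[p] - fmin[p]
        return 0.0 if rng == 0 else abs(X[i, p] - X[j, p]) / rng

    W = [0.0] * f
    for t in range(n):
        ls = {c for c in range(m) if Y[t, c] == 1}
        same = [i for i in range(n) if i != t and all(Y[i, c] == Y[t, c] for c in range(m))]
        hits = sorted(same, key=lambda i: (-S[t][i], i))[:k]
        if ls:
            p_ls = sum(priors[c] for c in sorted(ls)) / len(ls)
        else:
            p_ls = 0.0
        p_ls = min(p_ls, 1.0 - 1e-12)
        for p in range(f):
            if hits:
                num = sum(S[t][j] * d(p, t, j) for j in hits)
                den = n * sum(S[t][j] for j in hits)
                W[p] -= num / den
            for c in range(m):
                if c in ls:
                    continue
                cand = [i for i in range(n) if i != t and Y[i, c] == 1]
                miss = sorted(cand, key=lambda i: (-S[t][i], i))[:k]
                if not miss:
                    continue
                num = sum(S[t][j] * d(p, t, j) for j in miss)
                den = n * sum(S[t][j] for j in miss)
                W[p] += priors[c] / (1.0 - p_ls) * num / den
    return np.array(W)


# --- rank helpers ---------------------------------------------------------


def oracle_rank(f_row, j) -> int:
    """1-based rank of label j: higher score first, ties to lower index."""
    r = 1
    for k in range(len(f_row)):
        if f_row[k] > f_row[j] or (f_row[k] == f_row[j] and k < j):
            r += 1
    return r


# --- the eleven measures --------------------------------------------------


def oracle_hamming(Y, H) -> float:
    n, m = Y.shape
    return sum(1 for i in range(n) for j in range(m) if Y[i][j] != H[i][j]) / (n * m)


def oracle_one_error(Y, F) -> float:
    n, m = Y.shape
    total = 0
    for i in range(n):
        best = 0
        for j in range(1, m):
            if F[i][j] > F[i][best]:
                best = j
        total += 0 if Y[i][best] == 1 else 1
    return total / n


def oracle_coverage(Y, F, conventional=False) -> float:
    n, m = Y.shape
    total = 0
    for i in range(n):
        worst = max(oracle_rank(F[i], j) for j in range(m) if Y[i][j] == 1)
        total += worst - 1
    return total / (n if conventional else n * m)


def oracle_ranking_loss(Y, F) -> float:
    terms = []
    n, m = Y.shape
    for i in range(n):
        pos = [j for j in range(m) if Y[i][j] == 1]
        neg = [j for j in range(m) if Y[i][j] == 0]
        if not neg:
            continue
        bad = sum(1 for u in pos for v in neg if F[i][u] <= F[i][v])
        terms.append(bad / (len(pos) * len(neg)))
    return sum(terms) / len(terms)


def oracle_average_precision(Y, F) -> float:
    n, m = Y.shape
    outer = []
    for i in range(n):
        pos = [j for j in range(m) if Y[i][j] == 1]
        inner = []
        for j in pos:
            rj = oracle_rank(F[i], j)
            good = sum(1 for k in pos if oracle_rank(F[i], k) <= rj)
            inner.append(good / rj)
        outer.append(sum(inner) / len(inner))
    return sum(outer) / n


def oracle_macro_auc(Y, F) -> tuple[float, list]:
    n, m = Y.shape
    per_label = []
    for j in range(m):
        pos = [i for i in range(n) if Y[i][j] == 1]
        neg = [i for i in range(n) if Y[i][j] == 0]
        if not pos or not neg:
            per_label.append(None)
            continue
        good = sum(1 for a in pos for b in neg if F[a][j] > F[b][j])
        per_label.append(good / (len(pos) * len(neg)))
    vals = [v for v in per_label if v is not None]
    return sum(vals) / len(vals), per_label


def oracle_set_measures(Y, H) -> dict:
    n, m = Y.shape
    mlacc = mlpre = mlrec = acc = 0.0
    for i in range(n):
        yi = {j for j in range(m) if Y[i][j] == 1}
        hi = {j for j in range(m) if H[i][j] == 1}
        inter, union = yi & hi, yi | hi
        mlacc += len(inter) / len(union)
        mlpre += len(inter) / len(hi) if hi else 0.0
        mlrec += len(inter) / len(yi)
        acc += 1.0 if yi == hi else 0.0
    mlacc, mlpre, mlrec, acc = mlacc / n, mlpre / n, mlrec / n, acc / n
    mlf1 = 0.0 if mlpre + mlrec == 0 else 2 * mlpre * mlrec / (mlpre + mlrec)
    return {"mlacc": mlacc, "mlpre": mlpre, "mlrec": mlrec, "mlf1": mlf1, "acc": acc}
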