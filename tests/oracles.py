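"""Independent brute-force oracles used to freeze and cross-check expected
values. These deliberately avoid the code paths they validate."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

REL_TOL = 1e-7


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins, using exact binomial coefficients."""
    n1, n2, k = a + b, c + d, a + c
    den = comb(n1 + n2, k)
    probs = {
        x: comb(n1, x) * comb(n2, k - x) / den
        for x in range(max(0, k - n2), min(n1, k) + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + REL_TOL)))


def support_oracle(n1: int, n2: int, k: int) -> list[float]:
    """All attainable two-sided p-values for the margins, by enumeration."""
    den = comb(n1 + n2, k)
    probs = [
        comb(n1, x) * comb(n2, k - x) / den
        for x in range(max(0, k - n2), min(n1, k) + 1)
    ]
    return sorted(
        {
            min(1.0, sum(p for p in probs if p <= p0 * (1 + REL_TOL)))
            for p0 in probs
        }
    )


def dbh_oracle(p_raw, supports) -> np.ndarray:
    """Discrete BH step-up adjusted values by brute force over every
    candidate threshold in the union of the supports."""
    p_raw = np.asarray(p_raw, dtype=float)
    candidates = sorted({t for sup in supports for t in sup})
    out = np.empty(len(p_raw))
    for i, p in enumerate(p_raw):
        best = 1.0
        for t in candidates:
            if t < p - 1e-15:
                continue
            n_rejectable = int(np.sum(p_raw <= t * (1 + REL_TOL)))
            surrogate = sum(
                max((x for x in sup if x <= t * (1 + REL_TOL)), default=0.0)
                for sup in supports
            )
            best = min(best, surrogate / n_rejectable)
        out[i] = min(best, 1.0)
    return out


def bh_oracle(p_raw) -> np.ndarray:
    """Classical Benjamini-Hochberg adjusted values."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def auroc_oracle(scores, labels) -> float:
    """AUROC by exhaustive positive/negative pair counting (ties 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pam_optimal_cost(d: np.ndarray, k: int) -> float:
    """Global optimum PAM cost by exhaustive search over medoid sets."""
    n = d.shape[0]
    return min(
        d[:, list(medoids)].min(axis=1).sum()
        for medoids in combinations(range(n), k)
    )


def power_iteration_eigengene(x: np.ndarray, iters: int = 5000) -> np.ndarray:
    """First right-singular vector via power iteration on the Gram matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    gram = x.T @ x
    rng = np.random.default_rng(0)
    v = rng.normal(size=gram.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(iters):
        v = gram @ v
        norm = np.linalg.norm(v)
        if norm == 0:
            break
        v /= norm
    return v


def silhouette_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width by the textbook definition."""
    n = len(labels)
    widths = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            widths.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels)
            if other != labels[i]
        )
        widths.append((b - a) / max(a, b))
    return float(np.mean(widths))


def rank_pearson_oracle(x, y) -> float:
    """Spearman via explicit average ranks then Pearson formula."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
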