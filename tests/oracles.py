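"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (per-frame
scans, exhaustive enumeration, math.comb) and shares no code with the
implementation it checks.
"""

import itertools
import math

import numpy as np


def frame_scan_visits(track, arena):
    """Per-frame run-length scan: the reference for visit extraction with
    min_visit_duration 0 and no gap smoothing.

    Returns (zone_id, t_enter, t_exit, distance) tuples; distance uses the
    same credit rule (step credited to the zone of its first sample).
    """
    n = track.n_samples
    labels = []
    for i in range(n):
        if not (np.isfinite(track.x[i]) and np.isfinite(track.y[i])):
            labels.append("__missing__")
        else:
            labels.append(arena.locate(track.x[i], track.y[i]))
    visits = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] not in ("unassigned", "__missing__"):
            t_enter = track.t[i]
            t_exit = track.t[j + 1] if j + 1 < n else track.t[-1]
            if t_exit > t_enter:
                dist = 0.0
                for k in range(i, min(j + 1, n - 1)):
                    if np.isfinite(track.x[k + 1]) and np.isfinite(track.y[k + 1]):
                        dist += math.hypot(track.x[k + 1] - track.x[k],
                                           track.y[k + 1] - track.y[k])
                visits.append((labels[i], float(t_enter), float(t_exit), dist))
        i = j + 1
    return visits


def ranks_by_counting(values):
    """Ascending mid-ranks by pairwise counting (independent of scipy)."""
    out = []
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(math.nan)
            continue
        below = sum(1 for u in values
                    if u is not None and not math.isnan(u) and u < v)
        equal = sum(1 for u in values
                    if u is not None and not math.isnan(u) and u == v)
        out.append(below + (equal + 1) / 2.0)
    return out


def mann_whitney_enum_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of all group
    assignments: the fraction of assignments at least as extreme (in
    |U - mn/2|) as the observed one."""
    pooled = list(x) + list(y)
    m, n = len(x), len(y)
    ranks = ranks_by_counting(pooled)
    u_obs = sum(ranks[:m]) - m * (m + 1) / 2
    center = m * n / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(m + n), m):
        u = sum(ranks[i] for i in combo) - m * (m + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-9:
            hits += 1
    return hits / total


def wilcoxon_enum_p(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns of the
    non-zero differences (mid-ranks of |d|)."""
    d = [v for v in diffs if v != 0]
    ranks = ranks_by_counting([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    total_rank = sum(ranks)
    center = total_rank / 2.0
    hits = total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - center) >= abs(w_obs - center) - 1e-9:
            hits += 1
    return hits / total


def fisher_enum_p(table):
    """Two-sided Fisher p by hypergeometric enumeration with math.comb."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) < 0 or n == 0:
        return 1.0
    denom = math.comb(n, c1)

    def pmf(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(c1 + 1)
                        if pmf(k) <= p_obs * (1 + 1e-9)))


def pca_eigen_oracle(X):
    """Explicit covariance eigen-decomposition of a scaled, centered
    matrix: returns (explained-variance fractions, loadings)."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cov = Xs.T @ Xs / (len(Xs) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    return evals / evals.sum(), evecs[:, order]
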