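"""The non-parametric statistical battery and multivariate profiling.

Group comparisons use the two-sided Mann-Whitney U-test (exact null
distribution when both groups have <= 12 observations and the pooled data
are tie-free, otherwise a tie-corrected normal approximation); paired
trial comparisons use the Wilcoxon matched-pairs signed-rank test with
zero differences dropped; within-trial time courses use the Friedman test
followed by Dunn's pairwise post-hoc comparisons with Bonferroni
adjustment; occurrence (how many animals in a group express a behavior at
all) uses Fisher's exact test; monotonic association uses Spearman's rank
correlation with conventional strength bands.

Significance labeling is uniform: significant at p <= 0.05, trend (T) at
0.05 < p <= 0.1, otherwise ns.

Multivariate profiling: PCA on unit-variance scaled, mean-centered
parameters, and PLS-DA (partial least squares discriminant analysis,
NIPALS) relating the parameter matrix X to group membership Y; X-weights
are denoted w and Y-weights c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, UsageError

SIGNIFICANT, TREND, NS = "significant", "trend", "ns"


def label_significance(p: float) -> str:
    """significant iff p <= 0.05; trend iff 0.05 < p <= 0.1; else ns."""
    if not np.isfinite(p):
        return NS
    if p <= 0.05:
        return SIGNIFICANT
    if p <= 0.1:
        return TREND
    return NS


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    df: object = None
    p_adj: float | None = None
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.label:
            self.label = label_significance(
                self.p_adj if self.p_adj is not None else self.p)


# ---------------------------------------------------------------------------
# exact Mann-Whitney

@lru_cache(maxsize=None)
def _mw_null_counts(m: int, n: int) -> tuple:
    """Null distribution of the rank sum of group 1 (sizes m, n, no ties):
    counts[s] = number of m-subsets of ranks 1..m+n with sum s."""
    N = m + n
    max_sum = m * N  # loose upper bound
    ways = np.zeros((m + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(m, r), 0, -1):
            ways[k, r:] += ways[k - 1, :-r or None]
    return tuple(ways[m])


def mann_whitney_exact_p(u: float, m: int, n: int) -> float:
    """Two-sided exact p for Mann-Whitney U (no ties): twice the smaller
    tail probability, capped at 1."""
    counts = np.array(_mw_null_counts(m, n))
    offset = m * (m + 1) // 2  # rank sum = U + m(m+1)/2
    total = math.comb(m + n, m)
    u_vals = np.arange(len(counts)) - offset
    valid = (u_vals >= 0) & (u_vals <= m * n)
    pmf = counts[valid] / total
    uu = u_vals[valid]
    lo = pmf[uu <= u + 1e-9].sum()
    hi = pmf[uu >= u - 1e-9].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U-test.

    Exact when both samples have <= ``exact_max_n`` observations and the
    pooled data contain no ties; otherwise a tie-corrected normal
    approximation (no continuity correction).  Missing values are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise DegenerateInputError(
            f"Mann-Whitney needs >= 2 non-missing per group (got {m}, {n})")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:m].sum() - m * (m + 1) / 2)
    ties = len(np.unique(pooled)) < m + n
    if not ties and m <= exact_max_n and n <= exact_max_n:
        p = mann_whitney_exact_p(u, m, n)
        method = "exact"
    else:
        mu = m * n / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts ** 3 - tie_counts).sum()
        N = m + n
        var = m * n / 12.0 * (N + 1 - tie_term / (N * (N - 1)))
        if var <= 0:
            return TestResult("mann_whitney", u, 1.0,
                              extra={"method": "degenerate", "n": (m, n)})
        z = (u - mu) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal_tie_corrected"
    return TestResult("mann_whitney", u, p,
                      extra={"method": method, "n": (m, n)})


def _two_group_values(table: pd.DataFrame, parameter: str,
                      trial: str | None):
    if parameter not in table.columns:
        raise UsageError(f"unknown parameter {parameter!r}")
    sub = table
    if trial is not None:
        sub = table.xs(trial, level="trial", drop_level=False)
    groups = sorted(set(sub.index.get_level_values("group")))
    if len(groups) != 2:
        raise UsageError(f"need exactly 2 groups, got {groups}")
    gl = sub.index.get_level_values("group")
    return (sub.loc[gl == groups[0], parameter].to_numpy(float),
            sub.loc[gl == groups[1], parameter].to_numpy(float), groups)


def group_compare(table: pd.DataFrame, parameter: str,
                  trial: str | None = None) -> TestResult:
    """Mann-Whitney comparison of one parameter between the two groups."""
    x, y, groups = _two_group_values(table, parameter, trial)
    res = mann_whitney(x, y)
    res.extra.update(parameter=parameter, groups=groups, trial=trial)
    return res


# ---------------------------------------------------------------------------
# paired trial comparison

def _wilcoxon_exact_p(d: np.ndarray) -> float:
    """Two-sided exact signed-rank p by the sign-flip null distribution.

    Mid-ranks of |d| handle ties; the null flips every sign independently,
    so the distribution of W+ is the subset-sum distribution of the ranks.
    """
    ranks = sps.rankdata(np.abs(d))
    scaled = np.round(ranks * 2).astype(int)  # midranks -> integers
    total = int(scaled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in scaled:
        counts[r:] += counts[:-r or None].copy()
    counts /= counts.sum()
    w_obs = int(np.round(scaled[d > 0].sum()))
    lo = counts[:w_obs + 1].sum()
    hi = counts[w_obs:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_paired(x, y, exact_max_n: int = 15) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Pairs with a missing value are excluded; zero differences are dropped
    before ranking; all-zero differences give p = 1 by convention.  Exact
    (full sign-flip enumeration, tie-safe) when <= ``exact_max_n``
    non-zero differences, otherwise the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise DegenerateInputError("Wilcoxon needs >= 2 usable pairs")
    d = y - x
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult("wilcoxon", 0.0, 1.0,
                          extra={"method": "all_zero_differences",
                                 "n_pairs": len(x)})
    ranks = sps.rankdata(np.abs(nz))
    stat = float(min(ranks[nz > 0].sum(), ranks[nz < 0].sum()))
    if len(nz) <= exact_max_n:
        p, method = _wilcoxon_exact_p(nz), "exact"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.wilcoxon(d, zero_method="wilcox", method="approx")
        method = "approx"
    return TestResult("wilcoxon", stat, float(p),
                      extra={"method": method, "n_pairs": len(x),
                             "n_nonzero": len(nz)})


def trial_compare(table: pd.DataFrame, parameter: str, group: str,
                  trials: tuple = None) -> TestResult:
    """Within-group Wilcoxon comparison of a parameter between two trials."""
    if parameter not in table.columns:
        raise UsageError(f"unknown parameter {parameter!r}")
    gl = table.index.get_level_values("group")
    sub = table.loc[gl == group, parameter]
    wide = sub.droplevel("group").unstack("trial")
    if trials is None:
        trials = tuple(sorted(wide.columns))
    if len(trials) != 2:
        raise UsageError(f"need exactly 2 trials, got {trials}")
    res = wilcoxon_paired(wide[trials[0]].to_numpy(),
                          wide[trials[1]].to_numpy())
    res.extra.update(parameter=parameter, group=group, trials=trials)
    return res


# ---------------------------------------------------------------------------
# time course: Friedman + Dunn

def timecourse_test(binned: pd.DataFrame) -> TestResult:
    """Friedman test across time bins (columns) within one group of rats
    (rows), followed by pairwise Dunn post-hoc tests with Bonferroni
    adjustment.  Rats with a missing bin are excluded with a warning.

    The Friedman statistic is reported in its chi-square form.
    """
    complete = binned.dropna()
    if len(complete) < len(binned):
        warnings.warn(f"excluding {len(binned) - len(complete)} rat(s) "
                      "with a missing bin from the Friedman test")
    n, k = complete.shape
    if n < 2 or k < 2:
        raise DegenerateInputError("Friedman needs >= 2 rats and >= 2 bins")
    arr = complete.to_numpy(float)
    ranks = np.apply_along_axis(sps.rankdata, 1, arr)
    if np.allclose(arr, arr[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*[arr[:, j] for j in range(k)])
    rank_means = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            z = (rank_means[i] - rank_means[j]) / se
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
            posthoc[(str(binned.columns[i]), str(binned.columns[j]))] = {
                "z": float(z), "p": p_raw,
                "p_adj": min(1.0, p_raw * n_pairs),
                "label": label_significance(min(1.0, p_raw * n_pairs))}
    return TestResult("friedman", float(stat), float(p), df=k - 1,
                      extra={"n": n, "rank_means": rank_means.tolist(),
                             "dunn": posthoc})


# ---------------------------------------------------------------------------
# occurrence and correlation

def occurrence_test(counts) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 occurrence table
    [[pos_A, neg_A], [pos_B, neg_B]]."""
    tab = np.asarray(counts, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise UsageError("occurrence table must be 2x2 non-negative integers")
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p),
                      extra={"table": tab.tolist()})


CORRELATION_BANDS = ((0.80, "very strong"), (0.60, "strong"),
                     (0.40, "moderate"), (0.0, "weak/none"))


def correlation_strength(r: float) -> str:
    """Conventional |r| strength bands: <0.40 weak/none, 0.40-0.59
    moderate, 0.60-0.79 strong, >=0.80 very strong."""
    if not np.isfinite(r):
        return "undefined"
    a = abs(r)
    for lo, name in CORRELATION_BANDS:
        if a >= lo:
            return name
    return "weak/none"


def correlate(x, y) -> TestResult:
    """Spearman rank correlation with p-value, strength band and sign."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise DegenerateInputError("Spearman needs >= 4 complete pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return TestResult("spearman", float("nan"), float("nan"), label=NS,
                          extra={"strength": "undefined", "sign": "none",
                                 "n": len(x), "constant_input": True})
    r, p = sps.spearmanr(x, y)
    sign = "positive" if r > 0 else ("negative" if r < 0 else "none")
    return TestResult("spearman", float(r), float(p),
                      extra={"strength": correlation_strength(r),
                             "sign": sign, "n": len(x)})


# ---------------------------------------------------------------------------
# multivariate profiling

@dataclass
class MultivariateResult:
    """Scores, loadings/weights and explained variance of a latent-variable
    fit.  For PLS-DA, ``w`` holds the X-weights and ``c`` the Y-weights."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    r2x: np.ndarray
    w: pd.DataFrame | None = None
    c: np.ndarray | None = None
    dropped: list = field(default_factory=list)
    imputed: int = 0


def _preprocess(table: pd.DataFrame, parameters):
    """Unit-variance scaling + mean-centering; zero-variance columns are
    dropped with a warning; missing cells are imputed at the column mean
    after scaling (i.e. at 0) and counted."""
    missing_params = [p for p in parameters if p not in table.columns]
    if missing_params:
        raise UsageError(f"unknown parameters: {missing_params}")
    X = table[list(parameters)].to_numpy(float)
    sd = np.nanstd(X, axis=0, ddof=1)
    keep = np.isfinite(sd) & (sd > 0)
    dropped = [p for p, k in zip(parameters, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance column(s): {dropped}")
    params = [p for p, k in zip(parameters, keep) if k]
    X = X[:, keep]
    Xs = (X - np.nanmean(X, axis=0)) / np.nanstd(X, axis=0, ddof=1)
    imputed = int(np.isnan(Xs).sum())
    Xs = np.nan_to_num(Xs, nan=0.0)
    return Xs, params, dropped, imputed


def pca_profile(table: pd.DataFrame, parameters,
                n_components: int | None = None) -> MultivariateResult:
    """Principal component analysis of scaled, mean-centered parameters.

    Returns per-rat component scores, per-parameter loadings and the
    explained-variance fraction R2X of each component.
    """
    from sklearn.decomposition import PCA

    Xs, params, dropped, imputed = _preprocess(table, parameters)
    if Xs.shape[0] < 3 or Xs.shape[1] < 2:
        raise DegenerateInputError("PCA needs >= 3 rows and >= 2 parameters")
    k = n_components or min(Xs.shape[0] - 1, Xs.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xs)
    comp = [f"PC{i + 1}" for i in range(k)]
    return MultivariateResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp),
        loadings=pd.DataFrame(pca.components_.T, index=params, columns=comp),
        r2x=pca.explained_variance_ratio_,
        dropped=dropped, imputed=imputed)


def plsda_profile(table: pd.DataFrame, parameters,
                  n_components: int = 2) -> MultivariateResult:
    """PLS-DA: NIPALS partial least squares relating the scaled parameter
    matrix X to the group-membership indicator Y.

    Successive components maximize the covariance between X-scores and Y;
    the X-weights w rank parameter importance and the two groups locate on
    opposite sides of the first component for separable data.
    """
    from sklearn.cross_decomposition import PLSRegression

    groups = table.index.get_level_values("group")
    names = sorted(set(groups))
    if len(names) < 2:
        raise UsageError("PLS-DA needs two groups")
    if len(names) > 2:
        raise UsageError(f"only two-group PLS-DA is supported, got {names}")
    y = np.where(np.asarray(groups) == names[1], 1.0, 0.0)
    Xs, params, dropped, imputed = _preprocess(table, parameters)
    k = min(n_components, Xs.shape[1], Xs.shape[0] - 1)
    pls = PLSRegression(n_components=k, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, y - y.mean())
    comp = [f"LV{i + 1}" for i in range(k)]
    scores = pd.DataFrame(pls.x_scores_, index=table.index, columns=comp)
    # per-component fraction of X-variance captured by the X-scores
    total_var = (Xs ** 2).sum()
    t = pls.x_scores_
    p_load = pls.x_loadings_
    r2x = np.array([(np.outer(t[:, i], p_load[:, i]) ** 2).sum() / total_var
                    for i in range(k)])
    return MultivariateResult(
        scores=scores,
        loadings=pd.DataFrame(p_load, index=params, columns=comp),
        r2x=r2x,
        w=pd.DataFrame(pls.x_weights_, index=params, columns=comp),
        c=pls.y_weights_.ravel(),
        dropped=dropped, imputed=imputed)
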