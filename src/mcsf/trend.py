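"""Rank-based trend analysis over functional categories.

The trend analysis converts the parameter table into behavioral-profile
scores: rats are ranked across experimental groups and trials for each
parameter (ascending mid-ranks; parameters marked inverse are reversed
first so that low raw values earn high ranks), and the ranks of the
parameters belonging to one functional category are summed per rat-trial.
The five default categories are general activity, exploratory activity,
shelter seeking, risk assessment and risk taking.

Because the rank sums are approximately normal, category scores are
compared with parametric tests: an unpaired t-test between groups within
each trial, and - when two trials are present - a two-way repeated-measures
(mixed) ANOVA with group as the between factor, trial as the within
factor, and Bonferroni-adjusted within-group trial contrasts.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import ConfigError, DegenerateInputError, UsageError
from .stats import TestResult, label_significance


# ---------------------------------------------------------------------------
# category map

def load_category_map(path=None) -> dict[str, list[tuple[str, bool]]]:
    """Load a functional-category map; ``None`` loads the bundled default.

    Format: ``category: [[parameter, inverse], ...]``.
    """
    if path is None:
        text = resources.files("mcsf.data").joinpath(
            "trend_categories.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse category map: {exc}") from exc
    if not isinstance(raw, Mapping) or not raw:
        raise ConfigError("category map must be a non-empty mapping")
    out: dict[str, list[tuple[str, bool]]] = {}
    for cat, entries in raw.items():
        parsed = []
        for e in entries:
            if not (isinstance(e, Sequence) and len(e) == 2
                    and isinstance(e[1], bool)):
                raise ConfigError(
                    f"category {cat!r}: each entry must be [parameter, inverse-bool]")
            parsed.append((str(e[0]), bool(e[1])))
        out[str(cat)] = parsed
    return out


# ---------------------------------------------------------------------------
# ranking

def rank_parameter(values, inverse: bool = False) -> np.ndarray:
    """Ascending mid-ranks of the pooled non-missing values.

    ``inverse`` reverses the order before ranking (low raw value -> high
    rank).  Missing entries receive NaN ranks.  Requires >= 2 non-missing
    values.
    """
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    if mask.sum() < 2:
        raise DegenerateInputError(
            "ranking needs at least 2 non-missing values")
    ranks = np.full(v.shape, np.nan)
    ranks[mask] = sps.rankdata(-v[mask] if inverse else v[mask])
    return ranks


def trend_scores(table: pd.DataFrame,
                 category_map: Mapping[str, Sequence] | None = None,
                 missing_rank: str = "midrank") -> pd.DataFrame:
    """Per rat-trial category scores: sums of pooled parameter ranks.

    ``missing_rank='midrank'`` imputes a missing rank at the pooled
    mid-rank (m+1)/2 of that parameter so scores stay comparable across
    rats with different missingness; ``'listwise'`` propagates NaN instead.
    """
    if category_map is None:
        category_map = load_category_map()
    if missing_rank not in ("midrank", "listwise"):
        raise UsageError(f"unknown missing_rank {missing_rank!r}")
    unmapped = {p for entries in category_map.values()
                for p, _ in entries} - set(table.columns)
    if unmapped:
        raise UsageError(f"parameters not in table: {sorted(unmapped)}")

    scores = {}
    for cat, entries in category_map.items():
        total = np.zeros(len(table))
        for param, inverse in entries:
            r = rank_parameter(table[param].to_numpy(), inverse)
            if missing_rank == "midrank":
                m = np.isfinite(r).sum()
                r = np.where(np.isfinite(r), r, (m + 1) / 2.0)
            total = total + r
        scores[cat] = total
    return pd.DataFrame(scores, index=table.index)


# ---------------------------------------------------------------------------
# tests on category scores

def trend_tests(scores: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Statistical battery on trend-analysis category scores.

    Expects a DataFrame indexed by (rat_id, group, trial) with one column
    per category.  Returns a tidy results table with, per category:
    within-trial unpaired t-tests and, when two trials are present, the
    mixed ANOVA main effects and interaction plus Bonferroni-adjusted
    within-group paired trial contrasts.
    """
    idx = scores.index
    groups = sorted(set(idx.get_level_values("group")))
    trials = sorted(set(idx.get_level_values("trial")))
    if len(groups) != 2:
        raise UsageError(f"need exactly 2 groups, got {groups}")

    rows = []
    for cat in scores.columns:
        s = scores[cat]
        for trial in trials:
            a = s.xs(trial, level="trial")[
                s.xs(trial, level="trial").index.get_level_values("group") == groups[0]]
            b = s.xs(trial, level="trial")[
                s.xs(trial, level="trial").index.get_level_values("group") == groups[1]]
            a, b = a.dropna(), b.dropna()
            t, p = sps.ttest_ind(a, b)
            rows.append({"category": cat, "test": "unpaired_t",
                         "trial": trial, "effect": "group",
                         "statistic": float(t), "df": len(a) + len(b) - 2,
                         "p": float(p), "p_adj": np.nan,
                         "label": label_significance(p)})
        if len(trials) == 2:
            rows.extend(_mixed_anova_rows(s, cat, groups, trials))
    return pd.DataFrame(rows)


def _mixed_anova_rows(s: pd.Series, cat: str, groups, trials) -> list[dict]:
    import pingouin as pg

    long = s.rename("score").reset_index()
    # listwise exclusion of rats missing a trial
    counts = long.dropna(subset=["score"]).groupby("rat_id")["trial"].nunique()
    keep = counts[counts == len(trials)].index
    if len(keep) < len(counts):
        warnings.warn(f"{cat}: excluding {len(counts) - len(keep)} rat(s) "
                      "missing a trial from the repeated-measures ANOVA")
    long = long[long.rat_id.isin(keep)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=long, dv="score", within="trial",
                             subject="rat_id", between="group")
    rows = []
    for _, r in aov.iterrows():
        effect = {"group": "group", "trial": "trial",
                  "Interaction": "interaction"}.get(r["Source"], r["Source"])
        rows.append({"category": cat, "test": "mixed_anova", "trial": "both",
                     "effect": effect, "statistic": float(r["F"]),
                     "df": (int(r["DF1"]), int(r["DF2"])),
                     "p": float(r["p_unc"]), "p_adj": np.nan,
                     "label": label_significance(r["p_unc"])})
    # Bonferroni-adjusted within-group paired trial contrasts
    for g in groups:
        sub = long[long.group == g].pivot(index="rat_id", columns="trial",
                                          values="score").dropna()
        if len(sub) < 2:
            continue
        t, p = sps.ttest_rel(sub[trials[0]], sub[trials[1]])
        p_adj = min(1.0, float(p) * len(groups))
        rows.append({"category": cat, "test": "paired_t_bonferroni",
                     "trial": "both", "effect": f"trial_within_{g}",
                     "statistic": float(t), "df": len(sub) - 1,
                     "p": float(p), "p_adj": p_adj,
                     "label": label_significance(p_adj)})
    return rows
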