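"""Ethogram bout scoring for the novel cage and home cage change tests.

Behaviors are manually scored as timed bouts; per rat the relative
frequency and relative duration of each behavior are its fractions of the
total categorized behavior scored for that rat, and a functional-category
score is the sum of the relative measures of its member behaviors.  The
frequency-variant (and, when total duration is positive, the
duration-variant) category scores therefore sum to 1 over categories.

Standalone behaviors (burrowing in the home cage change test) are not part
of the social/coping repertoire: they are excluded from both denominators
and reported raw, in bouts and seconds.  Point events (t_stop == t_start,
e.g. passing) contribute to frequency scores only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, DataError, DegenerateInputError

_BUNDLED = {"novel_cage": "ethogram_novel_cage.yaml",
            "home_cage_change": "ethogram_home_cage.yaml"}

BOUT_LOG_COLUMNS = ["rat_id", "session", "behavior", "t_start_s", "t_stop_s"]


@dataclass(frozen=True)
class EthogramDefinition:
    """Behavior inventory of one test: category map plus standalone set."""

    test_type: str
    categories: Mapping[str, tuple]  # category -> behavior names
    descriptions: Mapping[str, str]
    standalone: tuple = ()
    session_duration: float | None = None

    @property
    def behavior_to_category(self) -> dict[str, str]:
        return {b: c for c, bs in self.categories.items() for b in bs}

    @property
    def behaviors(self) -> tuple:
        return tuple(self.behavior_to_category) + tuple(self.standalone)


def load_ethogram(which="novel_cage") -> EthogramDefinition:
    """Load an ethogram definition: a bundled test type name or a path."""
    if which in _BUNDLED:
        text = resources.files("mcsf.data").joinpath(_BUNDLED[which]).read_text()
    else:
        text = Path(which).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse ethogram: {exc}") from exc
    if "categories" not in raw or "test_type" not in raw:
        raise ConfigError("ethogram needs 'test_type' and 'categories' keys")
    cats, desc = {}, {}
    for cat, behaviors in raw["categories"].items():
        cats[str(cat)] = tuple(str(b) for b in behaviors)
        for b, d in behaviors.items():
            if b in desc:
                raise ConfigError(f"behavior {b!r} mapped to multiple categories")
            desc[str(b)] = str(d)
    standalone = tuple(str(b) for b in (raw.get("standalone") or {}))
    for b, d in (raw.get("standalone") or {}).items():
        if b in desc:
            raise ConfigError(f"behavior {b!r} both categorized and standalone")
        desc[str(b)] = str(d)
    return EthogramDefinition(
        test_type=str(raw["test_type"]), categories=cats, descriptions=desc,
        standalone=standalone,
        session_duration=float(raw["session_duration"])
        if "session_duration" in raw else None)


@dataclass
class BoutLog:
    """Timestamped behavior bouts of one rat in one session."""

    rat_id: str
    session: str
    bouts: list  # of (behavior, t_start, t_stop)
    partner_id: str | None = None
    overlaps_flagged: int = 0

    def __post_init__(self):
        for i, (b, t0, t1) in enumerate(self.bouts):
            if t1 < t0:
                raise DataError(f"bout {i + 1} ({b!r}): t_stop < t_start")

    def validate_against(self, definition: EthogramDefinition) -> None:
        known = set(definition.behaviors)
        for i, (b, _, _) in enumerate(self.bouts):
            if b not in known:
                raise DataError(f"bout {i + 1}: unknown behavior {b!r}")
        if definition.session_duration is not None:
            for i, (b, t0, t1) in enumerate(self.bouts):
                if t1 > definition.session_duration + 1e-9 or t0 < 0:
                    raise DataError(
                        f"bout {i + 1} ({b!r}) outside the "
                        f"{definition.session_duration:.0f}-s session")

    def flag_overlaps(self) -> int:
        """Count overlapping bout pairs (two behaviors may co-occur)."""
        iv = sorted((t0, t1) for _, t0, t1 in self.bouts)
        n = 0
        for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
            if b0 < a1:
                n += 1
        self.overlaps_flagged = n
        return n


def read_bout_log(path, definition: EthogramDefinition | None = None) -> list[BoutLog]:
    """Read a bout-log CSV (rat_id, session, behavior, t_start_s, t_stop_s)
    into one BoutLog per (rat_id, session); overlaps are permitted but
    flagged with a warning."""
    try:
        df = pd.read_csv(path, dtype={"rat_id": str, "session": str,
                                      "behavior": str})
    except pd.errors.EmptyDataError as exc:
        raise DegenerateInputError(f"empty bout log: {path}") from exc
    missing = [c for c in BOUT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"bout log missing columns {missing}")
    if df.empty:
        raise DegenerateInputError(f"bout log has no rows: {path}")
    bad = df.index[df.t_stop_s < df.t_start_s]
    if len(bad):
        raise DataError(f"bout log row {bad[0] + 2}: t_stop < t_start")
    if definition is not None:
        known = set(definition.behaviors)
        unknown = df.index[~df.behavior.isin(known)]
        if len(unknown):
            raise DataError(f"bout log row {unknown[0] + 2}: unknown "
                            f"behavior {df.behavior[unknown[0]]!r}")
    logs = []
    for (rid, session), sub in df.groupby(["rat_id", "session"], sort=True):
        log = BoutLog(rat_id=str(rid), session=str(session),
                      bouts=[(r.behavior, float(r.t_start_s), float(r.t_stop_s))
                             for r in sub.itertuples()])
        if log.flag_overlaps():
            warnings.warn(f"rat {rid!r} session {session!r}: "
                          f"{log.overlaps_flagged} overlapping bout pair(s)")
        logs.append(log)
    return logs


def write_bout_log(logs: Sequence[BoutLog], path) -> None:
    rows = [(lg.rat_id, lg.session, b, t0, t1)
            for lg in logs for (b, t0, t1) in lg.bouts]
    pd.DataFrame(rows, columns=BOUT_LOG_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scoring

def relative_behavior_measures(log: BoutLog,
                               definition: EthogramDefinition) -> pd.DataFrame:
    """Per-behavior relative frequency and duration.

    Fractions of the total categorized behavior of this rat; standalone
    behaviors are excluded from both denominators and reported raw.
    """
    log.validate_against(definition)
    cat_of = definition.behavior_to_category
    counts: dict[str, float] = {b: 0.0 for b in definition.behaviors}
    durs: dict[str, float] = {b: 0.0 for b in definition.behaviors}
    for b, t0, t1 in log.bouts:
        counts[b] += 1
        durs[b] += t1 - t0
    total_n = sum(counts[b] for b in cat_of)
    total_d = sum(durs[b] for b in cat_of)
    if total_n == 0:
        raise DegenerateInputError(
            f"rat {log.rat_id!r}: no categorized bouts to normalize against")
    rows = []
    for b in definition.behaviors:
        standalone = b not in cat_of
        rows.append({
            "behavior": b,
            "category": cat_of.get(b, "standalone"),
            "freq": counts[b],
            "dur": durs[b],
            "rel_freq": float("nan") if standalone else counts[b] / total_n,
            "rel_dur": float("nan") if standalone or total_d == 0
            else durs[b] / total_d,
        })
    return pd.DataFrame(rows).set_index("behavior")


def category_scores(log: BoutLog, definition: EthogramDefinition) -> dict:
    """Functional-category scores: sums of member behaviors' relative
    measures, plus raw frequency/duration for standalone behaviors.

    Returns ``{"rel_freq": {...}, "rel_dur": {...}, "standalone": {...}}``.
    """
    rel = relative_behavior_measures(log, definition)
    freq_scores, dur_scores = {}, {}
    for cat, members in definition.categories.items():
        sub = rel.loc[list(members)]
        freq_scores[cat] = float(sub.rel_freq.sum())
        dur_scores[cat] = float(sub.rel_dur.sum()) \
            if sub.rel_dur.notna().any() else float("nan")
    standalone = {b: {"freq": float(rel.loc[b, "freq"]),
                      "dur": float(rel.loc[b, "dur"])}
                  for b in definition.standalone}
    return {"rel_freq": freq_scores, "rel_dur": dur_scores,
            "standalone": standalone}


def score_cohort(logs: Sequence[BoutLog],
                 definition: EthogramDefinition,
                 groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Category scores for many rats as a tidy table (one row per rat)."""
    rows = []
    for log in logs:
        sc = category_scores(log, definition)
        row = {"rat_id": log.rat_id, "session": log.session}
        if groups:
            row["group"] = groups.get(log.rat_id, "")
        for cat, v in sc["rel_freq"].items():
            row[f"relfreq_{cat}"] = v
        for cat, v in sc["rel_dur"].items():
            row[f"reldur_{cat}"] = v
        for b, v in sc["standalone"].items():
            row[f"{b}_freq"] = v["freq"]
            row[f"{b}_dur"] = v["dur"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("rat_id")
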