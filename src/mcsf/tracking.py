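"""Tracking-log ingestion, zone-visit extraction and path metrics.

A track is the per-frame (t, x, y) record of one tracked body point of one
rat in one session.  Visits are maximal runs of constant zone assignment of
that point; every downstream frequency (FRQ), duration (DUR) and latency
(LAT) measure derives from them.

Timing convention: sample i covers the half-open interval [t_i, t_{i+1});
the final sample carries no duration.  With that convention the sum of
visit durations, unassigned time and missing-frame time equals the total
tracked time exactly.

Distance convention: the step from sample i to i+1 is credited to the zone
of sample i, including steps that cross a zone boundary.  Steps that start
at an unassigned sample, or that span a missing-coordinate gap, belong to
no visit.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig, UNASSIGNED
from .errors import DataError, UsageError

VISIT_LOG_COLUMNS = ["rat_id", "group", "trial", "zone_id",
                     "t_enter", "t_exit", "distance"]


@dataclass
class Track:
    """Per-frame positional record of one rat-trial.

    Missing detections are kept in place with NaN coordinates so that the
    time base stays intact.
    """

    rat_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    group: str = ""
    trial: str = ""
    frame_rate: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise DataError("t, x, y must have equal length")
        if len(self.t) == 0:
            raise DataError("empty track")
        if self.t[0] < 0:
            raise DataError("first timestamp is negative")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise DataError(f"non-monotonic timestamps at row {bad[0] + 2}")
        if self.frame_rate is None and len(self.t) > 1:
            self.frame_rate = 1.0 / float(np.median(np.diff(self.t)))

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def missing(self) -> np.ndarray:
        return ~(np.isfinite(self.x) & np.isfinite(self.y))

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class Visit:
    """One zone-entry/exit interval of one rat."""

    rat_id: str
    zone_id: str
    t_enter: float
    t_exit: float
    distance: float = 0.0

    def __post_init__(self):
        if not self.t_exit > self.t_enter:
            raise DataError(f"visit to {self.zone_id!r} has t_exit <= t_enter")
        if self.distance < 0:
            raise DataError("negative visit distance")

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


# ---------------------------------------------------------------------------
# reading tracks

def read_track(path, dialect: str = "simple_csv", rat_id: str = "",
               group: str = "", trial: str = "") -> Track:
    """Read a plain-text tracking log.

    ``simple_csv`` expects columns time_s, x_cm, y_cm (header optional,
    extra columns ignored).  ``ethovision_like`` additionally tolerates a
    header preamble (non-numeric lines) and locale decimal commas; '-' is
    treated as a missing coordinate.
    """
    if dialect not in ("simple_csv", "ethovision_like"):
        raise UsageError(f"unknown dialect {dialect!r}")
    raw = Path(path).read_text()
    if not raw.strip():
        raise DataError(f"empty tracking file: {path}")
    lines = raw.splitlines()

    def _is_datarow(line: str, decimal: str) -> bool:
        first = line.split(";")[0].split(",")[0].split("\t")[0].strip()
        if decimal == ",":
            first = first.replace(",", ".")
        try:
            float(first)
            return True
        except ValueError:
            return False

    decimal = "."
    if dialect == "ethovision_like":
        body = [ln for ln in lines if ln.strip()]
        sample = next((ln for ln in body if _is_datarow(ln, ",")), "")
        sep = ";" if ";" in sample else ("\t" if "\t" in sample else ",")
        # decimal commas only make sense with a non-comma separator
        if sep != "," and "," in sample:
            decimal = ","
        start = 0
        for i, ln in enumerate(lines):
            if ln.strip() and _is_datarow(ln, decimal):
                start = i
                break
        text = "\n".join(lines[start:])
        df = pd.read_csv(io.StringIO(text), sep=sep, header=None,
                         decimal=decimal, na_values=["-", "NA", ""])
    else:
        has_header = not _is_datarow(lines[0], ".")
        df = pd.read_csv(io.StringIO(raw), header=0 if has_header else None)
        if has_header:
            cols = {c.strip().lower(): c for c in df.columns}
            want = ["time_s", "x_cm", "y_cm"]
            if all(w in cols for w in want):
                df = df[[cols[w] for w in want]]
    if df.shape[1] < 3:
        raise DataError(f"tracking file {path} has fewer than 3 columns")
    df = df.iloc[:, :3].apply(pd.to_numeric, errors="coerce")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if np.isnan(t).any():
        row = int(np.flatnonzero(np.isnan(t))[0]) + 1
        raise DataError(f"unparseable timestamp at data row {row}")
    return Track(rat_id=rat_id, group=group, trial=trial,
                 t=t, x=df.iloc[:, 1].to_numpy(float),
                 y=df.iloc[:, 2].to_numpy(float))


# ---------------------------------------------------------------------------
# visit extraction

def _runs(codes: np.ndarray):
    """Maximal runs of equal values: yields (start_idx, end_idx_exclusive, value)."""
    n = len(codes)
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [(int(s), int(e), int(codes[s])) for s, e in zip(starts, ends)]


def default_gap_tolerance(track: Track) -> float:
    """Missing-detection gaps up to this long do not break a visit."""
    if track.frame_rate and track.frame_rate > 0:
        return min(2.0, 5.0 / track.frame_rate)
    return 2.0


def extract_visits(track: Track, arena: ArenaConfig,
                   min_visit_duration: float = 0.0,
                   gap_tolerance: float | None = None) -> list[Visit]:
    """Partition a track into maximal constant-zone visits.

    Runs shorter than ``min_visit_duration`` are absorbed into the visit of
    the previous zone; unassigned runs never form visits; missing-frame
    gaps longer than ``gap_tolerance`` (default min(2 s, 5 frame
    intervals)) break the surrounding visit.
    """
    if min_visit_duration < 0:
        raise UsageError("min_visit_duration must be >= 0")
    if gap_tolerance is None:
        gap_tolerance = default_gap_tolerance(track)

    codes = arena.locate_array(track.x, track.y)  # -1 for unassigned
    missing = track.missing
    MISSING, UNASS = -2, -1
    codes = codes.copy()
    codes[missing] = MISSING
    if not (codes >= 0).any():
        raise DataError("track has zero zone-located samples")

    t = track.t
    n = len(t)
    # interval end of sample i is t[i+1]; the last sample carries no time
    nxt = np.concatenate((t[1:], [t[-1]]))

    runs = _runs(codes)  # (start, end_exclusive, code)

    # resolve short missing gaps: a missing run shorter than gap_tolerance
    # flanked by the same zone is relabeled to that zone
    changed = True
    while changed:
        changed = False
        for k, (s, e, c) in enumerate(runs):
            if c != MISSING:
                continue
            dur = nxt[e - 1] - t[s]
            if dur <= gap_tolerance and 0 < k < len(runs) - 1:
                prev_c, next_c = runs[k - 1][2], runs[k + 1][2]
                if prev_c == next_c and prev_c >= 0:
                    runs[k] = (s, e, prev_c)
                    changed = True
        runs = _merge_equal(runs)

    # absorb short runs into the previous zone's visit
    if min_visit_duration > 0:
        changed = True
        while changed:
            changed = False
            for k, (s, e, c) in enumerate(runs):
                if c == MISSING:
                    continue
                dur = nxt[e - 1] - t[s]
                if dur < min_visit_duration and k > 0 and runs[k - 1][2] >= 0 \
                        and runs[k - 1][2] != c:
                    runs[k] = (s, e, runs[k - 1][2])
                    changed = True
                    break
            runs = _merge_equal(runs)

    # distances: step i -> i+1 credited to sample i's zone; steps spanning
    # missing samples contribute nothing
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    step = np.hypot(dx, dy)
    step[~np.isfinite(step)] = 0.0

    visits: list[Visit] = []
    for s, e, c in runs:
        if c < 0:
            continue
        t_enter = float(t[s])
        t_exit = float(nxt[e - 1])
        if not t_exit > t_enter:
            continue  # zero-duration trailing run (single final sample)
        # steps starting at samples s..e-1 (step e-1 crosses into next run)
        hi = min(e, n - 1)
        dist = float(step[s:hi].sum())
        visits.append(Visit(rat_id=track.rat_id, zone_id=arena.zone_ids[c],
                            t_enter=t_enter, t_exit=t_exit, distance=dist))
    return visits


def _merge_equal(runs):
    out = []
    for r in runs:
        if out and out[-1][2] == r[2] and out[-1][1] == r[0]:
            out[-1] = (out[-1][0], r[1], r[2])
        else:
            out.append(list(r))
    return [tuple(r) for r in out]


def time_budget(track: Track, arena: ArenaConfig) -> dict:
    """Decompose total tracked time into zone / unassigned / missing time.

    Uses the raw per-frame assignment (no smoothing), so
    zone_time + unassigned_time + missing_time == track.duration() exactly.
    """
    codes = arena.locate_array(track.x, track.y)
    missing = track.missing
    dt = np.diff(track.t)
    zone_t = float(dt[(codes[:-1] >= 0) & ~missing[:-1]].sum())
    miss_t = float(dt[missing[:-1]].sum())
    unass_t = float(dt[(codes[:-1] < 0) & ~missing[:-1]].sum())
    return {"zone_time": zone_t, "unassigned_time": unass_t,
            "missing_time": miss_t, "total_time": track.duration()}


# ---------------------------------------------------------------------------
# binning

def bin_track(track: Track, bin_width: float,
              session_duration: float | None = None) -> list[Track]:
    """Split a track into contiguous segments of ``bin_width`` seconds.

    Segments cover [0, session_duration); a sample lying exactly on a bin
    boundary goes to the later bin.  Empty segments are returned as None.
    """
    if bin_width <= 0:
        raise UsageError("bin_width must be > 0")
    if session_duration is None:
        session_duration = float(track.t[-1])
    n_bins = max(1, math.ceil(session_duration / bin_width - 1e-9))
    out = []
    for k in range(n_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        mask = (track.t >= lo) & (track.t < hi)
        if k == n_bins - 1:
            mask |= track.t == session_duration  # closing sample
        if not mask.any():
            out.append(None)
            continue
        out.append(Track(rat_id=track.rat_id, group=track.group,
                         trial=track.trial, t=track.t[mask],
                         x=track.x[mask], y=track.y[mask],
                         frame_rate=track.frame_rate))
    return out


# ---------------------------------------------------------------------------
# visit logs (the alternative direct input)

def visits_to_frame(visits: Sequence[Visit], group: str = "",
                    trial: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [(v.rat_id, group, trial, v.zone_id, v.t_enter, v.t_exit, v.distance)
         for v in visits], columns=VISIT_LOG_COLUMNS)


def write_visit_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_visit_log(path) -> pd.DataFrame:
    """Read a canonical visit log (rat_id, group, trial, zone_id, t_enter,
    t_exit, distance) and validate its invariants."""
    df = pd.read_csv(path, dtype={"rat_id": str, "group": str, "trial": str})
    missing_cols = [c for c in VISIT_LOG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"visit log missing columns {missing_cols}")
    bad = df.index[df.t_exit <= df.t_enter]
    if len(bad):
        raise DataError(f"visit log row {bad[0] + 2}: t_exit <= t_enter")
    if (df.distance < 0).any():
        raise DataError("visit log contains negative distances")
    for (rid, trial), sub in df.groupby(["rat_id", "trial"], sort=False):
        sub = sub.sort_values("t_enter")
        if (sub.t_enter.to_numpy()[1:] < sub.t_exit.to_numpy()[:-1] - 1e-9).any():
            raise DataError(f"overlapping visits for rat {rid!r} trial {trial!r}")
    return df
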