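"""Zone descriptors, aggregates, relative measures, indexes and the
rat x parameter table.

Per zone and rat-trial the descriptive measures are: latency to first
visit (LAT, s), number of visits (FRQ), total duration (DUR, s), mean
duration per visit (DUR/FRQ, s), distance moved (cm) and mean velocity
(cm/s, distance/duration).  Aggregates combine the three corridors
(tot_corr) and the whole arena (arena); TOTAL_ACT is the number of visits
to all zones.  Relative measures express FRQ and DUR as percentages.

Four summary indexes condense shelter vs. risk use:

* shelter/corridor index  = (FRQ dcr - FRQ corr_a) / (FRQ dcr + FRQ corr_a)
* slope/bridge interval   = (LAT slope - LAT bridge) / LAT slope
* risk/shelter duration   = (DUR bridge - DUR dcr) / (DUR bridge + DUR dcr)
* risk/shelter frequency  = (FRQ bridge - FRQ dcr) / (FRQ bridge + FRQ dcr)

A zero denominator or a missing input leaves the index missing (NaN).

Column naming: LAT_<zone>, FRQ_<zone>, DUR_<zone>, DURFRQ_<zone>,
DIST_<zone>, VEL_<zone>, PCT_FRQ_<zone>, PCT_DUR_<zone>, TOTAL_ACT, the
sidecar counts (rearings, saps, grooming, nose_pokes, urine_spots,
fecal_boli) and the four index columns.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig
from .errors import DataError, UsageError
from .tracking import Visit

INDEX_COLUMNS = ["shelter_corridor_index", "slope_bridge_interval",
                 "risk_shelter_dur_index", "risk_shelter_frq_index"]
SIDECAR_COUNTS = ["rearings", "saps", "grooming", "nose_pokes",
                  "urine_spots", "fecal_boli"]
_MEASURES = ("LAT", "FRQ", "DUR", "DURFRQ", "DIST", "VEL")


def _zone_keys(arena: ArenaConfig) -> list[str]:
    return list(arena.zone_ids) + list(arena.aggregates)


def parameter_columns(arena: ArenaConfig) -> list[str]:
    cols = []
    for m in _MEASURES:
        cols += [f"{m}_{z}" for z in _zone_keys(arena)]
    cols.append("TOTAL_ACT")
    cols += [f"PCT_FRQ_{z}" for z in arena.zone_ids]
    cols += [f"PCT_DUR_{z}" for z in arena.zone_ids]
    cols += SIDECAR_COUNTS + INDEX_COLUMNS
    return cols


# ---------------------------------------------------------------------------
# per rat-trial descriptor computation

def compute_zone_descriptors(visits: Sequence[Visit], arena: ArenaConfig,
                             session_duration: float | None = None) -> dict:
    """Raw per-zone descriptors for the visits of ONE rat-trial.

    Unvisited zones get LAT NaN, FRQ 0, DUR 0, DIST 0, VEL and DUR/FRQ NaN
    (the missing-value policy is applied later by ``apply_missing_rules``).
    """
    rats = {v.rat_id for v in visits}
    if len(rats) > 1:
        raise UsageError(f"visits from multiple rats: {sorted(rats)}")
    if session_duration is None:
        session_duration = arena.session_duration
    out: dict[str, float] = {}
    for z in arena.zone_ids:
        zv = [v for v in visits if v.zone_id == z]
        frq = len(zv)
        dur = sum(v.duration for v in zv)
        dist = sum(v.distance for v in zv)
        out[f"LAT_{z}"] = min(v.t_enter for v in zv) if zv else math.nan
        out[f"FRQ_{z}"] = float(frq)
        out[f"DUR_{z}"] = float(dur)
        out[f"DURFRQ_{z}"] = dur / frq if frq else math.nan
        out[f"DIST_{z}"] = float(dist)
        out[f"VEL_{z}"] = dist / dur if dur > 0 else math.nan
    return out


def compute_aggregates(desc: Mapping[str, float], arena: ArenaConfig) -> dict:
    """Augment raw descriptors with aggregate zones and TOTAL_ACT.

    Aggregate LAT is the minimum member LAT; FRQ/DUR/DIST sum; DUR/FRQ is
    summed DUR over summed FRQ; VEL is summed distance over summed DUR.
    """
    out = dict(desc)
    for name, members in arena.aggregates.items():
        lats = [desc[f"LAT_{z}"] for z in members
                if not math.isnan(desc[f"LAT_{z}"])]
        frq = sum(desc[f"FRQ_{z}"] for z in members)
        dur = sum(desc[f"DUR_{z}"] for z in members)
        dist = sum(desc[f"DIST_{z}"] for z in members)
        out[f"LAT_{name}"] = min(lats) if lats else math.nan
        out[f"FRQ_{name}"] = frq
        out[f"DUR_{name}"] = dur
        out[f"DIST_{name}"] = dist
        out[f"DURFRQ_{name}"] = dur / frq if frq else math.nan
        out[f"VEL_{name}"] = dist / dur if dur > 0 else math.nan
    out["TOTAL_ACT"] = sum(desc[f"FRQ_{z}"] for z in arena.zone_ids)
    return out


def compute_relative_measures(desc: Mapping[str, float], arena: ArenaConfig,
                              denominator_mode: str = "total_visits_time",
                              session_duration: float | None = None) -> dict:
    """Add PCT_FRQ_<zone> and PCT_DUR_<zone>.

    %FRQ is always frequency as percent of TOTAL_ACT.  %DUR divides by the
    total time in all zones (``total_visits_time``) or by the session
    duration (``trial_time``).
    """
    if denominator_mode not in ("total_visits_time", "trial_time"):
        raise UsageError(f"unknown denominator_mode {denominator_mode!r}")
    if session_duration is None:
        session_duration = arena.session_duration
    out = dict(desc)
    total_act = desc.get("TOTAL_ACT", math.nan)
    total_time = sum(desc[f"DUR_{z}"] for z in arena.zone_ids)
    dur_denom = total_time if denominator_mode == "total_visits_time" \
        else session_duration
    for z in arena.zone_ids:
        if total_act and total_act > 0:
            out[f"PCT_FRQ_{z}"] = 100.0 * desc[f"FRQ_{z}"] / total_act
        else:
            out[f"PCT_FRQ_{z}"] = math.nan
        if dur_denom and dur_denom > 0 and total_act and total_act > 0:
            out[f"PCT_DUR_{z}"] = 100.0 * desc[f"DUR_{z}"] / dur_denom
        else:
            out[f"PCT_DUR_{z}"] = math.nan
    return out


def compute_indexes(desc: Mapping[str, float]) -> dict:
    """The four summary indexes; zero denominators / missing inputs -> NaN."""

    def ratio(num, den):
        if any(map(_isnan, (num, den))) or den == 0:
            return math.nan
        return num / den

    frq_dcr = desc.get("FRQ_dcr", math.nan)
    frq_ca = desc.get("FRQ_corr_a", math.nan)
    lat_sl = desc.get("LAT_slope", math.nan)
    lat_br = desc.get("LAT_bridge", math.nan)
    dur_br = desc.get("DUR_bridge", math.nan)
    dur_dcr = desc.get("DUR_dcr", math.nan)
    frq_br = desc.get("FRQ_bridge", math.nan)
    return {
        "shelter_corridor_index": ratio(frq_dcr - frq_ca, frq_dcr + frq_ca),
        "slope_bridge_interval": ratio(lat_sl - lat_br, lat_sl),
        "risk_shelter_dur_index": ratio(dur_br - dur_dcr, dur_br + dur_dcr),
        "risk_shelter_frq_index": ratio(frq_br - frq_dcr, frq_br + frq_dcr),
    }


def _isnan(v) -> bool:
    try:
        return math.isnan(v)
    except TypeError:
        return v is None


# ---------------------------------------------------------------------------
# the parameter table

def descriptor_row(visits: Sequence[Visit], arena: ArenaConfig,
                   session_duration: float | None = None,
                   denominator_mode: str = "total_visits_time",
                   counts: Mapping[str, float] | None = None) -> dict:
    """Full raw parameter row (descriptors + aggregates + relative measures
    + indexes + sidecar counts) for one rat-trial."""
    d = compute_zone_descriptors(visits, arena, session_duration)
    d = compute_aggregates(d, arena)
    d = compute_relative_measures(d, arena, denominator_mode, session_duration)
    d.update(compute_indexes(d))
    for c in SIDECAR_COUNTS:
        d[c] = float(counts[c]) if counts and c in counts else math.nan
    return d


def build_parameter_table(visit_log: pd.DataFrame, arena: ArenaConfig,
                          session_duration: float | None = None,
                          denominator_mode: str = "total_visits_time",
                          sidecar: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the rats x parameters matrix from a canonical visit log.

    Returns a DataFrame indexed by (rat_id, group, trial).  ``sidecar``
    optionally supplies the manually scored counts, keyed by rat_id and
    trial.
    """
    if session_duration is None:
        session_duration = arena.session_duration
    side_lookup: dict = {}
    if sidecar is not None:
        for _, r in sidecar.iterrows():
            side_lookup[(str(r["rat_id"]), str(r["trial"]))] = \
                {c: r[c] for c in SIDECAR_COUNTS if c in sidecar.columns}
    rows, index = [], []
    for (rid, group, trial), sub in visit_log.groupby(
            ["rat_id", "group", "trial"], sort=True):
        visits = [Visit(rat_id=str(rid), zone_id=r.zone_id,
                        t_enter=r.t_enter, t_exit=r.t_exit,
                        distance=r.distance)
                  for r in sub.itertuples()]
        rows.append(descriptor_row(visits, arena, session_duration,
                                   denominator_mode,
                                   side_lookup.get((str(rid), str(trial)))))
        index.append((str(rid), str(group), str(trial)))
    if not rows:
        raise DataError("visit log produced no parameter rows")
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["rat_id", "group", "trial"]))
    order = [c for c in parameter_columns(arena) if c in table.columns]
    return table[order]


def compute_occurrence(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per group: number of rats with parameter > 0, and group size.

    Suitable for FRQ columns and behavior counts; returns a 2x2-ready
    table with columns ``positive`` and ``n``.
    """
    if parameter not in table.columns:
        raise UsageError(f"unknown parameter {parameter!r}")
    groups = table.index.get_level_values("group")
    out = []
    for g in sorted(set(groups)):
        vals = table.loc[groups == g, parameter]
        out.append({"group": g,
                    "positive": int((vals.fillna(0) > 0).sum()),
                    "n": int(len(vals))})
    return pd.DataFrame(out).set_index("group")


def apply_missing_rules(table: pd.DataFrame, mode: str,
                        session_duration: float, arena: ArenaConfig) -> pd.DataFrame:
    """Apply the unvisited-zone missing-value policy.

    ``within_trial``: all measures of an unvisited zone (LAT, DUR, FRQ,
    DIST, VEL, DUR/FRQ, percent measures) become missing.
    ``between_trial``: DUR and FRQ stay 0, LAT is imputed at the session
    duration; DUR/FRQ and VEL remain missing.  Index columns are left as
    computed (absent values stay missing).  Idempotent in both modes.
    """
    if mode not in ("within_trial", "between_trial"):
        raise UsageError(f"unknown missing mode {mode!r}")
    out = table.copy()
    for z in arena.zone_ids:
        unvisited = out[f"FRQ_{z}"].fillna(0) == 0
        # an imputed between-trial row has FRQ 0 and LAT == session_duration;
        # re-deriving "unvisited" from FRQ==0 keeps the rules idempotent
        if mode == "within_trial":
            for m in _MEASURES:
                out.loc[unvisited, f"{m}_{z}"] = np.nan
            for m in ("PCT_FRQ", "PCT_DUR"):
                col = f"{m}_{z}"
                if col in out.columns:
                    out.loc[unvisited, col] = np.nan
        else:
            out.loc[unvisited, f"FRQ_{z}"] = 0.0
            out.loc[unvisited, f"DUR_{z}"] = 0.0
            out.loc[unvisited, f"DIST_{z}"] = 0.0
            out.loc[unvisited, f"LAT_{z}"] = float(session_duration)
            out.loc[unvisited, f"DURFRQ_{z}"] = np.nan
            out.loc[unvisited, f"VEL_{z}"] = np.nan
    return out


def write_parameter_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path)


def read_parameter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"rat_id": str, "group": str, "trial": str})
    for col in ("rat_id", "group", "trial"):
        if col not in df.columns:
            raise DataError(f"parameter table missing column {col!r}")
    return df.set_index(["rat_id", "group", "trial"])
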