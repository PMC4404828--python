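"""Synthetic behavior cohorts with known group structure.

Arena sessions are simulated as a semi-Markov walk on the zone adjacency
graph: per-zone dwell times are exponential (floored at two frame
intervals when frame-level tracks are emitted, so every visit contains at
least one sample), the next zone is drawn from normalized transition
weights over adjacent zones, and a within-trial habituation factor scales
all rates per 10-min bin.  The within-zone path is a persistent random
walk clipped to the zone polygon at the profile's nominal speed.

Manually scored point behaviors (rearings, SAPs, grooming, nose pokes)
are Poisson counts per 10-min bin with the same habituation decay; bout
logs for the novel cage and home cage change tests come from an
alternating-renewal process (behavior chosen with probability
proportional to its rate, bout length exponential at its mean), so the
expected relative frequency of a behavior equals its normalized rate.

The two group profiles are identical by default; group differences are
injected only through named effect multipliers applied to the second
group, which makes null-calibration and parameter-recovery experiments
direct to set up.  Every output is a pure function of (config, master
seed).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig, load_arena_config
from .descriptors import SIDECAR_COUNTS, descriptor_row, apply_missing_rules
from .errors import ConfigError, UsageError
from .ethogram import BoutLog, EthogramDefinition, load_ethogram
from .tracking import Track, Visit, visits_to_frame

BIN_WIDTH = 600.0  # s; the 10-min analysis bin

POINT_BEHAVIORS = ("rearings", "saps", "grooming", "nose_pokes")
SESSION_COUNTS = ("urine_spots", "fecal_boli")


# ---------------------------------------------------------------------------
# profiles and config

@dataclass
class GroupProfile:
    """Behavioral profile of one experimental group.

    Rates are per minute, dwell means and bout means in seconds, speeds in
    cm/s; ``habituation`` is the multiplicative activity decay per 10-min
    bin (dwell means are divided by it, event rates multiplied).
    """

    dwell_mean: dict
    transition: dict            # zone -> {neighbor: weight}
    speed: dict                 # zone -> cm/s
    point_rates: dict           # behavior -> events/min
    session_count_means: dict   # behavior -> mean count/session
    novel_cage_rates: dict      # behavior -> bouts/min
    novel_cage_bout_means: dict  # behavior -> s (0 => point event)
    home_cage_rates: dict
    home_cage_bout_means: dict
    habituation: float = 0.85
    inter_bout_gap_mean: float = 2.0
    complementary_prob: float = 0.5
    start_zone: str = "center"

    def validate(self, arena: ArenaConfig) -> None:
        problems = []
        for z in arena.zone_ids:
            if self.dwell_mean.get(z, 0) <= 0:
                problems.append(f"dwell_mean missing/non-positive for {z!r}")
            if self.speed.get(z, 0) <= 0:
                problems.append(f"speed missing/non-positive for {z!r}")
        for z, weights in self.transition.items():
            nb = set(arena.neighbors(z))
            for tgt, w in weights.items():
                if tgt not in nb:
                    problems.append(
                        f"transition {z!r}->{tgt!r} is not arena-adjacent")
                if w < 0:
                    problems.append(f"negative transition weight {z!r}->{tgt!r}")
            if weights and sum(weights.values()) <= 0:
                problems.append(f"all-zero transition weights from {z!r}")
        if self.habituation <= 0:
            problems.append("habituation factor must be > 0")
        for name, rates in (("point_rates", self.point_rates),
                            ("novel_cage_rates", self.novel_cage_rates),
                            ("home_cage_rates", self.home_cage_rates)):
            if any(r < 0 for r in rates.values()):
                problems.append(f"negative rate in {name}")
        if problems:
            raise ConfigError("invalid group profile:\n  - "
                              + "\n  - ".join(problems))

    @classmethod
    def default(cls, arena: ArenaConfig | None = None) -> "GroupProfile":
        if arena is None:
            arena = load_arena_config()
        dwell = {"center": 15.0, "ctrci": 5.0, "corr_a": 20.0, "corr_b": 20.0,
                 "corr_c": 20.0, "dcr": 40.0, "hurdle": 15.0, "slope": 8.0,
                 "be": 6.0, "bridge": 10.0}
        speed = {"center": 10.0, "ctrci": 8.0, "corr_a": 12.0, "corr_b": 12.0,
                 "corr_c": 12.0, "dcr": 4.0, "hurdle": 8.0, "slope": 8.0,
                 "be": 8.0, "bridge": 6.0}
        transition = {z: {n: 1.0 for n in arena.neighbors(z)}
                      for z in arena.zone_ids}
        return cls(
            dwell_mean=dwell, transition=transition, speed=speed,
            point_rates={"rearings": 2.0, "saps": 1.0, "grooming": 0.5,
                         "nose_pokes": 1.5},
            session_count_means={"urine_spots": 1.0, "fecal_boli": 2.0},
            novel_cage_rates={"stretched_approach": 0.5, "sap": 0.8,
                              "grooming": 0.6, "freezing": 0.4,
                              "motionless": 0.6, "free_rearing": 1.2,
                              "investigating": 2.5, "wall_rearing": 1.0,
                              "walking": 2.0},
            novel_cage_bout_means={"stretched_approach": 3.0, "sap": 3.0,
                                   "grooming": 8.0, "freezing": 6.0,
                                   "motionless": 15.0, "free_rearing": 4.0,
                                   "investigating": 10.0, "wall_rearing": 4.0,
                                   "walking": 5.0},
            home_cage_rates={"head_head": 0.6, "nose_side": 0.8,
                             "nose_nose": 0.6, "passing": 0.8,
                             "head_tail": 0.4, "nose_genitals": 0.3,
                             "following": 0.4, "approaching": 0.6,
                             "nuzzling": 0.5, "mount1": 0.2, "mount2": 0.1,
                             "chasing": 0.15, "fight": 0.15, "avoiding": 0.4,
                             "crawling_under": 0.15,
                             "submissive_posture": 0.2, "burrowing": 0.5},
            home_cage_bout_means={"head_head": 3.0, "nose_side": 4.0,
                                  "nose_nose": 3.0, "passing": 0.0,
                                  "head_tail": 3.0, "nose_genitals": 3.0,
                                  "following": 5.0, "approaching": 4.0,
                                  "nuzzling": 6.0, "mount1": 4.0,
                                  "mount2": 4.0, "chasing": 4.0, "fight": 5.0,
                                  "avoiding": 3.0, "crawling_under": 4.0,
                                  "submissive_posture": 5.0, "burrowing": 8.0},
        )


def apply_effects(profile: GroupProfile,
                  effects: Mapping[str, float]) -> GroupProfile:
    """Return a copy of ``profile`` with named multipliers applied.

    Effect keys: ``rate:<behavior>`` (point or bout behavior),
    ``dwell:<zone>``, ``speed:<zone>``, ``transition:<zone>`` (scales all
    inbound weights), ``habituation``.
    """
    p = copy.deepcopy(profile)
    for key, factor in effects.items():
        if key == "habituation":
            p.habituation *= factor
            continue
        if ":" not in key:
            raise ConfigError(f"malformed effect key {key!r}")
        kind, target = key.split(":", 1)
        if kind == "rate":
            hit = False
            for rates in (p.point_rates, p.novel_cage_rates, p.home_cage_rates):
                if target in rates:
                    rates[target] *= factor
                    hit = True
            if target in p.session_count_means:
                p.session_count_means[target] *= factor
                hit = True
            if not hit:
                raise ConfigError(f"effect {key!r}: unknown behavior")
        elif kind == "dwell":
            if target not in p.dwell_mean:
                raise ConfigError(f"effect {key!r}: unknown zone")
            p.dwell_mean[target] *= factor
        elif kind == "speed":
            if target not in p.speed:
                raise ConfigError(f"effect {key!r}: unknown zone")
            p.speed[target] *= factor
        elif kind == "transition":
            hit = False
            for weights in p.transition.values():
                if target in weights:
                    weights[target] *= factor
                    hit = True
            if not hit:
                raise ConfigError(f"effect {key!r}: unknown zone")
        else:
            raise ConfigError(f"effect {key!r}: unknown kind {kind!r}")
    return p


def affected_parameters(effects: Mapping[str, float]) -> list[str]:
    """Parameter-table columns directly targeted by the named effects."""
    out = []
    for key in effects:
        if key == "habituation":
            continue
        kind, target = key.split(":", 1)
        if kind == "rate":
            out.append(target)
        elif kind == "dwell":
            out += [f"DUR_{target}", f"DURFRQ_{target}"]
        elif kind == "speed":
            out += [f"VEL_{target}", f"DIST_{target}"]
        elif kind == "transition":
            out.append(f"FRQ_{target}")
    return out


@dataclass
class SimulationConfig:
    """Cohort contract: group profiles, sizes, sessions and master seed."""

    group_profiles: dict = None          # group name -> GroupProfile
    n_per_group: int = 12
    trials: tuple = ("1", "2")
    mcsf_duration: float = 1800.0
    novel_cage_duration: float = 300.0
    home_cage_duration: float = 600.0
    frame_rate: float = 5.0
    master_seed: int = 0
    effect_multipliers: dict = field(default_factory=dict)
    emit_tracks: bool = False
    simulate_ethogram_tests: bool = True

    def __post_init__(self):
        if self.group_profiles is None:
            base = GroupProfile.default()
            self.group_profiles = {"g1": base, "g2": copy.deepcopy(base)}
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if len(self.group_profiles) != 2:
            raise ConfigError("exactly two group profiles are required")

    def resolved_profiles(self) -> dict:
        """Profiles with effect multipliers applied to the second group."""
        names = list(self.group_profiles)
        out = {names[0]: self.group_profiles[names[0]]}
        out[names[1]] = apply_effects(self.group_profiles[names[1]],
                                      self.effect_multipliers) \
            if self.effect_multipliers else self.group_profiles[names[1]]
        return out


# ---------------------------------------------------------------------------
# MCSF session simulation

def _habituation_factor(profile: GroupProfile, t: float) -> float:
    return profile.habituation ** int(t // BIN_WIDTH)


def simulate_mcsf_visits(profile: GroupProfile, arena: ArenaConfig,
                         duration: float, rng: np.random.Generator,
                         rat_id: str = "", min_dwell: float = 0.0) -> list[Visit]:
    """Semi-Markov zone-visit sequence for one session (fast path: no
    frame-level track).  Visit distance is dwell x nominal speed with
    lognormal tortuosity noise."""
    profile.validate(arena)
    zone = profile.start_zone
    t = 0.0
    visits: list[Visit] = []
    while t < duration:
        if visits and duration - t < max(min_dwell, 1e-9):
            # remainder too short to form a samplable visit: extend the
            # previous one to the session end instead
            last = visits[-1]
            visits[-1] = Visit(rat_id=last.rat_id, zone_id=last.zone_id,
                               t_enter=last.t_enter, t_exit=duration,
                               distance=last.distance)
            break
        h = _habituation_factor(profile, t)
        dwell = rng.exponential(profile.dwell_mean[zone] / h)
        dwell = max(dwell, min_dwell)
        t_exit = min(t + dwell, duration)
        dist = profile.speed[zone] * (t_exit - t) \
            * float(np.exp(rng.normal(0.0, 0.15)))
        visits.append(Visit(rat_id=rat_id, zone_id=zone, t_enter=t,
                            t_exit=t_exit, distance=dist))
        t = t_exit
        weights = profile.transition.get(zone) or {}
        if not weights:
            break  # absorbing zone
        targets = list(weights)
        w = np.array([weights[z] for z in targets], dtype=float)
        if w.sum() <= 0:
            break
        zone = targets[rng.choice(len(targets), p=w / w.sum())]
    return visits


def _interior_point(arena: ArenaConfig, zone_id: str,
                    rng: np.random.Generator) -> tuple:
    """Random point inside a zone but outside its child zones."""
    geom = arena.zone(zone_id).geometry
    children = [arena.zone(c).geometry for c in arena.children(zone_id)]
    minx, miny, maxx, maxy = geom.as_shapely().bounds
    for _ in range(1000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if geom.contains(x, y) and not any(c.contains(x, y) for c in children):
            return x, y
    cx, cy = geom.centroid()
    return cx, cy


def simulate_mcsf_session(profile: GroupProfile, arena: ArenaConfig,
                          duration: float, seed, rat_id: str = "",
                          frame_rate: float = 5.0):
    """One full arena session: returns ``(Track, visits)``.

    The exact visit schedule that generated the track is returned
    alongside; ``extract_visits`` on the track recovers it up to frame
    quantization of the entry/exit times.
    """
    rng = np.random.default_rng(seed)
    min_dwell = 2.0 / frame_rate
    visits = simulate_mcsf_visits(profile, arena, duration, rng,
                                  rat_id=rat_id, min_dwell=min_dwell)
    n_frames = int(round(duration * frame_rate))
    t = np.arange(n_frames) / frame_rate
    starts = np.array([v.t_enter for v in visits])
    vidx = np.searchsorted(starts, t, side="right") - 1
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    heading = rng.uniform(0, 2 * math.pi)
    px = py = None
    child_geoms = {z: [arena.zone(c).geometry for c in arena.children(z)]
                   for z in arena.zone_ids}
    for i in range(n_frames):
        zone = visits[vidx[i]].zone_id
        geom = arena.zone(zone).geometry
        kids = child_geoms[zone]
        if i == 0 or vidx[i] != vidx[i - 1]:
            px, py = _interior_point(arena, zone, rng)
        else:
            step = profile.speed[zone] / frame_rate
            for _ in range(12):
                heading += rng.normal(0.0, 0.6)
                nx = px + step * math.cos(heading)
                ny = py + step * math.sin(heading)
                if geom.contains(nx, ny) and \
                        not any(k.contains(nx, ny) for k in kids):
                    px, py = nx, ny
                    break
                heading = rng.uniform(0, 2 * math.pi)
        x[i], y[i] = px, py
    track = Track(rat_id=rat_id, t=t, x=x, y=y, frame_rate=frame_rate)
    # recompute visit distances from the frame path (step credited to the
    # zone of its first sample) so track and visit log agree
    step_len = np.hypot(np.diff(x), np.diff(y))
    out = []
    for k, v in enumerate(visits):
        in_visit = vidx[:-1] == k
        out.append(Visit(rat_id=v.rat_id, zone_id=v.zone_id,
                         t_enter=v.t_enter, t_exit=v.t_exit,
                         distance=float(step_len[in_visit].sum())))
    return track, out


def simulate_point_behaviors(profile: GroupProfile, duration: float,
                             rng: np.random.Generator) -> dict:
    """Per-bin Poisson counts of the manually scored behaviors, with
    habituation decay, plus per-session counts (urine spots, fecal boli)."""
    n_bins = max(1, int(math.ceil(duration / BIN_WIDTH)))
    out: dict[str, float] = {}
    for b in POINT_BEHAVIORS:
        rate = profile.point_rates.get(b, 0.0)
        total = 0
        for k in range(n_bins):
            bin_len = min(BIN_WIDTH, duration - k * BIN_WIDTH) / 60.0
            lam = rate * bin_len * profile.habituation ** k
            c = int(rng.poisson(lam))
            out[f"{b}_bin{k + 1}"] = c
            total += c
        out[b] = total
    for b in SESSION_COUNTS:
        out[b] = int(rng.poisson(profile.session_count_means.get(b, 0.0)))
    return out


# ---------------------------------------------------------------------------
# bout logs

def simulate_bout_log(profile: GroupProfile, definition: EthogramDefinition,
                      duration: float, seed, rat_id: str = "",
                      session: str | None = None) -> BoutLog:
    """Alternating-renewal bout log: behavior with probability proportional
    to its rate, exponential bout lengths, exponential inter-bout gaps."""
    rng = np.random.default_rng(seed)
    if definition.test_type == "novel_cage":
        rates, means = profile.novel_cage_rates, profile.novel_cage_bout_means
    else:
        rates, means = profile.home_cage_rates, profile.home_cage_bout_means
    behaviors = [b for b in definition.behaviors if rates.get(b, 0.0) > 0]
    if not behaviors:
        raise ConfigError("all ethogram behavior rates are zero")
    w = np.array([rates[b] for b in behaviors], dtype=float)
    p = w / w.sum()
    bouts = []
    t = float(rng.exponential(profile.inter_bout_gap_mean))
    while t < duration:
        b = behaviors[rng.choice(len(behaviors), p=p)]
        mean_len = means.get(b, 0.0)
        length = float(rng.exponential(mean_len)) if mean_len > 0 else 0.0
        t_stop = min(t + length, duration)
        bouts.append((b, t, t_stop))
        t = t_stop + float(rng.exponential(profile.inter_bout_gap_mean))
    return BoutLog(rat_id=rat_id, session=session or definition.test_type,
                   bouts=bouts)


def simulate_home_cage_pair(profile_a: GroupProfile, profile_b: GroupProfile,
                            definition: EthogramDefinition, duration: float,
                            seed, rat_a: str, rat_b: str):
    """Joint home-cage logs of two cage mates: each rat's own bouts plus,
    with probability ``complementary_prob``, a submissive response in the
    partner's log time-locked to each dominant/aggressive bout."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_a, s_b, s_pair = ss.spawn(3)
    log_a = simulate_bout_log(profile_a, definition, duration, s_a, rat_a)
    log_b = simulate_bout_log(profile_b, definition, duration, s_b, rat_b)
    rng = np.random.default_rng(s_pair)
    trigger = set(definition.categories.get("dominant", ())) \
        | set(definition.categories.get("aggressive", ()))
    responses = tuple(definition.categories.get("submissive", ())) or ("avoiding",)
    for src, dst, p in ((log_a, log_b, profile_a.complementary_prob),
                        (log_b, log_a, profile_b.complementary_prob)):
        extra = []
        for b, t0, t1 in src.bouts:
            if b in trigger and rng.random() < p:
                resp = responses[rng.choice(len(responses))]
                extra.append((resp, t0, max(t0, min(t1, duration))))
        dst.bouts = sorted(dst.bouts + extra, key=lambda x: x[1])
        dst.partner_id = src.rat_id
    log_a.flag_overlaps()
    log_b.flag_overlaps()
    return log_a, log_b


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortData:
    """One simulated cohort in the pipeline's input formats."""

    visit_log: pd.DataFrame
    counts: pd.DataFrame          # sidecar + per-bin behavior counts
    novel_logs: list
    home_logs: list
    groups: dict                  # rat_id -> group
    tracks: dict = field(default_factory=dict)  # (rat_id, trial) -> Track
    manifest: dict = field(default_factory=dict)
    visits: dict = field(default_factory=dict)  # (rat_id, trial) -> [Visit]


def simulate_cohort(config: SimulationConfig,
                    arena: ArenaConfig | None = None) -> CohortData:
    """Generate a full synthetic cohort from a validated config.

    Per-rat seeds are spawned deterministically from the master seed, so
    the same config yields byte-identical outputs.
    """
    if arena is None:
        arena = load_arena_config()
    profiles = config.resolved_profiles()
    for prof in profiles.values():
        prof.validate(arena)
    novel_def = load_ethogram("novel_cage")
    home_def = load_ethogram("home_cage_change")

    root = np.random.SeedSequence(config.master_seed)
    group_seeds = dict(zip(profiles, root.spawn(len(profiles))))

    visit_frames, count_rows = [], []
    novel_logs, home_logs = [], []
    groups, tracks, visit_map = {}, {}, {}
    for gname, prof in profiles.items():
        rat_seeds = group_seeds[gname].spawn(config.n_per_group)
        rats = [f"{gname}_r{i + 1:02d}" for i in range(config.n_per_group)]
        for rid, rseed in zip(rats, rat_seeds):
            groups[rid] = gname
            per_session = rseed.spawn(len(config.trials) + 2)
            for trial, tseed in zip(config.trials, per_session):
                if config.emit_tracks:
                    track, visits = simulate_mcsf_session(
                        prof, arena, config.mcsf_duration, tseed,
                        rat_id=rid, frame_rate=config.frame_rate)
                    track.group, track.trial = gname, str(trial)
                    tracks[(rid, str(trial))] = track
                else:
                    rng = np.random.default_rng(tseed)
                    visits = simulate_mcsf_visits(
                        prof, arena, config.mcsf_duration, rng, rat_id=rid,
                        min_dwell=2.0 / config.frame_rate)
                visit_map[(rid, str(trial))] = visits
                visit_frames.append(visits_to_frame(visits, group=gname,
                                                    trial=str(trial)))
                rng_b = np.random.default_rng(tseed.spawn(1)[0])
                row = {"rat_id": rid, "group": gname, "trial": str(trial)}
                row.update(simulate_point_behaviors(
                    prof, config.mcsf_duration, rng_b))
                count_rows.append(row)
            if config.simulate_ethogram_tests:
                novel_logs.append(simulate_bout_log(
                    prof, novel_def, config.novel_cage_duration,
                    per_session[-2], rat_id=rid))
        if config.simulate_ethogram_tests:
            pair_seeds = group_seeds[gname].spawn(1)[0].spawn(
                (config.n_per_group + 1) // 2)
            for k in range(0, config.n_per_group - 1, 2):
                a, b = simulate_home_cage_pair(
                    prof, prof, home_def, config.home_cage_duration,
                    pair_seeds[k // 2], rats[k], rats[k + 1])
                home_logs += [a, b]

    cohort = CohortData(
        visit_log=pd.concat(visit_frames, ignore_index=True),
        counts=pd.DataFrame(count_rows),
        novel_logs=novel_logs, home_logs=home_logs,
        groups=groups, tracks=tracks, visits=visit_map,
        manifest={"master_seed": config.master_seed,
                  "n_per_group": config.n_per_group,
                  "trials": list(config.trials),
                  "groups": list(profiles),
                  "effect_multipliers": dict(config.effect_multipliers),
                  "mcsf_duration": config.mcsf_duration,
                  "frame_rate": config.frame_rate})
    return cohort


def cohort_parameter_table(cohort: CohortData, arena: ArenaConfig,
                           session_duration: float = 1800.0,
                           trial: str | None = None,
                           missing_mode: str = "within_trial") -> pd.DataFrame:
    """Fast in-memory path from a simulated cohort to the parameter table."""
    counts = cohort.counts.set_index(["rat_id", "trial"])
    rows, index = [], []
    for (rid, tr), visits in cohort.visits.items():
        if trial is not None and tr != trial:
            continue
        crow = counts.loc[(rid, tr)]
        side = {c: float(crow[c]) for c in SIDECAR_COUNTS}
        rows.append(descriptor_row(visits, arena, session_duration,
                                   counts=side))
        index.append((rid, cohort.groups[rid], tr))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["rat_id", "group", "trial"]))
    return apply_missing_rules(table, missing_mode, session_duration, arena)


def write_cohort(cohort: CohortData, outdir) -> list:
    """Write a cohort in the pipeline's input formats; returns the paths."""
    from .ethogram import write_bout_log
    from .tracking import write_visit_log

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _save(df, name):
        p = out / name
        df.to_csv(p, index=False)
        paths.append(p)

    _save(cohort.visit_log, "visits.csv")
    _save(cohort.counts, "scored_counts.csv")
    if cohort.novel_logs:
        write_bout_log(cohort.novel_logs, out / "novel_cage_bouts.csv")
        paths.append(out / "novel_cage_bouts.csv")
    if cohort.home_logs:
        write_bout_log(cohort.home_logs, out / "home_cage_bouts.csv")
        paths.append(out / "home_cage_bouts.csv")
    for (rid, trial), track in cohort.tracks.items():
        p = out / f"track_{rid}_t{trial}.csv"
        pd.DataFrame({"time_s": track.t, "x_cm": track.x,
                      "y_cm": track.y}).to_csv(p, index=False)
        paths.append(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)
    paths.append(out / "manifest.json")
    return paths


# ---------------------------------------------------------------------------
# end-to-end recovery / calibration experiments

def recovery_experiment(config: SimulationConfig, n_replicates: int,
                        alpha: float = 0.05,
                        parameters: Sequence[str] | None = None,
                        arena: ArenaConfig | None = None,
                        category_map: Mapping | None = None) -> dict:
    """Power / type-I report over replicated simulated cohorts.

    Each replicate draws a fresh cohort (single MCSF trial, visit-level
    fast path), runs the group comparison on every parameter and the
    trend-analysis group t-test on every category, and tallies rejections
    at ``alpha``.  Parameters targeted by the config's effect multipliers
    are reported as 'affected' (power), the rest as type-I rates.
    """
    from .stats import group_compare
    from .trend import load_category_map, trend_scores, trend_tests

    if arena is None:
        arena = load_arena_config()
    if category_map is None:
        category_map = load_category_map()
    if parameters is None:
        parameters = sorted({p for entries in category_map.values()
                             for p, _ in entries})
    rep_seeds = np.random.SeedSequence(config.master_seed).spawn(n_replicates)
    rej_param = {p: 0 for p in parameters}
    rej_cat = {c: 0 for c in category_map}
    for rep, rs in enumerate(rep_seeds):
        cfg = copy.deepcopy(config)
        cfg.master_seed = int(rs.generate_state(1)[0] % (2 ** 31))
        cfg.trials = (config.trials[0],)
        cfg.emit_tracks = False
        cfg.simulate_ethogram_tests = False
        cohort = simulate_cohort(cfg, arena)
        table = cohort_parameter_table(cohort, arena, config.mcsf_duration)
        for p in parameters:
            if group_compare(table, p).p <= alpha:
                rej_param[p] += 1
        scores = trend_scores(table, category_map)
        tests = trend_tests(scores)
        for _, r in tests[(tests.test == "unpaired_t")].iterrows():
            if r.p <= alpha:
                rej_cat[r.category] += 1
    affected = [p for p in affected_parameters(config.effect_multipliers)
                if p in rej_param]
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "parameter_rejection_rate": {p: rej_param[p] / n_replicates
                                     for p in parameters},
        "category_rejection_rate": {c: rej_cat[c] / n_replicates
                                    for c in category_map},
        "affected_parameters": affected,
        "unaffected_parameters": [p for p in parameters if p not in affected],
    }
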