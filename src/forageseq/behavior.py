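"""Trial segmentation, performance metrics and trajectory-sequence templates.

A *trial* runs from one goal reward to the next and splits into a foraging
trajectory (goal reward to the entry into the last zone before the foraging
reward) and a goal-directed trajectory (foraging reward to the first entry
into the goal zone). Foraging trajectories are summarized as spatial maps
of movement-direction vectors on a 5-cm grid; trials are clustered on the
correlation distance between those complex maps, clusters with more than 30
member trials become sequence templates, and a trial counts as a *sequence
trial* when its map correlates above 0.6 with any template. Dark-condition
trials are matched against the templates found in the light condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import (
    ARENA_RADIUS_CM,
    BEHAVIOR_DT,
    BehaviorFrame,
    DIRECTION_BIN_DEG,
    SPATIAL_BIN_CM,
    SessionRecording,
)

N_SPATIAL_BINS = int(round(2 * ARENA_RADIUS_CM / SPATIAL_BIN_CM))  # 20 x 20 grid
DWELL_COLLAPSE_S = 0.2  # same-bin dwells are collapsed in <= 200-ms chunks
MIN_TEMPLATE_TRIALS = 30  # a cluster is a template when it has > 30 members
TEMPLATE_MATCH_R = 0.6
CUT_SEARCH = np.round(np.arange(0.10, 0.401, 0.01), 10)


class EventOrderError(ValueError):
    """Reward events do not alternate goal/foraging as the task requires."""


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    span: tuple[float, float]  # [previous goal reward, this goal reward]
    foraging_segment: tuple[float, float]
    goal_segment: tuple[float, float]
    foraging_reward_t: float
    goal_entry_t: float


@dataclass
class DirectionVectorMap:
    """Per-trial complex map M = l*exp(i*theta) of mean direction vectors."""

    trial_id: int
    m: np.ndarray  # complex (N, N); 0 on unvisited bins
    visited: np.ndarray  # bool (N, N)


@dataclass
class SequenceTemplate:
    template_id: int
    m: np.ndarray  # complex mean map over member trials
    visited: np.ndarray
    member_trials: np.ndarray  # indices into the map list used for clustering
    cut_threshold: float


# --------------------------------------------------------------------------
# trial segmentation and performance metrics
# --------------------------------------------------------------------------


def segment_trials(session: SessionRecording) -> list[TrialRecord]:
    """One TrialRecord per complete inter-goal-reward interval.

    A trailing partial trial (no closing goal reward) is dropped. Two
    foraging rewards between consecutive goal rewards violate the task's
    reward alternation and raise :class:`EventOrderError`.
    """
    events = sorted(session.events, key=lambda e: e.t)
    goal_ts = [e.t for e in events if e.kind == "goal_reward"]
    trials: list[TrialRecord] = []
    for k in range(len(goal_ts) - 1):
        g0, g1 = goal_ts[k], goal_ts[k + 1]
        forag = [e.t for e in events if e.kind == "foraging_reward" and g0 < e.t <= g1]
        if len(forag) > 1:
            raise EventOrderError(
                "event-order: consecutive foraging rewards without a goal reward"
            )
        if not forag:
            continue  # malformed trial: no foraging reward recorded
        f_t = forag[0]
        zone_entries = [
            e.t
            for e in events
            if e.kind == "zone_entry" and e.zone_id != "goal" and g0 < e.t <= f_t
        ]
        goal_entries = [
            e.t
            for e in events
            if e.kind == "zone_entry" and e.zone_id == "goal" and f_t < e.t <= g1
        ]
        forag_end = zone_entries[-1] if zone_entries else f_t
        goal_entry = goal_entries[0] if goal_entries else g1
        trials.append(
            TrialRecord(
                trial_index=k,
                span=(g0, g1),
                foraging_segment=(g0, forag_end),
                goal_segment=(f_t, goal_entry),
                foraging_reward_t=f_t,
                goal_entry_t=goal_entry,
            )
        )
    return trials


def path_length(frame: BehaviorFrame, t0: float, t1: float) -> float:
    """Traveled distance (cm) between t0 and t1 on the 100-Hz path."""
    i0, i1 = frame.index_of(np.array([t0, t1]))
    if i1 <= i0:
        return 0.0
    dx = np.diff(frame.x[i0 : i1 + 1])
    dy = np.diff(frame.y[i0 : i1 + 1])
    return float(np.sum(np.hypot(dx, dy)))


def trial_metrics(trials: list[TrialRecord], frame: BehaviorFrame) -> dict:
    """Per-day performance metrics.

    rewards/min counts both reward types over the frame span; foraging
    distance is the median traveled distance over foraging segments; the
    goal-directed distance of each trial is normalized by the straight-line
    distance between the foraging-reward position and the goal-entry
    position (trials with zero straight-line distance are excluded) and the
    median across trials is reported.
    """
    duration_min = (frame.t[-1] - frame.t[0]) / 60.0
    forag_d = [path_length(frame, *tr.foraging_segment) for tr in trials]
    goal_norm = []
    for tr in trials:
        d = path_length(frame, *tr.goal_segment)
        ia, ib = frame.index_of(np.array([tr.goal_segment[0], tr.goal_segment[1]]))
        straight = float(np.hypot(frame.x[ib] - frame.x[ia], frame.y[ib] - frame.y[ia]))
        if straight > 0:
            goal_norm.append(d / straight)
    n_rewards = 2 * len(trials)  # one foraging + one goal reward per complete trial
    return {
        "n_trials": len(trials),
        "rewards_per_min": n_rewards / duration_min if duration_min > 0 else np.nan,
        "median_foraging_distance": float(np.median(forag_d)) if forag_d else np.nan,
        "median_goal_distance_norm": float(np.median(goal_norm)) if goal_norm else np.nan,
    }


# --------------------------------------------------------------------------
# direction-vector maps
# --------------------------------------------------------------------------


def _spatial_bin(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    bx = np.clip(((x + ARENA_RADIUS_CM) / SPATIAL_BIN_CM).astype(int), 0, N_SPATIAL_BINS - 1)
    by = np.clip(((y + ARENA_RADIUS_CM) / SPATIAL_BIN_CM).astype(int), 0, N_SPATIAL_BINS - 1)
    return bx * N_SPATIAL_BINS + by


def direction_vector_map(
    frame: BehaviorFrame, trial: TrialRecord | tuple[float, float], trial_id: int = 0
) -> DirectionVectorMap:
    """Complex direction-vector map of one trial's foraging trajectory.

    Movement directions are discretized to 20-deg bin centers. Consecutive
    samples in the same 5-cm spatial bin are collapsed (in chunks of at most
    200 ms) to a single unit vector at their circular mean direction; the
    unit vectors falling in each spatial bin are then averaged into
    M = l*exp(i*theta) with l in [0, 1].
    """
    seg = trial.foraging_segment if isinstance(trial, TrialRecord) else trial
    i0, i1 = frame.index_of(np.array(seg))
    sl = slice(i0, i1 + 1)
    ok = frame.valid[sl] & np.isfinite(frame.direction[sl])
    m = np.zeros((N_SPATIAL_BINS, N_SPATIAL_BINS), dtype=complex)
    visited = np.zeros((N_SPATIAL_BINS, N_SPATIAL_BINS), dtype=bool)
    if not np.any(ok):
        return DirectionVectorMap(trial_id, m, visited)

    x = frame.x[sl][ok]
    y = frame.y[sl][ok]
    d = frame.direction[sl][ok]
    # discretize direction to 20-deg bin centers
    d = (np.floor(d / DIRECTION_BIN_DEG) * DIRECTION_BIN_DEG) + DIRECTION_BIN_DEG / 2
    bins = _spatial_bin(x, y)

    # split into maximal same-bin runs, then into <= 200-ms chunks
    max_chunk = int(round(DWELL_COLLAPSE_S / BEHAVIOR_DT))
    change = np.flatnonzero(np.diff(bins) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [bins.size]))

    acc = np.zeros(N_SPATIAL_BINS * N_SPATIAL_BINS, dtype=complex)
    cnt = np.zeros(N_SPATIAL_BINS * N_SPATIAL_BINS, dtype=int)
    z = np.exp(1j * np.radians(d))
    for s, e in zip(starts, ends):
        b = bins[s]
        for cs in range(s, e, max_chunk):
            v = np.sum(z[cs : min(cs + max_chunk, e)])
            if np.abs(v) > 1e-9:  # chunks with no net heading contribute nothing
                acc[b] += v / np.abs(v)  # unit vector at the circular mean
                cnt[b] += 1
    vis = cnt > 0
    acc[vis] = acc[vis] / cnt[vis]
    m = acc.reshape(N_SPATIAL_BINS, N_SPATIAL_BINS)
    visited = vis.reshape(N_SPATIAL_BINS, N_SPATIAL_BINS)
    return DirectionVectorMap(trial_id, m, visited)


def trial_distance(a: DirectionVectorMap, b: DirectionVectorMap) -> float:
    """Correlation distance in [0, 2] between two direction-vector maps.

    Real part of the conjugate inner product over commonly visited bins,
    normalized by the product of the common-bin map norms; NaN when the
    maps share no visited bin (such pairs are excluded from clustering).
    """
    common = a.visited & b.visited
    if not np.any(common):
        return np.nan
    mi = a.m[common]
    mj = b.m[common]
    den = np.sqrt(np.sum(np.abs(mi) ** 2) * np.sum(np.abs(mj) ** 2))
    if den == 0:
        return np.nan
    return float(1.0 - np.real(np.sum(mi * np.conj(mj))) / den)


def distance_matrix(maps: list[DirectionVectorMap]) -> np.ndarray:
    n = len(maps)
    stack = np.stack([mp.m for mp in maps]).reshape(n, -1)
    vis = np.stack([mp.visited for mp in maps]).reshape(n, -1)
    d = np.zeros((n, n))
    for i in range(n):
        common = vis[i] & vis[i + 1 :]
        mi = np.where(common, stack[i], 0)
        mj = np.where(common, stack[i + 1 :], 0)
        num = np.real(np.sum(mi * np.conj(mj), axis=1))
        den = np.sqrt(
            np.sum(np.abs(mi) ** 2, axis=1) * np.sum(np.abs(mj) ** 2, axis=1)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.clip(1.0 - num / den, 0.0, 2.0)  # guard float round-off
        row[~np.any(common, axis=1) | (den == 0)] = np.nan
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def cluster_templates(
    maps: list[DirectionVectorMap],
    min_members: int = MIN_TEMPLATE_TRIALS,
) -> list[SequenceTemplate]:
    """Hierarchical clustering of trials into sequence templates.

    Average-linkage dendrogram on the trial-distance matrix; the cut
    threshold is searched over [0.1, 0.4] in 0.01 steps and the cut
    maximizing the number of clusters with more than ``min_members`` trials
    is retained (ties resolved toward the lowest threshold). An empty
    result is a legitimate outcome. Pairs without common coverage enter the
    linkage at the maximal distance 2.
    """
    if len(maps) <= min_members:
        return []
    d = distance_matrix(maps)
    d = np.where(np.isnan(d), 2.0, d)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")

    best_t, best_count, best_labels = None, 0, None
    for t in CUT_SEARCH:
        labels = fcluster(z, t, criterion="distance")
        counts = np.bincount(labels)
        n_valid = int(np.sum(counts > min_members))
        if n_valid > best_count:
            best_t, best_count, best_labels = float(t), n_valid, labels
    if best_count == 0:
        return []

    templates = []
    counts = np.bincount(best_labels)
    tid = 0
    for lab in np.flatnonzero(counts > min_members):
        members = np.flatnonzero(best_labels == lab)
        mean_m = np.mean(np.stack([maps[i].m for i in members]), axis=0)
        visited = np.any(np.stack([maps[i].visited for i in members]), axis=0)
        templates.append(SequenceTemplate(tid, mean_m, visited, members, best_t))
        tid += 1
    return templates


def template_correlation(
    mp: DirectionVectorMap, tpl: SequenceTemplate, centered: bool = True
) -> float:
    """Pearson correlation between a trial map and a template over their
    commonly visited bins, on the concatenated real and imaginary parts."""
    common = mp.visited & tpl.visited
    if np.sum(common) < 2:
        return np.nan
    a = np.concatenate([np.real(mp.m[common]), np.imag(mp.m[common])])
    b = np.concatenate([np.real(tpl.m[common]), np.imag(tpl.m[common])])
    if centered:
        a = a - a.mean()
        b = b - b.mean()
    den = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if den == 0:
        return np.nan
    return float(np.sum(a * b) / den)


def match_sequence_trials(
    maps: list[DirectionVectorMap],
    templates: list[SequenceTemplate],
    threshold: float = TEMPLATE_MATCH_R,
    centered: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Flag sequence trials and compute the sequence fraction.

    Returns ``(is_sequence, best_template, fraction)``; a trial is a
    sequence trial when its correlation with any template exceeds the
    threshold. With no templates the fraction is 0 by definition.
    """
    n = len(maps)
    flags = np.zeros(n, dtype=bool)
    best = np.full(n, -1, dtype=int)
    if templates:
        for i, mp in enumerate(maps):
            rs = np.array([template_correlation(mp, tp, centered) for tp in templates])
            rs = np.where(np.isnan(rs), -np.inf, rs)
            j = int(np.argmax(rs))
            if rs[j] > threshold:
                flags[i] = True
                best[i] = templates[j].template_id
    fraction = float(np.mean(flags)) if n else 0.0
    return flags, best, fraction
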