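"""Synthetic foraging sessions with known ground truth.

The generator emulates the task structure of a hidden-zone foraging task in
a 100-cm circular arena: on each trial the animal visits one zone of each of
three types (A/B/C) in any order, receives a *foraging* reward after a
random 0.6-2-s delay upon entering the last zone, then returns to a hidden
goal zone and dwells 1 s for the *goal* reward. Trials are either
*sequence* trials (a stereotyped waypoint path through one template's zones
with small steering noise) or *random* foraging (random zone choice, random
order, random via-points, large steering noise).

On top of the trajectory it synthesizes a theta-bearing LFP (6-9 Hz
sinusoid with slow amplitude modulation plus white noise) and spike trains
with multiplicative position x direction x speed x theta-phase tuning,
optional phase precession, and optional light-to-dark degradation of the
direction gain and place-field contrast. Spikes are drawn as an
inhomogeneous Poisson process by thinning, with the rate held constant
within each 10-ms frame.

Every stochastic choice flows from a single :class:`numpy.random.Generator`
so a fixed seed reproduces a session bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ARENA_RADIUS_CM,
    BEHAVIOR_DT,
    BehaviorFrame,
    Condition,
    Event,
    SessionRecording,
    Zone,
    ZoneLayout,
    wrap_deg,
)

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def default_zone_layout() -> ZoneLayout:
    """One central type-A zone, three type-B and three type-C peripheral
    zones (8-cm radius), and a goal zone near the wall."""
    r_ring, r_zone = 28.0, 8.0
    zones = [Zone("A1", "A", (0.0, 0.0), r_zone)]
    for i, ang in enumerate((0.0, 120.0, 240.0)):
        a = np.radians(ang)
        zones.append(Zone(f"B{i+1}", "B", (r_ring * np.cos(a), r_ring * np.sin(a)), r_zone))
    for i, ang in enumerate((60.0, 180.0, 300.0)):
        a = np.radians(ang)
        zones.append(Zone(f"C{i+1}", "C", (r_ring * np.cos(a), r_ring * np.sin(a)), r_zone))
    goal = Zone("goal", "goal", (0.0, -40.0), 8.0)
    return ZoneLayout(goal_zone=goal, foraging_zones=tuple(zones))


@dataclass(frozen=True)
class CellGroundTruth:
    """Generative tuning of one simulated cell.

    The instantaneous rate is the product of a 2-D Gaussian place field, a
    cosine direction gain ``1 + g_d*cos(dir - dir_pref)``, a linear speed
    ramp and a theta-phase gain ``1 + theta_depth*cos(phase - theta_pref)``.
    For precessing cells the preferred phase advances with the position in
    the field projected on the running direction (pdcd):
    ``theta_pref(t) = theta0 + precession_slope * pdcd(t)``.
    Gains for covariates absent from ``covariate_set`` are identically 1.
    """

    cell_id: str
    covariate_set: str = "P"  # subset of {P, D, S} or "none"
    field_center: tuple[float, float] = (0.0, 0.0)
    field_width: float = 10.0  # Gaussian SD, cm
    peak_rate: float = 8.0  # Hz above baseline at field center
    baseline_rate: float = 0.5  # Hz
    g_d: float = 0.0  # direction modulation depth in [0, 1]
    dir_pref: float = 0.0  # deg
    g_s: float = 0.0  # speed ramp depth over the speed range
    theta_depth: float = 0.0  # m in [0, 1]
    theta_pref: float = 180.0  # deg
    precession_slope: float = 0.0  # deg per pdcd unit, <= 0 for precession

    def __post_init__(self) -> None:
        if not (0 <= self.g_d <= 1 and 0 <= self.theta_depth <= 1):
            raise ValueError("gain depths must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "covariate_set": self.covariate_set,
            "field_center": list(self.field_center),
            "field_width": self.field_width,
            "peak_rate": self.peak_rate,
            "baseline_rate": self.baseline_rate,
            "g_d": self.g_d,
            "dir_pref": self.dir_pref,
            "g_s": self.g_s,
            "theta_depth": self.theta_depth,
            "theta_pref": self.theta_pref,
            "precession_slope": self.precession_slope,
        }


@dataclass
class SimConfig:
    """Study conditions for one simulated session."""

    seed: int = 0
    n_trials: int = 40
    sequence_fraction_true: float = 0.6
    templates: list[list[str]] = field(default_factory=lambda: [["B1", "A1", "C1"]])
    speed_mean: float = 15.0  # cm/s
    theta_freq: float = 8.0  # Hz, must lie in the 6-9-Hz theta band
    theta_freq_sd: float = 0.3  # slow instantaneous-frequency wander (Hz)
    lfp_snr: float = 5.0  # theta amplitude / noise SD
    cells: list[CellGroundTruth] = field(default_factory=list)
    dark_gain_direction: float = 1.0  # multiplies g_d in dark sessions
    dark_gain_position: float = 1.0  # 1 keeps the field, 0 flattens it
    foraging_delay: tuple[float, float] = (0.6, 2.0)
    goal_dwell: float = 1.0
    heading_noise_seq: float = 0.06  # rad per 10-ms step
    heading_noise_rand: float = 0.18
    zones: ZoneLayout = field(default_factory=default_zone_layout)

    def __post_init__(self) -> None:
        if not 0.0 <= self.sequence_fraction_true <= 1.0:
            raise ValueError("sequence_fraction_true must lie in [0, 1]")
        if not 6.0 <= self.theta_freq <= 9.0:
            raise ValueError("theta_freq must lie in the 6-9-Hz band")
        if not (0 <= self.dark_gain_direction <= 1 and 0 <= self.dark_gain_position <= 1):
            raise ValueError("dark gains must lie in [0, 1]")
        for tpl in self.templates:
            types = {self.zones.zone_by_id(z).type_label for z in tpl}
            if len(types) < 3:
                raise ValueError("bad-template: template must visit all 3 zone types")


# --------------------------------------------------------------------------
# trajectory simulation
# --------------------------------------------------------------------------


class _Walker:
    """Heading-relaxation random walker on the 100-Hz grid.

    The inner loop runs once per 10-ms step over whole sessions, so it
    sticks to scalar ``math`` operations.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        goal = config.zones.goal_zone
        self.x, self.y = float(goal.center[0]), float(goal.center[1])
        self.heading = float(rng.uniform(0, 2 * math.pi))
        self.speed = config.speed_mean
        self.cruise = config.speed_mean

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def new_leg(self) -> None:
        """Draw a fresh cruising speed (mice vary pace a lot between legs)."""
        v = self.cfg.speed_mean * (1.0 + 0.5 * self.rng.standard_normal())
        self.cruise = min(max(v, 4.0), 2.5 * self.cfg.speed_mean)

    def step(self, tx: float, ty: float, noise: float, slow: bool = False) -> None:
        rng = self.rng
        bearing = math.atan2(ty - self.y, tx - self.x)
        err = (bearing - self.heading + math.pi) % (2 * math.pi) - math.pi
        self.heading += min(max(0.25 * err, -0.3), 0.3) + noise * rng.standard_normal()
        target_speed = 1.5 if slow else self.cruise
        self.speed += 0.05 * (target_speed - self.speed) + 0.8 * rng.standard_normal()
        self.speed = min(max(self.speed, 0.5 if slow else 3.0), 2.5 * self.cfg.speed_mean)
        self.x += self.speed * BEHAVIOR_DT * math.cos(self.heading)
        self.y += self.speed * BEHAVIOR_DT * math.sin(self.heading)
        r = math.hypot(self.x, self.y)
        if r > ARENA_RADIUS_CM - 1.0:  # bounce off the wall
            f = (ARENA_RADIUS_CM - 1.0) / r
            self.x *= f
            self.y *= f
            normal = math.atan2(self.y, self.x)
            self.heading = normal + math.pi + 0.5 * rng.standard_normal()


def _plan_trial(
    config: SimConfig, rng: np.random.Generator, is_sequence: bool
) -> tuple[str, list]:
    """Pick the waypoint plan (zone ids and via-points) for one trial."""
    zones = config.zones
    if is_sequence:
        k = int(rng.integers(len(config.templates)))
        plan = [("zone", z) for z in config.templates[k]]
        return f"template_{k}", plan
    by_type = {"A": [], "B": [], "C": []}
    for z in zones.foraging_zones:
        by_type[z.type_label].append(z.zone_id)
    order = ["A", "B", "C"]
    rng.shuffle(order)
    plan: list = []
    for t in order:
        if rng.random() < 0.6:  # wander before the next zone
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0.05, 0.85)) * ARENA_RADIUS_CM
            plan.append(("point", (rad * np.cos(ang), rad * np.sin(ang))))
        plan.append(("zone", by_type[t][int(rng.integers(len(by_type[t])))]))
    return "random", plan


def _target_of(step, zones: ZoneLayout, rng: np.random.Generator):
    """(x, y, reach radius) of one waypoint-plan step."""
    kind, what = step
    if kind == "zone":
        z = zones.zone_by_id(what)
        return (
            z.center[0] + rng.uniform(-2, 2),
            z.center[1] + rng.uniform(-2, 2),
            z.radius * 0.5,
        )
    return what[0], what[1], 6.0


def simulate_behavior(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict, list[str]]:
    """Simulate the trajectory and the reward-event log.

    Returns a dict with the 100-Hz path (``t``, ``x``, ``y``), the event
    list and per-trial ground truth, plus the list of per-trial labels
    (``template_<k>`` or ``random``) for the ``n_trials`` complete trials.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    zones = config.zones
    walker = _Walker(config, rng)
    all_zones = [zones.goal_zone, *zones.foraging_zones]
    zx = [z.center[0] for z in all_zones]
    zy = [z.center[1] for z in all_zones]
    zr2 = [z.radius**2 for z in all_zones]
    zid = [z.zone_id for z in all_zones]
    ztype = [z.type_label for z in all_zones]
    inside = [z.zone_id == "goal" for z in all_zones]

    xs: list[float] = []
    ys: list[float] = []
    events: list[Event] = []
    labels: list[str] = []
    trial_starts: list[float] = []

    i = 0  # frame counter

    def record() -> tuple[float, int]:
        """Advance one frame; return (t, entered-zone index or -1)."""
        nonlocal i
        x, y = walker.x, walker.y
        xs.append(x)
        ys.append(y)
        t = i * BEHAVIOR_DT
        i += 1
        entered = -1
        for k in range(len(all_zones)):
            now_in = (x - zx[k]) ** 2 + (y - zy[k]) ** 2 <= zr2[k]
            if now_in and not inside[k]:
                events.append(Event("zone_entry", t, zid[k]))
                entered = k
            inside[k] = now_in
        return t, entered

    # initial dwell in the goal zone -> a leading goal reward so that every
    # subsequent inter-goal-reward interval is one complete labeled trial
    gx, gy = zones.goal_zone.center
    for _ in range(int(config.goal_dwell / BEHAVIOR_DT)):
        t, _e = record()
        walker.step(gx, gy, 0.3, slow=True)
    events.append(Event("goal_reward", t, "goal"))

    goal_r2 = zones.goal_zone.radius**2
    for _trial in range(config.n_trials):
        is_seq = rng.random() < config.sequence_fraction_true
        label, plan = _plan_trial(config, rng, is_seq)
        labels.append(label)
        trial_starts.append(i * BEHAVIOR_DT)
        walker.new_leg()
        noise = config.heading_noise_seq if is_seq else config.heading_noise_rand
        types_seen: set[str] = set()
        # --- foraging phase ---
        step_idx = 0
        reward_t = math.inf
        delay = rng.uniform(*config.foraging_delay)
        tx, ty, reach = _target_of(plan[0], zones, rng)
        while True:
            walker.step(tx, ty, noise)
            t, entered = record()
            if entered >= 0 and zid[entered] != "goal":
                types_seen.add(ztype[entered])
                if len(types_seen) == 3 and not math.isfinite(reward_t):
                    reward_t = t + delay
            if (
                step_idx < len(plan) - 1
                and math.hypot(walker.x - tx, walker.y - ty) < reach
            ):
                step_idx += 1
                walker.new_leg()
                tx, ty, reach = _target_of(plan[step_idx], zones, rng)
            if t >= reward_t:
                events.append(Event("foraging_reward", t, None))
                break
        # --- goal-directed phase ---
        walker.new_leg()
        dwell = 0.0
        while True:
            in_goal = (walker.x - gx) ** 2 + (walker.y - gy) ** 2 <= goal_r2
            walker.step(gx, gy, config.heading_noise_seq, slow=in_goal)
            t, _e = record()
            if (walker.x - gx) ** 2 + (walker.y - gy) ** 2 <= goal_r2:
                dwell += BEHAVIOR_DT
                if dwell >= config.goal_dwell:
                    events.append(Event("goal_reward", t, "goal"))
                    break
            else:
                dwell = 0.0

    t_grid = np.arange(len(xs)) * BEHAVIOR_DT
    return (
        {
            "t": t_grid,
            "x": np.array(xs),
            "y": np.array(ys),
            "events": events,
            "trial_starts": np.array(trial_starts),
        },
        labels,
    )


# --------------------------------------------------------------------------
# LFP simulation
# --------------------------------------------------------------------------


def simulate_lfp(
    config: SimConfig,
    duration: float,
    rng: np.random.Generator | None = None,
    sample_rate: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Theta-band LFP with slow frequency wander and amplitude modulation.

    The carrier's instantaneous frequency drifts around ``theta_freq``
    (Gaussian wander of SD ``theta_freq_sd``, ~1-s correlation time,
    clipped to the 6-9-Hz band): biological theta is not a metronome, and
    the circular-shift significance test for phase tuning relies on that —
    against a perfectly periodic theta a time-shifted train keeps its
    phase relationships and the shuffle null would be degenerate. White
    noise of SD amplitude/snr is added on top.

    Returns ``(samples, true_peak_times)``; the true peaks are the maxima
    of the noise-free carrier.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    if config.theta_freq_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        drift = gaussian_filter1d(rng.standard_normal(n), sample_rate, mode="nearest")
        sd = drift.std()
        drift = drift * (config.theta_freq_sd / sd) if sd > 0 else drift
        f_inst = np.clip(config.theta_freq + drift, 6.0, 9.0)
    else:
        f_inst = np.full(n, config.theta_freq)
    phi = 2 * np.pi * np.cumsum(f_inst) / sample_rate
    amp = 1.0 + 0.3 * np.sin(2 * np.pi * 0.2 * t)
    carrier = np.sin(phi)
    noise_sd = 1.0 / config.lfp_snr if config.lfp_snr > 0 else 0.0
    samples = amp * carrier + noise_sd * rng.standard_normal(n)
    # carrier peaks where the accumulated phase crosses pi/2 + 2*pi*k
    targets = np.arange(np.pi / 2, phi[-1], 2 * np.pi)
    peaks = np.interp(targets, phi, t)
    return samples, peaks


def phase_from_peaks(times: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Ground-truth phase (deg) of arbitrary times by linear interpolation
    between successive theta peaks; NaN outside the peak span."""
    times = np.asarray(times, dtype=float)
    phase = np.full(times.shape, np.nan)
    if peaks.size < 2:
        return phase
    idx = np.searchsorted(peaks, times, side="right") - 1
    ok = (idx >= 0) & (idx < peaks.size - 1)
    p0 = peaks[idx[ok]]
    p1 = peaks[np.minimum(idx[ok] + 1, peaks.size - 1)]
    phase[ok] = 360.0 * (times[ok] - p0) / (p1 - p0)
    return phase


# --------------------------------------------------------------------------
# spike simulation
# --------------------------------------------------------------------------

SPEED_MID_CM_S = 15.0  # center of the speed ramp
SPEED_SPAN_CM_S = 30.0  # speed range over which g_s applies fully


def cell_rate(
    cell: CellGroundTruth,
    frame: BehaviorFrame,
    phase: np.ndarray | None,
    condition: Condition = Condition.LIGHT,
    dark_gain_direction: float = 1.0,
    dark_gain_position: float = 1.0,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) on the 100-Hz grid for one cell."""
    cs = cell.covariate_set
    n = len(frame)
    if "P" in cs:
        cx, cy = cell.field_center
        d2 = (frame.x - cx) ** 2 + (frame.y - cy) ** 2
        place = cell.baseline_rate + cell.peak_rate * np.exp(-d2 / (2 * cell.field_width**2))
        if condition is Condition.DARK and dark_gain_position < 1.0:
            m = float(np.mean(place))
            place = m + dark_gain_position * (place - m)
    else:
        place = np.full(n, cell.baseline_rate + cell.peak_rate)

    rate = place.astype(float)

    if "D" in cs and cell.g_d > 0:
        g_d = cell.g_d * (dark_gain_direction if condition is Condition.DARK else 1.0)
        gain = 1.0 + g_d * np.cos(np.radians(frame.direction - cell.dir_pref))
        rate = rate * np.where(np.isfinite(gain), gain, 1.0)

    if "S" in cs and cell.g_s != 0:
        gain = 1.0 + cell.g_s * (frame.speed - SPEED_MID_CM_S) / SPEED_SPAN_CM_S
        rate = rate * np.clip(gain, 0.05, None)

    if cell.theta_depth > 0 and phase is not None:
        if cell.precession_slope != 0 and "P" in cs:
            cx, cy = cell.field_center
            u = np.radians(frame.direction)
            proj = (frame.x - cx) * np.cos(u) + (frame.y - cy) * np.sin(u)
            pdcd = np.clip(proj / (2.0 * cell.field_width), -1.5, 1.5)
            pdcd = np.where(np.isfinite(pdcd), pdcd, 0.0)
            pref = cell.theta_pref + cell.precession_slope * pdcd
        else:
            pref = cell.theta_pref
        gain = 1.0 + cell.theta_depth * np.cos(np.radians(phase - pref))
        rate = rate * np.where(np.isfinite(gain), gain, 1.0)

    if np.any(rate < 0):
        raise ValueError("negative instantaneous rate: invalid ground-truth gains")
    return rate


def poisson_thinning(
    rate: np.ndarray, t0: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning.

    The rate is treated as piecewise constant over 10-ms frames. Candidate
    events are drawn from a homogeneous process at the peak rate and
    accepted with probability rate/peak, which is exact for a piecewise
    constant intensity.
    """
    rate = np.asarray(rate, dtype=float)
    lam_max = float(rate.max(initial=0.0))
    duration = rate.size * BEHAVIOR_DT
    if lam_max <= 0 or duration <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.minimum((cand / BEHAVIOR_DT).astype(int), rate.size - 1)
    keep = rng.uniform(0.0, lam_max, n_cand) < rate[idx]
    return t0 + cand[keep]


def simulate_cells(
    config: SimConfig,
    frame: BehaviorFrame,
    phase: np.ndarray | None,
    condition: Condition = Condition.LIGHT,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Draw spike trains for every configured cell on the given timeline."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    spikes: dict[str, np.ndarray] = {}
    for cell in config.cells:
        rate = cell_rate(
            cell,
            frame,
            phase,
            condition=condition,
            dark_gain_direction=config.dark_gain_direction,
            dark_gain_position=config.dark_gain_position,
        )
        spikes[cell.cell_id] = poisson_thinning(rate, float(frame.t[0]), rng)
    return spikes


# --------------------------------------------------------------------------
# full-session assembly
# --------------------------------------------------------------------------


def default_cell_population(
    n_cells: int, rng: np.random.Generator
) -> list[CellGroundTruth]:
    """A mixed population: place cells of every covariate category plus
    untuned cells, fields scattered over the arena."""
    cats = ["P", "PD", "PS", "PDS", "none"]
    cells = []
    for i in range(n_cells):
        cat = cats[i % len(cats)]
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 0.7)) * ARENA_RADIUS_CM
        cells.append(
            CellGroundTruth(
                cell_id=f"cell_{i:03d}",
                covariate_set=cat,
                field_center=(rad * np.cos(ang), rad * np.sin(ang)),
                field_width=float(rng.uniform(8, 12)),
                peak_rate=float(rng.uniform(6, 12)) if cat != "none" else 0.0,
                baseline_rate=0.5 if cat != "none" else float(rng.uniform(1, 3)),
                g_d=0.5 if "D" in cat else 0.0,
                dir_pref=float(rng.uniform(0, 360)),
                g_s=0.5 if "S" in cat else 0.0,
                theta_depth=0.5,
                theta_pref=float(rng.uniform(0, 360)),
            )
        )
    return cells


def simulate_session(
    config: SimConfig,
    condition: Condition = Condition.LIGHT,
    session_id: str = "sim",
) -> tuple[SessionRecording, dict]:
    """Generate one full session plus its ground-truth sidecar dict."""
    rng = np.random.default_rng(config.seed)
    beh, labels = simulate_behavior(config, rng)
    duration = float(beh["t"][-1]) + BEHAVIOR_DT
    lfp, true_peaks = simulate_lfp(config, duration, rng)

    frame = BehaviorFrame(
        t=beh["t"],
        x=beh["x"],
        y=beh["y"],
        direction=_heading_of(beh["x"], beh["y"]),
        speed=_speed_of(beh["x"], beh["y"]),
        valid=np.ones(beh["t"].size, dtype=bool),
    )
    phase = phase_from_peaks(frame.t, true_peaks)
    spikes = simulate_cells(config, frame, phase, condition=condition, rng=rng)

    # export tracking at the nominal 25-Hz camera rate
    sl = slice(None, None, 4)
    session = SessionRecording(
        session_id=session_id,
        condition=condition,
        tracking_t=beh["t"][sl],
        tracking_x=beh["x"][sl],
        tracking_y=beh["y"][sl],
        spikes=spikes,
        lfp=lfp,
        events=beh["events"],
        zones=config.zones,
    )
    truth = {
        "trial_labels": labels,
        "trial_starts": beh["trial_starts"].tolist(),
        "theta_peaks": np.asarray(true_peaks).round(6).tolist(),
        "cells": [c.to_dict() for c in config.cells],
        "condition": condition.value,
        "seed": config.seed,
    }
    return session, truth


def _heading_of(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = np.diff(x, append=x[-1])
    dy = np.diff(y, append=y[-1])
    with np.errstate(invalid="ignore"):
        d = wrap_deg(np.degrees(np.arctan2(dy, dx)))
    return np.where((dx == 0) & (dy == 0), np.nan, d)


def _speed_of(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = np.diff(x, append=x[-1])
    dy = np.diff(y, append=y[-1])
    return np.hypot(dx, dy) / BEHAVIOR_DT
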