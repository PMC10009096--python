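"""Domain types, kinematics, unit classification and session I/O.

Conventions used throughout the package:

* the arena center is the coordinate origin, positions in cm;
* angles are in degrees, counterclockwise from the +x axis, in [0, 360);
* time is in seconds; all bins are half-open ``[lo, hi)``;
* the behavioral timeline is resampled to a uniform 100-Hz grid and only
  frames where the animal runs faster than 2.5 cm/s are analyzed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter1d

# --------------------------------------------------------------------------
# constants shared across stages
# --------------------------------------------------------------------------

BEHAVIOR_RATE_HZ = 100.0  #: analysis timeline rate
BEHAVIOR_DT = 1.0 / BEHAVIOR_RATE_HZ
TRACKING_RATE_HZ = 25.0  #: nominal camera rate
SPEED_GATE_CM_S = 2.5  #: frames slower than this are excluded from analysis
ARENA_RADIUS_CM = 50.0  #: 100-cm diameter circular arena
SPATIAL_BIN_CM = 5.0
DIRECTION_BIN_DEG = 20.0
POSITION_SMOOTH_SD_S = 0.05  # pre-differentiation position smoothing
TRACKING_GAP_S = 0.2  # gaps longer than this are not interpolated across


class Condition(str, Enum):
    LIGHT = "light"
    DARK = "dark"


class CellClass(str, Enum):
    PYRAMIDAL = "pyramidal"
    INTERNEURON = "interneuron"
    UNCLASSIFIED = "unclassified"


class SessionError(ValueError):
    """Raised for malformed session containers or timelines."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Zone:
    zone_id: str
    type_label: str  # "A" | "B" | "C"
    center: tuple[float, float]
    radius: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class ZoneLayout:
    """Hidden foraging zones (types A/B/C) and the goal zone of the arena."""

    arena_center: tuple[float, float] = (0.0, 0.0)
    arena_radius: float = ARENA_RADIUS_CM
    goal_zone: Zone = field(
        default_factory=lambda: Zone("goal", "goal", (0.0, -32.0), 8.0)
    )
    foraging_zones: tuple[Zone, ...] = ()

    def __post_init__(self) -> None:
        labels = {z.type_label for z in self.foraging_zones}
        if self.foraging_zones and not {"A", "B", "C"} <= labels:
            raise SessionError("zone layout must contain all three type labels A, B, C")
        for z in (*self.foraging_zones, self.goal_zone):
            cx, cy = z.center
            d = np.hypot(cx - self.arena_center[0], cy - self.arena_center[1])
            if d + z.radius > self.arena_radius + 1e-9:
                raise SessionError(f"zone {z.zone_id} extends outside the arena")

    def zone_by_id(self, zone_id: str) -> Zone:
        if zone_id == self.goal_zone.zone_id:
            return self.goal_zone
        for z in self.foraging_zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)


@dataclass(frozen=True)
class Event:
    kind: str  # "foraging_reward" | "goal_reward" | "zone_entry"
    t: float
    zone_id: str | None = None


@dataclass
class SessionRecording:
    """Raw per-session container (tracking, spikes, LFP, events, zones)."""

    session_id: str
    condition: Condition
    tracking_t: np.ndarray  # (n,) s, strictly increasing, ~25 Hz
    tracking_x: np.ndarray  # (n,) cm
    tracking_y: np.ndarray  # (n,) cm
    spikes: dict[str, np.ndarray]  # unit_id -> sorted spike times (s)
    lfp: np.ndarray  # (m,) arbitrary units
    lfp_rate: float = 1000.0
    events: list[Event] = field(default_factory=list)
    zones: ZoneLayout = field(default_factory=ZoneLayout)

    def __post_init__(self) -> None:
        self.tracking_t = np.asarray(self.tracking_t, dtype=float)
        self.tracking_x = np.asarray(self.tracking_x, dtype=float)
        self.tracking_y = np.asarray(self.tracking_y, dtype=float)
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.tracking_t.size and np.any(np.diff(self.tracking_t) <= 0):
            raise SessionError("bad-timeline: tracking times must strictly increase")
        t0, t1 = (self.tracking_t[0], self.tracking_t[-1]) if self.tracking_t.size else (0, 0)
        for uid, st in self.spikes.items():
            st = np.asarray(st, dtype=float)
            if np.any(np.diff(st) < 0):
                raise SessionError(f"spike times for unit {uid} are not sorted")
            if st.size and (st[0] < t0 - 1.0 or st[-1] > t1 + 1.0):
                raise SessionError(
                    f"spike times for unit {uid} fall outside the tracking span"
                )
            self.spikes[uid] = st

    @property
    def span(self) -> tuple[float, float]:
        return float(self.tracking_t[0]), float(self.tracking_t[-1])

    @property
    def duration(self) -> float:
        a, b = self.span
        return b - a


@dataclass
class BehaviorFrame:
    """100-Hz resampled behavioral timeline.

    ``direction`` is the heading of the displacement over one 10-ms step,
    NaN where the (smoothed) displacement is zero. ``valid`` requires speed
    above the 2.5-cm/s gate and no tracking gap at that frame.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    direction: np.ndarray  # deg in [0, 360) or NaN
    speed: np.ndarray  # cm/s, >= 0
    valid: np.ndarray  # bool
    theta_phase: np.ndarray | None = None  # deg in [0, 360) or NaN

    def __len__(self) -> int:
        return self.t.size

    def index_of(self, times: np.ndarray) -> np.ndarray:
        """Nearest-frame index of arbitrary times (clipped to the span)."""
        idx = np.round((np.asarray(times) - self.t[0]) * BEHAVIOR_RATE_HZ).astype(int)
        return np.clip(idx, 0, len(self) - 1)

    def with_phase(self, phase: np.ndarray) -> "BehaviorFrame":
        valid = self.valid & np.isfinite(phase)
        return BehaviorFrame(self.t, self.x, self.y, self.direction, self.speed,
                             valid, theta_phase=phase)


@dataclass(frozen=True)
class UnitInfo:
    unit_id: str
    mean_rate: float
    burst_index: float
    has_early_acg_peak: bool
    cell_class: CellClass


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [0, 360)."""
    return np.mod(angle, 360.0)


def ang_diff_deg(a, b):
    """Signed angular difference a - b in (-180, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d)


def resample_behavior(session: SessionRecording) -> BehaviorFrame:
    """Resample tracking to the 100-Hz analysis grid.

    Positions are linearly interpolated; speed and heading are computed on a
    Gaussian-smoothed (50-ms SD) copy of the positions so that camera jitter
    does not dominate the derivative. Frames falling inside tracking gaps
    longer than 200 ms, or slower than the 2.5-cm/s run-speed gate, are
    marked invalid.
    """
    t_src = session.tracking_t
    if t_src.size == 0:
        raise SessionError("no-tracking: session has no tracking samples")
    if t_src.size < 2:
        raise SessionError("no-tracking: need at least 2 tracking samples")

    t0, t1 = session.span
    n = int(np.floor((t1 - t0) * BEHAVIOR_RATE_HZ)) + 1
    t = t0 + np.arange(n) * BEHAVIOR_DT
    x = np.interp(t, t_src, session.tracking_x)
    y = np.interp(t, t_src, session.tracking_y)

    # smooth only for differentiation; exported positions stay interpolated
    sigma = POSITION_SMOOTH_SD_S * BEHAVIOR_RATE_HZ
    xs = gaussian_filter1d(x, sigma, mode="nearest")
    ys = gaussian_filter1d(y, sigma, mode="nearest")

    dx = np.empty(n)
    dy = np.empty(n)
    dx[:-1] = np.diff(xs)
    dy[:-1] = np.diff(ys)
    dx[-1] = dx[-2] if n > 1 else 0.0
    dy[-1] = dy[-2] if n > 1 else 0.0

    speed = np.hypot(dx, dy) / BEHAVIOR_DT
    with np.errstate(invalid="ignore"):
        direction = wrap_deg(np.degrees(np.arctan2(dy, dx)))
    direction = np.where(np.hypot(dx, dy) == 0.0, np.nan, direction)

    valid = speed > SPEED_GATE_CM_S

    # invalidate frames interpolated across tracking gaps > 200 ms
    gaps = np.flatnonzero(np.diff(t_src) > TRACKING_GAP_S)
    for g in gaps:
        valid &= ~((t > t_src[g]) & (t < t_src[g + 1]))

    return BehaviorFrame(t=t, x=x, y=y, direction=direction, speed=speed, valid=valid)


# --------------------------------------------------------------------------
# unit classification
# --------------------------------------------------------------------------


def autocorrelogram(
    spike_times: np.ndarray, bin_ms: float = 1.0, max_lag_ms: float = 300.0
) -> np.ndarray:
    """Spike-train autocorrelogram as counts per lag bin (positive lags).

    Bin ``i`` covers lags ``[i, i+1)`` ms; the zero-lag bin excludes the
    self-pairs.
    """
    st = np.asarray(spike_times, dtype=float)
    n_bins = int(round(max_lag_ms / bin_ms))
    counts = np.zeros(n_bins, dtype=float)
    if st.size < 2:
        return counts
    max_lag = max_lag_ms / 1000.0
    hi = np.searchsorted(st, st + max_lag, side="left")
    for i in range(st.size):
        lags = st[i + 1 : hi[i]] - st[i]
        if lags.size:
            idx = np.minimum((lags * 1000.0 / bin_ms).astype(int), n_bins - 1)
            np.add.at(counts, idx, 1.0)
    return counts


def classify_unit(
    spike_times: np.ndarray, duration: float, unit_id: str = "unit"
) -> UnitInfo:
    """Classify a unit as putative pyramidal cell / interneuron.

    Pyramidal criteria: mean rate < 5 Hz, burst index > 2 and a prominent
    early autocorrelogram peak (3-18 ms at least twice the 200-300-ms
    baseline). The burst index is the mean autocorrelogram value in the
    3-6-ms band divided by the 200-300-ms baseline mean.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    st = np.asarray(spike_times, dtype=float)
    mean_rate = st.size / duration
    if st.size < 50:
        return UnitInfo(unit_id, mean_rate, np.nan, False, CellClass.UNCLASSIFIED)

    acg = autocorrelogram(st)
    baseline = float(np.mean(acg[200:300]))
    if baseline <= 0:
        burst_index = np.inf if np.mean(acg[3:6]) > 0 else 0.0
        early_peak = bool(np.max(acg[3:18]) > 0)
    else:
        burst_index = float(np.mean(acg[3:6]) / baseline)
        early_peak = bool(np.max(acg[3:18]) >= 2.0 * baseline)

    if mean_rate < 5.0 and burst_index > 2.0 and early_peak:
        cls = CellClass.PYRAMIDAL
    elif mean_rate >= 5.0 and burst_index <= 2.0:
        cls = CellClass.INTERNEURON
    else:
        cls = CellClass.UNCLASSIFIED
    return UnitInfo(unit_id, mean_rate, burst_index, early_peak, cls)


# --------------------------------------------------------------------------
# session I/O (HDF5 container + CSV export)
# --------------------------------------------------------------------------

_REQUIRED_GROUPS = ("tracking", "spikes", "lfp", "events", "zones", "meta")


def write_session(
    session: SessionRecording, path: str | Path, ground_truth: Mapping | None = None
) -> None:
    """Write a session to one HDF5 file (groups /tracking, /spikes/<unit>,
    /lfp, /events, /zones, /meta); optionally a JSON ground-truth sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("tracking")
        g.create_dataset("t", data=session.tracking_t)
        g.create_dataset("x", data=session.tracking_x)
        g.create_dataset("y", data=session.tracking_y)
        g = f.create_group("spikes")
        for uid, st in session.spikes.items():
            g.create_dataset(uid, data=st)
        g = f.create_group("lfp")
        g.create_dataset("samples", data=session.lfp)
        g.attrs["sample_rate"] = session.lfp_rate
        g = f.create_group("events")
        ev = session.events
        g.create_dataset("kind", data=np.array([e.kind for e in ev], dtype="S"))
        g.create_dataset("t", data=np.array([e.t for e in ev], dtype=float))
        g.create_dataset(
            "zone_id", data=np.array([e.zone_id or "" for e in ev], dtype="S")
        )
        g = f.create_group("zones")
        g.attrs["arena_center"] = session.zones.arena_center
        g.attrs["arena_radius"] = session.zones.arena_radius
        zs = [session.zones.goal_zone, *session.zones.foraging_zones]
        g.create_dataset("zone_id", data=np.array([z.zone_id for z in zs], dtype="S"))
        g.create_dataset("type_label", data=np.array([z.type_label for z in zs], dtype="S"))
        g.create_dataset("center", data=np.array([z.center for z in zs], dtype=float))
        g.create_dataset("radius", data=np.array([z.radius for z in zs], dtype=float))
        g = f.create_group("meta")
        g.attrs["session_id"] = session.session_id
        g.attrs["condition"] = session.condition.value
    if ground_truth is not None:
        sidecar_path(path).write_text(json.dumps(ground_truth, indent=1))


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".truth.json")


def read_session(path: str | Path) -> SessionRecording:
    """Read a session container written by :func:`write_session`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for grp in _REQUIRED_GROUPS:
            if grp not in f:
                raise SessionError(f"missing: {grp}")
        tr = f["tracking"]
        spikes = {uid: np.asarray(ds[()], dtype=float) for uid, ds in f["spikes"].items()}
        lfp_rate = float(f["lfp"].attrs["sample_rate"])
        if lfp_rate != 1000.0:
            raise SessionError(f"unsupported lfp sample rate {lfp_rate}")
        ev_kind = [s.decode() for s in f["events"]["kind"][()]]
        ev_t = f["events"]["t"][()]
        ev_zone = [s.decode() or None for s in f["events"]["zone_id"][()]]
        events = [Event(k, float(t), z) for k, t, z in zip(ev_kind, ev_t, ev_zone)]
        zg = f["zones"]
        ids = [s.decode() for s in zg["zone_id"][()]]
        labels = [s.decode() for s in zg["type_label"][()]]
        centers = zg["center"][()]
        radii = zg["radius"][()]
        zone_objs = [
            Zone(i, lab, (float(c[0]), float(c[1])), float(r))
            for i, lab, c, r in zip(ids, labels, centers, radii)
        ]
        goal = next(z for z in zone_objs if z.type_label == "goal")
        forag = tuple(z for z in zone_objs if z.type_label != "goal")
        zones = ZoneLayout(
            arena_center=tuple(zg.attrs["arena_center"]),
            arena_radius=float(zg.attrs["arena_radius"]),
            goal_zone=goal,
            foraging_zones=forag,
        )
        session = SessionRecording(
            session_id=str(f["meta"].attrs["session_id"]),
            condition=Condition(str(f["meta"].attrs["condition"])),
            tracking_t=tr["t"][()],
            tracking_x=tr["x"][()],
            tracking_y=tr["y"][()],
            spikes=spikes,
            lfp=f["lfp"]["samples"][()],
            lfp_rate=lfp_rate,
            events=events,
            zones=zones,
        )
    return session


def read_ground_truth(path: str | Path) -> dict | None:
    sp = sidecar_path(path)
    return json.loads(sp.read_text()) if sp.exists() else None


def export_csv(session: SessionRecording, out_dir: str | Path) -> None:
    """Write human-readable CSV copies of /tracking and /events."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"t": session.tracking_t, "x": session.tracking_x, "y": session.tracking_y}
    ).to_csv(out / f"{session.session_id}_tracking.csv", index=False)
    pd.DataFrame(
        [{"kind": e.kind, "t": e.t, "zone_id": e.zone_id} for e in session.events]
    ).to_csv(out / f"{session.session_id}_events.csv", index=False)
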