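"""Theta-phase extraction, phase tuning, and theta-phase precession.

The LFP is zero-phase band-passed at 6-9 Hz; local maxima closer than
60 ms to the previously retained peak are discarded and the instantaneous
phase is the elapsed fraction of the inter-peak interval (0-360 deg, 0 at
each retained peak).

Phase tuning divides circularly smoothed (20-deg-SD Gaussian) spike-count
and occupancy histograms over 18 x 20-deg phase bins; the theta modulation
index is the amplitude of the best-fitting sinusoid divided by the mean of
the tuning curve, with circular-shift-shuffle significance.

Phase precession correlates the spike phase with the position of the
animal in the place field projected on its running direction (pdcd,
normalized so that -1/0/+1 mark field entry / center of mass / exit). The
slope maximizes the resultant length of the phase residuals, the
circular-linear correlation and its z statistic follow the standard
construction, and ``p = 1 - erf(|z|/sqrt(2))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage, signal
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, QhullError
from scipy.special import erf

from .core import ARENA_RADIUS_CM, BEHAVIOR_DT, BehaviorFrame, SPATIAL_BIN_CM
from .placefields import RateMap, ShuffleEnsemble, circular_shift_shuffle

THETA_BAND_HZ = (6.0, 9.0)
PEAK_REFRACTORY_S = 0.06
N_PHASE_BINS = 18  # 20-deg bins
PHASE_SMOOTH_SD_BINS = 1.0  # 20-deg Gaussian SD
MIN_SPIKES_PHASE = 30
PRECESSION_ALPHA = 0.025
MIN_PHASE_COVERAGE_DEG = 45.0
MIN_SPIKES_IN_FIELD = 30
# Physiological precession advances less than one theta cycle per field
# traversal; a traversal spans pdcd -1..+1, so |slope| < 0.5 cycles per pdcd
# unit. Widening the search range inflates the resultant-maximization
# statistic under the null (slope selection acts like multiple testing),
# so the search is restricted to the physiological range.
SLOPE_RANGE = 0.5  # cycles per pdcd unit
SLOPE_GRID_STEP = 0.01


# --------------------------------------------------------------------------
# phase extraction
# --------------------------------------------------------------------------


@dataclass
class ThetaPhaseSeries:
    peaks: np.ndarray  # retained peak times (s)
    phase: np.ndarray  # per-frame phase, deg in [0, 360) or NaN
    coverage: np.ndarray  # bool, frames between retained peaks

    def phase_at(self, times: np.ndarray) -> np.ndarray:
        return phase_between_peaks(np.asarray(times, float), self.peaks)


def retain_peaks(candidates: np.ndarray, refractory: float = PEAK_REFRACTORY_S) -> np.ndarray:
    """Sequential scan keeping peaks at least ``refractory`` apart."""
    kept: list[float] = []
    for t in np.asarray(candidates, dtype=float):
        if not kept or t - kept[-1] >= refractory:
            kept.append(t)
    return np.array(kept)


def phase_between_peaks(times: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Phase = 360 * elapsed fraction of the surrounding inter-peak interval."""
    phase = np.full(times.shape, np.nan)
    if peaks.size < 2:
        return phase
    idx = np.searchsorted(peaks, times, side="right") - 1
    ok = (idx >= 0) & (idx < peaks.size - 1)
    p0 = peaks[np.clip(idx, 0, peaks.size - 2)]
    p1 = peaks[np.clip(idx + 1, 1, peaks.size - 1)]
    with np.errstate(invalid="ignore"):
        ph = 360.0 * (times - p0) / (p1 - p0)
    phase[ok] = np.clip(ph[ok], 0.0, np.nextafter(360.0, 0.0))
    return phase


def extract_theta_phase(
    lfp: np.ndarray,
    frame: BehaviorFrame,
    lfp_rate: float = 1000.0,
    lfp_t0: float = 0.0,
) -> ThetaPhaseSeries:
    """Band-pass the LFP at 6-9 Hz (zero-phase) and convert peak-to-peak
    intervals into per-frame phases."""
    nyq = lfp_rate / 2.0
    b, a = signal.butter(3, [THETA_BAND_HZ[0] / nyq, THETA_BAND_HZ[1] / nyq], "bandpass")
    filt = signal.filtfilt(b, a, np.asarray(lfp, dtype=float))
    cand_idx, _ = signal.find_peaks(filt)
    peaks = retain_peaks(lfp_t0 + cand_idx / lfp_rate)
    phase = phase_between_peaks(frame.t, peaks)
    coverage = np.isfinite(phase)
    return ThetaPhaseSeries(peaks=peaks, phase=phase, coverage=coverage)


# --------------------------------------------------------------------------
# phase tuning and modulation index
# --------------------------------------------------------------------------


@dataclass
class PhaseTuning:
    rate: np.ndarray  # (18,) Hz per 20-deg bin (smoothed)
    amplitude: float
    preferred_phase: float  # deg
    offset: float
    modulation_index: float
    n_spikes: int
    sig_modulation: bool = False


def _phase_bin_rate(
    spike_phases: np.ndarray, frame_phases: np.ndarray, smooth_sd: float = PHASE_SMOOTH_SD_BINS
) -> np.ndarray:
    """Occupancy-normalized phase tuning with circular Gaussian smoothing."""
    width = 360.0 / N_PHASE_BINS
    sp = np.clip((spike_phases // width).astype(int), 0, N_PHASE_BINS - 1)
    fp = np.clip((frame_phases // width).astype(int), 0, N_PHASE_BINS - 1)
    cnt = np.bincount(sp, minlength=N_PHASE_BINS).astype(float)
    occ = np.bincount(fp, minlength=N_PHASE_BINS).astype(float) * BEHAVIOR_DT
    if smooth_sd > 0:
        cnt = gaussian_filter1d(cnt, smooth_sd, mode="wrap")
        occ = gaussian_filter1d(occ, smooth_sd, mode="wrap")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, cnt / np.maximum(occ, 1e-300), 0.0)
    return rate


def fit_sinusoid(rate: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least-squares fit of ``c + A cos(phi - phi0)`` on the
    phase-bin centers. Returns (A, phi0 deg, c)."""
    centers = np.radians((np.arange(N_PHASE_BINS) + 0.5) * 360.0 / N_PHASE_BINS)
    b = 2.0 * np.mean(rate * np.cos(centers))
    c = 2.0 * np.mean(rate * np.sin(centers))
    amp = float(np.hypot(b, c))
    phi0 = float(np.degrees(np.arctan2(c, b)) % 360.0)
    return amp, phi0, float(np.mean(rate))


def modulation_index_of(rate: np.ndarray) -> float:
    amp, _, mean = fit_sinusoid(rate)
    return float(amp / mean) if mean > 0 else 0.0


def phase_tuning(
    spikes: np.ndarray,
    phase_series: ThetaPhaseSeries,
    frame: BehaviorFrame,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
) -> PhaseTuning:
    """Theta-phase tuning curve, sinusoid fit and shuffle significance.

    With fewer than 30 phase-defined spikes the tuning is still returned
    but ``sig_modulation`` is forced false.
    """
    rng = np.random.default_rng() if rng is None else rng
    spikes = np.asarray(spikes, dtype=float)
    ok_frames = frame.valid & phase_series.coverage
    idx = frame.index_of(spikes)
    sp_ok = ok_frames[idx]
    sp_phase = phase_series.phase_at(spikes[sp_ok])
    sp_phase = sp_phase[np.isfinite(sp_phase)]
    fr_phase = phase_series.phase[ok_frames]

    rate = _phase_bin_rate(sp_phase, fr_phase)
    amp, phi0, offset = fit_sinusoid(rate)
    index = float(amp / offset) if offset > 0 else 0.0
    tuning = PhaseTuning(rate, amp, phi0, offset, index, n_spikes=sp_phase.size)

    if sp_phase.size < MIN_SPIKES_PHASE:
        return tuning

    span = (float(frame.t[0]), float(frame.t[-1]) + BEHAVIOR_DT)
    shifted = circular_shift_shuffle(spikes, span, n=n_shuffles, rng=rng)
    sh_idx = frame.index_of(shifted.ravel())
    sh_keep = ok_frames[sh_idx].reshape(n_shuffles, -1)
    sh_phase = phase_series.phase_at(shifted.ravel()).reshape(n_shuffles, -1)
    width = 360.0 / N_PHASE_BINS
    occ = np.bincount(
        np.clip((fr_phase // width).astype(int), 0, N_PHASE_BINS - 1),
        minlength=N_PHASE_BINS,
    ).astype(float) * BEHAVIOR_DT
    occ = gaussian_filter1d(occ, PHASE_SMOOTH_SD_BINS, mode="wrap")
    null = np.empty(n_shuffles)
    good = sh_keep & np.isfinite(sh_phase)
    sh_binned = np.nan_to_num(sh_phase, nan=0.0) // width
    bins = np.where(good, np.clip(sh_binned.astype(int), 0, N_PHASE_BINS - 1), 0)
    flat = bins + np.arange(n_shuffles)[:, None] * N_PHASE_BINS
    cnts = np.bincount(
        flat.ravel()[good.ravel()], minlength=n_shuffles * N_PHASE_BINS
    ).reshape(n_shuffles, N_PHASE_BINS).astype(float)
    cnts = gaussian_filter1d(cnts, PHASE_SMOOTH_SD_BINS, mode="wrap", axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, cnts / np.maximum(occ, 1e-300), 0.0)
    for i in range(n_shuffles):
        null[i] = modulation_index_of(rates[i])
    tuning.sig_modulation = bool(index > np.percentile(null, 95))
    return tuning


# --------------------------------------------------------------------------
# field boundary and pdcd
# --------------------------------------------------------------------------


@dataclass
class FieldBoundary:
    significant: np.ndarray  # (N, N) bool, chosen subfield only
    hull: np.ndarray  # (k, 2) hull vertices, cm, counterclockwise
    com: tuple[float, float]  # rate-weighted centroid of the subfield

    @property
    def path(self) -> MplPath:
        return MplPath(self.hull)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        return self.path.contains_points(pts, radius=1e-9)


def _bin_centers(mask: np.ndarray) -> np.ndarray:
    ix, iy = np.nonzero(mask)
    return np.column_stack(
        [
            -ARENA_RADIUS_CM + (ix + 0.5) * SPATIAL_BIN_CM,
            -ARENA_RADIUS_CM + (iy + 0.5) * SPATIAL_BIN_CM,
        ]
    )


def field_boundary(rmap: RateMap, ensemble: ShuffleEnsemble) -> FieldBoundary | None:
    """Significant-bin subfield, convex hull and center of mass.

    Bins whose rate exceeds the per-bin 95th percentile of the shuffle
    maps are kept; 4-connected components are labeled and only the
    largest-area subfield is analyzed. Returns None when no bin is
    significant.
    """
    sig = rmap.valid & np.isfinite(ensemble.percentile95) & (
        np.nan_to_num(rmap.rate, nan=-np.inf) > ensemble.percentile95
    )
    if not np.any(sig):
        return None
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_comp = ndimage.label(sig, structure=structure)
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    sub = labels == best

    centers = _bin_centers(sub)
    w = rmap.rate[sub]
    com = tuple(np.average(centers, axis=0, weights=w))
    try:
        hull = ConvexHull(centers)
        verts = centers[hull.vertices]
    except QhullError:  # < 3 bins or collinear: use the bin squares' corners
        h = SPATIAL_BIN_CM / 2.0
        corners = np.concatenate(
            [centers + [dx, dy] for dx in (-h, h) for dy in (-h, h)]
        )
        verts = corners[ConvexHull(corners).vertices]
    return FieldBoundary(significant=sub, hull=verts, com=(float(com[0]), float(com[1])))


def _ray_exit_distance(boundary: FieldBoundary, origin: np.ndarray, u: np.ndarray) -> float:
    """Distance from origin to the hull boundary along direction u."""
    verts = boundary.hull
    p1 = verts
    p2 = np.roll(verts, -1, axis=0)
    e = p2 - p1
    # solve origin + t*u = p1 + s*e, 0<=s<=1, t>0
    denom = u[0] * (-e[:, 1]) - u[1] * (-e[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        d = p1 - origin
        t = (d[:, 0] * (-e[:, 1]) - d[:, 1] * (-e[:, 0])) / denom
        s = (u[0] * d[:, 1] - u[1] * d[:, 0]) / denom
    ok = np.isfinite(t) & (t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9)
    if not np.any(ok):
        return np.nan
    return float(np.min(t[ok]))


def pdcd_of(
    x: np.ndarray, y: np.ndarray, direction_deg: np.ndarray, boundary: FieldBoundary
) -> np.ndarray:
    """Position in the field projected on the running direction.

    Signed distance from the field's center of mass along the unit running
    direction, normalized by the COM-to-hull distance along that direction
    (-1 at field entry, 0 at the COM, +1 at the exit). NaN where the
    direction is undefined.
    """
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    direction_deg = np.atleast_1d(np.asarray(direction_deg, float))
    com = np.array(boundary.com)
    out = np.full(x.shape, np.nan)
    for i in range(x.size):
        if not np.isfinite(direction_deg[i]):
            continue
        u = np.array(
            [np.cos(np.radians(direction_deg[i])), np.sin(np.radians(direction_deg[i]))]
        )
        raw = (x[i] - com[0]) * u[0] + (y[i] - com[1]) * u[1]
        norm = _ray_exit_distance(boundary, com, u if raw >= 0 else -u)
        if np.isfinite(norm) and norm > 0:
            out[i] = raw / norm
    return out


def compute_pdcd(
    frame: BehaviorFrame, boundary: FieldBoundary, spike_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spike (pdcd, spike time) for spikes inside the field hull.

    Spikes on invalid frames or with undefined running direction are
    dropped.
    """
    spikes = np.asarray(spike_times, dtype=float)
    idx = frame.index_of(spikes)
    ok = frame.valid[idx] & np.isfinite(frame.direction[idx])
    ok &= boundary.contains(frame.x[idx], frame.y[idx])
    spikes = spikes[ok]
    idx = idx[ok]
    d = pdcd_of(frame.x[idx], frame.y[idx], frame.direction[idx], boundary)
    fine = np.isfinite(d)
    return d[fine], spikes[fine]


# --------------------------------------------------------------------------
# circular-linear fit and precession test
# --------------------------------------------------------------------------


@dataclass
class PrecessionResult:
    slope: float  # cycles per pdcd unit
    rho: float
    z: float
    p: float
    phase_coverage: float  # deg
    n_spikes_in_field: int
    significant: bool


def circular_linear_fit(phases_deg: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Slope and circular-linear correlation of phase against pdcd.

    The slope s (in cycles per pdcd unit, searched over the physiological
    range +-0.5) maximizes
    the mean resultant length of ``phase - 360*s*d``; the correlation is
    computed between the spike phases and ``theta_k = 2*pi*|s|*d_k`` using
    circular means.
    """
    phi = np.radians(np.asarray(phases_deg, dtype=float))
    d = np.asarray(d, dtype=float)

    def neg_resultant(s: float) -> float:
        return -np.abs(np.mean(np.exp(1j * (phi - 2 * np.pi * s * d))))

    grid = np.arange(-SLOPE_RANGE, SLOPE_RANGE + SLOPE_GRID_STEP / 2, SLOPE_GRID_STEP)
    vals = np.abs(np.mean(np.exp(1j * (phi[None, :] - 2 * np.pi * grid[:, None] * d[None, :])), axis=1))
    s0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        neg_resultant,
        bounds=(max(-SLOPE_RANGE, s0 - SLOPE_GRID_STEP), min(SLOPE_RANGE, s0 + SLOPE_GRID_STEP)),
        method="bounded",
    )
    s = float(res.x)

    theta = 2 * np.pi * np.abs(s) * d
    rho = _circ_corr(phi, theta)
    return s, rho


def _circ_mean(a: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * a))))


def _circ_corr(phi: np.ndarray, theta: np.ndarray) -> float:
    sp = np.sin(phi - _circ_mean(phi))
    st = np.sin(theta - _circ_mean(theta))
    den = np.sqrt(np.sum(sp**2) * np.sum(st**2))
    if den == 0:
        return np.nan
    return float(np.sum(sp * st) / den)


def precession_test(
    phases_deg: np.ndarray, d: np.ndarray, fit: tuple[float, float] | None = None
) -> PrecessionResult:
    """Significance of theta-phase precession.

    ``z = rho * sqrt(S20 * S02 / S22)`` with
    ``Sij = sum sin^i(phi - mean) sin^j(theta - mean)``, and
    ``p = 1 - erf(|z| / sqrt(2))``. A cell precesses significantly when
    p < .025, the phase coverage across the field traversal exceeds 45 deg
    and at least 30 spikes fall inside the field.
    """
    phases_deg = np.asarray(phases_deg, dtype=float)
    d = np.asarray(d, dtype=float)
    n = phases_deg.size
    if fit is None:
        fit = circular_linear_fit(phases_deg, d)
    s, rho = fit
    phi = np.radians(phases_deg)
    theta = 2 * np.pi * np.abs(s) * d
    sp = np.sin(phi - _circ_mean(phi))
    st = np.sin(theta - _circ_mean(theta))
    s20 = np.sum(sp**2)
    s02 = np.sum(st**2)
    s22 = np.sum(sp**2 * st**2)
    if s22 <= 0 or not np.isfinite(rho):
        z, p = 0.0, 1.0
    else:
        z = float(rho * np.sqrt(s20 * s02 / s22))
        p = float(1.0 - erf(np.abs(z) / np.sqrt(2.0)))
    coverage = 360.0 * np.abs(s) * (d.max() - d.min()) if n else 0.0
    significant = bool(
        p < PRECESSION_ALPHA and coverage > MIN_PHASE_COVERAGE_DEG and n >= MIN_SPIKES_IN_FIELD
    )
    return PrecessionResult(
        slope=s, rho=rho, z=z, p=p, phase_coverage=float(coverage),
        n_spikes_in_field=int(n), significant=significant,
    )


# --------------------------------------------------------------------------
# clean-run selection
# --------------------------------------------------------------------------


def select_clean_runs(
    frame: BehaviorFrame, boundary: FieldBoundary
) -> list[tuple[int, int]]:
    """Index spans (start, stop) of fast straight central field traversals.

    A contiguous in-field run is retained iff min speed > 5 cm/s, mean
    speed > 10 cm/s, circular SD of the heading < 30 deg, and it passes
    within |pdcd| < 0.2 of the field center.
    """
    inside = boundary.contains(frame.x, frame.y) & frame.valid
    runs: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(inside.astype(int)))
    starts = edges[inside[edges + 1]] + 1 if edges.size else np.array([], int)
    stops = edges[~inside[np.minimum(edges + 1, inside.size - 1)]] + 1 if edges.size else np.array([], int)
    if inside[0]:
        starts = np.concatenate(([0], starts))
    if inside[-1]:
        stops = np.concatenate((stops, [inside.size]))
    for a, b in zip(starts, stops):
        if b - a < 2:
            continue
        sp = frame.speed[a:b]
        di = frame.direction[a:b]
        di = di[np.isfinite(di)]
        if di.size == 0 or sp.min() <= 5.0 or sp.mean() <= 10.0:
            continue
        rbar = np.abs(np.mean(np.exp(1j * np.radians(di))))
        circ_sd = np.degrees(np.sqrt(max(-2.0 * np.log(max(rbar, 1e-12)), 0.0)))
        if circ_sd >= 30.0:
            continue
        d = pdcd_of(frame.x[a:b], frame.y[a:b], frame.direction[a:b], boundary)
        d = d[np.isfinite(d)]
        if d.size and np.min(np.abs(d)) < 0.2:
            runs.append((int(a), int(b)))
    return runs
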