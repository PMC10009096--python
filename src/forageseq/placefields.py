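"""Occupancy-normalized rate maps and place-cell classification.

A place field is the ratio of a spike-count map to an occupancy map on a
5-cm grid, both smoothed with a 5-cm-SD Gaussian; bins visited on fewer
than 3 trials are masked out before smoothing. Spatial tuning strength is
the sparsity ``1 - (sum R)^2 / (N sum R^2)`` over the N valid bins.

Significance is shuffle-based throughout: spike trains are circularly
shifted by a uniform random delay (> 5 s) 500 times; a cell is
significantly tuned when its observed strength exceeds the 95th percentile
of the shuffled strengths. Predictive power is assessed by 10-fold
cross-validated Poisson likelihood against a constant-rate prediction, and
stability by the place-field correlation between sessions against
shuffle-vs-shuffle correlations. A putative pyramidal cell is a place cell
when all three criteria are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import chi2

from .core import ARENA_RADIUS_CM, BEHAVIOR_DT, BehaviorFrame, SPATIAL_BIN_CM

N_BINS = int(round(2 * ARENA_RADIUS_CM / SPATIAL_BIN_CM))
SMOOTH_SD_BINS = 1.0  # 5-cm Gaussian SD on a 5-cm grid
MIN_TRIAL_VISITS = 3
N_SHUFFLES = 500
MIN_SHIFT_S = 5.0
SIG_ALPHA = 0.05


class CoverageError(ValueError):
    """Raised when a session has no valid spatial coverage."""


# --------------------------------------------------------------------------
# rate maps
# --------------------------------------------------------------------------


def position_bins(frame: BehaviorFrame) -> np.ndarray:
    """Flat 5-cm-bin index of every frame."""
    bx = np.clip(((frame.x + ARENA_RADIUS_CM) / SPATIAL_BIN_CM).astype(int), 0, N_BINS - 1)
    by = np.clip(((frame.y + ARENA_RADIUS_CM) / SPATIAL_BIN_CM).astype(int), 0, N_BINS - 1)
    return bx * N_BINS + by


def visit_mask(
    frame: BehaviorFrame, trial_spans: list[tuple[float, float]] | None
) -> np.ndarray:
    """Bins visited on at least MIN_TRIAL_VISITS trials (bool, N x N).

    Without trial spans every bin with valid occupancy is kept.
    """
    bins = position_bins(frame)
    if not trial_spans:
        occ = np.bincount(bins[frame.valid], minlength=N_BINS * N_BINS)
        return (occ > 0).reshape(N_BINS, N_BINS)
    visits = np.zeros(N_BINS * N_BINS, dtype=int)
    for t0, t1 in trial_spans:
        i0, i1 = frame.index_of(np.array([t0, t1]))
        sel = bins[i0 : i1 + 1][frame.valid[i0 : i1 + 1]]
        visits[np.unique(sel)] += 1
    return (visits >= MIN_TRIAL_VISITS).reshape(N_BINS, N_BINS)


@dataclass
class RateMap:
    rate: np.ndarray  # (N, N) Hz; NaN on invalid bins
    valid: np.ndarray  # (N, N) bool
    occupancy: np.ndarray  # (N, N) raw seconds per bin (valid frames)
    n_spikes: int
    smoothing_sd_bins: float = SMOOTH_SD_BINS

    def strengths_input(self) -> np.ndarray:
        return self.rate[self.valid]


def _smooth_masked(img: np.ndarray, mask: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian smoothing restricted to a mask (zeros leak no mass in)."""
    return gaussian_filter(np.where(mask, img, 0.0), sd, mode="constant")


def spike_frame_counts(frame: BehaviorFrame, spikes: np.ndarray) -> np.ndarray:
    """Spike count per 10-ms frame (spikes outside the span are dropped)."""
    spikes = np.asarray(spikes, dtype=float)
    inside = (spikes >= frame.t[0]) & (spikes <= frame.t[-1] + BEHAVIOR_DT)
    idx = frame.index_of(spikes[inside])
    return np.bincount(idx, minlength=len(frame))


def estimate_rate_map(
    frame: BehaviorFrame,
    spikes: np.ndarray,
    trial_spans: list[tuple[float, float]] | None = None,
    valid_bins: np.ndarray | None = None,
    smooth_sd: float = SMOOTH_SD_BINS,
) -> RateMap:
    """Smoothed occupancy-normalized firing map.

    Count and occupancy maps are masked to bins visited on >= 3 trials,
    each smoothed with the 5-cm Gaussian, then divided.
    """
    if valid_bins is None:
        valid_bins = visit_mask(frame, trial_spans)
    bins = position_bins(frame)
    ok = frame.valid & valid_bins.reshape(-1)[bins]
    if not np.any(ok):
        raise CoverageError("no-coverage: no valid occupancy anywhere")

    occ = np.bincount(bins[ok], minlength=N_BINS * N_BINS).reshape(N_BINS, N_BINS)
    occ = occ * BEHAVIOR_DT
    counts = spike_frame_counts(frame, spikes)
    cnt = np.bincount(bins[ok], weights=counts[ok], minlength=N_BINS * N_BINS)
    cnt = cnt.reshape(N_BINS, N_BINS)

    if smooth_sd > 0:
        occ_s = _smooth_masked(occ, valid_bins, smooth_sd)
        cnt_s = _smooth_masked(cnt, valid_bins, smooth_sd)
    else:
        occ_s, cnt_s = occ * valid_bins, cnt * valid_bins
    rate = np.full((N_BINS, N_BINS), np.nan)
    good = valid_bins & (occ_s > 0)
    rate[good] = cnt_s[good] / occ_s[good]
    return RateMap(rate=rate, valid=good, occupancy=occ, n_spikes=int(cnt.sum()))


def spatial_tuning_strength(values: np.ndarray | RateMap) -> float:
    """Sparsity-based tuning strength ``1 - (sum R)^2 / (N sum R^2)``.

    0 for a constant map, ``1 - 1/N`` for a one-hot map; invariant to
    positive rescaling. All-zero input returns 0 by convention.
    """
    r = values.strengths_input() if isinstance(values, RateMap) else np.asarray(values, float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return 0.0
    ss = np.sum(r**2)
    if ss == 0:
        return 0.0
    return float(1.0 - np.sum(r) ** 2 / (r.size * ss))


# --------------------------------------------------------------------------
# circular-shift shuffles
# --------------------------------------------------------------------------


def circular_shift_shuffle(
    spikes: np.ndarray,
    span: tuple[float, float],
    n: int = N_SHUFFLES,
    min_shift: float = MIN_SHIFT_S,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Circularly shift a spike train by uniform random delays.

    Each of the ``n`` shuffles adds one delay drawn uniformly from
    ``[min_shift, span_length - min_shift]`` and wraps modulo the span;
    spike count and inter-spike intervals (up to the single wrap point) are
    preserved exactly. Returns an (n, n_spikes) array of shifted times.
    """
    rng = np.random.default_rng() if rng is None else rng
    t0, t1 = span
    length = t1 - t0
    if length <= 2 * min_shift:
        raise ValueError("span too short for the minimum circular shift")
    spikes = np.asarray(spikes, dtype=float)
    shifts = rng.uniform(min_shift, length - min_shift, size=n)
    return t0 + np.mod(spikes[None, :] - t0 + shifts[:, None], length)


@dataclass
class ShuffleEnsemble:
    """Summary of 500 circularly shifted rate maps for one cell."""

    strengths: np.ndarray  # (n,) shuffled tuning strengths
    percentile95: np.ndarray  # (N, N) per-bin 95th percentile rate
    maps: np.ndarray  # (n, N, N) shuffled rate maps (NaN outside mask)
    n: int = N_SHUFFLES


def shuffle_ensemble(
    frame: BehaviorFrame,
    spikes: np.ndarray,
    valid_bins: np.ndarray,
    n: int = N_SHUFFLES,
    rng: np.random.Generator | None = None,
    smooth_sd: float = SMOOTH_SD_BINS,
) -> ShuffleEnsemble:
    """Rate maps and tuning strengths of ``n`` circular-shift shuffles.

    All shuffles share the session's occupancy, so only the spike-count
    maps are recomputed (vectorized across shuffles).
    """
    bins = position_bins(frame)
    ok = frame.valid & valid_bins.reshape(-1)[bins]
    occ = np.bincount(bins[ok], minlength=N_BINS * N_BINS).reshape(N_BINS, N_BINS)
    occ = occ * BEHAVIOR_DT
    occ_s = _smooth_masked(occ, valid_bins, smooth_sd)

    span = (float(frame.t[0]), float(frame.t[-1]) + BEHAVIOR_DT)
    shifted = circular_shift_shuffle(spikes, span, n=n, rng=rng)
    idx = frame.index_of(shifted.ravel()).reshape(n, -1)
    keep = ok[idx]
    flat = np.where(keep, bins[idx], 0) + np.arange(n)[:, None] * (N_BINS * N_BINS)
    cnt = np.bincount(
        flat.ravel()[keep.ravel()], minlength=n * N_BINS * N_BINS
    ).reshape(n, N_BINS, N_BINS).astype(float)
    cnt *= valid_bins[None, :, :]
    cnt_s = gaussian_filter(cnt, (0, smooth_sd, smooth_sd), mode="constant")

    maps = np.full((n, N_BINS, N_BINS), np.nan)
    good = valid_bins & (occ_s > 0)
    maps[:, good] = cnt_s[:, good] / occ_s[good]
    strengths = np.array([spatial_tuning_strength(m[good]) for m in maps])
    pct = np.full((N_BINS, N_BINS), np.nan)
    pct[good] = np.percentile(maps[:, good], 95, axis=0)
    return ShuffleEnsemble(strengths=strengths, percentile95=pct, maps=maps, n=n)


def significance_tuning(observed_strength: float, ensemble: ShuffleEnsemble) -> bool:
    """Strictly above the linearly interpolated 95th shuffle percentile."""
    return bool(observed_strength > np.percentile(ensemble.strengths, 95))


# --------------------------------------------------------------------------
# cross-validated predictive power
# --------------------------------------------------------------------------


def cv_predictive_power(
    frame: BehaviorFrame,
    spikes: np.ndarray,
    valid_bins: np.ndarray,
    n_folds: int = 10,
    smooth_sd: float = SMOOTH_SD_BINS,
) -> tuple[float, float]:
    """Held-out log-likelihood gain of the place field and its LR p-value.

    The valid timeline is split into 10 contiguous blocks; each block's
    10-ms spike counts are predicted from the place field estimated on the
    other 90% and scored under a Poisson likelihood, against a
    constant-mean-rate prediction. The LR statistic ``2 * dLL`` is referred
    to a chi-square with ``valid bins - 1`` degrees of freedom.
    """
    bins = position_bins(frame)
    ok = frame.valid & valid_bins.reshape(-1)[bins]
    idx_ok = np.flatnonzero(ok)
    if idx_ok.size < n_folds:
        raise CoverageError("no-coverage: too few valid frames")
    counts = spike_frame_counts(frame, spikes)

    edges = np.linspace(0, idx_ok.size, n_folds + 1).astype(int)
    ll_map = 0.0
    ll_const = 0.0
    for k in range(n_folds):
        test = idx_ok[edges[k] : edges[k + 1]]
        train = np.concatenate([idx_ok[: edges[k]], idx_ok[edges[k + 1] :]])
        occ = np.bincount(bins[train], minlength=N_BINS * N_BINS).reshape(N_BINS, N_BINS)
        cnt = np.bincount(
            bins[train], weights=counts[train], minlength=N_BINS * N_BINS
        ).reshape(N_BINS, N_BINS)
        occ_s = _smooth_masked(occ * BEHAVIOR_DT, valid_bins, smooth_sd)
        cnt_s = _smooth_masked(cnt, valid_bins, smooth_sd)
        mean_rate = counts[train].sum() / (train.size * BEHAVIOR_DT)
        rate = np.full(N_BINS * N_BINS, mean_rate)
        covered = (occ_s > 0).reshape(-1)
        rate[covered] = cnt_s.reshape(-1)[covered] / occ_s.reshape(-1)[covered]

        y = counts[test]
        mu0 = max(mean_rate * BEHAVIOR_DT, 1e-12)
        # common floor: smoothed-count bins with no training spikes sit at
        # the likelihood boundary; held-out spikes there must not dominate
        mu = np.maximum(rate[bins[test]] * BEHAVIOR_DT, 0.01 * mu0)
        ll_map += float(np.sum(y * np.log(mu) - mu))
        ll_const += float(np.sum(y * np.log(mu0) - mu0))

    lr = 2.0 * (ll_map - ll_const)
    df = max(int(valid_bins.sum()) - 1, 1)
    p = float(chi2.sf(lr, df)) if lr > 0 else 1.0
    return ll_map - ll_const, p


# --------------------------------------------------------------------------
# stability and classification
# --------------------------------------------------------------------------


def field_stability(map_a: RateMap, map_b: RateMap) -> float:
    """Pearson correlation of two rate maps over commonly valid bins."""
    common = map_a.valid & map_b.valid
    if common.sum() < 3:
        return np.nan
    a = map_a.rate[common]
    b = map_b.rate[common]
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if den == 0:
        return np.nan
    return float(np.sum(a * b) / den)


def stability_significance(
    r_observed: float, ens_a: ShuffleEnsemble, ens_b: ShuffleEnsemble
) -> bool:
    """Observed stability against shuffle-vs-shuffle correlations.

    Shuffle i of session a is paired with shuffle i of session b; the
    observed correlation must exceed the 95th percentile of the null
    correlations (strictly).
    """
    n = min(ens_a.n, ens_b.n)
    common = np.isfinite(ens_a.maps[0]) & np.isfinite(ens_b.maps[0])
    if common.sum() < 3 or not np.isfinite(r_observed):
        return False
    a = ens_a.maps[:n][:, common]
    b = ens_b.maps[:n][:, common]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    den = np.sqrt(np.sum(a**2, axis=1) * np.sum(b**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r = np.sum(a * b, axis=1) / den
    null_r = null_r[np.isfinite(null_r)]
    if null_r.size == 0:
        return False
    return bool(r_observed > np.percentile(null_r, 95))


@dataclass
class PlaceCellResult:
    unit_id: str
    tuning_strength: float
    sig_tuning: bool
    prediction_gain: float
    prediction_p: float
    sig_prediction: bool
    stability_r: float
    sig_stability: bool
    is_place_cell: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_place_cell = bool(
            self.sig_tuning and self.sig_prediction and self.sig_stability
        )


def classify_place_cell(
    unit_id: str,
    frame: BehaviorFrame,
    spikes: np.ndarray,
    trial_spans: list[tuple[float, float]] | None = None,
    frame_b: BehaviorFrame | None = None,
    spikes_b: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_shuffles: int = N_SHUFFLES,
) -> tuple[PlaceCellResult, RateMap, ShuffleEnsemble]:
    """Full place-cell test battery for one unit.

    Stability is computed between the (frame, spikes) data and the
    (frame_b, spikes_b) data when given; otherwise between the two halves
    of the session.
    """
    rng = np.random.default_rng() if rng is None else rng
    valid_bins = visit_mask(frame, trial_spans)
    rmap = estimate_rate_map(frame, spikes, valid_bins=valid_bins)
    strength = spatial_tuning_strength(rmap)
    ens = shuffle_ensemble(frame, spikes, valid_bins, n=n_shuffles, rng=rng)
    sig_tun = significance_tuning(strength, ens)
    gain, p = cv_predictive_power(frame, spikes, valid_bins)

    if frame_b is None:
        frame_a, spk_a, frame_b, spikes_b = _split_half(frame, spikes)
    else:
        frame_a, spk_a = frame, spikes
    vb_a = visit_mask(frame_a, None) & valid_bins
    vb_b = visit_mask(frame_b, None) & valid_bins
    try:
        map_a = estimate_rate_map(frame_a, spk_a, valid_bins=vb_a)
        map_b = estimate_rate_map(frame_b, spikes_b, valid_bins=vb_b)
        r = field_stability(map_a, map_b)
        ens_a = shuffle_ensemble(frame_a, spk_a, vb_a, n=n_shuffles, rng=rng)
        ens_b = shuffle_ensemble(frame_b, spikes_b, vb_b, n=n_shuffles, rng=rng)
        sig_stab = stability_significance(r, ens_a, ens_b)
    except (CoverageError, ValueError):
        r, sig_stab = np.nan, False

    res = PlaceCellResult(
        unit_id=unit_id,
        tuning_strength=strength,
        sig_tuning=sig_tun,
        prediction_gain=gain,
        prediction_p=p,
        sig_prediction=bool(p < SIG_ALPHA),
        stability_r=r,
        sig_stability=sig_stab,
    )
    return res, rmap, ens


def _split_half(frame: BehaviorFrame, spikes: np.ndarray):
    mid = len(frame) // 2
    t_mid = frame.t[mid]
    fa = BehaviorFrame(frame.t[:mid], frame.x[:mid], frame.y[:mid],
                       frame.direction[:mid], frame.speed[:mid], frame.valid[:mid])
    fb = BehaviorFrame(frame.t[mid:], frame.x[mid:], frame.y[mid:],
                       frame.direction[mid:], frame.speed[mid:], frame.valid[mid:])
    spikes = np.asarray(spikes)
    return fa, spikes[spikes < t_mid], fb, spikes[spikes >= t_mid]
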