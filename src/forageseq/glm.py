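"""Poisson GLM selectivity to position, direction and speed.

Spike counts in 10-ms frames are modeled as ``N = exp(a0 + B X)`` where B
one-hot-codes the binned behavioral state (position in 5-cm bins on the
place-field valid mask, movement direction in 20-deg bins, speed in
5-cm/s bins with an open top bin) and X holds one coefficient per occupied
bin. A forward model-selection procedure picks the covariate set: the best
single covariate by 10-fold cross-validated log-likelihood, then a second
(and third) covariate only when it improves the held-out likelihood
significantly (LR test on 2x the CV log-likelihood gain, df = number of
added coefficients), with a final gate against the constant-mean model.
Coefficients convert to firing-rate tuning curves by exponentiation and
Gaussian smoothing, and to tuning strengths via the sparsity index.

The likelihood is concave and the design is purely categorical, so the
solver is a dense Newton iteration whose gradient and Hessian are
assembled with bincount over the per-sample bin codes; one reference bin
per covariate is pinned at zero for identifiability (the mean-centering in
the tuning-curve conversion absorbs the gauge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.stats import chi2

from .core import BEHAVIOR_DT, BehaviorFrame
from .placefields import N_BINS, position_bins, spatial_tuning_strength, spike_frame_counts

SPEED_BIN_CM_S = 5.0
N_SPEED_BINS = 9  # [0,5), ..., [35,40), [40, inf)
N_DIR_BINS = 18
COV_ORDER = ("P", "D", "S")  # deterministic tie-break order
LR_ALPHA = 0.05
ETA_MAX = 5.0  # cap on log mean count per 10-ms frame
COEF_CAP = 15.0
# Held-out rates are floored at this fraction of the training mean rate:
# bins with occupancy but no training spikes sit at the likelihood boundary
# (log-rate -> -inf) and a single held-out spike there would otherwise
# dominate the CV comparison by an amount that depends on the capped
# coefficient rather than on the data. A common floor keeps the held-out
# likelihood finite and model-independent in such bins.
MIN_RATE_FRACTION = 0.01


class DegenerateCovariateError(ValueError):
    """A requested covariate occupies fewer than 2 bins."""


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------


@dataclass
class DesignData:
    """Per-sample bin codes for all three covariates plus spike counts."""

    y: np.ndarray  # (n,) spike counts per included 10-ms sample
    codes: dict[str, np.ndarray]  # covariate -> (n,) bin code
    n_bins: dict[str, int]  # covariate -> number of coded bins
    pos_columns: np.ndarray  # flat 20x20 grid index of every P code

    @property
    def n_samples(self) -> int:
        return self.y.size


def build_design(
    frame: BehaviorFrame, spikes: np.ndarray, valid_bins: np.ndarray
) -> DesignData:
    """Bin codes and spike counts on the common sample set.

    Samples must be valid (speed gate), fall in a position bin visited on
    enough trials, and have a defined movement direction, so that every
    candidate model in the forward selection sees identical data.
    """
    pos = position_bins(frame)
    ok = frame.valid & valid_bins.reshape(-1)[pos] & np.isfinite(frame.direction)
    counts = spike_frame_counts(frame, spikes)

    pos_occ = np.unique(pos[ok])
    remap = np.full(N_BINS * N_BINS, -1)
    remap[pos_occ] = np.arange(pos_occ.size)
    if pos_occ.size < 2:
        raise DegenerateCovariateError("degenerate-covariate: P")

    d_codes = np.clip((frame.direction[ok] // (360.0 / N_DIR_BINS)).astype(int), 0, N_DIR_BINS - 1)
    s_codes = np.clip((frame.speed[ok] // SPEED_BIN_CM_S).astype(int), 0, N_SPEED_BINS - 1)
    return DesignData(
        y=counts[ok].astype(float),
        codes={"P": remap[pos[ok]], "D": d_codes, "S": s_codes},
        n_bins={"P": pos_occ.size, "D": N_DIR_BINS, "S": N_SPEED_BINS},
        pos_columns=pos_occ,
    )


def design_matrix(data: DesignData, covariates: tuple[str, ...]):
    """Explicit sparse one-hot design (intercept excluded), for inspection
    and tests; the solver works from the bin codes directly."""
    from scipy import sparse

    blocks = []
    for c in covariates:
        n = data.n_bins[c]
        blocks.append(
            sparse.csr_matrix(
                (np.ones(data.n_samples), (np.arange(data.n_samples), data.codes[c])),
                shape=(data.n_samples, n),
            )
        )
    return sparse.hstack(blocks, format="csr")


# --------------------------------------------------------------------------
# Poisson MLE
# --------------------------------------------------------------------------


@dataclass
class GLMFit:
    covariates: tuple[str, ...]
    a0: float
    coefs: dict[str, np.ndarray]  # per-bin coefficients, NaN where unoccupied
    ll: float  # training log-likelihood (log y! terms omitted)
    converged: bool
    n_params: int  # coefficients beyond the intercept


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.exp(eta)))


def fit_poisson(
    data: DesignData,
    covariates: tuple[str, ...],
    sample_idx: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 60,
    init: GLMFit | None = None,
) -> GLMFit:
    """Maximum-likelihood Poisson log-link fit (no regularization).

    A single-covariate indicator model has the closed-form solution rate =
    per-bin empirical mean; multi-covariate models run the Newton
    iteration. Bins unoccupied in the (sub)sample carry NaN coefficients.
    """
    idx = np.arange(data.n_samples) if sample_idx is None else sample_idx
    y = data.y[idx]
    codes = {c: data.codes[c][idx] for c in covariates}
    occ = {c: np.bincount(codes[c], minlength=data.n_bins[c]) for c in covariates}
    for c in covariates:
        if int(np.sum(occ[c] > 0)) < 2:
            raise DegenerateCovariateError(f"degenerate-covariate: {c}")
    n_params = sum(int(np.sum(occ[c] > 0)) - 1 for c in covariates)

    if len(covariates) == 0:
        a0 = float(np.log(max(y.mean(), 1e-12)))
        return GLMFit((), a0, {}, _loglik(y, np.full(y.size, a0)), True, 0)

    if len(covariates) == 1:
        c = covariates[0]
        sums = np.bincount(codes[c], weights=y, minlength=data.n_bins[c])
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(occ[c] > 0, sums / np.maximum(occ[c], 1), np.nan)
        logm = np.clip(np.log(np.maximum(mean, 1e-12)), -COEF_CAP, COEF_CAP)
        a0 = float(np.nanmean(logm))
        coef = logm - a0
        eta = a0 + coef[codes[c]]
        return GLMFit(covariates, a0, {c: coef}, _loglik(y, eta), True, n_params)

    return _newton_fit(y, codes, occ, covariates, data.n_bins, n_params, tol, max_iter, init)


def _newton_fit(y, codes, occ, covariates, n_bins, n_params, tol, max_iter, init=None):
    if init is not None and init.covariates == tuple(covariates):
        a0 = init.a0
        coefs = {c: np.nan_to_num(init.coefs[c], nan=0.0) for c in covariates}
    else:
        # warm start from marginal per-bin means
        a0 = float(np.log(max(y.mean(), 1e-12)))
        coefs = {}
        for c in covariates:
            sums = np.bincount(codes[c], weights=y, minlength=n_bins[c])
            with np.errstate(divide="ignore", invalid="ignore"):
                m = np.where(occ[c] > 0, sums / np.maximum(occ[c], 1), np.nan)
            co = np.clip(np.log(np.maximum(m, 1e-12)), -COEF_CAP, COEF_CAP) - a0
            coefs[c] = np.where(occ[c] > 0, co, 0.0)

    refs = {c: int(np.argmax(occ[c])) for c in covariates}
    free = {c: np.flatnonzero((occ[c] > 0) & (np.arange(n_bins[c]) != refs[c])) for c in covariates}
    for c in covariates:  # gauge: reference bin pinned at 0
        coefs[c] = coefs[c] - coefs[c][refs[c]]

    sizes = [1] + [free[c].size for c in covariates]
    offs = np.cumsum([0] + sizes)
    n_free = offs[-1]

    def eta_of(a0v, cf):
        e = np.full(y.size, a0v)
        for c in covariates:
            e += cf[c][codes[c]]
        return np.clip(e, -30.0, ETA_MAX)

    ll = _loglik(y, eta_of(a0, coefs))
    converged = False
    for _ in range(max_iter):
        eta = eta_of(a0, coefs)
        mu = np.exp(eta)
        resid = y - mu

        grad = np.zeros(n_free)
        grad[0] = resid.sum()
        hess = np.zeros((n_free, n_free))
        hess[0, 0] = mu.sum()
        gblocks = {c: np.bincount(codes[c], weights=resid, minlength=n_bins[c]) for c in covariates}
        hblocks0 = {c: np.bincount(codes[c], weights=mu, minlength=n_bins[c]) for c in covariates}
        for i, c in enumerate(covariates):
            sl = slice(offs[i + 1], offs[i + 2])
            grad[sl] = gblocks[c][free[c]]
            hess[0, sl] = hess[sl, 0] = hblocks0[c][free[c]]
            hess.flat[np.arange(offs[i + 1], offs[i + 2]) * (n_free + 1)] = hblocks0[c][free[c]]
            for j in range(i + 1, len(covariates)):
                c2 = covariates[j]
                cross = np.bincount(
                    codes[c] * n_bins[c2] + codes[c2], weights=mu,
                    minlength=n_bins[c] * n_bins[c2],
                ).reshape(n_bins[c], n_bins[c2])
                sub = cross[np.ix_(free[c], free[c2])]
                sl2 = slice(offs[j + 1], offs[j + 2])
                hess[sl, sl2] = sub
                hess[sl2, sl] = sub.T

        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(n_free), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]

        scale = 1.0
        for _ in range(25):
            a0n = a0 + scale * step[0]
            cfn = {}
            for i, c in enumerate(covariates):
                v = coefs[c].copy()
                v[free[c]] += scale * step[offs[i + 1] : offs[i + 2]]
                cfn[c] = np.clip(v, -COEF_CAP, COEF_CAP)
            ll_new = _loglik(y, eta_of(a0n, cfn))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        a0, coefs = a0n, cfn
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    out = {}
    for c in covariates:
        v = coefs[c].copy()
        v[occ[c] == 0] = np.nan
        out[c] = v
    return GLMFit(tuple(covariates), a0, out, ll, converged, n_params)


def predict_eta(fit: GLMFit, data: DesignData, idx: np.ndarray) -> np.ndarray:
    """Linear predictor for arbitrary samples; NaN where a sample falls in
    a bin that carried no coefficient."""
    eta = np.full(idx.size, fit.a0)
    for c in fit.covariates:
        eta += fit.coefs[c][data.codes[c][idx]]
    return eta


# --------------------------------------------------------------------------
# cross-validated likelihood and forward selection
# --------------------------------------------------------------------------


def cv_loglik(
    data: DesignData, covariates: tuple[str, ...], n_folds: int = 10
) -> np.ndarray:
    """Held-out Poisson log-likelihood per contiguous fold.

    Test samples in bins unoccupied during training fall back to the
    intercept-only (training-mean) prediction.
    """
    n = data.n_samples
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    lls = np.zeros(n_folds)
    warm = fit_poisson(data, covariates) if len(covariates) > 1 else None
    for k in range(n_folds):
        test = np.arange(edges[k], edges[k + 1])
        train = np.concatenate([np.arange(0, edges[k]), np.arange(edges[k + 1], n)])
        fit = fit_poisson(data, covariates, sample_idx=train, init=warm)
        eta = predict_eta(fit, data, test)
        mean_mu = max(data.y[train].mean(), 1e-12)
        eta = np.where(np.isfinite(eta), eta, np.log(mean_mu))
        mu = np.exp(np.clip(eta, -30.0, ETA_MAX))
        mu = np.maximum(mu, MIN_RATE_FRACTION * mean_mu)
        lls[k] = float(np.sum(data.y[test] * np.log(mu) - mu))
    return lls


@dataclass
class ModelSelection:
    chosen: tuple[str, ...]  # () means "none": no model beats constant mean
    path: list[dict] = field(default_factory=list)
    cv_ll: float = np.nan  # total held-out LL of the chosen model
    category: str = "none"


def _category(chosen: tuple[str, ...]) -> str:
    if not chosen:
        return "none"
    s = "".join(c for c in COV_ORDER if c in chosen)
    return {"P": "P_only"}.get(s, s)


def forward_select(data: DesignData, n_folds: int = 10) -> ModelSelection:
    """Forward covariate selection.

    The best single covariate is the one with the highest 10-fold
    cross-validated (held-out) log-likelihood. A second covariate is added
    when its extension improves the fitted likelihood significantly by the
    classical likelihood-ratio test (2x the training log-likelihood gain
    against a chi-square with df = number of added coefficients), at level
    alpha divided by the number of candidate extensions considered — the
    Bonferroni correction accounts for picking the best extension before
    testing it; among significant extensions the one with the best
    held-out likelihood wins. The three-covariate model is then tested
    against the chosen two-covariate model at level alpha. Finally the
    selected model must beat the constant-mean model both on held-out
    likelihood and by the LR test — a model that predicts worse than a
    constant rate is "none" regardless of its fit. Ties break
    deterministically in the order P > D > S.

    Testing 2x the CV-likelihood gain against the chi-square instead would
    penalize complexity twice (the held-out likelihood already pays about
    one unit per added coefficient) and was found to have almost no power
    for the weakest covariates.
    """
    sel = ModelSelection(chosen=())
    cvll: dict[tuple, float] = {}
    trll: dict[tuple, float] = {}

    def score(covs: tuple[str, ...]) -> None:
        if covs not in cvll:
            cvll[covs] = cv_loglik(data, covs, n_folds).sum()
            trll[covs] = fit_poisson(data, covs).ll

    def n_coef(covs: tuple[str, ...]) -> int:
        return sum(int(np.sum(np.bincount(data.codes[c], minlength=data.n_bins[c]) > 0)) - 1
                   for c in covs)

    def lr_p(big: tuple, small: tuple) -> float:
        lr = 2.0 * (trll[big] - trll[small])
        df = n_coef(big) - n_coef(small)
        return float(chi2.sf(lr, max(df, 1))) if lr > 0 else 1.0

    score(())
    candidates = [(c,) for c in COV_ORDER]
    for covs in candidates:
        score(covs)
    best1 = max(candidates, key=lambda c: (cvll[c], -COV_ORDER.index(c[0])))
    sel.path.append({"model": best1, "cv_ll": cvll[best1]})
    current = best1

    two_var = [tuple(sorted(best1 + (c,), key=COV_ORDER.index)) for c in COV_ORDER if c not in best1]
    for covs in two_var:
        score(covs)
    alpha2 = LR_ALPHA / max(len(two_var), 1)
    significant = [c for c in two_var if lr_p(c, best1) < alpha2]
    for covs in two_var:
        sel.path.append({"model": covs, "cv_ll": cvll[covs], "lr_p": lr_p(covs, best1)})
    if significant:
        current = max(significant, key=lambda c: cvll[c])
        full = tuple(COV_ORDER)
        score(full)
        p3 = lr_p(full, current)
        sel.path.append({"model": full, "cv_ll": cvll[full], "lr_p": p3})
        if p3 < LR_ALPHA:
            current = full

    p0 = lr_p(current, ())
    validated = cvll[current] > cvll[()] and p0 < LR_ALPHA
    sel.path.append({"model": current, "vs_constant_p": p0})
    if validated:
        sel.chosen = current
        sel.cv_ll = cvll[current]
    sel.category = _category(sel.chosen)
    return sel


# --------------------------------------------------------------------------
# tuning curves and strengths
# --------------------------------------------------------------------------

_SMOOTH_SD = {"P": 1.0, "D": 1.0, "S": 1.0}  # 5 cm / 20 deg / 5 cm/s = 1 bin


@dataclass
class CovariateTuning:
    curves: dict[str, np.ndarray]  # covariate -> rate (Hz) per bin, NaN unoccupied
    strengths: dict[str, float]


def tuning_from_fit(fit: GLMFit, data: DesignData) -> CovariateTuning:
    """Convert coefficients into smoothed firing-rate tuning curves.

    ``y_k(bin) = alpha * exp(X_k(bin)) / dt`` with
    ``alpha = exp(a0) * prod_{j != k} exp(mean X_j)`` (unweighted bin
    means); smoothing (5-cm, circular 20-deg, 5-cm/s Gaussian) is applied
    after exponentiation; the strength is the sparsity of the curve.
    """
    curves: dict[str, np.ndarray] = {}
    strengths: dict[str, float] = {}
    for k in fit.covariates:
        alpha = np.exp(fit.a0)
        for j in fit.covariates:
            if j != k:
                alpha *= np.exp(np.nanmean(fit.coefs[j]))
        y = alpha * np.exp(fit.coefs[k]) / BEHAVIOR_DT  # Hz, NaN unoccupied
        curves[k] = _smooth_curve(k, y, data)
        strengths[k] = spatial_tuning_strength(curves[k][np.isfinite(curves[k])])
    return CovariateTuning(curves=curves, strengths=strengths)


def _smooth_curve(cov: str, y: np.ndarray, data: DesignData) -> np.ndarray:
    sd = _SMOOTH_SD[cov]
    if cov == "D":
        return gaussian_filter1d(np.nan_to_num(y, nan=np.nanmean(y)), sd, mode="wrap")
    if cov == "S":
        out = y.copy()
        occ = np.isfinite(y)
        filled = np.nan_to_num(y, nan=0.0)
        norm = gaussian_filter1d(occ.astype(float), sd, mode="constant")
        sm = gaussian_filter1d(filled, sd, mode="constant")
        out[occ] = (sm / np.maximum(norm, 1e-12))[occ]
        return out
    # position: scatter onto the 20x20 grid, masked smoothing
    grid = np.full(N_BINS * N_BINS, np.nan)
    grid[data.pos_columns] = y
    grid = grid.reshape(N_BINS, N_BINS)
    mask = np.isfinite(grid)
    sm = gaussian_filter(np.where(mask, grid, 0.0), sd, mode="constant")
    norm = gaussian_filter(mask.astype(float), sd, mode="constant")
    out = np.full(N_BINS * N_BINS, np.nan)
    out[data.pos_columns] = (sm / np.maximum(norm, 1e-12))[mask]
    return out


def light_dark_contrast(
    tuning_light: CovariateTuning, tuning_dark: CovariateTuning
) -> dict[str, float]:
    """Per-covariate tuning-strength difference dark - light, over the
    covariates of the light-condition model."""
    out = {}
    for c, s_light in tuning_light.strengths.items():
        s_dark = tuning_dark.strengths.get(c, np.nan)
        out[c] = s_dark - s_light
    return out


def analyze_cell(
    frame: BehaviorFrame, spikes: np.ndarray, valid_bins: np.ndarray
) -> tuple[ModelSelection, CovariateTuning | None, GLMFit | None]:
    """Forward selection plus tuning curves of the chosen model."""
    data = build_design(frame, spikes, valid_bins)
    sel = forward_select(data)
    if not sel.chosen:
        return sel, None, None
    fit = fit_poisson(data, sel.chosen)
    return sel, tuning_from_fit(fit, data), fit
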