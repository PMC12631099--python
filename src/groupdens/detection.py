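"""Point-transect detection-function fitting for binned camera-trap distances.

Distances arrive as interval bands, so fitting maximises a multinomial
interval likelihood with bin probabilities proportional to the integral of
``r * g(r)`` over each band (point-transect geometry).  Candidate keys are
half-normal (Hermite adjustments), hazard-rate (cosine adjustments) and
uniform (cosine adjustments); model choice uses QAIC with an overdispersion
factor estimated from the most-parameterised candidate.

The angular fall-off of detections is fitted separately with a half-normal
curve over absolute angles, yielding the effective detection angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .observations import distance_bands

__all__ = [
    "AngleFit",
    "DetectionFit",
    "DetectionModel",
    "FitError",
    "candidate_models",
    "estimate_overdispersion",
    "fit_all_candidates",
    "fit_detection_function",
    "fit_effective_angle",
    "qaic",
    "select_model",
    "truncate_distances",
]

_FAMILIES = ("half-normal", "hazard-rate", "uniform")
_FAMILY_ORDER = {"half-normal": 0, "hazard-rate": 1, "uniform": 2}

# 16-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


class FitError(RuntimeError):
    """Detection-function fitting failed to converge."""


@dataclass
class DetectionModel:
    """A detection-function family plus its adjustment-series order."""

    family: str
    n_adjust: int = 0
    params: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_adjust < 0:
            raise ValueError("n_adjust must be >= 0")

    @property
    def n_params(self) -> int:
        base = {"half-normal": 1, "hazard-rate": 2, "uniform": 0}[self.family]
        return base + self.n_adjust


def candidate_models() -> list[DetectionModel]:
    """The fixed candidate set used for model selection."""
    return [
        DetectionModel("half-normal", 0),
        DetectionModel("half-normal", 1),
        DetectionModel("uniform", 1),
        DetectionModel("uniform", 2),
        DetectionModel("hazard-rate", 0),
        DetectionModel("hazard-rate", 1),
        DetectionModel("hazard-rate", 2),
    ]


@dataclass
class DetectionFit:
    """A fitted detection model with derived quantities.

    ``p_hat`` is the mean detection probability over the annulus
    (w_left, w_right]; ``edr`` the effective detection radius, i.e. the
    radius containing the same expected number of detections under perfect
    detection: edr^2 = p_hat * (w^2 - w_left^2) + w_left^2.
    """

    model: DetectionModel
    w_left: float
    w_right: float
    loglik: float
    n_obs: int
    p_hat: float
    edr: float
    se_edr: float = float("nan")
    qaic: float | None = None
    monotone_warning: bool = False
    param_cov: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    bin_counts: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.model.n_params


# ---------------------------------------------------------------------------
# detection-curve evaluation
# ---------------------------------------------------------------------------


def _hermite(x: np.ndarray, order: int) -> np.ndarray:
    if order == 4:
        return x**4 - 6 * x**2 + 3
    if order == 6:
        return x**6 - 15 * x**4 + 45 * x**2 - 15
    raise ValueError(order)


def _g_unnormalised(
    model: DetectionModel, params: np.ndarray, r: np.ndarray, w: float
) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if model.family == "half-normal":
        sigma = math.exp(min(max(params[0], -30.0), 30.0))
        key = np.exp(-0.5 * (r / sigma) ** 2)
        adj = params[1:]
        series = np.ones_like(r)
        x = r / sigma
        for j, a in enumerate(adj):
            series = series + a * _hermite(x, 4 + 2 * j)
    elif model.family == "hazard-rate":
        sigma = math.exp(min(max(params[0], -30.0), 30.0))
        b = 1.0 + math.exp(min(max(params[1], -30.0), 8.0))
        with np.errstate(divide="ignore", over="ignore"):
            key = 1.0 - np.exp(-((np.maximum(r, 1e-12) / sigma) ** (-b)))
        adj = params[2:]
        series = np.ones_like(r)
        x = r / w
        for j, a in enumerate(adj):
            series = series + a * np.cos((j + 2) * np.pi * x)
    else:  # uniform
        key = np.ones_like(r)
        adj = params
        series = np.ones_like(r)
        x = r / w
        for j, a in enumerate(adj):
            series = series + a * np.cos((j + 1) * np.pi * x)
    return np.clip(key * series, 0.0, None)


def detection_curve(model: DetectionModel, w: float):
    """Return ``g(r)`` scaled to a maximum of 1 on [0, w]."""
    if model.params is None:
        raise ValueError("model has no fitted parameters")
    grid = np.linspace(0.0, w, 512)
    peak = float(np.max(_g_unnormalised(model, model.params, grid, w)))
    if peak <= 0:
        raise FitError("degenerate fitted curve (non-positive everywhere)")

    def g(r):
        return np.minimum(_g_unnormalised(model, model.params, np.asarray(r), w) / peak, 1.0)

    return g


def _bin_integrals(
    model: DetectionModel, params: np.ndarray, edges: np.ndarray, w: float
) -> np.ndarray:
    """∫ r g(r) dr over each bin, by Gauss-Legendre quadrature."""
    lo = edges[:-1][:, None]
    width = np.diff(edges)[:, None]
    r = lo + width * _GL_X[None, :]
    vals = _g_unnormalised(model, params, r, w) * r
    return (vals * _GL_W[None, :]).sum(axis=1) * width[:, 0]


# ---------------------------------------------------------------------------
# histogramming
# ---------------------------------------------------------------------------


def _band_histogram(
    bands: list[tuple[float, float]], w_left: float, w: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scheme bins spanning (w_left, w] and the observation counts in each."""
    max_hi = max(max(hi for _, hi in bands), w)
    scheme = [b for b in distance_bands(max_hi) if b[0] >= w_left - 1e-9 and b[1] <= w + 1e-9]
    if not scheme:
        raise ValueError("no scheme bins inside the truncation window")
    edges = np.array([scheme[0][0]] + [b[1] for b in scheme])
    counts = np.zeros(len(scheme))
    index = {(round(lo, 6), round(hi, 6)): i for i, (lo, hi) in enumerate(scheme)}
    for lo, hi in bands:
        key = (round(lo, 6), round(hi, 6))
        if key in index:
            counts[index[key]] += 1
    return edges, counts


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _nll(model, params, edges, counts, w):
    integrals = _bin_integrals(model, params, edges, w)
    total = integrals.sum()
    if not np.isfinite(total) or total <= 0:
        return 1e10
    p = integrals / total
    mask = counts > 0
    if np.any(p[mask] <= 0):
        return 1e10
    return -float(np.sum(counts[mask] * np.log(p[mask])))


def _start_points(model: DetectionModel, w_left: float, w: float) -> list[np.ndarray]:
    span = w - w_left
    starts = []
    sigmas = np.log(span * np.array([0.15, 0.3, 0.6, 1.2]))
    if model.family == "half-normal":
        for s in sigmas:
            starts.append(np.concatenate([[s], np.zeros(model.n_adjust)]))
    elif model.family == "hazard-rate":
        for s in sigmas:
            for b in (math.log(1.5 - 1), math.log(3.0 - 1)):
                starts.append(np.concatenate([[s, b], np.zeros(model.n_adjust)]))
    else:
        starts.append(np.zeros(model.n_adjust))
        starts.append(np.full(model.n_adjust, 0.1))
    return starts


def fit_detection_function(
    bands: list[tuple[float, float]],
    model: DetectionModel,
    w_left: float = 0.0,
    w: float = 25.0,
) -> DetectionFit:
    """Maximum-likelihood fit of a detection model to banded distances.

    ``bands`` are per-observation distance intervals; observations outside
    (w_left, w] are ignored.  Raises :class:`FitError` on non-convergence
    and ``ValueError`` when there are fewer non-empty bins than parameters
    plus one.
    """
    if w <= w_left:
        raise ValueError("w must exceed w_left")
    edges, counts = _band_histogram(bands, w_left, w)
    n_obs = int(counts.sum())
    nonempty = int((counts > 0).sum())
    if nonempty < model.n_params + 1:
        raise ValueError(
            f"{nonempty} non-empty bins cannot support {model.n_params} parameters"
        )

    if model.n_params == 0:  # degenerate uniform: nothing to optimise
        params = np.zeros(0)
        ll = -_nll(model, params, edges, counts, w)
        return _finish_fit(model, params, None, edges, counts, w_left, w, ll, n_obs)

    best = None
    for x0 in _start_points(model, w_left, w):
        res = optimize.minimize(
            lambda p: _nll(model, p, edges, counts, w),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        status = getattr(best, "message", "no candidate start converged")
        raise FitError(f"detection fit failed: {status}")
    params = np.asarray(best.x, dtype=float)
    cov = _param_cov(model, params, edges, counts, w)
    return _finish_fit(model, params, cov, edges, counts, w_left, w, -best.fun, n_obs)


def _param_cov(model, params, edges, counts, w) -> np.ndarray | None:
    k = len(params)
    if k == 0:
        return None
    h = 1e-4
    hess = np.zeros((k, k))
    f0 = _nll(model, params, edges, counts, w)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = _nll(model, params + ei + ej, edges, counts, w)
            fpm = _nll(model, params + ei - ej, edges, counts, w)
            fmp = _nll(model, params - ei + ej, edges, counts, w)
            fmm = _nll(model, params - ei - ej, edges, counts, w)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) < 0):
        return None
    return cov


def _p_hat_edr(model, params, w_left, w) -> tuple[float, float]:
    grid = np.linspace(0.0, w, 512)
    peak = float(np.max(_g_unnormalised(model, params, grid, w)))
    if peak <= 0:
        raise FitError("fitted curve is zero everywhere")
    edges = np.linspace(w_left, w, 65)  # panels: integrand may be concentrated
    integral = float(_bin_integrals(model, params, edges, w).sum()) / peak
    p_hat = min(1.0, 2.0 * integral / (w**2 - w_left**2))
    edr = math.sqrt(p_hat * (w**2 - w_left**2) + w_left**2)
    return p_hat, edr


def _finish_fit(model, params, cov, edges, counts, w_left, w, loglik, n_obs) -> DetectionFit:
    fitted = DetectionModel(model.family, model.n_adjust, params=params)
    p_hat, edr = _p_hat_edr(fitted, params, w_left, w)

    # monotonicity check on a grid (soft: flag, don't constrain)
    grid = np.linspace(w_left, w, 256)
    gv = _g_unnormalised(fitted, params, grid, w)
    mono_warn = bool(np.any(np.diff(gv) > 1e-6 * max(gv.max(), 1e-12)))

    se_edr = float("nan")
    if cov is not None and len(params) > 0:
        grad = np.zeros(len(params))
        h = 1e-4
        for i in range(len(params)):
            e = np.zeros(len(params)); e[i] = h
            _, ep = _p_hat_edr(fitted, params + e, w_left, w)
            _, em = _p_hat_edr(fitted, params - e, w_left, w)
            grad[i] = (ep - em) / (2 * h)
        var = float(grad @ cov @ grad)
        if var >= 0:
            se_edr = math.sqrt(var)

    return DetectionFit(
        model=fitted,
        w_left=w_left,
        w_right=w,
        loglik=loglik,
        n_obs=n_obs,
        p_hat=p_hat,
        edr=edr,
        se_edr=se_edr,
        monotone_warning=mono_warn,
        param_cov=cov,
        bin_edges=edges,
        bin_counts=counts,
    )


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


def truncate_distances(
    bands: list[tuple[float, float]],
    left: float = 0.0,
    right_rule: float | str = "detection-prob-0.15",
    model: DetectionModel | None = None,
    threshold: float = 0.15,
) -> tuple[list[tuple[float, float]], float, float]:
    """Apply left/right truncation; returns (kept bands, w_left, w).

    ``right_rule`` is either a fixed distance or ``"detection-prob-0.15"``,
    which iteratively drops the outermost band until the refitted detection
    probability at w is at least ``threshold``.
    """
    if not bands:
        raise ValueError("no observations to truncate")
    if isinstance(right_rule, (int, float)):
        w = float(right_rule)
        kept = [b for b in bands if b[0] >= left - 1e-9 and b[1] <= w + 1e-9]
        if not kept:
            raise ValueError("truncation removed all observations")
        return kept, left, w

    if right_rule != "detection-prob-0.15":
        raise ValueError(f"unknown right_rule {right_rule!r}")
    model = model or DetectionModel("half-normal", 0)
    hi_edges = sorted({b[1] for b in bands if b[0] >= left - 1e-9})
    while hi_edges:
        w = hi_edges[-1]
        kept = [b for b in bands if b[0] >= left - 1e-9 and b[1] <= w + 1e-9]
        try:
            fit = fit_detection_function(kept, DetectionModel(model.family, model.n_adjust), left, w)
        except (ValueError, FitError):
            break
        g = detection_curve(fit.model, w)
        if float(g(np.array([w]))[0]) >= threshold:
            return kept, left, w
        hi_edges.pop()
    raise ValueError("right-truncation rule removed all observations")


# ---------------------------------------------------------------------------
# overdispersion and model selection
# ---------------------------------------------------------------------------


def estimate_overdispersion(fit: DetectionFit) -> float:
    """chi-square overdispersion factor from observed vs expected bin counts.

    Computed on the most-parameterised candidate's fit; floored at 1.
    Raises when the fit leaves no residual degrees of freedom.
    """
    if fit.bin_edges is None or fit.bin_counts is None:
        raise ValueError("fit carries no binned data")
    counts = fit.bin_counts
    df = len(counts) - fit.n_params - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom for overdispersion")
    integrals = _bin_integrals(fit.model, fit.model.params, fit.bin_edges, fit.w_right)
    p = integrals / integrals.sum()
    expected = counts.sum() * p
    mask = expected > 0
    chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return max(1.0, chi2 / df)


def qaic(fit: DetectionFit, c_hat: float) -> float:
    """Quasi-AIC: -2 loglik / c_hat + 2 (n_params + 1)."""
    if c_hat < 1:
        raise ValueError("c_hat must be >= 1")
    return -2.0 * fit.loglik / c_hat + 2.0 * (fit.n_params + 1)


def select_model(fits: list[DetectionFit], c_hat: float) -> DetectionFit:
    """Minimum-QAIC fit; ties go to fewer parameters, then family order."""
    if not fits:
        raise FitError("no converged candidate fits")
    for f in fits:
        f.qaic = qaic(f, c_hat)
    return min(
        fits,
        key=lambda f: (round(f.qaic, 9), f.n_params, _FAMILY_ORDER[f.model.family]),
    )


def fit_all_candidates(
    bands: list[tuple[float, float]],
    w_left: float = 0.0,
    w: float = 25.0,
    models: list[DetectionModel] | None = None,
) -> tuple[DetectionFit, list[DetectionFit], float]:
    """Fit the candidate set, estimate c-hat, select by QAIC.

    Returns (selected fit, all converged fits, c_hat).
    """
    models = models if models is not None else candidate_models()
    fits: list[DetectionFit] = []
    for m in models:
        try:
            fits.append(fit_detection_function(bands, m, w_left, w))
        except (FitError, ValueError):
            continue
    if not fits:
        raise FitError("all candidate detection fits failed")
    most = max(fits, key=lambda f: f.n_params)
    try:
        c_hat = estimate_overdispersion(most)
    except ValueError:
        c_hat = 1.0
    return select_model(fits, c_hat), fits, c_hat


# ---------------------------------------------------------------------------
# effective angle
# ---------------------------------------------------------------------------


@dataclass
class AngleFit:
    """Effective full detection angle (radians) from angular fall-off."""

    effective_angle: float
    se: float
    sigma: float
    n_obs: int
    half_angle: float


def _theta_from_sigma(sigma: float, half_angle: float) -> float:
    val = 2.0 * sigma**2 * (1.0 - math.exp(-(half_angle**2) / (2 * sigma**2)))
    return 2.0 * min(math.sqrt(val), half_angle)


def fit_effective_angle(angles: np.ndarray, half_angle: float) -> AngleFit:
    """Half-normal fit to absolute angles; returns the effective full angle.

    Availability is assumed uniform across the viewshed, so the sample
    density is g(a) / integral(g) on [0, half_angle].
    """
    a = np.asarray(angles, dtype=float)
    if len(a) < 10:
        raise ValueError("need at least 10 angles")
    if np.any(a < -1e-9) or np.any(a > half_angle + 1e-9):
        raise ValueError("angles outside [0, half_angle]")
    a = np.clip(a, 0.0, half_angle)

    sqrt2 = math.sqrt(2.0)

    def nll(log_sigma: float) -> float:
        s = math.exp(log_sigma)
        mu = s * math.sqrt(math.pi / 2.0) * math.erf(half_angle / (s * sqrt2))
        if mu <= 0:
            return 1e10
        return float(np.sum(0.5 * (a / s) ** 2) + len(a) * math.log(mu))

    res = optimize.minimize_scalar(
        nll,
        bounds=(math.log(half_angle / 100.0), math.log(half_angle * 100.0)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    log_s = float(res.x)
    sigma = math.exp(log_s)
    theta = _theta_from_sigma(sigma, half_angle)

    # SE via observed information on log sigma, delta method to theta
    h = 1e-4
    d2 = (nll(log_s + h) - 2 * nll(log_s) + nll(log_s - h)) / h**2
    se = float("nan")
    if d2 > 0:
        var_log_s = 1.0 / d2
        dtheta = (
            _theta_from_sigma(math.exp(log_s + h), half_angle)
            - _theta_from_sigma(math.exp(log_s - h), half_angle)
        ) / (2 * h)
        se = abs(dtheta) * math.sqrt(var_log_s)
    return AngleFit(effective_angle=theta, se=se, sigma=sigma, n_obs=len(a), half_angle=half_angle)


def tags_to_bands(tags) -> list[tuple[float, float]]:
    """Distance bands of a tag sequence (convenience for estimators)."""
    return [t.distance_band for t in tags]


def tags_to_angles(tags, half_angle: float) -> np.ndarray:
    """Absolute band-midpoint angles of a tag sequence."""
    return np.array([t.angle(half_angle) for t in tags], dtype=float)
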