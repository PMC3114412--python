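"""Multivariate autoregressive (MVAR / VAR) model fitting and validation.

A VAR(p) model expresses each channel at time t as a lagged linear
combination of all channels plus innovation noise::

    x[t] = sum_{k=1..p} A_k @ x[t-k] + e[t],   e[t] ~ (0, Sigma)

with the index convention ``A_k[i, j]`` = influence of source channel j at
lag k on sink channel i (row = sink, column = source).  Fitting pools
regression rows across trials; rows never straddle a trial boundary, since
trials are separate realizations of the process.

Two estimators are provided: ordinary least squares on lag-stacked
regressors, and the Vieira-Morf lattice algorithm (multichannel Levinson
recursion with geometric-mean normalized reflection coefficients), which is
better conditioned on short windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

from .dataset import EpochedTimeSeries
from .exceptions import InvalidArgumentError, UnderdeterminedModelError

__all__ = [
    "VARModel",
    "ModelDiagnostics",
    "fit_var",
    "select_order",
    "validate_model",
    "companion_matrix",
    "spectral_radius",
    "simulate_var",
]


@dataclass
class VARModel:
    """Fitted VAR(p) model for one analysis window.

    Attributes
    ----------
    order : int
        Model order p (number of lags), >= 0.
    coeffs : ndarray, shape (p, M, M)
        Coefficient matrices A_1..A_p; ``coeffs[k-1][i, j]`` is the lag-k
        influence of channel j (source) on channel i (sink).
    noise_cov : ndarray, shape (M, M)
        Innovation covariance Sigma (symmetric positive semidefinite).
    srate : float
        Sampling rate of the fitted data, Hz.
    n_obs : int
        Number of regression rows used in the fit.
    regressor_cov : ndarray or None, shape (p*M, p*M)
        Second-moment matrix of the lag-stacked regressors, Z'Z / n_obs,
        retained for analytic significance tests.
    window_center : float or None
        Event-relative window center in seconds, when fitted on a window.
    """

    order: int
    coeffs: np.ndarray
    noise_cov: np.ndarray
    srate: float
    n_obs: int
    regressor_cov: np.ndarray | None = None
    window_center: float | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        m = self.noise_cov.shape[0]
        if self.order < 0:
            raise InvalidArgumentError(f"order must be >= 0, got {self.order}")
        if self.coeffs.shape != (self.order, m, m):
            raise InvalidArgumentError(
                f"coeffs shape {self.coeffs.shape} != ({self.order}, {m}, {m})"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise InvalidArgumentError("coefficients contain non-finite values")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise InvalidArgumentError("noise covariance is not symmetric")
        ev = np.linalg.eigvalsh(0.5 * (self.noise_cov + self.noise_cov.T))
        if ev.min() < -1e-10 * max(1.0, ev.max()):
            raise InvalidArgumentError("noise covariance is not PSD")

    @property
    def n_channels(self) -> int:
        return self.noise_cov.shape[0]


@dataclass(frozen=True)
class ModelDiagnostics:
    """Validation summary for a fitted VAR model on its window."""

    is_stable: bool
    spectral_radius: float
    whiteness_pvalue: float
    consistency_pct: float


def companion_matrix(coeffs: np.ndarray) -> np.ndarray:
    """Companion form of VAR coefficient matrices, shape (p*M, p*M)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, m, _ = coeffs.shape
    if p == 0:
        return np.zeros((0, 0))
    top = coeffs.transpose(1, 0, 2).reshape(m, p * m)
    comp = np.zeros((p * m, p * m))
    comp[:m, :] = top
    if p > 1:
        comp[m:, :-m] = np.eye((p - 1) * m)
    return comp


def spectral_radius(coeffs: np.ndarray) -> float:
    """Largest eigenvalue modulus of the companion matrix (0 for p=0)."""
    comp = companion_matrix(coeffs)
    if comp.size == 0:
        return 0.0
    return float(np.abs(np.linalg.eigvals(comp)).max())


def _lag_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (Y, Z) regression arrays for data x of shape (M, N, T).

    Y has shape (n_obs, M); Z has shape (n_obs, p*M) with column block k-1
    holding x[t-k].  Rows are pooled over trials without crossing boundaries.
    """
    m, n, t = x.shape
    ys, zs = [], []
    for tr in range(t):
        xt = x[:, :, tr]
        ys.append(xt[:, p:].T)
        if p > 0:
            z = np.empty((n - p, p * m))
            for k in range(1, p + 1):
                z[:, (k - 1) * m:k * m] = xt[:, p - k:n - k].T
            zs.append(z)
    y = np.concatenate(ys, axis=0)
    z = np.concatenate(zs, axis=0) if p > 0 else np.zeros((y.shape[0], 0))
    return y, z


def _check_fit_preconditions(window: EpochedTimeSeries, order: int) -> None:
    if order < 0:
        raise InvalidArgumentError(f"order must be >= 0, got {order}")
    m, n, t = window.data.shape
    if n <= order:
        raise UnderdeterminedModelError(
            f"per-trial sample count {n} must exceed order {order}"
        )
    n_obs = t * (n - order)
    if order > 0 and n_obs < order * m + 1:
        raise UnderdeterminedModelError(
            f"{n_obs} pooled rows < {order * m + 1} needed for order "
            f"{order} with {m} channels"
        )


def _fit_ols(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    m = x.shape[0]
    y, z = _lag_design(x, p)
    n_obs = y.shape[0]
    if p == 0:
        coeffs = np.zeros((0, m, m))
        resid = y
        gamma = np.zeros((0, 0))
    else:
        b, *_ = np.linalg.lstsq(z, y, rcond=None)
        resid = y - z @ b
        coeffs = b.T.reshape(m, p, m).transpose(1, 0, 2)
        gamma = z.T @ z / n_obs
    dof = max(n_obs - p * m, 1)
    sigma = resid.T @ resid / dof
    return coeffs, 0.5 * (sigma + sigma.T), n_obs, gamma


def _sym_sqrt(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric PSD square root and its (pseudo-)inverse."""
    w, v = np.linalg.eigh(0.5 * (a + a.T))
    w = np.clip(w, 0.0, None)
    s = np.sqrt(w)
    s_inv = np.where(s > 1e-14 * max(s.max(), 1e-300), 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return (v * s) @ v.T, (v * s_inv) @ v.T


def _fit_vieira_morf(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Vieira-Morf multichannel lattice with trial pooling.

    Forward/backward prediction errors are updated jointly across trials;
    reflection coefficients use the geometric-mean (square-root) normalization
    of the forward and backward error covariances.
    """
    m, n, t = x.shape
    if p == 0:
        return _fit_ols(x, 0)
    ef = x.copy()  # forward errors, ef[:, s, tr] valid for s >= stage
    eb = x.copy()  # backward errors, eb[:, s, tr] valid for s <= n-1-stage
    a = np.zeros((p, m, m))  # forward prediction coefficients
    b = np.zeros((p, m, m))  # backward prediction coefficients
    for stage in range(1, p + 1):
        f = ef[:, stage:, :]          # e_f[t], t = stage..n-1
        g = eb[:, stage - 1:-1, :]    # e_b[t-1]
        pf = np.einsum("ist,jst->ij", f, f)
        pb = np.einsum("ist,jst->ij", g, g)
        pfb = np.einsum("ist,jst->ij", f, g)
        sf, sf_inv = _sym_sqrt(pf)
        sb, sb_inv = _sym_sqrt(pb)
        rho = sf_inv @ pfb @ sb_inv  # normalized partial correlation
        kf = sf @ rho @ sb_inv       # forward reflection matrix
        kb = sb @ rho.T @ sf_inv     # backward reflection matrix
        a_new = a.copy()
        b_new = b.copy()
        a_new[stage - 1] = kf
        b_new[stage - 1] = kb
        for k in range(1, stage):
            a_new[k - 1] = a[k - 1] - kf @ b[stage - k - 1]
            b_new[k - 1] = b[k - 1] - kb @ a[stage - k - 1]
        a, b = a_new, b_new
        f_new = f - np.einsum("ij,jst->ist", kf, g)
        g_new = g - np.einsum("ij,jst->ist", kb, f)
        ef[:, stage:, :] = f_new
        eb[:, stage:, :] = g_new
    n_obs = t * (n - p)
    resid = ef[:, p:, :].reshape(m, -1)
    dof = max(n_obs - p * m, 1)
    sigma = resid @ resid.T / dof
    # regressor second moments, for analytic tests, from the raw design
    _, z = _lag_design(x, p)
    gamma = z.T @ z / n_obs
    return a, 0.5 * (sigma + sigma.T), n_obs, gamma


def fit_var(
    window: EpochedTimeSeries,
    order: int,
    method: str = "ols",
    window_center: float | None = None,
) -> VARModel:
    """Fit a VAR(``order``) model to one analysis window, pooling trials.

    Parameters
    ----------
    window : EpochedTimeSeries
    order : int
        Model order p >= 0.
    method : {'ols', 'vieira_morf'}
        'ols' solves the pooled lag-stacked least-squares problem;
        'vieira_morf' runs the multichannel lattice recursion.
    window_center : float, optional
        Event-relative center to record on the model.

    Returns
    -------
    VARModel
        The innovation covariance uses the degrees-of-freedom corrected
        denominator ``n_obs - p * n_channels``.
    """
    _check_fit_preconditions(window, order)
    if method == "ols":
        coeffs, sigma, n_obs, gamma = _fit_ols(window.data, order)
    elif method in ("vieira_morf", "vm"):
        coeffs, sigma, n_obs, gamma = _fit_vieira_morf(window.data, order)
    else:
        raise InvalidArgumentError(f"unknown fit method {method!r}")
    return VARModel(order=order, coeffs=coeffs, noise_cov=sigma,
                    srate=window.srate, n_obs=n_obs,
                    regressor_cov=gamma if order > 0 else None,
                    window_center=window_center)


def select_order(
    window: EpochedTimeSeries,
    p_range: tuple[int, int],
    criterion: str = "bic",
) -> tuple[int, np.ndarray]:
    """Select the VAR order by an information criterion over ``p_range``.

    Fits every order in ``[p_min, p_max]`` with OLS and evaluates
    ``ln det(Sigma_mle) + penalty * p * M**2 / n_obs`` where the penalty is
    2 (aic), ln(n_obs) (bic) or 2 ln ln(n_obs) (hq).  Ties break toward the
    smaller order.

    Returns
    -------
    (p_opt, curve) : int, ndarray
        The argmin order and the full criterion curve (one value per order).
    """
    p_min, p_max = int(p_range[0]), int(p_range[1])
    if p_max < p_min or p_min < 0:
        raise InvalidArgumentError(f"invalid order range {p_range}")
    if criterion not in ("aic", "bic", "hq"):
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")
    m = window.n_channels
    curve = np.empty(p_max - p_min + 1)
    for idx, p in enumerate(range(p_min, p_max + 1)):
        model = fit_var(window, p, method="ols")
        n = model.n_obs
        # refold the dof correction into the ML covariance estimate
        sigma_mle = model.noise_cov * max(n - p * m, 1) / n
        sign, logdet = np.linalg.slogdet(sigma_mle)
        if sign <= 0:
            logdet = -np.inf  # perfect fit; criterion will not pick a larger p anyway
        if criterion == "aic":
            penalty = 2.0
        elif criterion == "bic":
            penalty = np.log(n)
        else:
            penalty = 2.0 * np.log(np.log(n))
        curve[idx] = logdet + penalty * p * m * m / n
    p_opt = p_min + int(np.argmin(curve))
    return p_opt, curve


def residuals(model: VARModel, window: EpochedTimeSeries) -> np.ndarray:
    """One-step prediction residuals, shape (M, N - p, n_trials)."""
    p = model.order
    x = window.data
    m, n, t = x.shape
    pred = np.zeros((m, n - p, t))
    for k in range(1, p + 1):
        pred += np.einsum("ij,jst->ist", model.coeffs[k - 1], x[:, p - k:n - k, :])
    return x[:, p:, :] - pred


def _portmanteau_pvalue(resid: np.ndarray, p: int, h: int) -> float:
    """Multivariate Ljung-Box portmanteau test on residual autocorrelations.

    Q = n^2 * sum_{k=1..h} tr(C_k' C_0^-1 C_k C_0^-1) / (n - k), with n the
    per-trial residual length times trials (autocovariances averaged over
    trials without crossing boundaries); asymptotically chi^2 with
    M^2 (h - p) degrees of freedom.
    """
    m, nr, t = resid.shape
    r = resid - resid.mean(axis=1, keepdims=True)
    n_eff = nr * t
    c0 = np.einsum("ist,jst->ij", r, r) / n_eff
    c0_inv = np.linalg.pinv(c0)
    q = 0.0
    for k in range(1, h + 1):
        ck = np.einsum("ist,jst->ij", r[:, k:, :], r[:, :-k, :]) / n_eff
        q += np.trace(ck.T @ c0_inv @ ck @ c0_inv) / (n_eff - k)
    q *= n_eff * n_eff
    dof = m * m * (h - p)
    if dof <= 0:
        return float("nan")
    return float(scipy.stats.chi2.sf(q, dof))


def _consistency_pct(model: VARModel, window: EpochedTimeSeries,
                     seed: int = 0, max_lag: int = 20) -> float:
    """Percent of the data's correlation structure reproduced by the model.

    Simulates a dataset of the same shape from the fitted model and compares
    the stacked auto/cross-correlation vectors (all channel pairs, lags
    0..max_lag): 100 * (1 - ||R_sim - R_real|| / ||R_real||).
    """
    m, n, t = window.data.shape
    rng = np.random.default_rng(seed)
    sim = simulate_var(model.coeffs, model.noise_cov, n, t, rng=rng)
    lag = min(max_lag, n - 1)

    def corr_vec(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=(1, 2), keepdims=True)
        denom = np.sqrt(np.einsum("ist,ist->i", xc, xc))
        denom = np.where(denom > 0, denom, 1.0)
        vals = []
        for k in range(lag + 1):
            ck = np.einsum("ist,jst->ij", xc[:, k:, :], xc[:, :n - k, :])
            vals.append(ck / np.outer(denom, denom))
        return np.concatenate([v.ravel() for v in vals])

    r_real = corr_vec(window.data)
    r_sim = corr_vec(sim)
    norm = np.linalg.norm(r_real)
    if norm == 0:
        return float("nan")
    return float(100.0 * (1.0 - np.linalg.norm(r_sim - r_real) / norm))


def validate_model(model: VARModel, window: EpochedTimeSeries) -> ModelDiagnostics:
    """Stability, residual whiteness, and percent-consistency diagnostics."""
    radius = spectral_radius(model.coeffs)
    h = min(20, window.n_samples // 4)
    resid = residuals(model, window)
    if h > model.order and resid.shape[1] > h:
        pw = _portmanteau_pvalue(resid, model.order, h)
    else:
        pw = float("nan")
    cons = _consistency_pct(model, window)
    return ModelDiagnostics(
        is_stable=bool(radius < 1.0),
        spectral_radius=radius,
        whiteness_pvalue=pw,
        consistency_pct=min(cons, 100.0) if np.isfinite(cons) else cons,
    )


def simulate_var(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    burn_in: int = 1000,
) -> np.ndarray:
    """Generate realizations of a stationary VAR process.

    Returns an array of shape (M, n_samples, n_trials); each trial is an
    independent realization started from ``burn_in`` discarded samples.
    """
    rng = np.random.default_rng(rng)
    coeffs = np.asarray(coeffs, dtype=float)
    noise_cov = np.asarray(noise_cov, dtype=float)
    m = noise_cov.shape[0]
    p = coeffs.shape[0] if coeffs.size else 0
    chol = np.linalg.cholesky(noise_cov + 1e-15 * np.eye(m))
    total = burn_in + n_samples
    e = rng.standard_normal((total, m, n_trials))
    x = np.zeros((total, m, n_trials))
    for s in range(total):
        acc = chol @ e[s]
        for k in range(1, min(p, s) + 1):
            acc += coeffs[k - 1] @ x[s - k]
        x[s] = acc
    return np.ascontiguousarray(x[burn_in:].transpose(1, 0, 2))
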