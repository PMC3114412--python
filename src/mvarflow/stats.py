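"""Significance assessment for connectivity estimates.

Nonparametric nulls come from phase-randomization surrogates (independent
uniform phases per channel, destroying all cross-channel dependence while
exactly preserving each channel's amplitude spectrum), trial-label
permutation (between-condition differences), and trial bootstrap
(confidence bands).  Analytic asymptotic tests are provided for PDC and DTF
via the delta method on the fitted coefficients.  Multiple comparisons are
corrected by Benjamini-Hochberg or Benjamini-Yekutieli FDR.

Surrogate and permutation p-values use the finite-sample-valid
``(1 + exceedances) / (1 + N)`` convention and therefore can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .dataset import EpochedTimeSeries
from .exceptions import InvalidArgumentError, MvarflowError
from .measures import ConnectivityResult
from .var import VARModel

__all__ = [
    "StatResult",
    "ConfidenceBands",
    "phase_surrogate",
    "surrogate_test",
    "bootstrap_ci",
    "permutation_test",
    "analytic_test",
    "fdr_correct",
]


@dataclass
class StatResult:
    """Null-based significance result aligned with a ConnectivityResult.

    ``pvalues``, ``qvalues`` and ``mask`` share the observed result's
    (sink, source, freq, window) index space; diagonal cells are NaN/False.
    ``method`` records the test descriptor (type, n resamples, seed, tail).
    """

    observed: ConnectivityResult
    pvalues: np.ndarray
    qvalues: np.ndarray
    mask: np.ndarray
    method: dict
    null_samples: np.ndarray | None = None


@dataclass
class ConfidenceBands:
    """Elementwise percentile confidence bands over a ConnectivityResult."""

    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise InvalidArgumentError(f"level must be in (0,1), got {self.level}")


def phase_surrogate(
    ts: EpochedTimeSeries, seed: int | np.random.Generator | None = None
) -> EpochedTimeSeries:
    """Phase-randomization surrogate of an epoched dataset.

    Per channel and trial: discrete Fourier transform, amplitudes kept
    exactly, phases of all non-DC, non-Nyquist bins replaced by i.i.d.
    uniform(-pi, pi) draws — independently across channels, so any
    cross-channel dependence is destroyed while each autospectrum is
    preserved.  DC and Nyquist bins stay real; the output is real.
    """
    if ts.n_samples < 4:
        raise InvalidArgumentError("phase surrogate needs n_samples >= 4")
    rng = np.random.default_rng(seed)
    n = ts.n_samples
    spec = np.fft.rfft(ts.data, axis=1)
    nbins = spec.shape[1]
    lo, hi = 1, nbins - 1 if n % 2 == 0 else nbins  # skip DC; skip Nyquist if present
    phases = rng.uniform(-np.pi, np.pi, size=(ts.n_channels, hi - lo, ts.n_trials))
    amp = np.abs(spec[:, lo:hi, :])
    spec[:, lo:hi, :] = amp * np.exp(1j * phases)
    out = np.fft.irfft(spec, n=n, axis=1)
    return ts.with_data(out)


def _exceedance_p(observed: np.ndarray, null: np.ndarray, tail: str) -> np.ndarray:
    """(1 + #exceedances) / (1 + N) per cell; null has shape (N, ...)."""
    n = null.shape[0]
    if tail == "right":
        exceed = (null >= observed[None]).sum(axis=0)
    elif tail == "two":
        exceed = (np.abs(null) >= np.abs(observed)[None]).sum(axis=0)
    else:
        raise InvalidArgumentError(f"unknown tail {tail!r}")
    return (1.0 + exceed) / (1.0 + n)


def _mask_diagonal(p: np.ndarray) -> np.ndarray:
    m = p.shape[0]
    idx = np.arange(m)
    p[idx, idx, :, :] = np.nan
    return p


def surrogate_test(
    pipeline,
    ts: EpochedTimeSeries,
    n_surrogates: int = 99,
    seed: int | None = None,
    tail: str = "right",
    q: float = 0.05,
    fdr_mode: str = "bh",
    keep_null: bool = False,
) -> StatResult:
    """Phase-randomization surrogate test for a connectivity pipeline.

    ``pipeline`` maps an EpochedTimeSeries to a ConnectivityResult (fit +
    measure with identical settings); it is applied to ``n_surrogates``
    phase-randomized datasets to build the null.  The diagonal is excluded.
    """
    if n_surrogates < 19:
        raise InvalidArgumentError("need n_surrogates >= 19")
    observed = pipeline(ts)
    rng = np.random.default_rng(seed)
    null = np.empty((n_surrogates,) + observed.values.shape)
    for b in range(n_surrogates):
        try:
            null[b] = pipeline(phase_surrogate(ts, rng)).values
        except MvarflowError as exc:
            raise type(exc)(f"pipeline failed on surrogate {b}: {exc}") from exc
    p = _mask_diagonal(_exceedance_p(observed.values, null, tail))
    qv, mask = fdr_correct(p, q=q, mode=fdr_mode)
    return StatResult(
        observed=observed, pvalues=p, qvalues=qv, mask=mask,
        method={"test": "phase_surrogate", "n_surrogates": n_surrogates,
                "seed": seed, "tail": tail, "q": q, "fdr": fdr_mode,
                "phase_randomization": "independent per channel"},
        null_samples=null if keep_null else None,
    )


def bootstrap_ci(
    pipeline,
    ts: EpochedTimeSeries,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int | None = None,
) -> ConfidenceBands:
    """Trial-bootstrap percentile confidence bands for a pipeline's output."""
    if ts.n_trials < 2:
        raise InvalidArgumentError("bootstrap needs n_trials >= 2")
    if n_boot < 100:
        raise InvalidArgumentError("need n_boot >= 100")
    rng = np.random.default_rng(seed)
    first = pipeline(ts)
    boots = np.empty((n_boot,) + first.values.shape)
    for b in range(n_boot):
        idx = rng.integers(0, ts.n_trials, size=ts.n_trials)
        boots[b] = pipeline(ts.with_data(ts.data[:, :, idx])).values
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boots, alpha, axis=0)
    upper = np.quantile(boots, 1.0 - alpha, axis=0)
    return ConfidenceBands(lower=lower, upper=upper, level=level)


def permutation_test(
    pipeline,
    ts_a: EpochedTimeSeries,
    ts_b: EpochedTimeSeries,
    n_perm: int = 199,
    seed: int | None = None,
    q: float = 0.05,
    fdr_mode: str = "bh",
) -> StatResult:
    """Between-condition permutation test on measure(a) - measure(b).

    Trial condition labels are shuffled; the two-sided p-value uses the
    ``(1 + exceedances)/(1 + N)`` convention.
    """
    if ts_a.n_channels != ts_b.n_channels or ts_a.n_samples != ts_b.n_samples \
            or ts_a.srate != ts_b.srate:
        raise InvalidArgumentError("conditions must share channels, samples and srate")
    if n_perm < 19:
        raise InvalidArgumentError("need n_perm >= 19")
    obs_a = pipeline(ts_a)
    obs_b = pipeline(ts_b)
    observed = replace(obs_a, measure=obs_a.measure + "_diff",
                       values=obs_a.values - obs_b.values)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([ts_a.data, ts_b.data], axis=2)
    na = ts_a.n_trials
    null = np.empty((n_perm,) + observed.values.shape)
    for b in range(n_perm):
        idx = rng.permutation(pooled.shape[2])
        perm_a = ts_a.with_data(pooled[:, :, idx[:na]])
        perm_b = ts_a.with_data(pooled[:, :, idx[na:]])
        null[b] = pipeline(perm_a).values - pipeline(perm_b).values
    p = _exceedance_p(observed.values, null, "two")
    qv, mask = fdr_correct(p, q=q, mode=fdr_mode)
    return StatResult(
        observed=observed, pvalues=p, qvalues=qv, mask=mask,
        method={"test": "permutation", "n_perm": n_perm, "seed": seed,
                "tail": "two", "q": q, "fdr": fdr_mode},
    )


# ---------------------------------------------------------------------------
# analytic asymptotics for PDC / DTF
# ---------------------------------------------------------------------------

def _coef_cov_blocks(model: VARModel) -> np.ndarray:
    """Per-row coefficient covariance basis: inv(Gamma) / n_obs, (pM, pM).

    The OLS coefficient rows satisfy cov(b_i, b_m) = Sigma[i, m] * this
    matrix, with regressor layout block k-1 holding the lag-k channels.
    """
    if model.regressor_cov is None:
        raise InvalidArgumentError(
            "model carries no regressor covariance; refit with fit_var"
        )
    return np.linalg.pinv(model.regressor_cov) / model.n_obs


def analytic_test(
    cr: ConnectivityResult,
    model: VARModel,
    measure: str | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
    fdr_mode: str = "bh",
) -> StatResult:
    """Asymptotic chi-squared significance test for PDC or DTF.

    Under the null of no coupling j -> i, the estimated numerator
    (``|Abar_ij(f)|^2`` for PDC, ``|H_ij(f)|^2`` for DTF via the delta
    method) is asymptotically a two-degree-of-freedom chi-squared variable
    scaled by the estimator variance, which shrinks as 1/n_obs.  P-values
    and per-cell null thresholds come from that approximation, divided by
    the observed normalization denominator.  The result is asymptotic: its
    calibration is checked empirically, not assumed.
    """
    from .spectral import spectral_set  # local import to avoid a cycle

    name = measure or cr.measure
    if name not in ("pdc", "dtf"):
        raise InvalidArgumentError(
            f"analytic test supports 'pdc' and 'dtf', not {name!r}"
        )
    if not (0 < alpha < 1):
        raise InvalidArgumentError(f"alpha must be in (0,1), got {alpha}")
    m = model.n_channels
    p_ord = model.order
    g_inv = _coef_cov_blocks(model)  # (pM, pM)
    ss = spectral_set(model, cr.freqs)
    nf = cr.freqs.size
    sigma = model.noise_cov
    # phase vector per frequency: c[f, k] = exp(-i w k)
    cvec = np.exp(-2j * np.pi * np.outer(cr.freqs, np.arange(1, p_ord + 1)) / model.srate)
    scale = np.full((m, m, nf), np.nan)  # mean of the 2x2 Re/Im covariance eigenvalues
    if name == "pdc":
        a2 = np.abs(ss.A_f) ** 2
        denom = a2.sum(axis=1)  # (F, M): per source column
        for f in range(nf):
            for j in range(m):
                cols = np.arange(p_ord) * m + j  # positions of channel j's lags
                v_base = g_inv[np.ix_(cols, cols)]
                c = cvec[f]
                re_c, im_c = np.real(c), np.imag(c)
                for i in range(m):
                    if i == j:
                        continue
                    v = sigma[i, i] * v_base
                    vrr = re_c @ v @ re_c
                    vii = im_c @ v @ im_c
                    scale[i, j, f] = 0.5 * (vrr + vii)
        stat = np.abs(ss.A_f.transpose(1, 2, 0)) ** 2  # (M, M, F)
        norm = denom.T[None, :, :]  # (1, M_source, F) broadcast over sinks
    else:  # dtf
        h = ss.H_f
        h2 = np.abs(h) ** 2
        denom = h2.sum(axis=2)  # (F, M): per sink row
        big = np.kron(sigma, g_inv)  # cov over index (m, (k, l)) flattened
        for f in range(nf):
            c = cvec[f]
            for i in range(m):
                for j in range(m):
                    if i == j:
                        continue
                    # delta method: dH_ij = sum_{m', l, k} H_im' H_lj e^{-iwk} dA_k[m', l]
                    w = np.einsum("a,b,k->akb", h[f, i, :], h[f, :, j], c)
                    wf = w.reshape(-1)  # (m' , k, l) -> matches kron(Sigma, Ginv) layout
                    re_w, im_w = np.real(wf), np.imag(wf)
                    vrr = re_w @ big @ re_w
                    vii = im_w @ big @ im_w
                    scale[i, j, f] = 0.5 * (vrr + vii)
        stat = h2.transpose(1, 2, 0)
        norm = denom.T[:, None, :]  # (M_sink, 1, F) broadcast over sources
    with np.errstate(invalid="ignore", divide="ignore"):
        z = stat / scale  # ~ chi2(2) under the null
        pvals = scipy.stats.chi2.sf(z, df=2)
    pvals = pvals[:, :, :, None]
    idx = np.arange(m)
    pvals[idx, idx] = np.nan
    thresh = scale * scipy.stats.chi2.ppf(1.0 - alpha, df=2) / norm
    qv, mask = fdr_correct(pvals, q=q, mode=fdr_mode)
    return StatResult(
        observed=cr, pvalues=pvals, qvalues=qv, mask=mask,
        method={"test": "analytic", "measure": name, "alpha": alpha,
                "n_obs": model.n_obs, "q": q, "fdr": fdr_mode,
                "thresholds": thresh[:, :, :, None]},
    )


def fdr_correct(
    pvalues: np.ndarray, q: float = 0.05, mode: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """False-discovery-rate correction (Benjamini-Hochberg / Yekutieli).

    NaN p-values (e.g. diagonal cells) are passed through as NaN q-values
    and never rejected.  Returns ``(qvalues, mask)`` with the input shape;
    q-values are monotone nondecreasing in p-rank and the mask is
    ``qvalues <= q``.
    """
    if mode not in ("bh", "by"):
        raise InvalidArgumentError(f"unknown FDR mode {mode!r}")
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    flat = p[finite]
    if flat.size and (flat.min() < 0 or flat.max() > 1):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    qv = np.full(p.shape, np.nan)
    mask = np.zeros(p.shape, dtype=bool)
    if flat.size:
        method = "fdr_bh" if mode == "bh" else "fdr_by"
        rej, q_flat, _, _ = multipletests(flat, alpha=q, method=method)
        qv[finite] = np.minimum(q_flat, 1.0)
        mask[finite] = qv[finite] <= q
    return qv, mask
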