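"""Frequency-domain Granger-causal connectivity measures.

Every measure is a deterministic function of the fitted VAR model through its
:class:`~mvarflow.spectral.SpectralSet` (transfer matrix H, spectral matrix S,
inverse spectral matrix P, and spectral coefficient matrix Abar).  The index
convention is ``values[i, j, f, w]`` = flow from source j into sink i at
frequency f in window w, matching the coefficient orientation of
:mod:`mvarflow.var`.

Canonical definitions used (squared-magnitude forms are the registry
defaults; magnitude forms are explicit variants):

==================  ==========================================================
coherence           ``|S_ij|^2 / (S_ii S_jj)``
partial coherence   ``|P_ij|^2 / (P_ii P_jj)``
multiple coherence  ``1 - 1 / (S_ii P_ii)`` (diagonal)
DTF                 ``|H_ij|^2 / sum_m |H_im|^2`` (sink/row normalized)
ffDTF               ``|H_ij(f)|^2 / sum_f sum_m |H_im(f)|^2``
dDTF                ``ffDTF * partial coherence``
PDC                 ``|Abar_ij|^2 / sum_m |Abar_mj|^2`` (source/column norm.)
GPDC                PDC with each row i of Abar weighted by ``1/sigma_ii``
Geweke spectral GC  ``ln( S_ii / (S_ii - (Sig_jj - Sig_ij^2/Sig_ii)|H_ij|^2) )``
time-domain GC      ``ln( Sig_reduced[i,i] / Sig_full[i,i] )``
==================  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import EpochedTimeSeries
from .exceptions import DegenerateDataError, InvalidArgumentError
from .spectral import SpectralSet, spectral_set
from .var import VARModel, fit_var

__all__ = [
    "ConnectivityResult",
    "power_spectrum",
    "coherence",
    "partial_coherence",
    "multiple_coherence",
    "dtf",
    "ffdtf",
    "ddtf",
    "pdc",
    "gpdc",
    "gc_time",
    "ggc_spectral",
    "measure_registry",
    "evaluate_measure",
    "graph_measures",
]


@dataclass
class ConnectivityResult:
    """Connectivity values indexed (sink, source, frequency, window).

    ``values`` has shape (M, M, n_freqs, n_windows); ``freqs`` is in Hz
    (a single NaN for frequency-free measures), ``window_centers`` in
    event-relative seconds, and ``model_orders`` records the VAR order used
    in each window.
    """

    measure: str
    values: np.ndarray
    freqs: np.ndarray
    window_centers: np.ndarray
    model_orders: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[3]


def _wrap(measure: str, vals_fij: np.ndarray, ss: SpectralSet,
          window_center: float | None, order: int) -> ConnectivityResult:
    """Package an (F, M, M) per-frequency array as a one-window result."""
    values = vals_fij.transpose(1, 2, 0)[:, :, :, None]
    wc = 0.0 if window_center is None else float(window_center)
    return ConnectivityResult(
        measure=measure,
        values=np.ascontiguousarray(values),
        freqs=ss.freqs.copy(),
        window_centers=np.array([wc]),
        model_orders=np.array([order]),
    )


def _center_order(ss: SpectralSet, model: VARModel | None):
    if model is not None:
        return model.window_center, model.order
    return None, -1  # order unknown without the model


# ---------------------------------------------------------------------------
# spectra and coherences
# ---------------------------------------------------------------------------

def power_spectrum(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Spectral power on the diagonal; cross-spectral magnitude off it."""
    s = ss.S_f
    vals = np.abs(s)
    f_idx = np.arange(s.shape[1])
    vals[:, f_idx, f_idx] = np.real(s[:, f_idx, f_idx])
    wc, order = _center_order(ss, model)
    return _wrap("power", vals, ss, wc, order)


def _check_auto_positive(ss: SpectralSet) -> np.ndarray:
    auto = np.real(np.einsum("fii->fi", ss.S_f))
    if np.any(auto <= 0):
        f, i = np.argwhere(auto <= 0)[0]
        raise DegenerateDataError(
            f"zero auto-spectrum for channel {i} at f = {ss.freqs[f]:g} Hz"
        )
    return auto


def coherence(ss: SpectralSet, model: VARModel | None = None,
              squared: bool = True) -> ConnectivityResult:
    """Magnitude-squared (or magnitude) ordinary coherence."""
    auto = _check_auto_positive(ss)
    denom = auto[:, :, None] * auto[:, None, :]
    c = np.abs(ss.S_f) ** 2 / denom
    c = np.clip(c, 0.0, 1.0)
    if not squared:
        c = np.sqrt(c)
    wc, order = _center_order(ss, model)
    return _wrap("coherence" if squared else "coherence_mag", c, ss, wc, order)


def imaginary_coherence(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Absolute imaginary part of the complex coherency."""
    auto = _check_auto_positive(ss)
    denom = np.sqrt(auto[:, :, None] * auto[:, None, :])
    c = np.abs(np.imag(ss.S_f)) / denom
    wc, order = _center_order(ss, model)
    return _wrap("imag_coherence", np.clip(c, 0.0, 1.0), ss, wc, order)


def cross_spectrum(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Cross-spectral magnitude |S_ij(f)| (unnormalized)."""
    wc, order = _center_order(ss, model)
    return _wrap("cross_spectrum", np.abs(ss.S_f), ss, wc, order)


def partial_coherence(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Coherence after removing the linear influence of all other channels.

    Computed from the inverse spectral matrix P = S^-1 as
    ``|P_ij|^2 / (P_ii P_jj)``; for two channels it reduces to the ordinary
    coherence.
    """
    p = ss.P_f
    auto = np.real(np.einsum("fii->fi", p))
    denom = auto[:, :, None] * auto[:, None, :]
    c = np.abs(p) ** 2 / denom
    c = np.clip(c, 0.0, 1.0)
    f_idx = np.arange(p.shape[1])
    c[:, f_idx, f_idx] = 1.0
    wc, order = _center_order(ss, model)
    return _wrap("partial_coherence", c, ss, wc, order)


def multiple_coherence(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Coherence of each channel with all others jointly: 1 - 1/(S_ii P_ii).

    Stored on the diagonal; off-diagonal entries are zero.
    """
    s_auto = _check_auto_positive(ss)
    p_auto = np.real(np.einsum("fii->fi", ss.P_f))
    mc = np.clip(1.0 - 1.0 / (s_auto * p_auto), 0.0, 1.0)
    f, m = s_auto.shape
    vals = np.zeros((f, m, m))
    idx = np.arange(m)
    vals[:, idx, idx] = mc
    wc, order = _center_order(ss, model)
    return _wrap("multiple_coherence", vals, ss, wc, order)


# ---------------------------------------------------------------------------
# directed transfer function family
# ---------------------------------------------------------------------------

def dtf(ss: SpectralSet, model: VARModel | None = None,
        squared: bool = True, normalized: bool = True) -> ConnectivityResult:
    """Directed transfer function: |H_ij|^2 normalized over sources per sink."""
    h2 = np.abs(ss.H_f) ** 2
    vals = h2 / h2.sum(axis=2, keepdims=True) if normalized else h2
    name = "dtf" if normalized else "dtf_nonnorm"
    if not squared:
        vals = np.sqrt(vals)
        name += "_mag"
    wc, order = _center_order(ss, model)
    return _wrap(name, vals, ss, wc, order)


def ffdtf(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Full-frequency DTF: |H_ij(f)|^2 / sum_f sum_m |H_im(f)|^2 per sink."""
    h2 = np.abs(ss.H_f) ** 2
    denom = h2.sum(axis=2).sum(axis=0)  # per sink, over sources and freqs
    vals = h2 / denom[None, :, None]
    wc, order = _center_order(ss, model)
    return _wrap("ffdtf", vals, ss, wc, order)


def ddtf(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Direct DTF: elementwise ffDTF × partial coherence.

    The partial-coherence factor suppresses indirect (cascade) pathways that
    plain DTF cannot distinguish from direct ones.
    """
    a = ffdtf(ss, model)
    b = partial_coherence(ss, model)
    return replace(a, measure="ddtf", values=a.values * b.values)


# ---------------------------------------------------------------------------
# partial directed coherence family
# ---------------------------------------------------------------------------

def pdc(ss: SpectralSet, model: VARModel | None = None,
        squared: bool = True, normalized: bool = True) -> ConnectivityResult:
    """Partial directed coherence: |Abar_ij|^2 normalized over sinks per source."""
    a2 = np.abs(ss.A_f) ** 2
    if normalized:
        vals = a2 / a2.sum(axis=1, keepdims=True)
        name = "pdc"
    else:
        vals = a2
        name = "pdc_factor"
    if not squared:
        vals = np.sqrt(vals)
        if normalized:
            name = "pdc_mag"
    wc, order = _center_order(ss, model)
    return _wrap(name, vals, ss, wc, order)


def gpdc(ss: SpectralSet, model: VARModel | None = None) -> ConnectivityResult:
    """Generalized PDC: rows of Abar weighted by 1/sigma_ii before normalizing.

    Scale-invariant: rescaling one channel's data leaves GPDC unchanged.
    """
    sig = np.diag(ss.noise_cov)
    if np.any(sig <= 0):
        i = int(np.argwhere(sig <= 0)[0])
        raise DegenerateDataError(f"zero innovation variance for channel {i}")
    w = np.abs(ss.A_f) ** 2 / sig[None, :, None]
    vals = w / w.sum(axis=1, keepdims=True)
    wc, order = _center_order(ss, model)
    return _wrap("gpdc", vals, ss, wc, order)


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def gc_time(window: EpochedTimeSeries, order: int,
            method: str = "ols", conditional: bool = True) -> ConnectivityResult:
    """Time-domain (conditional) Granger causality between all channel pairs.

    GC(j -> i) = ln( Sigma_reduced[i, i] / Sigma_full[i, i] ), where the
    reduced model omits channel j's lags from the regression for channel i
    (conditional on all remaining channels when ``conditional``; for two
    channels pairwise and conditional coincide).  Small negative values are
    clipped at 0.  The diagonal is NaN (self-causality is undefined).
    """
    m = window.n_channels
    full = fit_var(window, order, method=method)
    vals = np.full((m, m), np.nan)
    for j in range(m):
        keep = [c for c in range(m) if c != j]
        sub = EpochedTimeSeries(
            data=window.data[keep], srate=window.srate, times=window.times,
            channel_labels=[window.channel_labels[c] for c in keep],
            condition=window.condition,
        )
        reduced = fit_var(sub, order, method=method)
        for pos, i in enumerate(keep):
            if not conditional and m > 2:
                # pairwise: refit on the (i, j) pair only
                pair = EpochedTimeSeries(
                    data=window.data[[i, j]], srate=window.srate,
                    times=window.times,
                    channel_labels=[window.channel_labels[i],
                                    window.channel_labels[j]],
                )
                pm_full = fit_var(pair, order, method=method)
                pi = EpochedTimeSeries(
                    data=window.data[[i]], srate=window.srate,
                    times=window.times,
                    channel_labels=[window.channel_labels[i]],
                )
                pm_red = fit_var(pi, order, method=method)
                g = np.log(pm_red.noise_cov[0, 0] / pm_full.noise_cov[0, 0])
            else:
                g = np.log(reduced.noise_cov[pos, pos] / full.noise_cov[i, i])
            vals[i, j] = max(g, 0.0)
    return ConnectivityResult(
        measure="gc_time",
        values=vals[:, :, None, None],
        freqs=np.array([np.nan]),
        window_centers=np.array([0.0]),
        model_orders=np.array([order]),
    )


def _geweke_from_model(model: VARModel, freqs: np.ndarray | None) -> np.ndarray:
    """Geweke spectral GC from a bivariate (or per-pair valid) model.

    Returns (F, M, M) with [f, i, j] = f_{j->i}(f); diagonal 0.
    """
    ss = spectral_set(model, freqs)
    s = ss.S_f
    h2 = np.abs(ss.H_f) ** 2
    sig = model.noise_cov
    m = model.n_channels
    out = np.zeros((ss.freqs.size, m, m))
    for i in range(m):
        s_ii = np.real(s[:, i, i])
        for j in range(m):
            if i == j:
                continue
            # partial innovation variance of j given i
            sig_cond = sig[j, j] - sig[i, j] ** 2 / sig[i, i]
            intrinsic = s_ii - sig_cond * h2[:, i, j]
            ratio = s_ii / np.maximum(intrinsic, 1e-300)
            out[:, i, j] = np.maximum(np.log(np.maximum(ratio, 1e-300)), 0.0)
    return out


def ggc_spectral(
    window: EpochedTimeSeries | None = None,
    order: int | None = None,
    freqs: np.ndarray | None = None,
    model: VARModel | None = None,
    method: str = "ols",
) -> ConnectivityResult:
    """Geweke pairwise spectral Granger causality.

    For each ordered channel pair a bivariate VAR is refit on that pair and

        f_{j->i}(f) = ln( S_ii(f) / (S_ii(f) - (Sig_jj - Sig_ij^2/Sig_ii) |H_ij(f)|^2) )

    evaluated from the pair model; tiny negatives are clipped at 0.  When
    called with a two-channel ``model`` (no data), the formula is evaluated
    directly on it.
    """
    if window is None:
        if model is None or model.n_channels != 2:
            raise InvalidArgumentError(
                "ggc_spectral needs window data, or a 2-channel model"
            )
        vals = _geweke_from_model(model, freqs)
        ss = spectral_set(model, freqs)
        return _wrap("ggc_spectral", vals, ss, model.window_center, model.order)
    if order is None:
        raise InvalidArgumentError("order is required when fitting from data")
    m = window.n_channels
    ref_model = fit_var(window, order, method=method)
    ss = spectral_set(ref_model, freqs)
    out = np.zeros((ss.freqs.size, m, m))
    for i in range(m):
        for j in range(i + 1, m):
            pair = EpochedTimeSeries(
                data=window.data[[i, j]], srate=window.srate, times=window.times,
                channel_labels=[window.channel_labels[i], window.channel_labels[j]],
            )
            pm = fit_var(pair, order, method=method)
            g = _geweke_from_model(pm, ss.freqs)
            out[:, i, j] = g[:, 0, 1]
            out[:, j, i] = g[:, 1, 0]
    return _wrap("ggc_spectral", out, ss, None, order)


# ---------------------------------------------------------------------------
# registry and graph-level summaries
# ---------------------------------------------------------------------------

# name -> (callable(ss, model, window, order, freqs), normalized-to-[0,1]?)
_REGISTRY: dict[str, tuple] = {
    "power": (lambda ss, model, w, p, f: power_spectrum(ss, model), False),
    "cross_spectrum": (lambda ss, model, w, p, f: cross_spectrum(ss, model), False),
    "coherence": (lambda ss, model, w, p, f: coherence(ss, model), True),
    "coherence_mag": (lambda ss, model, w, p, f: coherence(ss, model, squared=False), True),
    "imag_coherence": (lambda ss, model, w, p, f: imaginary_coherence(ss, model), True),
    "partial_coherence": (lambda ss, model, w, p, f: partial_coherence(ss, model), True),
    "multiple_coherence": (lambda ss, model, w, p, f: multiple_coherence(ss, model), True),
    "dtf": (lambda ss, model, w, p, f: dtf(ss, model), True),
    "dtf_mag": (lambda ss, model, w, p, f: dtf(ss, model, squared=False), True),
    "dtf_nonnorm": (lambda ss, model, w, p, f: dtf(ss, model, normalized=False), False),
    "ffdtf": (lambda ss, model, w, p, f: ffdtf(ss, model), True),
    "ddtf": (lambda ss, model, w, p, f: ddtf(ss, model), True),
    "pdc": (lambda ss, model, w, p, f: pdc(ss, model), True),
    "pdc_mag": (lambda ss, model, w, p, f: pdc(ss, model, squared=False), True),
    "pdc_factor": (lambda ss, model, w, p, f: pdc(ss, model, normalized=False), False),
    "gpdc": (lambda ss, model, w, p, f: gpdc(ss, model), True),
    "ggc_spectral": (
        lambda ss, model, w, p, f: ggc_spectral(window=w, order=p, freqs=ss.freqs,
                                                model=model),
        False,
    ),
}


def measure_registry() -> list[str]:
    """Names of all frequency-domain measures derivable from a fitted model."""
    return list(_REGISTRY)


def is_normalized(name: str) -> bool:
    """True when the measure is bounded in [0, 1] by construction."""
    return _REGISTRY[name][1]


def evaluate_measure(
    name: str,
    model: VARModel,
    freqs: np.ndarray | None = None,
    window: EpochedTimeSeries | None = None,
    ss: SpectralSet | None = None,
) -> ConnectivityResult:
    """Dispatch a registry measure on a fitted model.

    ``window`` is only needed for measures requiring per-pair refits
    (``ggc_spectral`` with more than two channels); ``ss`` can be passed to
    reuse a precomputed spectral set.
    """
    if name not in _REGISTRY:
        raise InvalidArgumentError(
            f"unknown measure {name!r}; see measure_registry()"
        )
    if ss is None:
        ss = spectral_set(model, freqs)
    fn, _ = _REGISTRY[name]
    return fn(ss, model, window, model.order, ss.freqs)


def graph_measures(cr: ConnectivityResult, band: tuple[float, float]) -> dict:
    """Node-level causal-flow summaries in a frequency band, per window.

    Returns a dict with per-window arrays:

    * ``outflow``  (M, W): sum over sinks i != j of the band-averaged flow j->i
    * ``inflow``   (M, W): sum over sources i != j of the flow i->j
    * ``asymmetry_ratio`` (M, W): (outflow - inflow)/(outflow + inflow),
      +1 = pure causal source, -1 = pure causal sink, 0 when both are 0
    * ``causal_density`` (W,): mean off-diagonal band-averaged value
    """
    f_lo, f_hi = band
    sel = (cr.freqs >= f_lo) & (cr.freqs <= f_hi)
    if not np.any(sel):
        raise InvalidArgumentError(
            f"band [{f_lo}, {f_hi}] Hz contains no grid frequencies"
        )
    # band-average, then zero the diagonal for flow sums
    bm = cr.values[:, :, sel, :].mean(axis=2)  # (sink, source, window)
    m = bm.shape[0]
    off = bm.copy()
    idx = np.arange(m)
    off[idx, idx, :] = 0.0
    outflow = off.sum(axis=0)  # per source j: sum over sinks
    inflow = off.sum(axis=1)   # per sink j: sum over sources
    tot = outflow + inflow
    with np.errstate(invalid="ignore", divide="ignore"):
        asym = np.where(tot > 0, (outflow - inflow) / np.where(tot > 0, tot, 1.0), 0.0)
    density = off.sum(axis=(0, 1)) / (m * (m - 1)) if m > 1 else np.zeros(bm.shape[2])
    return {
        "outflow": outflow,
        "inflow": inflow,
        "asymmetry_ratio": asym,
        "causal_density": density,
    }
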