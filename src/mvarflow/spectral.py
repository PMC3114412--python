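"""Frequency-domain quantities derived from a fitted VAR model.

Fourier-transforming the VAR coefficient matrices gives, per frequency f,

* the spectral coefficient matrix  ``Abar(f) = I - sum_k A_k exp(-i 2 pi f k / srate)``,
* the transfer matrix              ``H(f) = Abar(f)^-1``,
* the spectral (cross-spectral density) matrix ``S(f) = H(f) Sigma H(f)^H``,
* the inverse spectral matrix      ``P(f) = S(f)^-1`` (computed lazily; it is
  only needed for the partial-coherence family).

``S`` is on the model's natural scale: the one-sided power spectral density in
units^2/Hz is ``2 S(f) / srate``, and the process variance equals the integral
of ``S`` over (0, Nyquist] times ``2/srate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np

from .exceptions import ConditioningError, InvalidArgumentError, SingularityError
from .var import VARModel, spectral_radius

__all__ = ["SpectralSet", "spectral_set", "default_freqs"]


@dataclass
class SpectralSet:
    """Per-frequency matrices for one VAR model.

    All matrix stacks have shape (n_freqs, M, M) and the [i, j] element is
    sink i, source j.
    """

    freqs: np.ndarray
    A_f: np.ndarray
    H_f: np.ndarray
    S_f: np.ndarray
    noise_cov: np.ndarray
    srate: float
    _P_f: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.S_f.shape[1]

    @property
    def P_f(self) -> np.ndarray:
        """Inverse spectral matrix S(f)^-1, computed on first access."""
        if self._P_f is None:
            cond = np.linalg.cond(self.S_f)
            worst = int(np.argmax(cond))
            if not np.all(np.isfinite(cond)) or cond.max() > 1e12:
                raise ConditioningError(
                    f"spectral matrix is near-singular at f = "
                    f"{self.freqs[worst]:g} Hz (condition number {cond.max():.3g})"
                )
            self._P_f = np.linalg.inv(self.S_f)
        return self._P_f


def default_freqs(srate: float, spacing: float = 1.0) -> np.ndarray:
    """Default linear grid: ``spacing`` Hz steps from ``spacing`` to Nyquist-1.

    DC is excluded because Abar(0) is near-singular for near-unit-root models.
    """
    nyq = srate / 2.0
    return np.arange(spacing, nyq - 1.0 + 1e-9, spacing)


def spectral_set(model: VARModel, freqs: np.ndarray | None = None) -> SpectralSet:
    """Evaluate Abar(f), H(f) and S(f) on a frequency grid.

    Parameters
    ----------
    model : VARModel
    freqs : ndarray, optional
        Frequencies in Hz, each in (0, srate/2]; defaults to
        :func:`default_freqs`.

    Raises
    ------
    SingularityError
        If Abar(f) is singular at some frequency (the message names it).
    """
    if freqs is None:
        freqs = default_freqs(model.srate)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise InvalidArgumentError("frequency grid is empty")
    nyq = model.srate / 2.0
    if np.any(freqs <= 0) or np.any(freqs > nyq + 1e-9):
        raise InvalidArgumentError(
            f"frequencies must lie in (0, {nyq}] Hz"
        )
    radius = spectral_radius(model.coeffs)
    if radius >= 1.0:
        warnings.warn(
            f"model is unstable (spectral radius {radius:.3f}); "
            "spectral quantities may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    m = model.n_channels
    p = model.order
    eye = np.eye(m)
    # phase factors exp(-i 2 pi f k / srate), shape (F, p)
    if p > 0:
        phase = np.exp(-2j * np.pi * np.outer(freqs, np.arange(1, p + 1)) / model.srate)
        a_f = eye[None, :, :] - np.einsum("fk,kij->fij", phase, model.coeffs)
    else:
        a_f = np.broadcast_to(eye.astype(complex), (freqs.size, m, m)).copy()
    det = np.abs(np.linalg.det(a_f))
    cond = np.linalg.cond(a_f)
    bad = (det < 1e-10) | ~np.isfinite(cond) | (cond > 1e13)
    if np.any(bad):
        f_bad = freqs[int(np.argmax(bad))]
        raise SingularityError(f"Abar(f) is singular at f = {f_bad:g} Hz")
    h_f = np.linalg.inv(a_f)
    s_f = h_f @ model.noise_cov @ h_f.conj().transpose(0, 2, 1)
    # enforce exact Hermitian symmetry (removes 1-ulp asymmetry)
    s_f = 0.5 * (s_f + s_f.conj().transpose(0, 2, 1))
    return SpectralSet(freqs=freqs, A_f=a_f, H_f=h_f, S_f=s_f,
                       noise_cov=model.noise_cov.copy(), srate=model.srate)
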