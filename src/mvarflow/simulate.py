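"""Ground-truth VAR simulator: stationary and transiently-coupled processes.

Every estimator in the package is validated against data generated here,
where the directed causal graph is known exactly.  A
:class:`SimulationSpec` combines a stable time-invariant VAR backbone
(``base_coeffs``, typically independent AR(2) oscillators on the diagonal)
with a list of directed :class:`Coupling` terms whose amplitude can be
modulated over the epoch by a named envelope (``none`` = always on,
``boxcar``, ``hann``), producing the locally-stationary regime that
sliding-window estimators are built for.

Innovations are Gaussian, matching the linear-Gaussian assumptions of the
Granger-causality framework.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .dataset import EpochedTimeSeries
from .exceptions import InvalidArgumentError
from .var import spectral_radius

__all__ = [
    "Coupling",
    "SimulationSpec",
    "check_stability",
    "simulate",
    "preset_scenarios",
    "oscillator_coeffs",
    "random_stable_var",
]


def oscillator_coeffs(pole_radius: float, freq_hz: float, srate: float) -> tuple[float, float]:
    """AR(2) coefficients (a1, a2) for a damped oscillator.

    Poles at ``pole_radius * exp(+- i 2 pi freq_hz / srate)`` give
    ``a1 = 2 r cos(2 pi f / srate)``, ``a2 = -r^2``; the periodogram peaks
    near ``freq_hz``.
    """
    w = 2.0 * np.pi * freq_hz / srate
    return 2.0 * pole_radius * np.cos(w), -pole_radius ** 2


@dataclass(frozen=True)
class Coupling:
    """One directed coupling term: source -> sink at a given lag.

    ``envelope`` is 'none' (active over the whole epoch), 'boxcar' or 'hann'
    (active between ``onset`` and ``offset`` seconds, event-relative; the
    hann envelope tapers the amplitude smoothly to zero at both ends).
    """

    sink: int
    source: int
    lag: int
    amplitude: float
    envelope: str = "none"
    onset: float | None = None
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise InvalidArgumentError(f"coupling lag must be >= 1, got {self.lag}")
        if self.envelope not in ("none", "boxcar", "hann"):
            raise InvalidArgumentError(f"unknown envelope {self.envelope!r}")
        if self.envelope != "none" and (self.onset is None or self.offset is None):
            raise InvalidArgumentError("boxcar/hann envelopes need onset and offset")

    def gain(self, t: np.ndarray) -> np.ndarray:
        """Envelope gain in [0, 1] at event-relative times ``t`` (seconds)."""
        if self.envelope == "none":
            return np.ones_like(t)
        g = np.zeros_like(t)
        inside = (t >= self.onset) & (t <= self.offset)
        if self.envelope == "boxcar":
            g[inside] = 1.0
        else:
            span = self.offset - self.onset
            phase = (t[inside] - self.onset) / span
            g[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        return g


@dataclass
class SimulationSpec:
    """Full description of a simulated epoched VAR dataset.

    The time-invariant part (``base_coeffs``) must be stable on its own and
    the instantaneous coefficients must stay stable at every sample once the
    couplings are added (checked by :func:`check_stability` before
    simulation).  ``t0`` is the event-relative time of the first sample.
    """

    n_channels: int
    order: int
    base_coeffs: np.ndarray
    noise_cov: np.ndarray
    srate: float
    couplings: list[Coupling] = field(default_factory=list)
    n_trials: int = 50
    n_samples: int = 256
    burn_in: int = 1000
    seed: int = 0
    t0: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.base_coeffs = np.asarray(self.base_coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        m, p = self.n_channels, self.order
        if self.base_coeffs.shape != (p, m, m):
            raise InvalidArgumentError(
                f"base_coeffs shape {self.base_coeffs.shape} != ({p}, {m}, {m})"
            )
        if self.noise_cov.shape != (m, m):
            raise InvalidArgumentError("noise_cov shape mismatch")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise InvalidArgumentError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() < -1e-12:
            raise InvalidArgumentError("noise_cov must be PSD")
        for c in self.couplings:
            if not (0 <= c.sink < m and 0 <= c.source < m):
                raise InvalidArgumentError(f"coupling channel out of range: {c}")
            if c.lag > p:
                raise InvalidArgumentError(
                    f"coupling lag {c.lag} exceeds model order {p}"
                )
            if c.envelope != "none":
                t_end = self.t0 + (self.n_samples - 1) / self.srate
                if not (self.t0 <= c.onset <= c.offset <= t_end + 1e-9):
                    raise InvalidArgumentError(
                        f"envelope [{c.onset}, {c.offset}] s outside epoch "
                        f"[{self.t0}, {t_end}] s"
                    )

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.srate

    def coeffs_at(self, t: float) -> np.ndarray:
        """Instantaneous coefficient matrices A_k(t), shape (p, M, M)."""
        a = self.base_coeffs.copy()
        tt = np.array([t])
        for c in self.couplings:
            a[c.lag - 1, c.sink, c.source] += c.amplitude * float(c.gain(tt)[0])
        return a

    def to_json(self) -> str:
        d = asdict(self)
        d["base_coeffs"] = self.base_coeffs.tolist()
        d["noise_cov"] = self.noise_cov.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        d["couplings"] = [Coupling(**c) for c in d.get("couplings", [])]
        d["base_coeffs"] = np.asarray(d["base_coeffs"], dtype=float)
        d["noise_cov"] = np.asarray(d["noise_cov"], dtype=float)
        return cls(**d)


def check_stability(spec: SimulationSpec) -> np.ndarray:
    """Companion spectral radius of the instantaneous coefficients per sample."""
    times = spec.times
    if not spec.couplings or all(c.envelope == "none" for c in spec.couplings):
        r = spectral_radius(spec.coeffs_at(times[0]))
        return np.full(spec.n_samples, r)
    return np.array([spectral_radius(spec.coeffs_at(t)) for t in times])


def simulate(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[EpochedTimeSeries, np.ndarray]:
    """Generate epoched data plus the ground-truth causal graph.

    Each trial runs ``burn_in`` samples of the time-invariant base process
    (discarded), then the possibly time-varying recursion over the epoch.
    Returns ``(ts, truth)`` where ``truth`` is a boolean array
    (sink, source, n_samples) marking where each directed coupling (or static
    base off-diagonal term) is active.

    Raises
    ------
    InvalidArgumentError
        If the instantaneous coefficients are unstable at some time point
        (the message names it).
    """
    radii = check_stability(spec)
    if radii.max() >= 1.0:
        t_bad = spec.times[int(np.argmax(radii))]
        raise InvalidArgumentError(
            f"unstable coefficients (radius {radii.max():.3f}) at t = {t_bad:g} s"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m, p = spec.n_channels, spec.order
    times = spec.times
    # per-sample coefficient stack over the epoch (base + enveloped couplings)
    a_t = np.broadcast_to(spec.base_coeffs, (spec.n_samples, p, m, m)).copy()
    for c in spec.couplings:
        a_t[:, c.lag - 1, c.sink, c.source] += c.amplitude * c.gain(times)
    chol = np.linalg.cholesky(spec.noise_cov + 1e-15 * np.eye(m))
    total = spec.burn_in + spec.n_samples
    e = rng.standard_normal((total, m, spec.n_trials))
    x = np.zeros((total, m, spec.n_trials))
    for s in range(total):
        acc = chol @ e[s]
        epoch_idx = s - spec.burn_in
        a_now = spec.base_coeffs if epoch_idx < 0 else a_t[epoch_idx]
        for k in range(1, min(p, s) + 1):
            acc += a_now[k - 1] @ x[s - k]
        x[s] = acc
    data = np.ascontiguousarray(x[spec.burn_in:].transpose(1, 0, 2))
    ts = EpochedTimeSeries(
        data=data, srate=spec.srate, times=times,
        channel_labels=[f"ch{i}" for i in range(m)],
        condition=spec.name or None,
    )
    truth = np.zeros((m, m, spec.n_samples), dtype=bool)
    for c in spec.couplings:
        if c.amplitude != 0.0:
            truth[c.sink, c.source, :] |= c.gain(times) > 0
    base_any = np.abs(spec.base_coeffs).sum(axis=0) > 0
    np.fill_diagonal(base_any, False)
    truth |= base_any[:, :, None]
    return ts, truth


def random_stable_var(
    n_channels: int,
    order: int,
    rng: np.random.Generator | int | None = None,
    radius: float = 0.7,
) -> np.ndarray:
    """Random VAR coefficients rescaled to a given companion spectral radius.

    Scaling lag-k matrices by ``s**k`` scales every companion eigenvalue by
    ``s``, so the radius can be set exactly.
    """
    rng = np.random.default_rng(rng)
    a = rng.normal(scale=1.0 / np.sqrt(order * n_channels),
                   size=(order, n_channels, n_channels))
    r = spectral_radius(a)
    if r == 0:
        return a
    s = radius / r
    return a * (s ** np.arange(1, order + 1))[:, None, None]


def preset_scenarios() -> dict[str, SimulationSpec]:
    """Bundled ground-truth scenarios used throughout the test bed.

    * ``uncoupled3``  — three independent AR(2) oscillators (5, 10, 20 Hz);
      the complete-null scenario for type-I error calibration.
    * ``chain3``      — x1 -> x2 -> x3 chain of 5 Hz oscillators with static
      couplings of 0.5 at lag 1; no direct x1 -> x3 term.
    * ``transient_theta`` — two 5 Hz (theta-band) oscillators with an
      x1 -> x2 coupling active only under a 300 ms hann envelope after the
      event, emulating a transient event-related causal burst.
    * ``bidirectional2`` — two 10 Hz oscillators symmetrically coupled with
      equal strength in both directions.

    All presets use srate 128 Hz, unit innovation covariance, pole radius
    0.9, and pass :func:`check_stability`.
    """
    srate = 128.0
    r = 0.9

    def osc_base(freqs_hz: list[float]) -> np.ndarray:
        m = len(freqs_hz)
        a = np.zeros((2, m, m))
        for i, f in enumerate(freqs_hz):
            a1, a2 = oscillator_coeffs(r, f, srate)
            a[0, i, i] = a1
            a[1, i, i] = a2
        return a

    presets: dict[str, SimulationSpec] = {}
    presets["uncoupled3"] = SimulationSpec(
        n_channels=3, order=2, base_coeffs=osc_base([5.0, 10.0, 20.0]),
        noise_cov=np.eye(3), srate=srate, couplings=[],
        n_trials=30, n_samples=256, seed=101, name="uncoupled3",
    )
    presets["chain3"] = SimulationSpec(
        n_channels=3, order=2, base_coeffs=osc_base([5.0, 5.0, 5.0]),
        noise_cov=np.eye(3), srate=srate,
        couplings=[
            Coupling(sink=1, source=0, lag=1, amplitude=0.5),
            Coupling(sink=2, source=1, lag=1, amplitude=0.5),
        ],
        n_trials=100, n_samples=500, seed=202, name="chain3",
    )
    presets["transient_theta"] = SimulationSpec(
        n_channels=2, order=2, base_coeffs=osc_base([5.0, 5.0]),
        noise_cov=np.eye(2), srate=srate,
        couplings=[
            Coupling(sink=1, source=0, lag=1, amplitude=0.8,
                     envelope="hann", onset=0.1, offset=0.4),
        ],
        n_trials=50, n_samples=192, t0=-0.5, seed=303, name="transient_theta",
    )
    presets["bidirectional2"] = SimulationSpec(
        n_channels=2, order=2, base_coeffs=osc_base([10.0, 10.0]),
        noise_cov=np.eye(2), srate=srate,
        couplings=[
            Coupling(sink=1, source=0, lag=1, amplitude=0.15),
            Coupling(sink=0, source=1, lag=1, amplitude=0.15),
        ],
        n_trials=100, n_samples=256, seed=404, name="bidirectional2",
    )
    return presets
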