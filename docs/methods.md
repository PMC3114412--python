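# Methods

## Model and assumptions

`mvarflow` analyzes epoched multichannel recordings
(channels × samples × trials, with sampling rate `fs` and an
event-relative time axis in seconds) under a linear-Gaussian vector
autoregression of order `p` per analysis window:

```
x[t] = Σ_{k=1..p} A_k x[t−k] + e[t],   e[t] ~ N(0, Σ)
```

The index convention is fixed throughout the package: **row = sink,
column = source** (`A_k[i, j]` is the influence of channel `j` on channel
`i` at lag `k`).  A single convention prevents the silent transposition
that otherwise creeps in between the sink-normalized DTF and the
source-normalized PDC; a unidirectional simulation asserts it in the test
suite.

Granger causality in this framework: channel `j` causes channel `i` when
`j`'s past improves the linear prediction of `i` beyond what `i`'s own past
(and, conditionally, everyone else's) achieves.  All frequency-domain
measures derive from the fitted `A_k` and `Σ` only.

Assumptions worth stating plainly: linear dynamics, Gaussian innovations,
and local stationarity within each window.  Trials are treated as
independent realizations of the same process — regression rows are pooled
across trials and never straddle a trial boundary.  Nonstationarity across
the epoch is handled by sliding windows, not by time-varying coefficients
in the estimator.

## Preprocessing

* **Detrending** (`constant` or `linear`) subtracts the least-squares
  constant/line per channel and trial (`scipy.signal.detrend`).
* **Normalization**: `temporal` z-scores each (channel, trial) series over
  samples; `ensemble` standardizes each (channel, sample) point over
  trials, removing the trial-averaged evoked component.  Both use the
  unbiased (n−1) standard deviation so tests can be exact.  Whether a
  pipeline should apply one, the other, or both is data-dependent; the CLI
  accepts `temporal`, `ensemble`, or `both` (temporal, then ensemble) and
  the default pipeline applies neither unless asked.
* **Downsampling** filters with a zero-phase (forward–backward) order-8
  Chebyshev-I lowpass cut at 0.8 × the new Nyquist, then decimates.
  Factor 1 is the bit-exact identity.
* **Windowing** is onset-anchored: windows start at the epoch start and
  advance by the hop while the full window fits; a trailing partial window
  is dropped, never zero-padded, because padding would inject artificial
  nonstationarity into a locally-stationary model.  A window is identified
  by its center in event-relative seconds.

## Estimators

**OLS** solves the pooled lag-stacked least-squares problem; the
innovation covariance uses the degrees-of-freedom corrected denominator
`n_obs − p·M` (`n_obs` regression rows, `M` channels), which keeps `Σ̂`
unbiased on the short windows where it matters.  The regressor
second-moment matrix is retained on the model for analytic tests.

**Vieira-Morf** is a multichannel lattice (Levinson–Whittle) recursion
with geometric-mean normalized reflection coefficients, pooling forward
and backward prediction errors across trials.  It is better conditioned
than OLS on short windows; on long stationary data the two agree to well
under the 0.05 coefficient tolerance asserted in tests.  Kalman-filter and
spectral-factorization adaptive variants are out of scope; the `method`
string leaves room to add them.

**Order selection** minimizes `ln det Σ̂_ML + penalty · p·M²/n_obs` with
penalty 2 (AIC), `ln n` (BIC) or `2 ln ln n` (HQ); ties break toward the
smaller order.  Each candidate order is fit on its own maximal sample
span, which keeps the code simple at a negligible cost in comparability
for the window lengths this package targets.

**Validation** reports the companion-matrix spectral radius (stable iff
< 1), a multivariate Ljung–Box portmanteau test on residual
autocorrelations up to lag `min(20, n_samples/4)` (χ² with `M²(h−p)`
degrees of freedom), and a percent-consistency score: the model simulates
a dataset of the same shape (fixed internal seed, so pipelines stay
deterministic) and the stacked cross-correlation vectors of real and
simulated data are compared as `100·(1 − ‖R_sim − R_real‖/‖R_real‖)`.

## Spectral quantities and measures

Per frequency `f` in an ascending grid within `(0, fs/2]`:

```
Ā(f) = I − Σ_k A_k e^(−i2πfk/fs),   H(f) = Ā(f)⁻¹,
S(f) = H(f) Σ H(f)ᴴ,                P(f) = S(f)⁻¹
```

`S` is kept on the model's natural scale: the one-sided PSD in units²/Hz
is `2S/fs`, and the process variance equals `∫ S · 2/fs` over
`(0, Nyquist]` (checked by a Parseval test).  The default grid is 1 Hz
spacing from 1 Hz to Nyquist − 1; DC is excluded because `Ā(0)` is
near-singular for near-unit-root oscillators.  `P(f)` is computed lazily
and refuses condition numbers above 1e12.

Registry definitions (squared forms are the defaults; magnitude and
unnormalized forms are explicit variants):

| measure | definition |
|---|---|
| coherence | `\|S_ij\|² / (S_ii S_jj)` |
| imaginary coherence | `\|Im(S_ij/√(S_ii S_jj))\|` |
| partial coherence | `\|P_ij\|² / (P_ii P_jj)` |
| multiple coherence | `1 − 1/(S_ii P_ii)` |
| DTF | `\|H_ij\|² / Σ_m \|H_im\|²` (sink rows sum to 1) |
| ffDTF | `\|H_ij(f)\|² / Σ_f Σ_m \|H_im\|²` |
| dDTF | ffDTF × partial coherence |
| PDC | `\|Ā_ij\|² / Σ_m \|Ā_mj\|²` (source columns sum to 1) |
| GPDC | PDC with rows of Ā weighted by `1/σ_ii` (scale-invariant) |
| time-domain GC | `ln(Σ_reduced[i,i] / Σ_full[i,i])`, reduced model omitting source lags |
| Geweke spectral GC | `ln(S_ii / (S_ii − (Σ_jj − Σ_ij²/Σ_ii)\|H_ij\|²))`, per bivariate refit |

The exact enumeration of the registry (17 names) is this package's own.
Spectral GC is pairwise — each ordered pair gets a bivariate refit —
because the conditional spectral decomposition is a different estimator
with different failure modes and is deliberately out of scope.  Tiny
negative GC values (numerical) are clipped at zero.

A practical note the `chain3` scenario makes vivid: DTF measures *total*
directed flow, so a cascade `x0 → x1 → x2` produces large DTF into `x2`
from `x0`, and the direct `x1 → x2` edge can carry a small DTF share even
though it is the true generative link.  dDTF (via the partial-coherence
factor) and PDC are the cascade-resistant measures; use them when the
question is about direct edges.

**Graph summaries** per node `j` and window, after band-averaging a
measure: outflow `Σ_{i≠j} v[i,j]`, inflow `Σ_{i≠j} v[j,i]`, asymmetry
ratio `(out−in)/(out+in)` (+1 pure source, −1 pure sink, 0 when both are
0), and causal density (mean off-diagonal value).

## Statistics

**Phase-randomization surrogates** transform each (channel, trial) series
to the frequency domain, keep the amplitudes exactly, and redraw all
non-DC/non-Nyquist phases i.i.d. uniform(−π, π) — *independently across
channels*, so the null hypothesis is "no cross-channel dependence, with
every autospectrum preserved".  (Randomizing with a common phase vector
per trial would instead preserve cross-spectra; the independent-phase
choice is recorded in `StatResult.method`.)  P-values use the
finite-sample-valid `(1 + exceedances)/(1 + N)` convention and can never
be zero.  Calibration on the `uncoupled3` null preset and power on the
`chain3` edge are tested empirically.

**Bootstrap** resamples trials with replacement and reports percentile
bands; coverage is verified by simulation.  **Permutation** shuffles trial
condition labels for a two-sided test on `measure(a) − measure(b)`.

**Analytic tests** for PDC and DTF: under the null of no `j → i`
coupling, the numerator (`|Ā_ij(f)|²`, or `|H_ij(f)|²` via the delta
method `dH = −H dĀ H`) is asymptotically a scaled χ²(2) variable.  The
scale comes from the OLS coefficient covariance `Σ ⊗ (ZᵀZ)⁻¹`, mapped
through the frequency-response linear form; the Re/Im covariance is
summarized by its trace (mean eigenvalue), which is exact when the two
components have equal variance and a good approximation otherwise.
Thresholds shrink as 1/n_obs.  These are asymptotic results: the package
tests their calibration on simulations rather than assuming it.

**FDR**: Benjamini–Hochberg (default) or Benjamini–Yekutieli step-up,
applied jointly across all (sink, source, frequency, window) cells per
measure; NaN cells (the diagonal) pass through unrejected.  BH is
verified cell-for-cell against an independently coded step-up oracle.

## Simulator

The simulator is the package's ground truth: every estimator is validated
on data whose causal graph is known exactly.  A scenario combines a
stable time-invariant backbone (typically independent AR(2) oscillators:
pole radius `r` and frequency `f` give `a1 = 2r cos(2πf/fs)`,
`a2 = −r²`) with directed couplings whose amplitude can be modulated by a
boxcar or hann envelope over the epoch — producing exactly the
locally-stationary regime the sliding-window estimator targets.
Innovations are Gaussian, matching the model family.  Stability of the
instantaneous coefficients is checked at every sample before simulation;
a 1000-sample burn-in (sufficient for pole radii ≤ 0.98) is discarded
per trial.

Presets (all at 128 Hz, unit innovation covariance, pole radius 0.9):

* `uncoupled3` — independent 5/10/20 Hz oscillators; 30 trials × 2 s.
  The complete null for type-I calibration.
* `chain3` — three 5 Hz oscillators, `x0 → x1 → x2` at strength 0.5,
  lag 1; 100 trials × 500 samples, enough for the surrogate test to
  detect the true edge in ≥ 90% of runs.
* `transient_theta` — two 5 Hz (theta) oscillators, `x0 → x1` at 0.8
  under a 300 ms hann envelope (0.1–0.4 s after the event); epoch −0.5 to
  1.0 s, 50 trials.  Emulates a transient event-related causal burst.
* `bidirectional2` — two 10 Hz oscillators coupled symmetrically at 0.15
  (the largest symmetric coupling that keeps 10 Hz oscillators of this
  radius stable); asymmetry ratios should vanish.

What the simulator does *not* emulate: volume conduction / field spread,
non-Gaussian or nonlinear dynamics, measurement noise distinct from
innovations, and inter-subject variability.  Passing tests therefore show
correctness of the estimators under the model's own assumptions — not
robustness to the ways real EEG violates them.

## Numerical choices

* Innovation covariance is symmetrized and required PSD to 1e-10.
* `S(f)` is explicitly re-Hermitianized to kill 1-ulp asymmetry.
* `Ā(f)` singularity (|det| < 1e-10 or condition > 1e13) raises an error
  naming the frequency; an unstable model warns rather than errors, since
  windows that straddle a transient coupling legitimately fit unstable
  coefficients.
* Normalized measures are clipped to [0, 1]; GC values to [0, ∞).
* Order-selection ties break toward the smaller order.
* The pipeline's artifact files are byte-reproducible: container archives
  carry fixed zip timestamps, CSV floats use round-trip (`%.17g`)
  formatting, and every random draw is seeded from the config.

## Limitations

* Sliding-window estimates trade time resolution against variance; very
  short windows need the lattice estimator and modest orders.
* The analytic PDC/DTF tests are asymptotic and anti-conservative on
  strongly coupled systems at small n; the surrogate test is the default
  for a reason.
* Pairwise spectral GC ignores conditioning on other channels; with more
  than two channels, cascades can masquerade as direct spectral GC.
* Inputs are assumed already source-separated (or acceptably
  channel-level); the package neither removes artifacts nor unmixes
  sources.
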