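# mvarflow

Sliding-window multivariate autoregressive (MVAR) modeling and
frequency-domain Granger-causal connectivity for multichannel neural time
series — EEG source activities, independent components, ECoG channels, or
any epoched multichannel recording.

`mvarflow` is for researchers who want to ask *directed* questions of their
data: does activity in area A help predict future activity in area B beyond
B's own history?  It implements the standard MVAR answer to that question
as a four-stage pipeline — preprocessing, model fitting and connectivity
estimation, statistical analysis, and data export — validated end to end
against a bundled ground-truth VAR simulator.

## The model

An epoched recording `x[t]` (channels × samples × trials) is modeled per
analysis window by a vector autoregression

```
x[t] = Σ_{k=1..p} A_k x[t−k] + e[t],      e[t] ~ N(0, Σ)
```

with `A_k[i, j]` the lag-`k` influence of source channel *j* on sink
channel *i*.  Regression rows are pooled across trials (never across trial
boundaries), and short sliding windows give a locally-stationary,
time-resolved model.  Fourier-transforming the coefficients yields, per
frequency,

```
Ā(f) = I − Σ_k A_k e^(−i2πfk/fs)      spectral coefficient matrix
H(f) = Ā(f)⁻¹                          transfer matrix
S(f) = H(f) Σ H(f)ᴴ                    (cross-)spectral matrix
```

from which a registry of 17 connectivity measures is evaluated: power and
cross-spectra; ordinary / partial / multiple / imaginary coherences; the
directed transfer function (DTF, row-normalized `|H_ij|²`), full-frequency
DTF and direct DTF (`ffDTF × partial coherence`, which suppresses indirect
cascade pathways); partial directed coherence (PDC, column-normalized
`|Ā_ij|²`) and its generalized, scale-invariant form (GPDC); and
time-domain and Geweke spectral Granger causality.

Significance comes from phase-randomization surrogates (channel-wise
random phases destroy cross-channel coupling while preserving every
autospectrum exactly), trial bootstrap, between-condition permutation, and
asymptotic analytic tests for PDC/DTF, all corrected with
Benjamini-Hochberg or Benjamini-Yekutieli FDR.  Graph-level summaries
(per-node outflow, inflow, asymmetry ratio, causal density) identify causal
sources and sinks.

## Worked example

The bundled `chain3` scenario is a chain of three 5 Hz oscillators with
directed couplings x0 → x1 → x2 (strength 0.5 at lag 1) and no direct
x0 → x2 edge:

```python
import numpy as np
from mvarflow import (preset_scenarios, simulate, fit_var,
                      evaluate_measure, graph_measures, surrogate_test)

spec = preset_scenarios()["chain3"]
ts, truth = simulate(spec, seed=1)

model = fit_var(ts, order=2)                  # pooled across 100 trials
freqs = np.arange(1.0, 64.0)
cr = evaluate_measure("dtf", model, freqs=freqs)

band = (freqs >= 3) & (freqs <= 7)
print(np.round(cr.values[:, :, band, 0].mean(axis=2), 3))
gm = graph_measures(cr, band=(3.0, 7.0))
print(np.round(gm["asymmetry_ratio"][:, 0], 2))

def pipe(data):
    return evaluate_measure("pdc", fit_var(data, 2), freqs=np.array([5.0]))
sr = surrogate_test(pipe, ts, n_surrogates=99, seed=1)
print(np.round(sr.pvalues[:, :, 0, 0], 2))
```

prints

```
[[1.    0.    0.   ]
 [0.987 0.013 0.   ]
 [0.987 0.013 0.   ]]
[ 1.   -0.97 -1.  ]
[[ nan 0.99 0.82]
 [0.01  nan 0.98]
 [1.   0.01  nan]]
```

The theta-band DTF (rows = sink, columns = source) shows information
flowing out of x0 into both x1 and x2 — DTF measures *total* directed flow,
so the indirect x0 → x2 cascade appears too.  The asymmetry ratios mark x0
as a pure causal source (+1) and x2 as a pure sink (−1).  The
phase-surrogate PDC test at 5 Hz then pinpoints exactly the two *direct*
edges (p = 0.01, the smallest attainable value with 99 surrogates);
everything else, including the reverse directions and the spurious
x0 → x2 link, is far from significance.

The same analysis runs from the shell:

```
mvarflow simulate --preset chain3 --seed 1 --out data.mvf
mvarflow fit data.mvf models.mvf --order 2
mvarflow connect models.mvf dtf.csv --measure dtf
mvarflow graph dtf.csv graph.csv --band 3 7
mvarflow run config.json        # full configurable pipeline
mvarflow config --template      # print all configuration defaults
```

## Documentation

`docs/methods.md` describes the model, the estimators, the surrogate and
analytic statistics, the simulator presets, numerical choices, and known
limitations.
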