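"""Connectivity measures: closed forms, simulations, and identities."""

import numpy as np
import pytest
import scipy.signal

from mvarflow import (InvalidArgumentError, VARModel, coherence, ddtf, dtf,
                      evaluate_measure, ffdtf, fit_var, gc_time, ggc_spectral,
                      gpdc, graph_measures, measure_registry,
                      multiple_coherence, partial_coherence, pdc,
                      power_spectrum, preset_scenarios, random_stable_var,
                      simulate, simulate_var, spectral_set)

from conftest import make_ts

FREQS = np.arange(1.0, 64.0)


def model_of(coeffs, sigma=None, srate=128.0):
    coeffs = np.asarray(coeffs, dtype=float)
    m = coeffs.shape[1] if coeffs.size else sigma.shape[0]
    return VARModel(order=coeffs.shape[0], coeffs=coeffs,
                    noise_cov=np.eye(m) if sigma is None else sigma,
                    srate=srate, n_obs=1000)


@pytest.fixture(scope="module")
def uncoupled_model():
    a = np.zeros((1, 3, 3))
    np.fill_diagonal(a[0], [0.5, 0.3, -0.4])
    return model_of(a)


@pytest.fixture(scope="module")
def chain_model():
    """True generative model of the chain3 preset: x0 -> x1 -> x2."""
    spec = preset_scenarios()["chain3"]
    return model_of(spec.coeffs_at(0.0), spec.noise_cov, spec.srate)


class TestCoherences:
    def test_uncoupled_model_has_zero_cross_terms(self, uncoupled_model):
        ss = spectral_set(uncoupled_model, FREQS)
        for fn in (coherence, partial_coherence):
            v = fn(ss).values
            off = v[~np.eye(3, dtype=bool)]
            assert np.abs(off).max() < 1e-12
        assert np.abs(multiple_coherence(ss).values).max() < 1e-12

    def test_instantaneous_correlation_closed_form(self):
        rho = 0.6
        sigma = np.array([[1.0, rho], [rho, 1.0]])
        model = model_of(np.zeros((0, 2, 2)), sigma)
        ss = spectral_set(model, FREQS)
        c = coherence(ss).values
        assert np.abs(c[0, 1] - rho ** 2).max() < 1e-12
        assert np.abs(c[1, 0] - rho ** 2).max() < 1e-12
        assert np.allclose(c[0, 0], 1.0)

    def test_coherence_matches_welch_oracle_on_chain(self):
        spec = preset_scenarios()["chain3"]
        x = simulate_var(spec.coeffs_at(0.0), spec.noise_cov, 100_000, 1,
                         np.random.default_rng(60))
        model = fit_var(make_ts(x), 2)
        ss = spectral_set(model, FREQS)
        c = coherence(ss).values
        f_w, c_w = scipy.signal.coherence(x[0, :, 0], x[1, :, 0], fs=128.0,
                                          nperseg=512)
        i5 = np.argmin(np.abs(FREQS - 5.0))
        w5 = np.argmin(np.abs(f_w - 5.0))
        assert c[1, 0, i5, 0] > 0.5
        assert abs(c[1, 0, i5, 0] - c_w[w5]) < 0.1

    def test_partial_coherence_removes_cascade(self, chain_model):
        ss = spectral_set(chain_model, FREQS)
        i5 = np.argmin(np.abs(FREQS - 5.0))
        coh = coherence(ss).values
        pc = partial_coherence(ss).values
        # x0 and x2 cohere only through x1: ordinary stays, partial vanishes
        assert coh[2, 0, i5, 0] > 0.3
        assert pc[2, 0, i5, 0] < 0.1

    def test_two_channel_partial_equals_ordinary(self):
        coeffs = random_stable_var(2, 2, np.random.default_rng(61), 0.7)
        ss = spectral_set(model_of(coeffs), FREQS)
        c = coherence(ss).values
        pc = partial_coherence(ss).values
        assert np.abs(c[0, 1] - pc[0, 1]).max() < 1e-10
        assert np.abs(c[1, 0] - pc[1, 0]).max() < 1e-10

    def test_two_channel_multiple_equals_ordinary(self):
        coeffs = random_stable_var(2, 2, np.random.default_rng(62), 0.7)
        ss = spectral_set(model_of(coeffs), FREQS)
        c = coherence(ss).values
        mc = multiple_coherence(ss).values
        assert np.abs(mc[0, 0] - c[0, 1]).max() < 1e-9
        assert np.abs(mc[1, 1] - c[1, 0]).max() < 1e-9

    def test_multiple_dominates_pairwise(self, chain_model):
        ss = spectral_set(chain_model, FREQS)
        c = coherence(ss).values
        mc = multiple_coherence(ss).values
        for i in range(3):
            pair_max = max(c[i, j].max() for j in range(3) if j != i)
            # joint coherence with all others >= best pairwise, per channel
            assert mc[i, i].max() >= pair_max - 1e-9


class TestPowerSpectrum:
    def test_white_noise_is_flat(self):
        model = model_of(np.zeros((0, 2, 2)), np.diag([2.0, 3.0]))
        v = power_spectrum(spectral_set(model, FREQS)).values
        assert np.allclose(v[0, 0], 2.0)
        assert np.allclose(v[1, 1], 3.0)

    def test_diagonal_nonnegative(self, chain_model):
        v = power_spectrum(spectral_set(chain_model, FREQS)).values
        assert v[np.arange(3), np.arange(3)].min() >= 0


class TestDirectedMeasures:
    def test_uncoupled_dtf_and_pdc_trivial(self, uncoupled_model):
        ss = spectral_set(uncoupled_model, FREQS)
        d = dtf(ss).values
        p = pdc(ss).values
        off = ~np.eye(3, dtype=bool)
        assert np.abs(d[off]).max() < 1e-12
        assert np.abs(p[off]).max() < 1e-12
        assert np.allclose(d[~off.reshape(3, 3)].reshape(3, -1), 1.0)

    def test_unidirectional_flow_one_way_only(self):
        a = np.array([[[0.5, 0.0], [0.6, 0.3]]])  # x0 -> x1 only
        ss = spectral_set(model_of(a), FREQS)
        d = dtf(ss).values
        p = pdc(ss).values
        assert d[1, 0].min() > 0
        assert d[0, 1].max() < 1e-10
        assert p[1, 0].min() > 0
        assert p[0, 1].max() < 1e-10

    def test_normalization_identities_random_models(self):
        rng = np.random.default_rng(63)
        for _ in range(20):
            m = int(rng.integers(2, 6))
            p = int(rng.integers(1, 5))
            coeffs = random_stable_var(m, p, rng, 0.8)
            ss = spectral_set(model_of(coeffs), FREQS)
            d = dtf(ss).values
            q = pdc(ss).values
            assert np.abs(d.sum(axis=1) - 1.0).max() < 1e-10  # sink rows
            assert np.abs(q.sum(axis=0) - 1.0).max() < 1e-10  # source columns

    def test_ffdtf_global_normalization_and_proportionality(self):
        coeffs = random_stable_var(3, 2, np.random.default_rng(64), 0.7)
        ss = spectral_set(model_of(coeffs), FREQS)
        f = ffdtf(ss).values
        # per sink: sum over sources and frequencies equals 1
        assert np.abs(f.sum(axis=(1, 2)) - 1.0).max() < 1e-10
        # oracle: proportional to |H|^2 at each frequency
        h2 = np.abs(ss.H_f) ** 2
        denom = h2.sum(axis=(0, 2))
        assert np.abs(f[:, :, :, 0] - h2.transpose(1, 2, 0) /
                      denom[:, None, None]).max() < 1e-12

    def test_ddtf_is_product_and_suppresses_cascade(self, chain_model):
        ss = spectral_set(chain_model, FREQS)
        product = ffdtf(ss).values * partial_coherence(ss).values
        dd = ddtf(ss).values
        assert np.abs(dd - product).max() < 1e-12
        i5 = np.argmin(np.abs(FREQS - 5.0))
        d = dtf(ss).values
        ratio_ddtf = dd[2, 0, i5, 0] / dd[1, 0, i5, 0]
        ratio_dtf = d[2, 0, i5, 0] / d[1, 0, i5, 0]
        assert ratio_ddtf < ratio_dtf

    def test_gpdc_reduces_to_pdc_for_scalar_noise(self):
        coeffs = random_stable_var(3, 2, np.random.default_rng(65), 0.7)
        model = model_of(coeffs, 2.5 * np.eye(3))
        ss = spectral_set(model, FREQS)
        assert np.abs(gpdc(ss).values - pdc(ss).values).max() < 1e-12
        assert np.abs(gpdc(ss).values.sum(axis=0) - 1.0).max() < 1e-10

    def test_gpdc_scale_invariant_under_refit(self):
        rng = np.random.default_rng(66)
        a = np.array([[[0.5, 0.2], [0.3, 0.4]]])
        x = simulate_var(a, np.eye(2), 5000, 1, rng)
        xs = x.copy()
        xs[0] *= 10.0
        res = []
        for data in (x, xs):
            model = fit_var(make_ts(data), 1)
            res.append(gpdc(spectral_set(model, FREQS), model).values)
        assert np.abs(res[0] - res[1]).max() < 1e-8


class TestGrangerCausality:
    def test_independent_channels_near_zero(self, rng):
        x = rng.standard_normal((2, 100_000, 1))
        g = gc_time(make_ts(x), 1).values
        assert np.nanmax(g) < 0.01
        assert np.isnan(g[0, 0, 0, 0]) and np.isnan(g[1, 1, 0, 0])

    def test_unidirectional_coupling_detected(self):
        a = np.array([[[0.5, 0.0], [0.5, 0.3]]])
        x = simulate_var(a, np.eye(2), 100_000, 1, np.random.default_rng(67))
        g = gc_time(make_ts(x), 1).values
        assert g[1, 0, 0, 0] > 0.1
        assert g[0, 1, 0, 0] < 0.01

    def test_geweke_integral_matches_time_domain(self, var2ch_long):
        _, ts = var2ch_long
        gt = gc_time(ts, 1).values
        freqs = np.linspace(0.25, 64.0, 256)
        gs = ggc_spectral(ts, 1, freqs).values
        # Geweke decomposition: frequency average equals time-domain GC
        assert abs(gs[1, 0, :, 0].mean() - gt[1, 0, 0, 0]) \
            / gt[1, 0, 0, 0] < 0.10
        assert gs[0, 1].max() < 1e-3  # no reverse pathway
        assert gs.min() >= 0

    def test_uncoupled_pair_flat_zero(self, rng):
        x = rng.standard_normal((2, 20_000, 1))
        gs = ggc_spectral(make_ts(x), 2, FREQS).values
        assert gs.max() < 0.01


class TestRegistry:
    def test_breadth_and_uniqueness(self):
        names = measure_registry()
        assert len(names) >= 15
        assert len(set(names)) == len(names)

    def test_every_measure_runs_on_two_channel_toy(self, rng):
        x = simulate_var(np.array([[[0.5, 0.1], [0.3, 0.4]]]), np.eye(2),
                         1000, 3, rng)
        ts = make_ts(x)
        model = fit_var(ts, 1)
        for name in measure_registry():
            r = evaluate_measure(name, model, freqs=FREQS, window=ts)
            assert np.all(np.isfinite(r.values)), name
            from mvarflow.measures import is_normalized
            if is_normalized(name):
                assert r.values.min() >= -1e-9, name
                assert r.values.max() <= 1 + 1e-9, name

    def test_unknown_name_rejected(self, uncoupled_model):
        with pytest.raises(InvalidArgumentError):
            evaluate_measure("granger_entropy", uncoupled_model)


class TestGraphMeasures:
    def test_pure_source_and_sink_asymmetry(self):
        a = np.array([[[0.5, 0.0], [0.6, 0.3]]])
        ss = spectral_set(model_of(a), FREQS)
        gm = graph_measures(dtf(ss), (1.0, 63.0))
        assert gm["asymmetry_ratio"][0, 0] == pytest.approx(1.0)
        assert gm["asymmetry_ratio"][1, 0] == pytest.approx(-1.0)

    def test_symmetric_coupling_balances(self):
        spec = preset_scenarios()["bidirectional2"]
        ts, _ = simulate(spec, seed=68)
        model = fit_var(ts, 2)
        gm = graph_measures(dtf(spectral_set(model, FREQS), model),
                            (8.0, 12.0))
        assert np.abs(gm["asymmetry_ratio"]).max() < 0.1

    def test_uncoupled_density_near_zero(self, uncoupled_model):
        gm = graph_measures(dtf(spectral_set(uncoupled_model, FREQS)),
                            (1.0, 63.0))
        assert gm["causal_density"][0] < 1e-12

    def test_empty_band_rejected(self, uncoupled_model):
        cr = dtf(spectral_set(uncoupled_model, FREQS))
        with pytest.raises(InvalidArgumentError):
            graph_measures(cr, (70.0, 80.0))


class TestBlockSeparation:
    @pytest.mark.parametrize("name", ["dtf", "ffdtf", "ddtf", "pdc", "gpdc"])
    def test_no_leakage_across_independent_blocks(self, name):
        rng = np.random.default_rng(69)
        coeffs = np.zeros((2, 4, 4))
        coeffs[:, :2, :2] = random_stable_var(2, 2, rng, 0.8)
        coeffs[:, 2:, 2:] = random_stable_var(2, 2, rng, 0.8)
        model = model_of(coeffs)
        v = evaluate_measure(name, model, freqs=FREQS).values
        assert np.abs(v[:2, 2:]).max() < 1e-10
        assert np.abs(v[2:, :2]).max() < 1e-10


class TestTransientDetection:
    def test_theta_burst_peaks_inside_envelope(self):
        from mvarflow import WindowSpec, segment_windows
        spec = preset_scenarios()["transient_theta"]
        ts, truth = simulate(spec, seed=70)
        centers, band_vals = [], []
        for center, w in segment_windows(ts, WindowSpec(0.375, 0.125)):
            model = fit_var(w, 2)
            r = ddtf(spectral_set(model, FREQS), model)
            band = (r.freqs >= 3.0) & (r.freqs <= 7.0)
            centers.append(center)
            band_vals.append(r.values[1, 0, band, 0].mean())
        peak_center = centers[int(np.argmax(band_vals))]
        on, off = spec.couplings[0].onset, spec.couplings[0].offset
        half = 0.375 / 2
        assert on - half <= peak_center <= off + half
        # truth graph marks the coupling as transient
        frac = truth[1, 0].mean()
        assert 0.0 < frac < 1.0
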