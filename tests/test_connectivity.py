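"""VAR estimation, parametric spectra, spectral GC and order selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import streamconn as sc
from streamconn.connectivity import (
    band_gc,
    default_freq_grid,
    parametric_density,
    welch_cross_spectra,
)
from streamconn.errors import (
    DegenerateSignalError,
    SizingError,
    StationarityError,
    ValidationError,
)

FS = 1.0 / 0.535


class TestPearsonFC:
    def test_self_and_sign_flip(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert sc.pearson_fc(x, x) == pytest.approx(1.0)
        assert sc.pearson_fc(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov 3.0 over sqrt(5)*sqrt(5)
        assert sc.pearson_fc([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            sc.pearson_fc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_positive_affine_transform(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 40))
        r0 = sc.pearson_fc(x, y)
        r1 = sc.pearson_fc(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestFitVAR:
    def test_ar1_coefficient_recovery(self):
        rng = np.random.default_rng(0)
        T = 2000
        x = np.zeros(T)
        x[0] = 1.0  # deterministic decay plus tiny jitter
        for t in range(1, T):
            x[t] = 0.5 * x[t - 1] + 1e-6 * rng.standard_normal()
        model = sc.fit_var(x, 1)
        assert model.coeffs[0, 0, 0] == pytest.approx(0.5, abs=1e-3)

    def test_white_noise_has_no_structure(self):
        x = np.random.default_rng(1).standard_normal((5000, 2))
        model = sc.fit_var(x, 1)
        assert np.all(np.abs(model.coeffs) < 0.05)
        np.testing.assert_allclose(model.sigma, np.eye(2), atol=0.06)

    def test_var2_parameter_recovery(self, var2_model):
        x = sc.simulate_var(var2_model, 3440, np.random.default_rng(7))
        fit = sc.fit_var(x, 2)
        rmse = np.sqrt(np.mean((fit.coeffs - var2_model.coeffs) ** 2))
        assert rmse < 0.05

    def test_agrees_with_statsmodels_var(self, var2_model):
        from statsmodels.tsa.api import VAR as SMVAR

        x = sc.simulate_var(var2_model, 4000, np.random.default_rng(3))
        ours = sc.fit_var(x, 2)
        sm_res = SMVAR(x - x.mean(axis=0)).fit(maxlags=2, trend="n")
        theirs = sm_res.coefs  # (p, k, k), same lag convention
        np.testing.assert_allclose(ours.coeffs, theirs, atol=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(SizingError):
            sc.fit_var(np.random.default_rng(0).standard_normal((50, 2)), 6)


class TestSimulateVAR:
    def test_nonstationary_model_rejected(self):
        bad = sc.VARModel(coeffs=np.array([[[1.05, 0.0], [0.0, 0.5]]]), sigma=np.eye(2))
        with pytest.raises(StationarityError):
            sc.simulate_var(bad, 100, np.random.default_rng(0))

    def test_ar1_variance_matches_lyapunov_solution(self):
        # AR(1) a=0.5, unit innovations: var = 1/(1-0.25) = 4/3
        model = sc.VARModel(
            coeffs=np.array([[[0.5, 0.0], [0.0, 0.0]]]), sigma=np.eye(2)
        )
        x = sc.simulate_var(model, 200000, np.random.default_rng(0))
        assert x[:, 0].var() == pytest.approx(4.0 / 3.0, rel=0.02)

    def test_independent_channels_uncorrelated_at_all_lags(self):
        model = sc.VARModel(
            coeffs=np.array([[[0.4, 0.0], [0.0, 0.4]]]), sigma=np.eye(2)
        )
        x = sc.simulate_var(model, 3440, np.random.default_rng(2))
        for lag in range(4):
            a = x[lag:, 0] if lag else x[:, 0]
            b = x[: x.shape[0] - lag, 1]
            assert abs(np.corrcoef(a, b)[0, 1]) < 0.06


class TestVarSpectrum:
    def test_pure_noise_spectrum_is_flat_identity(self):
        # order-1 model with zero coefficients behaves as p = 0 white noise
        model = sc.VARModel(coeffs=np.zeros((1, 2, 2)), sigma=np.eye(2), fs=FS)
        freqs = default_freq_grid(FS, 65)
        dec = sc.var_spectrum(model, freqs)
        for f_idx in range(len(freqs)):
            np.testing.assert_allclose(dec.S[f_idx], np.eye(2), atol=1e-12)

    def test_ar1_power_at_dc_closed_form(self):
        model = sc.VARModel(
            coeffs=np.array([[[0.5, 0.0], [0.0, 0.1]]]), sigma=np.eye(2), fs=FS
        )
        dec = sc.var_spectrum(model, np.array([0.0]))
        assert dec.S[0, 0, 0].real == pytest.approx(4.0)  # |1 - 0.5|^-2

    def test_reconstruction_identity_s_equals_h_sigma_h(self, var2_model):
        freqs = default_freq_grid(FS, 33)
        dec = sc.var_spectrum(var2_model, freqs)
        S_rebuilt = dec.H @ var2_model.sigma @ dec.H.conj().transpose(0, 2, 1)
        np.testing.assert_allclose(dec.S, S_rebuilt, atol=1e-12)
        # Hermitian PSD at every frequency
        for f_idx in range(len(freqs)):
            S_f = dec.S[f_idx]
            np.testing.assert_allclose(S_f, S_f.conj().T, atol=1e-12)
            assert np.linalg.eigvalsh(S_f).min() > -1e-12

    def test_matches_welch_estimate_of_long_simulation(self, var2_model):
        x = sc.simulate_var(var2_model, 100000, np.random.default_rng(5))
        freqs, S_np = welch_cross_spectra(x, FS, nperseg=256)
        S_par = parametric_density(var2_model, freqs)
        # broadband agreement away from the demeaning-biased DC bin
        rel = np.abs(S_par[2:, 0, 0].real - S_np[2:, 0, 0].real)
        assert rel.mean() / S_np[2:, 0, 0].real.mean() < 0.05


class TestSpectralGC:
    def test_zero_coupling_gives_exactly_zero(self):
        model = sc.VARModel(
            coeffs=np.array([[[0.5, 0.0], [0.0, 0.3]]]), sigma=np.eye(2), fs=FS
        )
        freqs = default_freq_grid(FS, 129)
        I = sc.spectral_gc(model, freqs, source=1, target=0)
        np.testing.assert_array_equal(I, np.zeros_like(I))

    def test_unidirectional_coupling_detected_with_silent_reverse(self):
        coeffs = np.array([[[0.3, 0.5], [0.0, 0.3]]])  # ch0 <- ch1
        model = sc.VARModel(coeffs=coeffs, sigma=np.eye(2), fs=FS)
        freqs = default_freq_grid(FS, 129)
        forward = sc.spectral_gc(model, freqs, source=1, target=0)
        reverse = sc.spectral_gc(model, freqs, source=0, target=1)
        assert forward.min() > 0
        np.testing.assert_allclose(reverse, 0.0, atol=1e-12)

    def test_channel_relabeling_symmetry(self, var2_model):
        freqs = default_freq_grid(FS, 65)
        I = sc.spectral_gc(var2_model, freqs, source=0, target=1)
        swapped = sc.VARModel(
            coeffs=var2_model.coeffs[:, ::-1, :][:, :, ::-1],
            sigma=var2_model.sigma[::-1, ::-1],
            fs=FS,
        )
        I_swapped = sc.spectral_gc(swapped, freqs, source=1, target=0)
        np.testing.assert_allclose(I, I_swapped, atol=1e-12)

    def test_nonnegative_on_fitted_models(self, var2_model):
        x = sc.simulate_var(var2_model, 3440, np.random.default_rng(11))
        fit = sc.fit_var(x, 2)
        fit.fs = FS
        freqs = default_freq_grid(FS, 257)
        for src, tgt in ((0, 1), (1, 0)):
            assert sc.spectral_gc(fit, freqs, source=src, target=tgt).min() >= 0.0


class TestBandGC:
    def test_constant_spectrum_integrates_to_itself(self):
        freqs = np.linspace(0.0, 0.9, 100)
        assert band_gc(np.full(100, 0.37), freqs, 0.05, 0.9) == pytest.approx(0.37)

    def test_linear_ramp_integrates_to_half(self):
        freqs = np.linspace(0.05, 0.9, 200)
        I = (freqs - 0.05) / 0.85
        assert band_gc(I, freqs, 0.05, 0.9) == pytest.approx(0.5, abs=1e-9)

    def test_band_outside_grid_rejected(self):
        freqs = np.linspace(0.0, 0.9, 100)
        with pytest.raises(ValidationError):
            band_gc(np.ones(100), freqs, 0.05, 1.2)

    def test_full_band_matches_reduced_model_variance_ratio(self):
        """Geweke identity: band mean of I over [0, fs/2] equals
        ln(reduced residual variance / full residual variance)."""
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = [[0.5, 0.0], [0.4, 0.3]]
        coeffs[1] = [[-0.1, 0.0], [0.1, 0.2]]
        true = sc.VARModel(coeffs=coeffs, sigma=np.eye(2), fs=FS)
        x = sc.simulate_var(true, 100000, np.random.default_rng(3))
        full = sc.fit_var(x, 2)
        full.fs = FS
        tgc = sc.time_domain_gc(full, source=0, target=1)
        reduced = sc.fit_var(x[:, 1], 2)
        oracle = np.log(reduced.sigma[0, 0] / full.sigma[1, 1])
        assert tgc == pytest.approx(oracle, rel=0.05)


class TestSelectOrder:
    def test_single_candidate_returned(self):
        x = np.random.default_rng(0).standard_normal((500, 2))
        assert sc.select_order(x, [3], fs=FS) == 3

    def test_recovers_var2_modally(self, var2_model):
        picks = [
            sc.select_order(
                sc.simulate_var(var2_model, 3440, np.random.default_rng(s)),
                range(2, 21),
                fs=FS,
            )
            for s in range(15)
        ]
        counts = np.bincount(picks, minlength=21)
        assert counts.argmax() == 2

    def test_all_candidates_infeasible_rejected(self):
        x = np.random.default_rng(0).standard_normal((100, 2))
        with pytest.raises(SizingError):
            sc.select_order(x, [10, 15, 20], fs=FS)


class TestDirectedGCAndTable:
    def test_tgc_declines_with_sample_size_under_null(self):
        model = sc.VARModel(
            coeffs=np.array([[[0.3, 0.0], [0.0, 0.3]]]), sigma=np.eye(2), fs=FS
        )
        medians = []
        for T in (500, 2000, 8000):
            vals = []
            for s in range(12):
                x = sc.simulate_var(model, T, np.random.default_rng(1000 + s))
                r01, _ = sc.directed_gc(x, fs=FS)
                vals.append(r01.tgc)
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]

    def test_directionality_recovered_at_study_length(self, default_config):
        model = sc.build_pair_model(0.3, default_config)
        wins = 0
        n_seeds = 20
        for s in range(n_seeds):
            x = sc.simulate_var(model, 3440, np.random.default_rng(s))
            r01, r10 = sc.directed_gc(x, fs=FS)
            wins += r01.tgc > r10.tgc
        assert wins >= 0.95 * n_seeds

    def test_connectivity_table_shape_and_symmetry(self, connections):
        import pandas as pd

        rng = np.random.default_rng(4)
        roi_names = sorted({r for c in connections for r in (c.roi_a, c.roi_b)})
        series = pd.DataFrame(
            rng.standard_normal((400, len(roi_names))), columns=roi_names
        )
        table = sc.pairwise_connectivity(
            series, connections, run_lengths=[200, 200], order=2, fs=FS,
            subject_id="S1",
        )
        assert len(table) == 12 * 3  # 12 FC rows + 24 directed TGC rows
        assert (table[table.metric == "fc"].direction == "undirected").all()
        assert len(table[table.metric == "tgc"]) == 24

    def test_missing_roi_column_named(self, connections):
        import pandas as pd

        series = pd.DataFrame(np.random.default_rng(0).standard_normal((300, 1)),
                              columns=["L SOG"])
        with pytest.raises(Exception, match="L SPL|L IPL"):
            sc.pairwise_connectivity(series, connections, order=2, fs=FS)
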