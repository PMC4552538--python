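"""Estimator contracts: design rows, MDL, RLS, surrogates, full fits."""

import numpy as np
import pytest

from cardiotv.branches import MEMORY
from cardiotv.estimator import (BranchStructure, ModelStructure,
                                _branch_block, aaft_surrogate, build_design,
                                fit_hrv_model, mdl_score, rls_track,
                                select_lambda, stabilized_estimate,
                                structure_search)
from cardiotv.meixner import laguerre_basis
from cardiotv.preprocess import preprocess_subject
from cardiotv.synthetic import default_truth, generate_inputs, make_subject

from conftest import lf_gain


def _hrv_structure(pole=0.9):
    return ModelStructure("hrv", (BranchStructure("ABR", 1.0, 1, 3, pole),
                                  BranchStructure("RCC", -1.0, 0, 3, pole)))


def _design_for(signals, structure):
    return build_design({"ABR": signals["dSBP"].values,
                         "RCC": signals["dVT"].values}, structure)


class TestDesign:
    def test_identity_dictionary_gives_raw_lags(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(200)
        block = _branch_block(u, np.eye(MEMORY, 6), delay_samples=0)
        t = 150
        assert np.allclose(block[t], u[t - np.arange(6)])

    def test_zero_input_gives_zero_rows(self):
        block = _branch_block(np.zeros(120), np.eye(MEMORY, 4), 2)
        assert np.all(block == 0.0)

    def test_geometric_function_constant_input(self):
        # single basis function a^i (normalized); constant input c
        basis = laguerre_basis(0.8, 1, MEMORY).matrix
        c = 2.5
        block = _branch_block(np.full(200, c), basis, 0)
        expected = c * basis[:, 0].sum()  # direct summation oracle
        assert block[150, 0] == pytest.approx(expected)

    def test_negative_delay_reads_future_samples(self):
        u = np.zeros(200)
        u[100] = 1.0
        basis = np.eye(MEMORY, 1)  # kernel = impulse at lag 0
        block = _branch_block(u, basis, -4)
        assert block[96, 0] == 1.0

    def test_delay_shift_commutation(self):
        # shifting the input by +1 sample while decreasing the delay by one
        # sample yields the same regressors on the common valid region
        rng = np.random.default_rng(3)
        u = rng.standard_normal(300)
        basis = laguerre_basis(0.9, 3, MEMORY).matrix
        a = _branch_block(u, basis, 4)
        u_shift = np.concatenate([[0.0], u[:-1]])
        b = _branch_block(u_shift, basis, 3)
        region = slice(MEMORY + 4, 300)
        assert np.allclose(a[region], b[region], atol=1e-12)

    def test_out_of_model_branch_rejected(self):
        with pytest.raises(ValueError):
            ModelStructure("hrv", (BranchStructure("BPC", 4.0, 2, 3),
                                   BranchStructure("RCC", -1.0, 0, 3)))

    def test_delay_and_grid_validation(self):
        with pytest.raises(ValueError, match="admissible range"):
            BranchStructure("ABR", 5.0, 1, 3)
        with pytest.raises(ValueError, match="generalization"):
            BranchStructure("ABR", 1.0, 0, 3)
        with pytest.raises(ValueError, match="basis functions"):
            BranchStructure("ABR", 1.0, 1, 2)


class TestMdl:
    def test_penalizes_parameters_at_equal_fit(self):
        assert mdl_score(10.0, 1000, 4) < mdl_score(10.0, 1000, 8)

    def test_rewards_fit_at_equal_size(self):
        assert mdl_score(5.0, 1000, 4) < mdl_score(10.0, 1000, 4)

    def test_closed_form_value(self):
        assert mdl_score(1000.0, 1000, 10) == pytest.approx(5.0 * np.log(1000.0))

    def test_perfect_fit_is_minus_infinity_with_warning(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert mdl_score(0.0, 100, 3) == -np.inf


class TestStructureSearch:
    def test_noise_free_truth_recovered(self):
        # direct synthesis (no beat conversion): recovery is exact
        from cardiotv.synthetic import synthesize_outputs
        truth = default_truth(seed=7)
        dsbp, dvt = generate_inputs(truth.input_spec, 1260.0, 2.0, 17)
        clean, _ = synthesize_outputs(truth, dsbp, dvt, 600.0)
        y = clean["dRRI"]
        u = {"ABR": dsbp.values, "RCC": dvt.values}
        structure, table = structure_search(y, u, model="hrv", profile="fast")
        delays = {b.branch: b.delay_s for b in structure.branches}
        assert delays["ABR"] == truth.branches["ABR"].delay_s
        assert delays["RCC"] == truth.branches["RCC"].delay_s
        best_ssr = table.loc[table["mdl"].idxmin(), "ssr"]
        assert best_ssr < 1e-6 * np.sum(y**2)

    def test_pure_noise_explains_little(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            dsbp, dvt = generate_inputs(default_truth(0).input_spec, 600.0, 2.0,
                                        seed)
            y = rng.standard_normal(len(dsbp))
            u = {"ABR": dsbp.values, "RCC": dvt.values}
            _, table = structure_search(y, u, model="hrv", profile="fast")
            best_ssr = table["ssr"].min()
            hits.append(1.0 - best_ssr / np.sum(y**2))
        assert max(hits) < 0.10

    def test_all_tied_candidates_return_first_in_grid_order(self):
        dsbp, dvt = generate_inputs(default_truth(0).input_spec, 400.0, 2.0, 1)
        y = np.zeros(len(dsbp))  # every candidate fits perfectly: all tied
        u = {"ABR": dsbp.values, "RCC": dvt.values}
        structure, _ = structure_search(y, u, model="hrv", profile="fast")
        b1, b2 = structure.branches
        # first candidate in documented order: smallest delay, gen, n_funcs
        assert (b1.delay_s, b1.gen_order, b1.n_funcs) == (0.5, 1, 3)
        assert (b2.delay_s, b2.gen_order, b2.n_funcs) == (-3.0, 0, 3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            structure_search(np.zeros(500), {"ABR": np.zeros(500),
                                             "RCC": np.zeros(500)},
                             model="hrv",
                             grids={"ABR": {"delays": (), "gen_orders": (1,),
                                            "n_funcs": (3,)},
                                    "RCC": {"delays": (-1.0,), "gen_orders": (0,),
                                            "n_funcs": (3,)}})


class TestRls:
    def test_lambda_one_matches_batch_least_squares(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        y = signals_snr10["dRRI"].values
        theta, _, _ = rls_track(y, X, valid, 1.0, init_scale=1e8)
        beta = np.linalg.lstsq(X[valid], y[valid], rcond=None)[0]
        from cardiotv.estimator import _expand_track
        k_rls, _ = _expand_track(theta[-1][None, :], structure)
        k_ols, _ = _expand_track(beta[None, :], structure)
        for b in k_rls:
            assert np.max(np.abs(k_rls[b] - k_ols[b])) < 1e-6

    def test_zero_output_keeps_zero_coefficients(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        theta, resid, _ = rls_track(np.zeros(len(valid)), X, valid, 0.9)
        assert np.all(theta == 0.0)
        assert np.all(resid == 0.0)

    def test_invalid_lambda_rejected(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        with pytest.raises(ValueError):
            rls_track(np.zeros(len(valid)), X, valid, 0.0)

    def test_tracks_gain_step_within_a_minute(self):
        # ABR gain doubles at stimulus onset; noise-free record
        truth = default_truth(seed=4, stimulus_gain={"ABR": (2.0, 1e9)})
        subj = make_subject(truth, snr=None)
        signals = preprocess_subject(subj)
        structure = _hrv_structure()
        X, valid = _design_for(signals, structure)
        y = signals["dRRI"].values
        theta, _, _ = rls_track(y, X, valid, 0.9)
        time = signals["dRRI"].times[valid]
        from cardiotv.estimator import _expand_track
        kernels, _ = _expand_track(theta, structure)
        gains = lf_gain(kernels["ABR"])
        target = 2.0 * float(lf_gain(truth.branches["ABR"].kernels[0]))
        within = np.abs(gains - target) <= 0.10 * target
        reached = time[(time > 0) & within]
        assert reached.size and reached[0] <= 60.0


class TestLambdaSelection:
    def test_time_invariant_truth_prefers_long_memory(self):
        grid = (0.85, 0.91, 0.97)
        wins = 0
        for seed in range(10):
            truth = default_truth(seed=seed)
            subj = make_subject(truth, snr=100.0)
            signals = preprocess_subject(subj)
            structure = _hrv_structure()
            X, valid = _design_for(signals, structure)
            lam, _ = select_lambda(signals["dRRI"].values, X, valid, grid)
            wins += lam == max(grid)
        assert wins >= 8

    def test_time_varying_truth_prefers_short_memory(self):
        grid = (0.85, 0.91, 0.97)
        shorter = 0
        for seed in range(10):
            truth = default_truth(seed=seed, stimulus_gain={"ABR": (2.0, 300.0),
                                                            "RCC": (0.4, 300.0)})
            subj = make_subject(truth, snr=100.0)
            signals = preprocess_subject(subj)
            structure = _hrv_structure()
            X, valid = _design_for(signals, structure)
            lam, _ = select_lambda(signals["dRRI"].values, X, valid, grid)
            shorter += lam < max(grid)
        assert shorter >= 6

    def test_single_element_grid(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        lam, sse = select_lambda(signals_snr10["dRRI"].values, X, valid, (0.91,))
        assert lam == 0.91 and set(sse) == {0.91}

    def test_empty_grid_rejected(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        with pytest.raises(ValueError):
            select_lambda(signals_snr10["dRRI"].values, X, valid, ())


class TestAaft:
    def test_sorted_values_preserved_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512) ** 3  # heavy-tailed amplitudes
        s = aaft_surrogate(x, np.random.default_rng(1))
        assert np.array_equal(np.sort(s), np.sort(x))

    def test_same_seed_same_surrogate(self):
        x = np.random.default_rng(2).standard_normal(256)
        a = aaft_surrogate(x, np.random.default_rng(7))
        b = aaft_surrogate(x, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_spectrum_approximately_preserved(self):
        from scipy.signal import lfilter, welch
        rng = np.random.default_rng(3)
        x = lfilter([1.0], [1.0, -0.7], rng.standard_normal(2048))
        s = aaft_surrogate(x, np.random.default_rng(4))
        f, pxx = welch(x, fs=2.0, nperseg=256)
        _, pss = welch(s, fs=2.0, nperseg=256)
        for band in [(0.04, 0.15), (0.15, 0.4), (0.4, 1.0)]:
            m = (f >= band[0]) & (f < band[1])
            assert abs(pss[m].sum() - pxx[m].sum()) / pxx[m].sum() < 0.10

    def test_constant_series_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="constant"):
            s = aaft_surrogate(np.full(64, 3.0), np.random.default_rng(0))
        assert np.all(s == 3.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            aaft_surrogate(np.arange(4.0), np.random.default_rng(0))


class TestStabilization:
    def test_zero_residuals_reproduce_initial_fit(self, noise_free_signals):
        # zero output -> the fit is exact, residuals identically zero, and
        # every surrogate re-estimate equals the initial (zero) fit
        structure = _hrv_structure()
        X, valid = _design_for(noise_free_signals, structure)
        y = np.zeros(len(valid))
        with pytest.warns(UserWarning, match="constant"):
            stab = stabilized_estimate(y, X, valid, structure, 0.97,
                                       n_surrogates=3, rng=0)
        for b in stab.kernels:
            assert np.all(stab.kernels[b] == 0.0)
            assert np.all(stab.spread[b] == 0.0)

    def test_single_surrogate_is_that_reestimate(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        y = signals_snr10["dRRI"].values
        stab = stabilized_estimate(y, X, valid, structure, 0.97,
                                   n_surrogates=1, rng=5)
        # recompute the single re-estimate by hand with the same stream
        rng = np.random.default_rng(5)
        theta0, resid0, pred0 = rls_track(y, X, valid, 0.97)
        y_k = y.copy()
        y_k[np.flatnonzero(valid)] = pred0 + aaft_surrogate(resid0, rng)
        theta_k, _, _ = rls_track(y_k, X, valid, 0.97)
        from cardiotv.estimator import _expand_track
        kernels_k, _ = _expand_track(theta_k, structure)
        for b in kernels_k:
            assert np.allclose(stab.kernels[b], kernels_k[b], atol=1e-12)

    def test_spread_is_nonnegative(self, signals_snr10):
        structure = _hrv_structure()
        X, valid = _design_for(signals_snr10, structure)
        stab = stabilized_estimate(signals_snr10["dRRI"].values, X, valid,
                                   structure, 0.95, n_surrogates=5, rng=2)
        for b, s in stab.spread.items():
            assert np.all(s >= 0.0)


class TestFullFit:
    def test_noise_free_kernels_recovered_uniform_path(self):
        # uniform (pre-beat-conversion) signals: recovery is essentially exact
        from cardiotv.series import UniformSeries
        from cardiotv.synthetic import synthesize_outputs
        truth = default_truth(seed=7)
        dsbp, dvt = generate_inputs(truth.input_spec, 1260.0, 2.0, 17)
        clean, _ = synthesize_outputs(truth, dsbp, dvt, 600.0)
        mk = lambda v, n: UniformSeries(-600.0, 2.0, v, n)
        fit = fit_hrv_model(mk(clean["dRRI"], "dRRI"), mk(dsbp.values, "dSBP"),
                            mk(dvt.values, "dVT"), n_surrogates=3, seed=0,
                            lambda_grid=(0.97,))
        for branch in ("ABR", "RCC"):
            k_true = truth.branches[branch].kernels[0]
            k_est = np.median(fit.stabilized.kernels[branch], axis=0)
            err = np.linalg.norm(k_est - k_true) / np.linalg.norm(k_true)
            assert err < 1e-3

    def test_noise_free_kernels_recovered_beat_path(self, noise_free_signals):
        # through beat-domain sampling the respiratory branch carries a small
        # interpolation floor (~1 Hz beat rate sampling 0.3 Hz content)
        truth = default_truth(seed=7)
        fit = fit_hrv_model(noise_free_signals["dRRI"],
                            noise_free_signals["dSBP"],
                            noise_free_signals["dVT"],
                            n_surrogates=3, seed=0,
                            lambda_grid=(0.97,))
        for branch in ("ABR", "RCC"):
            k_true = truth.branches[branch].kernels[0]
            k_est = np.median(fit.stabilized.kernels[branch], axis=0)
            err = np.linalg.norm(k_est - k_true) / np.linalg.norm(k_true)
            assert err < 0.05

    def test_silent_respiration_zeroes_rcc_branch(self, noise_free_subject):
        signals = preprocess_subject(noise_free_subject)
        zero_vt = signals["dVT"].copy_with(np.zeros(len(signals["dVT"])))
        fit = fit_hrv_model(signals["dRRI"], signals["dSBP"], zero_vt,
                            n_surrogates=2, seed=0, lambda_grid=(0.97,))
        rcc = fit.stabilized.kernels["RCC"]
        abr = fit.stabilized.kernels["ABR"]
        assert np.max(np.abs(rcc)) < 1e-9
        # ABR branch still explains the pressure-driven part
        truth = default_truth(seed=7)
        g_true = float(lf_gain(truth.branches["ABR"].kernels[0]))
        g_est = float(np.median(lf_gain(abr)))
        assert abs(g_est - g_true) / g_true < 0.25

    def test_shuffled_inputs_explain_little(self):
        # destroy the input-output coupling; the model should find ~nothing
        ratios = []
        for seed in range(10):
            truth = default_truth(seed=seed)
            subj = make_subject(truth, snr=10.0)
            signals = preprocess_subject(subj)
            rng = np.random.default_rng(seed)
            y = signals["dRRI"].values.copy()
            rng.shuffle(y)
            u = {"ABR": signals["dSBP"].values, "RCC": signals["dVT"].values}
            _, table = structure_search(y, u, model="hrv", profile="fast")
            ratios.append(1.0 - table["ssr"].min() / np.sum(y**2))
        assert max(ratios) < 0.10

    def test_misaligned_inputs_rejected(self, signals_snr10):
        bad = signals_snr10["dSBP"]
        bad = bad.copy_with(bad.values[:-10])
        with pytest.raises(ValueError, match="hrv"):
            fit_hrv_model(signals_snr10["dRRI"], bad, signals_snr10["dVT"])
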