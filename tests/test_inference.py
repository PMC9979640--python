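"""Cost functions, warm start, samplers, tracking, bulk efflux."""
import math

import numpy as np
import pytest
from scipy.optimize import minimize

import protonflux as pf
from protonflux import field_model, inference
from conftest import make_cell_frame, make_probe_frame


def _noise_free_frame(params, cell_xy, u_rep, probe_xy, c0):
    """Probe frame whose pH is the exact forward prediction of u_rep."""
    cells = make_cell_frame(cell_xy)
    geom = make_probe_frame(probe_xy, 7.0)
    K = pf.build_distance_matrix(cells, geom, params)
    state = np.concatenate([[0.0], np.asarray(u_rep, float)])
    c = pf.concentration_field(state * field_model.native_per_reported(params), K, c0)
    probes = make_probe_frame(probe_xy, pf.predicted_ph(c))
    return cells, probes


class TestFrameChi2:
    C0 = 1e-6

    def test_truth_on_noise_free_data_is_zero(self, params):
        cells, probes = _noise_free_frame(
            params, [[200.0, 200.0], [300.0, 250.0]], [2.0, -1.0],
            [[150.0, 150.0], [250.0, 300.0], [350.0, 200.0]], self.C0)
        flux = pf.FluxVector(0.0, cells.cell_ids, np.array([2.0, -1.0]))
        assert pf.frame_chi2(flux, cells, probes, params,
                             lambda1=0.0, c0=self.C0) == pytest.approx(0.0, abs=1e-18)

    def test_null_model_on_flat_field(self, params):
        # u = 0 and c0 matching every probe exactly: only lambda1*0 remains
        cells = make_cell_frame([[100.0, 100.0]])
        probes = make_probe_frame([[200.0, 200.0], [50.0, 300.0]], 6.8)
        flux = pf.FluxVector(0.0, cells.cell_ids, np.zeros(1))
        chi2 = pf.frame_chi2(flux, cells, probes, params, lambda1=17.0,
                             c0=10 ** -6.8)
        assert chi2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_hand_rolled_sum(self, params):
        rng = np.random.default_rng(42)
        cell_xy = rng.uniform(100, 400, (3, 2))
        probe_xy = rng.uniform(50, 450, (5, 2))
        cells = make_cell_frame(cell_xy)
        probes = make_probe_frame(probe_xy, rng.uniform(6.4, 6.6, 5),
                                  sigma=rng.uniform(0.01, 0.05, 5))
        u = rng.normal(0, 1, 3)
        U = 0.3
        lam1 = 0.7
        flux = pf.FluxVector(U, cells.cell_ids, u)
        # independent evaluation: explicit python loops over probes/sources
        bpts = pf.boundary_points(params)
        total = 0.0
        conv = params.cell_dry_weight_ng * 1e-9 / 3.6e6
        for mu in range(5):
            c = 10 ** -6.5
            for i in range(3):
                d = max(np.hypot(*(probe_xy[mu] - cell_xy[i])), 5.0)
                c += u[i] * conv * 1e15 / (4 * math.pi * 7000.0 * d)
            kb = np.mean([1e15 / (4 * math.pi * 7000.0 *
                                  max(np.hypot(*(probe_xy[mu] - b)), 5.0))
                          for b in bpts])
            c += U * conv * kb
            ph_pred = -math.log10(c)
            row = probes.probes.iloc[mu]
            total += (row.pH - ph_pred) ** 2 / row.sigma ** 2
        total += lam1 * float(u @ u)
        got = pf.frame_chi2(flux, cells, probes, params, lambda1=lam1, c0=10 ** -6.5)
        assert got == pytest.approx(total, rel=1e-10)

    def test_unphysical_flux_costs_infinity(self, params):
        cells = make_cell_frame([[200.0, 200.0]])
        probes = make_probe_frame([[210.0, 200.0]], 6.5)
        flux = pf.FluxVector(0.0, cells.cell_ids, np.array([-1e4]))
        assert pf.frame_chi2(flux, cells, probes, params, c0=10 ** -6.5) == np.inf


class TestTotalChi2:
    def _two_frames(self, params):
        xy = [[200.0, 200.0]]
        pxy = [[150.0, 150.0], [300.0, 280.0]]
        frames = [make_cell_frame(xy, frame_index=t, time_min=10.0 * t)
                  for t in range(2)]
        probes = [make_probe_frame(pxy, 6.5, frame_index=t, time_min=10.0 * t)
                  for t in range(2)]
        return frames, probes

    def test_decouples_without_lambda2_lambda3(self, params):
        frames, probes = self._two_frames(params)
        fluxes = [pf.FluxVector(0.0, ["c0"], np.array([v])) for v in (1.0, 3.0)]
        tot = pf.total_chi2(fluxes, frames, probes, params, lambda1=0.2,
                            c0=10 ** -6.5)
        per_frame = sum(pf.frame_chi2(fv, cf, pfr, params, lambda1=0.2, c0=10 ** -6.5)
                        for fv, cf, pfr in zip(fluxes, frames, probes))
        assert tot == pytest.approx(per_frame, rel=1e-12)

    def test_constant_fluxes_zero_smoothness_cost(self, params):
        frames, probes = self._two_frames(params)
        fluxes = [pf.FluxVector(0.0, ["c0"], np.array([2.0]))] * 2
        a = pf.total_chi2(fluxes, frames, probes, params, lambda2=0.0, c0=10 ** -6.5)
        b = pf.total_chi2(fluxes, frames, probes, params, lambda2=50.0, c0=10 ** -6.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_lambda2_term_hand_value(self, params):
        # one tracked cell with u = (1, 3), lambda2 = 0.5 -> adds 0.5*(3-1)^2 = 2
        frames, probes = self._two_frames(params)
        fluxes = [pf.FluxVector(0.0, ["c0"], np.array([v])) for v in (1.0, 3.0)]
        base = pf.total_chi2(fluxes, frames, probes, params, lambda2=0.0, c0=10 ** -6.5)
        with_l2 = pf.total_chi2(fluxes, frames, probes, params, lambda2=0.5, c0=10 ** -6.5)
        assert with_l2 - base == pytest.approx(2.0, rel=1e-12)

    def test_lambda3_without_bulk_raises(self, params):
        frames, probes = self._two_frames(params)
        fluxes = [pf.FluxVector(0.0, ["c0"], np.array([1.0]))] * 2
        with pytest.raises(pf.InferenceError, match="lambda3"):
            pf.total_chi2(fluxes, frames, probes, params, lambda3=1.0, c0=10 ** -6.5)


class TestWarmStart:
    def test_recovers_single_source_noise_free(self, params):
        c0 = 10 ** -6.5
        probe_xy = [[180.0, 200.0], [230.0, 210.0], [200.0, 170.0],
                    [250.0, 250.0], [150.0, 260.0], [300.0, 150.0],
                    [120.0, 120.0], [330.0, 330.0]]
        cells, probes = _noise_free_frame(params, [[210.0, 215.0]], [1.7],
                                          probe_xy, c0)
        p = pf.PhysicalParams(background_concentration_c0=c0)
        prob = pf.build_problem([cells], [probes], p, lambda1=1e-10, lambda2=0.0)
        states = pf.gaussian_warm_start(prob)
        assert states[0][1] == pytest.approx(1.7, rel=1e-6)

    def test_infinite_prior_shrinks_to_zero(self, params):
        c0 = 10 ** -6.5
        cells, probes = _noise_free_frame(params, [[210.0, 215.0]], [1.7],
                                          [[180.0, 200.0], [260.0, 230.0]], c0)
        p = pf.PhysicalParams(background_concentration_c0=c0)
        prob = pf.build_problem([cells], [probes], p, lambda1=1e9, lambda2=0.0)
        states = pf.gaussian_warm_start(prob)
        assert abs(states[0][1]) < 1e-4

    def test_underdetermined_without_prior_raises(self, params):
        c0 = 10 ** -6.5
        cells, probes = _noise_free_frame(
            params, [[150.0, 150.0], [250.0, 250.0], [350.0, 350.0]], [1.0, 0.5, -0.5],
            [[200.0, 200.0], [300.0, 300.0]], c0)
        p = pf.PhysicalParams(background_concentration_c0=c0)
        prob = pf.build_problem([cells], [probes], p, lambda1=0.0, lambda2=0.0)
        with pytest.raises(pf.InferenceError, match="lambda1"):
            pf.gaussian_warm_start(prob)

    def test_matches_generic_minimizer_on_small_instance(self, params):
        rng = np.random.default_rng(5)
        c0 = 10 ** -6.5
        cell_xy = rng.uniform(120, 380, (3, 2))
        probe_xy = rng.uniform(60, 440, (20, 2))
        cells, probes = _noise_free_frame(params, cell_xy, [1.2, -0.7, 0.4],
                                          probe_xy, c0)
        noisy = probes.probes.copy()
        noisy["pH"] = noisy["pH"] + rng.normal(0, 0.02, len(noisy))
        probes = pf.ProbeFrame(0, 0.0, noisy)
        p = pf.PhysicalParams(background_concentration_c0=c0)
        lam1 = 0.05
        prob = pf.build_problem([cells], [probes], p, lambda1=lam1, lambda2=0.0)
        states = pf.gaussian_warm_start(prob)

        def cost(x):
            return inference.total_chi2_states(prob, [x])

        res = minimize(cost, np.zeros(4), method="Powell",
                       options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000})
        scale = np.maximum(np.abs(res.x), 0.05)
        assert np.all(np.abs(states[0] - res.x) / scale < 0.01)


class TestSampler:
    def _small_problem(self, params, seed=0, n_probes=12):
        rng = np.random.default_rng(seed)
        c0 = 10 ** -6.5
        cell_xy = rng.uniform(150, 350, (2, 2))
        probe_xy = rng.uniform(80, 420, (n_probes, 2))
        cells, probes = _noise_free_frame(params, cell_xy, [0.8, -0.5], probe_xy, c0)
        noisy = probes.probes.copy()
        noisy["pH"] = noisy["pH"] + rng.normal(0, 0.02, len(noisy))
        probes = pf.ProbeFrame(0, 0.0, noisy)
        p = pf.PhysicalParams(background_concentration_c0=c0)
        return pf.build_problem([cells], [probes], p, lambda1=1.0, lambda2=0.0)

    def test_moments_match_gaussian_approximation(self, params):
        """Near the MAP the posterior is Gaussian with covariance H^-1."""
        prob = self._small_problem(params)
        states, hess = pf.gaussian_warm_start(prob, return_hessians=True)
        hyper = pf.Hyperparams(lambda1=1.0, lambda2=0.0, n_samples=10000,
                               burn_in=1500, seed=1)
        rng = np.random.default_rng(1)
        chain, diag = pf.sample_posterior(prob, states, hess, hyper, rng)
        # chi2 - chi2* = d^T H d, so exp(-chi2/2) has covariance H^-1
        cov_expected = np.linalg.inv(hess[0])
        sd_expected = np.sqrt(np.diag(cov_expected))
        sd_chain = chain.std(axis=0)
        assert np.all(np.abs(sd_chain / sd_expected - 1) < 0.2)
        # chain mean within a few effective standard errors of the MAP
        assert np.all(np.abs(chain.mean(axis=0) - states[0]) < 6 * sd_expected /
                      np.sqrt(len(chain) / 50))

    def test_seed_reproduces_chain_exactly(self, params):
        prob = self._small_problem(params)
        states, hess = pf.gaussian_warm_start(prob, return_hessians=True)
        hyper = pf.Hyperparams(lambda1=1.0, lambda2=0.0, n_samples=300,
                               burn_in=100, seed=7)
        c1, _ = pf.sample_posterior(prob, states, hess, hyper,
                                    np.random.default_rng(7))
        c2, _ = pf.sample_posterior(prob, states, hess, hyper,
                                    np.random.default_rng(7))
        assert np.array_equal(c1, c2)

    def test_acceptance_rate_reported_in_sane_range(self, params):
        prob = self._small_problem(params)
        states, hess = pf.gaussian_warm_start(prob, return_hessians=True)
        hyper = pf.Hyperparams(lambda1=1.0, lambda2=0.0, n_samples=500,
                               burn_in=500, seed=2)
        _, diag = pf.sample_posterior(prob, states, hess, hyper,
                                      np.random.default_rng(2))
        assert 0.1 < diag["acceptance_rate"] < 0.6


class TestAnnealing:
    def test_does_not_worsen_a_minimum(self, params):
        rng = np.random.default_rng(3)
        c0 = 10 ** -6.5
        cell_xy = rng.uniform(150, 350, (2, 2))
        probe_xy = rng.uniform(80, 420, (10, 2))
        cells, probes = _noise_free_frame(params, cell_xy, [0.8, -0.5], probe_xy, c0)
        p = pf.PhysicalParams(background_concentration_c0=c0)
        prob = pf.build_problem([cells], [probes], p, lambda1=0.3, lambda2=0.0)
        states, hess = pf.gaussian_warm_start(prob, return_hessians=True)
        start_cost = inference.total_chi2_states(prob, states)
        hyper = pf.Hyperparams(lambda1=0.3, lambda2=0.0,
                               anneal_t_initial=10.0, anneal_cooling=0.8,
                               anneal_sweeps_per_temp=50, seed=0)
        _, best_cost = pf.anneal_to_map(prob, states, hess, hyper,
                                        np.random.default_rng(0))
        assert best_cost <= start_cost + 1e-9

    def test_double_well_finds_global_basin(self):
        """Annealed random walk escapes the shallow basin of a double well."""
        def cost(x):
            return float((x[0] ** 2 - 1.0) ** 2 * 8.0 + 0.8 * x[0])
        xs = np.linspace(-2, 2, 4001)
        global_min_x = xs[np.argmin([cost([x]) for x in xs])]
        assert global_min_x < 0
        hits = 0
        n_runs = 100
        for s in range(n_runs):
            x, _ = inference.simulated_annealing(
                cost, np.array([1.0]), proposal_scale=0.15,
                t_initial=20.0, cooling=0.9, steps_per_temp=60,
                rng=np.random.default_rng(s))
            hits += abs(x[0] - global_min_x) < 0.3
        assert hits >= 95


class TestConfidenceIntervals:
    def test_gaussian_chain_halfwidth_matches_sigma(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(2.0, 0.5, size=(20000, 1))
        low, high, sigma = pf.confidence_intervals(chain, level=0.68)
        half = (high[0] - low[0]) / 2
        assert half == pytest.approx(0.4944 * 1.0114, rel=0.1)  # ~z_0.84 * sd
        assert sigma[0] == pytest.approx(0.5, rel=0.05)

    def test_level_zero_degenerates_to_median(self):
        rng = np.random.default_rng(1)
        chain = rng.normal(0, 1, size=(500, 2))
        low, high, _ = pf.confidence_intervals(chain, level=0.0)
        assert np.allclose(low, np.median(chain, axis=0))
        assert np.allclose(low, high)

    def test_short_chain_raises(self):
        with pytest.raises(pf.InferenceError):
            pf.confidence_intervals(np.zeros((50, 3)))


class TestBulkEfflux:
    def test_constant_ph_gives_zero_efflux(self, params):
        t = np.arange(0, 60, 10.0)
        out = pf.estimate_bulk_efflux(t, np.full(len(t), 7.0), 100, params)
        assert np.allclose(out.bulk_efflux, 0.0)

    def test_linear_concentration_growth(self, params):
        # [H+] growing at r mol/L/min into volume V with N cells
        r, N = 2.0e-9, 50
        t = np.arange(0, 120, 10.0)
        c = 1e-7 + r * t
        ph = -np.log10(c)
        out = pf.estimate_bulk_efflux(t, ph, N, params)
        expected_native = r / 60.0 * params.medium_volume_L / N
        expected = pf.convert_flux_units(expected_native, params)
        assert np.allclose(out.bulk_efflux[1:-1], expected, rtol=1e-9)

    def test_time_reversal_flips_sign(self, params):
        rng = np.random.default_rng(0)
        t = np.arange(0, 100, 10.0)
        ph = 7.0 + np.cumsum(rng.normal(0, 0.01, len(t)))
        fwd = pf.estimate_bulk_efflux(t, ph, 10, params)
        rev = pf.estimate_bulk_efflux(t, ph[::-1], 10, params)
        assert np.allclose(fwd.bulk_efflux, -rev.bulk_efflux[::-1])

    def test_too_few_points_raises(self, params):
        with pytest.raises(pf.InferenceError):
            pf.estimate_bulk_efflux([0.0, 10.0], [7.0, 7.0], 10, params)


class TestTracking:
    def test_identical_positions_match_identically(self):
        a = make_cell_frame([[10.0, 10.0], [100.0, 100.0]], frame_index=0)
        b = make_cell_frame([[10.0, 10.0], [100.0, 100.0]], frame_index=1,
                            time_min=10.0)
        assert pf.track_cells([a, b]) == [{"c0": "c0", "c1": "c1"}]

    def test_small_displacement_within_gate_matches(self):
        a = make_cell_frame([[50.0, 50.0]], frame_index=0)
        b = make_cell_frame([[58.0, 56.0]], frame_index=1, time_min=10.0)
        assert pf.track_cells([a, b]) == [{"c0": "c0"}]

    def test_displacement_beyond_gate_breaks_tracks(self):
        # two cells swapping distant neighbourhoods: both tracks end
        a = make_cell_frame([[50.0, 50.0], [400.0, 400.0]], frame_index=0)
        b = make_cell_frame([[400.0, 400.0], [50.0, 50.0]], frame_index=1,
                            time_min=10.0, ids=["d0", "d1"])
        m = pf.track_cells([a, b], max_displacement_um=30.0)
        # mutual NN pairs are (c0 -> d1) and (c1 -> d0), both within the gate
        # at zero displacement in space, so they match; force a true break:
        c = make_cell_frame([[250.0, 250.0]], frame_index=1, time_min=10.0,
                            ids=["far"])
        assert pf.track_cells([a, c], max_displacement_um=30.0) == [{}]

    def test_single_frame_yields_empty_map(self):
        a = make_cell_frame([[50.0, 50.0]])
        assert pf.track_cells([a]) == []


class TestRegularizationMonotonicity:
    def _instance(self, params):
        exp = pf.generate_experiment("uniform", n_cells=10, n_probes=14,
                                     n_frames=3, noise_sigma=0.02, seed=4)
        p = pf.PhysicalParams(background_concentration_c0=exp.c0)
        return exp, p

    def test_flux_norm_non_increasing_in_lambda1(self, params):
        exp, p = self._instance(params)
        norms = []
        for lam1 in (0.01, 1.0, 100.0):
            prob = pf.build_problem(exp.cell_frames, exp.probe_frames, p,
                                    lambda1=lam1, lambda2=0.1)
            states = pf.gaussian_warm_start(prob)
            norms.append(sum(float(s[1:] @ s[1:]) for s in states))
        assert norms[0] >= norms[1] >= norms[2]

    def test_temporal_roughness_non_increasing_in_lambda2(self, params):
        exp, p = self._instance(params)
        rough = []
        for lam2 in (0.01, 1.0, 100.0):
            prob = pf.build_problem(exp.cell_frames, exp.probe_frames, p,
                                    lambda1=0.1, lambda2=lam2)
            states = pf.gaussian_warm_start(prob)
            r = 0.0
            for t in range(len(states) - 1):
                ii, jj = prob.links[t]
                d = states[t + 1][jj] - states[t][ii]
                r += float(d @ d)
            rough.append(r)
        assert rough[0] >= rough[1] >= rough[2]


class TestGCV:
    def test_selected_lambda_is_positive_and_moderate(self, params):
        exp = pf.generate_experiment("uniform", n_cells=8, n_probes=12,
                                     n_frames=2, noise_sigma=0.02, seed=1)
        p = pf.PhysicalParams(background_concentration_c0=exp.c0)
        prob = pf.build_problem(exp.cell_frames, exp.probe_frames, p, 0.0, 0.0)
        lam = pf.select_lambda1_gcv(prob)
        assert lam > 0
        assert np.isfinite(lam)
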