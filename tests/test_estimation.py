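"""Update-map estimation: trimming, OLS, labeled eigenanalysis, residuals."""

import numpy as np
import pandas as pd
import pytest

from gemdyn import (
    BodyState,
    TaskConfig,
    eigenanalysis,
    fit_update_matrix,
    fluctuations,
    gem_frame,
    operating_point,
    residual_noise,
    steady_state_std,
    to_eigencoordinates,
)
from gemdyn.estimation import (
    ComplexEigenvaluesError,
    DegenerateEigenvaluesError,
    fit_linear_model,
)
from gemdyn.series import TrialSeries
from gemdyn.simulate import SimulationSpec, build_update_matrix, simulate_series

from conftest import make_exact_linear_flucts


def _series_from_states(states, cfg, block_len=50):
    n = len(states)
    n_blocks = n // block_len
    df = pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, n_blocks + 1), block_len),
            "trial": np.tile(np.arange(1, block_len + 1), n_blocks),
            "x": states[:, 0],
            "v": states[:, 1],
            "e": np.zeros(n),
        }
    )
    return TrialSeries(data=df, cfg=cfg)


class TestOperatingPoint:
    def test_mean_of_two(self, cfg):
        ts = _series_from_states(np.array([[0.0, 0.0], [2.0, 2.0]] * 25), cfg, block_len=50)
        op = operating_point(ts)
        assert (op.x, op.v) == (1.0, 1.0)

    def test_noise_free_simulation_recovers_spec_point(self, cfg):
        spec = SimulationSpec(cfg=cfg, sigma_nw=0.0, sigma_ns=0.0, seed=1)
        op = operating_point(simulate_series(spec))
        truth = spec.resolve_op_point()
        assert op.x == pytest.approx(truth.x, abs=1e-12)
        assert op.v == pytest.approx(truth.v, abs=1e-12)


class TestFluctuationPairs:
    def test_default_trimming_gives_450_pairs(self, study_series):
        fl = fluctuations(study_series)
        assert fl.n_pairs == 450
        assert len(fl.concat_index) == 460
        # current states are trials 5..49 of each block
        trials = study_series.data["trial"].to_numpy()
        assert set(trials[fl.pair_index[:, 0]]) == set(range(5, 50))
        assert np.all(trials[fl.pair_index[:, 1]] == trials[fl.pair_index[:, 0]] + 1)

    def test_no_pair_spans_blocks(self, study_series):
        fl = fluctuations(study_series)
        blocks = study_series.block_index()
        assert np.all(blocks[fl.pair_index[:, 0]] == blocks[fl.pair_index[:, 1]])

    def test_no_trimming_gives_49_per_block(self, study_series):
        fl = fluctuations(study_series, trim_head=0, use_first=49)
        assert fl.n_pairs == 49 * 10

    def test_minimal_block(self, cfg):
        states = np.random.default_rng(0).standard_normal((6, 2))
        ts = _series_from_states(states, cfg, block_len=6)
        assert fluctuations(ts).n_pairs == 1

    def test_block_too_short_raises(self, cfg):
        ts = _series_from_states(np.zeros((5, 2)), cfg, block_len=5)
        with pytest.raises(ValueError):
            fluctuations(ts)


class TestFitUpdateMatrix:
    def test_exact_recovery_on_noise_free_pairs(self):
        B0 = np.array([[0.7, -0.2], [0.05, -0.1]])
        fl = make_exact_linear_flucts(B0, n_pairs=50)
        assert np.max(np.abs(fit_update_matrix(fl.pairs()) - B0)) < 1e-10

    def test_white_noise_estimates_shrink(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10_000, 2))
        Y = rng.standard_normal((10_000, 2))
        assert np.linalg.norm(fit_update_matrix((X, Y))) < 0.1

    def test_rank_deficiency_raises(self):
        X = np.ones((100, 2))
        with pytest.raises(np.linalg.LinAlgError):
            fit_update_matrix((X, X))


class TestEigenanalysis:
    def test_printed_mean_matrix(self, frame):
        # mean update matrix reported for the aggregate shuffleboard data
        B = np.array([[0.76, -0.26], [-0.01, -0.03]])
        model = eigenanalysis(B, frame)
        assert round(model.lambda_w, 2) == 0.76
        assert round(model.lambda_s, 2) == -0.03
        assert model.lambda_w == pytest.approx(0.763, abs=5e-3)
        assert model.lambda_s == pytest.approx(-0.033, abs=5e-3)

    def test_degenerate_matrix_raises(self, frame):
        with pytest.raises(DegenerateEigenvaluesError):
            eigenanalysis(0.5 * np.eye(2), frame)

    def test_complex_pair_raises(self, frame):
        with pytest.raises(ComplexEigenvaluesError):
            eigenanalysis(np.array([[0.0, -1.0], [1.0, 0.0]]), frame)

    def test_angle_conventions(self, cfg, frame):
        spec = SimulationSpec(cfg=cfg, lambda_w=0.7, lambda_s=0.2,
                              theta_w_deg=-3.0, theta_s_deg=120.0)
        model = eigenanalysis(build_update_matrix(spec, frame), frame)
        assert model.theta_w_deg == pytest.approx(-3.0, abs=1e-7)
        assert model.theta_s_deg == pytest.approx(120.0, abs=1e-7)
        assert model.beta == pytest.approx(np.sin(np.radians(120.0)), abs=1e-9)
        assert model.e_w @ frame.e_t >= 0
        assert model.e_s @ frame.e_n >= 0

    def test_scale_invariance_of_fit_and_eigen(self, study_analysis):
        _, fl, fr, model = study_analysis
        X, Y = fl.pairs()
        scaled = fit_update_matrix((X * 37.2, Y * 37.2))
        model2 = eigenanalysis(scaled, fr)
        assert model2.lambda_w == pytest.approx(model.lambda_w, abs=1e-12)
        assert model2.theta_s_deg == pytest.approx(model.theta_s_deg, abs=1e-9)


class TestEigencoordinates:
    def test_basis_vectors_map_to_axes(self, study_analysis):
        *_, model = study_analysis
        z = to_eigencoordinates(np.stack([model.e_w, model.e_s]), model.E)
        assert np.allclose(z, np.eye(2), atol=1e-12)

    def test_round_trip(self, study_analysis):
        *_, model = study_analysis
        u = np.random.default_rng(4).standard_normal((200, 2))
        assert np.max(np.abs(to_eigencoordinates(u, model.E) @ model.E.T - u)) < 1e-10


class TestResidualNoise:
    def test_zero_for_exact_linear_data(self, frame):
        B0 = np.array([[0.7, 0.1], [0.0, 0.2]])
        fl = make_exact_linear_flucts(B0, n_pairs=100)
        model = eigenanalysis(B0, frame)
        r, s_nw, s_ns = residual_noise(fl.pairs(), B0, model.E)
        assert s_nw < 1e-12 and s_ns < 1e-12

    def test_recovers_injected_noise_scale(self, cfg):
        spec = SimulationSpec(cfg=cfg, sigma_nw=0.5e-3, sigma_ns=0.5 * 1e-3,
                              n_blocks=200, seed=8)
        ts = simulate_series(spec)
        fr = gem_frame(operating_point(ts), cfg)
        model = fit_linear_model(fluctuations(ts), fr)
        assert model.sigma_ns == pytest.approx(0.5e-3, rel=0.03)
        assert model.sigma_nw == pytest.approx(0.5e-3, rel=0.03)

    def test_permutation_invariance(self, study_analysis):
        _, fl, _, model = study_analysis
        X, Y = fl.pairs()
        perm = np.random.default_rng(5).permutation(len(X))
        _, s_nw, s_ns = residual_noise((X[perm], Y[perm]), model.B, model.E)
        assert s_nw == pytest.approx(model.sigma_nw, abs=1e-15)
        assert s_ns == pytest.approx(model.sigma_ns, abs=1e-15)


class TestSteadyStateStd:
    @pytest.mark.parametrize("lam, sigma, expected", [
        (0.0, 1.0, 1.0),
        (0.76, 1.0, 1.539),
    ])
    def test_values(self, lam, sigma, expected):
        assert steady_state_std(lam, sigma) == pytest.approx(expected, abs=1e-3)

    def test_random_walk_boundary_raises(self):
        with pytest.raises(ValueError):
            steady_state_std(1.0, 1.0)

    def test_matches_long_simulation(self, cfg):
        spec = SimulationSpec(cfg=cfg, n_blocks=400, seed=9)
        ts = simulate_series(spec)
        fr = gem_frame(operating_point(ts), cfg)
        fl = fluctuations(ts)
        model = fit_linear_model(fl, fr)
        z = to_eigencoordinates(fl.u, model.E)
        for col, (lam, sig) in enumerate(
            [(model.lambda_w, model.sigma_nw), (model.lambda_s, model.sigma_ns)]
        ):
            assert z[:, col].std() == pytest.approx(steady_state_std(lam, sig), rel=0.10)


class TestPipelineRecovery:
    def test_parameter_recovery_bias(self, cfg):
        """Estimates at N=450 are unbiased within 0.05 / 5 deg over 50 seeds."""
        spec0 = SimulationSpec(cfg=cfg, lambda_w=0.7, lambda_s=0.0,
                               theta_w_deg=2.0, theta_s_deg=75.0)
        est = []
        for seed in range(50):
            spec = SimulationSpec(**{**spec0.__dict__, "seed": seed})
            ts = simulate_series(spec)
            fr = gem_frame(operating_point(ts), cfg)
            model = fit_linear_model(fluctuations(ts), fr)
            est.append([model.lambda_w, model.lambda_s, model.theta_w_deg,
                        model.theta_s_deg, model.sigma_nw, model.sigma_ns])
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - 0.7) < 0.05
        assert abs(mean[1] - 0.0) < 0.05
        assert abs(mean[2] - 2.0) < 5.0
        assert abs(mean[3] - 75.0) < 5.0
        assert abs(mean[4] / 1e-3 - 1) < 0.05
        assert abs(mean[5] / 1e-3 - 1) < 0.05
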