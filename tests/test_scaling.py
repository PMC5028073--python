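"""Scaling law: s_TOT arithmetic, per-condition points, fits, hypotheses."""

import numpy as np
import pytest

from gemdyn import (
    TaskConfig,
    bootstrap_scaling,
    fit_scaling,
    fluctuations,
    gem_frame,
    hypothesis_report,
    operating_point,
    s_total,
    scaling_point,
)
from gemdyn.estimation import fit_linear_model
from gemdyn.resampling import BootstrapDistribution
from gemdyn.scaling import ScalingFit, ScalingPoint
from gemdyn.simulate import SimulationSpec, simulate_experiment, simulate_series


def _analyze(series):
    fr = gem_frame(operating_point(series), series.cfg)
    fl = fluctuations(series)
    model = fit_linear_model(fl, fr)
    return fl, fr, model


def _point(condition, s_tot_val, ratio):
    # back out a consistent ScalingPoint with beta=1, lambda_s=0
    return ScalingPoint(
        condition=condition, sigma_e=ratio, sigma_R=np.nan, sigma_N=np.nan,
        sigma_ns=1.0, s=s_tot_val, beta=1.0, lambda_s=0.0, mean_e=0.0,
    )


class TestSTotal:
    def test_trivial_active_factor(self):
        assert s_total(beta=1.0, s=50.0, lambda_s=0.0) == 50.0

    def test_study_aggregate_values(self):
        val = s_total(beta=np.sin(np.radians(79.75)), s=50.01, lambda_s=-0.03)
        assert val == pytest.approx(49.23, abs=0.05)

    def test_monotonicity(self):
        assert s_total(0.9, 60.0, 0.0) > s_total(0.9, 50.0, 0.0)
        assert s_total(0.95, 50.0, 0.0) > s_total(0.9, 50.0, 0.0)
        with pytest.raises(ValueError):
            s_total(1.0, 50.0, 1.0)


class TestScalingPoint:
    def test_sigma_e_matches_passive_amplification(self, study_analysis):
        # sigma_e = s * sigma_R for small fluctuations
        series, fl, fr, model = study_analysis
        point = scaling_point(series, fr, model)
        assert point.sigma_e == pytest.approx(fr.s * point.sigma_R, rel=0.05)

    def test_ratio_matches_s_tot(self, study_analysis):
        series, fl, fr, model = study_analysis
        point = scaling_point(series, fr, model)
        assert point.ratio / point.s_tot == pytest.approx(1.0, abs=0.1)


class TestFitScaling:
    def test_exact_line(self):
        points = [_point(f"c{i}", s, s) for i, s in enumerate([10.0, 20.0, 30.0, 40.0])]
        fit = fit_scaling(points)
        assert fit.a == pytest.approx(1.0, abs=1e-12)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate(self):
        fit = fit_scaling([_point("a", 10.0, 12.0), _point("b", 20.0, 30.0)])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.a == pytest.approx(1.8)

    def test_degenerate_abscissa_raises(self):
        with pytest.raises(ValueError):
            fit_scaling([_point("a", 10.0, 1.0), _point("b", 10.0, 2.0)])


@pytest.fixture(scope="module")
def experiment(cfg):
    base = SimulationSpec(cfg=cfg, seed=99)
    series = simulate_experiment(base)
    return [(s, *(_analyze(s)[:2])) for s in series]


class TestBootstrapScaling:
    def test_slope_near_unity(self, experiment):
        fit = bootstrap_scaling(experiment, n_iter=1000, seed=0)
        assert fit.a == pytest.approx(1.0, abs=0.05)
        assert abs(fit.b) < 5.0  # small relative to ratios of order 30-50
        assert fit.dist_a.ci_low <= 1.0 <= fit.dist_a.ci_high

    def test_pooled_fit_matches_iterate_mean(self, experiment):
        fit = bootstrap_scaling(experiment, n_iter=2000, seed=1)
        assert fit.a == pytest.approx(fit.dist_a.mean, rel=0.01)

    def test_determinism(self, experiment):
        a = bootstrap_scaling(experiment, n_iter=200, seed=2)
        b = bootstrap_scaling(experiment, n_iter=200, seed=2)
        assert np.array_equal(a.dist_a.samples, b.dist_a.samples)

    def test_too_few_conditions(self, experiment):
        with pytest.raises(ValueError):
            bootstrap_scaling(experiment[:2], n_iter=100, seed=3)


def _dist(name, mean, half_width, n=1000):
    rng = np.random.default_rng(abs(hash(name)) % 2**31)
    samples = mean + rng.uniform(-half_width, half_width, n)
    return BootstrapDistribution(name, samples, n_iter=n)


class TestHypothesisReport:
    def aggregates(self):
        # distributions matching the study's reported aggregate means/CIs
        return {
            "lambda_w": _dist("lambda_w", 0.76, 0.14),
            "lambda_s": _dist("lambda_s", -0.03, 0.19),
            "theta_w_deg": _dist("theta_w_deg", 0.90, 3.1),
            "theta_s_deg": _dist("theta_s_deg", 79.75, 60.0),
            "R_w1": _dist("R_w1", 0.76, 0.12),
            "R_s1": _dist("R_s1", -0.03, 0.19),
            "alpha_w": _dist("alpha_w", 0.99, 0.13),
            "alpha_s": _dist("alpha_s", 0.52, 0.075),
        }

    def test_reported_aggregates_pass_all_four(self):
        fit = ScalingFit(a=0.99, b=0.21, r_squared=0.996,
                         dist_a=_dist("a", 0.99, 0.05), dist_b=_dist("b", 0.21, 1.2))
        report = hypothesis_report(self.aggregates(), fit)
        assert all(report[h]["pass"] for h in ("H1", "H2", "H3", "H4"))

    def test_white_noise_data_fails_h1(self):
        dists = self.aggregates()
        dists["lambda_w"] = _dist("lambda_w_null", 0.0, 0.1)
        report = hypothesis_report(dists)
        assert report["H1"]["pass"] is False

    def test_missing_inputs_reported(self):
        report = hypothesis_report({})
        assert report["H1"]["pass"] is None
        assert "lambda_w" in report["H1"]["missing"]

    def test_white_noise_pipeline_fails_h1(self, cfg):
        # end-to-end null case: essentially no inter-trial dynamics.  The
        # estimated B is sampling noise, so either the bootstrap flags that no
        # real eigenstructure exists, or the lambda_w CI straddles 0 and H1
        # fails.
        from gemdyn import bootstrap_model, fit_update_matrix
        from gemdyn.resampling import DegenerateBootstrapError

        spec = SimulationSpec(cfg=cfg, lambda_w=1e-6, lambda_s=0.0,
                              theta_w_deg=1.0, theta_s_deg=80.0, seed=13)
        ts = simulate_series(spec)
        fr = gem_frame(operating_point(ts), cfg)
        fl = fluctuations(ts)
        assert np.linalg.norm(fit_update_matrix(fl.pairs())) < 0.25
        try:
            dists = bootstrap_model(fl, fr, n_iter=500, seed=1)
        except DegenerateBootstrapError:
            return
        report = hypothesis_report(dists)
        assert report["H1"]["pass"] is False

    def test_misaligned_weak_direction_fails_h1(self, cfg):
        # strong persistence along a direction far from the GEM tangent
        from gemdyn import bootstrap_model

        spec = SimulationSpec(cfg=cfg, lambda_w=0.76, lambda_s=-0.03,
                              theta_w_deg=45.0, theta_s_deg=135.0, seed=14)
        ts = simulate_series(spec)
        fl, fr, model = _analyze(ts)
        dists = bootstrap_model(fl, fr, n_iter=500, seed=2)
        report = hypothesis_report(dists)
        assert report["H1"]["pass"] is False
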