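import numpy as np
import pytest

from gemdyn import BodyState, TaskConfig, fluctuations, gem_frame, operating_point
from gemdyn.estimation import FluctuationSeries, fit_linear_model
from gemdyn.simulate import SimulationSpec, simulate_series


@pytest.fixture(scope="session")
def cfg():
    """Default task geometry at the low-friction reference value."""
    return TaskConfig(mu=0.016)


@pytest.fixture(scope="session")
def frame(cfg):
    """GEM frame at the on-GEM point x*=0, v*=0.4 (goal_function = 0)."""
    return gem_frame(BodyState(x=0.0, v=0.4), cfg)


@pytest.fixture(scope="session")
def study_spec(cfg):
    """Simulation spec at the study-condition defaults (10x50 trials)."""
    return SimulationSpec(cfg=cfg, seed=12345)


@pytest.fixture(scope="session")
def study_series(study_spec):
    return simulate_series(study_spec)


@pytest.fixture(scope="session")
def study_analysis(study_series):
    """(series, flucts, frame, model) for the default simulated condition."""
    op = operating_point(study_series)
    fr = gem_frame(op, study_series.cfg)
    fl = fluctuations(study_series)
    model = fit_linear_model(fl, fr)
    return study_series, fl, fr, model


def make_exact_linear_flucts(B0, n_pairs=300, seed=0, op=None):
    """FluctuationSeries whose pairs follow u' = B0 u exactly (no noise)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_pairs, 2))
    Y = X @ np.asarray(B0, dtype=float).T
    u = np.empty((2 * n_pairs, 2))
    u[0::2] = X
    u[1::2] = Y
    pair_index = np.column_stack([np.arange(0, 2 * n_pairs, 2), np.arange(1, 2 * n_pairs, 2)])
    return FluctuationSeries(
        u=u,
        pair_index=pair_index,
        block=np.ones(2 * n_pairs, dtype=int),
        concat_index=np.arange(2 * n_pairs),
        op_point=op or BodyState(0.0, 0.4),
    )
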