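"""Synthetic shuffleboard experiment with a known linear inter-trial controller.

Trial-to-trial fluctuations about an on-GEM operating point follow the linear
update

    u[k+1] = B u[k] + nu[k],        nu[k] = E n[k],

where B has one weakly stable eigendirection nearly tangent to the GEM
(eigenvalue ``lambda_w``, somewhat below 1) and one strongly stable direction
transverse to it (``lambda_s`` near 0), and ``n[k]`` is zero-mean Gaussian
noise specified independently in the two eigendirections.  Release states are
``x[k] = x* + u[k]`` and errors come from the exact nonlinear goal function,
so the data carry the same structure the estimation modules assume — plus the
(small) linearization error a real task would have.

The defaults encode the study conditions this package analyses: 10 blocks of
50 trials per condition, eigenvalues (0.76, -0.03), eigenvector angles
(1 deg, 80 deg) from the GEM tangent, equal eigendirection noise of 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .series import TrialSeries
from .task import BodyState, GemFrame, TaskConfig, friction_set, gem_frame, gem_speed, goal_function

__all__ = [
    "SimulationSpec",
    "build_update_matrix",
    "simulate_series",
    "stationary_covariance",
    "simulate_experiment",
]

_PARALLEL_TOL = 1e-9


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters for one simulated participant/condition.

    Angles are measured from the GEM tangent, in degrees; ``theta_w_deg`` is
    signed (the weak eigenvector is expected nearly tangent), ``theta_s_deg``
    lies in (0, 180).  Noise standard deviations ``sigma_nw, sigma_ns`` apply
    to the independent Gaussian components in the weak/strong eigendirections.
    ``measurement_noise_frac`` adds independent Gaussian read-out noise to the
    recorded x and v with standard deviation equal to that fraction of each
    component's fluctuation standard deviation (0.02 emulates ~2% apparatus
    precision).
    """

    cfg: TaskConfig
    op_point: BodyState | None = None  # default: on-GEM at x*=1
    lambda_w: float = 0.76
    lambda_s: float = -0.03
    theta_w_deg: float = 1.0
    theta_s_deg: float = 80.0
    sigma_nw: float = 1e-3
    sigma_ns: float = 1e-3
    n_blocks: int = 10
    block_len: int = 50
    burn_in: int = 200
    measurement_noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (abs(self.lambda_w) < 1 and abs(self.lambda_s) < 1):
            raise ValueError(
                f"SimulationSpec requires |lambda| < 1 for stationarity, got "
                f"({self.lambda_w}, {self.lambda_s})"
            )
        if abs((self.theta_w_deg - self.theta_s_deg) % 180.0) < _PARALLEL_TOL:
            raise ValueError("SimulationSpec: eigenvector angles coincide mod 180 deg")
        if self.sigma_nw < 0 or self.sigma_ns < 0:
            raise ValueError("SimulationSpec: noise scales must be >= 0")
        if self.n_blocks < 1 or self.block_len < 2 or self.burn_in < 0:
            raise ValueError("SimulationSpec: invalid block structure")

    def resolve_op_point(self) -> BodyState:
        if self.op_point is not None:
            return self.op_point
        return BodyState(x=1.0, v=gem_speed(1.0, self.cfg))

    def frame(self) -> GemFrame:
        return gem_frame(self.resolve_op_point(), self.cfg)


def _eigvec_matrix(spec: SimulationSpec, frame: GemFrame) -> np.ndarray:
    """Columns (e_w, e_s) built from GEM-relative angles."""
    tw = np.deg2rad(spec.theta_w_deg)
    ts = np.deg2rad(spec.theta_s_deg)
    e_w = np.cos(tw) * frame.e_t + np.sin(tw) * frame.e_n
    e_s = np.cos(ts) * frame.e_t + np.sin(ts) * frame.e_n
    E = np.column_stack([e_w, e_s])
    if abs(np.linalg.det(E)) < _PARALLEL_TOL:
        raise ValueError("eigenvectors are (numerically) parallel")
    return E


def build_update_matrix(spec: SimulationSpec, frame: GemFrame | None = None) -> np.ndarray:
    """B = E diag(lambda_w, lambda_s) E^-1 with eigenvectors at the spec angles."""
    frame = spec.frame() if frame is None else frame
    E = _eigvec_matrix(spec, frame)
    return E @ np.diag([spec.lambda_w, spec.lambda_s]) @ np.linalg.inv(E)


def simulate_series(spec: SimulationSpec) -> TrialSeries:
    """Iterate the noisy linear update and record blocked trials.

    Starts at u = 0, discards ``burn_in`` iterates, then records
    ``n_blocks * block_len`` trials.  Errors are computed from the exact
    nonlinear goal function at the (noise-free) release state; optional
    measurement noise perturbs only the *recorded* x and v.
    Identical spec (including seed) gives identical output.
    """
    frame = spec.frame()
    E = _eigvec_matrix(spec, frame)
    B = E @ np.diag([spec.lambda_w, spec.lambda_s]) @ np.linalg.inv(E)
    op = spec.resolve_op_point().as_array()

    n_rec = spec.n_blocks * spec.block_len
    n_tot = spec.burn_in + n_rec
    rng = np.random.default_rng(spec.seed)
    # eigencoordinate noise, mapped to the laboratory frame through E
    n_eig = rng.standard_normal((n_tot, 2)) * np.array([spec.sigma_nw, spec.sigma_ns])
    nu = n_eig @ E.T

    u = np.zeros((n_tot + 1, 2))
    for k in range(n_tot):
        u[k + 1] = B @ u[k] + nu[k]
    u_rec = u[spec.burn_in + 1 : n_tot + 1]

    states = op + u_rec
    e = goal_function((states[:, 0], states[:, 1]), spec.cfg)

    if spec.measurement_noise_frac > 0:
        sd = u_rec.std(axis=0, ddof=0) * spec.measurement_noise_frac
        states = states + rng.standard_normal(states.shape) * sd

    df = pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, spec.n_blocks + 1), spec.block_len),
            "trial": np.tile(np.arange(1, spec.block_len + 1), spec.n_blocks),
            "x": states[:, 0],
            "v": states[:, 1],
            "e": e,
        }
    )
    return TrialSeries(data=df, cfg=spec.cfg, condition="sim", provenance=f"simulated:seed={spec.seed}")


def stationary_covariance(B: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Steady-state covariance of u[k+1] = B u[k] + nu[k], Cov(nu) = noise_cov.

    Solves the discrete Lyapunov equation Sigma = B Sigma B^T + noise_cov.
    Projections onto the eigendirections reproduce the scalar steady-state
    variances sigma_n^2 / (1 - lambda^2).  Used as an independent oracle for
    the simulator in tests.
    """
    B = np.asarray(B, dtype=float)
    if np.max(np.abs(np.linalg.eigvals(B))) >= 1:
        raise ValueError("stationary_covariance: spectral radius >= 1, no stationary solution")
    return scipy.linalg.solve_discrete_lyapunov(B, np.asarray(noise_cov, dtype=float))


def simulate_experiment(base_spec: SimulationSpec, times=None) -> list[TrialSeries]:
    """Simulate the full 8-condition experiment.

    ``times`` are ideal-trial stop times (default: 8 uniformly spaced on
    [3, 5] s); each yields a friction coefficient, an on-GEM operating point at
    x* = 1, and one TrialSeries sharing the base spec's dynamics.  Passive
    sensitivity varies across conditions through mu.  Per-condition seeds are
    spawned deterministically from the base spec's seed.
    """
    if times is None:
        times = np.linspace(3.0, 5.0, 8)
    times = np.asarray(times, dtype=float)
    mus = friction_set(times, base_spec.cfg)
    seeds = np.random.SeedSequence(base_spec.seed).generate_state(len(mus)) % (2**31)
    out = []
    for i, (mu, sub_seed) in enumerate(zip(mus, seeds)):
        cfg = replace(base_spec.cfg, mu=float(mu))
        spec = replace(base_spec, cfg=cfg, op_point=None, seed=int(sub_seed))
        ts = simulate_series(spec)
        ts.condition = f"C{i+1}-t{times[i]:.2f}s"
        ts.data["condition"] = ts.condition
        out.append(ts)
    return out
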