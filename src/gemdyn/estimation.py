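"""Estimation of the linear inter-trial update map and its eigenstructure.

Fluctuations u[k] = x[k] - x* about the sample-mean operating point are paired
within blocks (dropping block-retraining trials and the spurious cross-block
transition), and the update matrix B of u[k+1] = B u[k] + nu[k] is estimated by
ordinary least squares.  The eigenanalysis labels the weakly and strongly
stable directions, measures their angles from the GEM tangent, and extracts
the residual noise scales in eigencoordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import TrialSeries
from .task import BodyState, GemFrame

__all__ = [
    "FluctuationSeries",
    "LinearModel",
    "operating_point",
    "fluctuations",
    "fit_update_matrix",
    "eigenanalysis",
    "to_eigencoordinates",
    "residual_noise",
    "steady_state_std",
    "fit_linear_model",
]

_EIG_TOL = 1e-9


class ComplexEigenvaluesError(ValueError):
    """The fitted update matrix has a complex-conjugate eigenvalue pair."""


class DegenerateEigenvaluesError(ValueError):
    """The fitted update matrix has (numerically) repeated eigenvalues."""


@dataclass
class FluctuationSeries:
    """Fluctuations about the operating point with valid regression pairs.

    ``u`` holds one 2-vector (p, q) = (x - x*, v - v*) per trial, in trial
    order; ``pair_index`` lists (k, k+1) index pairs valid for the one-step
    regression (never spanning a block boundary); ``block`` is the per-trial
    block label; ``concat_index`` selects the trials entering the DFA
    concatenation (first ``trim_head`` of each block removed, all remaining
    trials kept in order).
    """

    u: np.ndarray
    pair_index: np.ndarray
    block: np.ndarray
    concat_index: np.ndarray
    op_point: BodyState

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(current, next) fluctuation arrays, each (n_pairs, 2)."""
        k = self.pair_index
        return self.u[k[:, 0]], self.u[k[:, 1]]

    def concatenated(self) -> np.ndarray:
        """Fluctuation series under the DFA concatenation rule, (n, 2)."""
        return self.u[self.concat_index]


@dataclass
class LinearModel:
    """Fitted update matrix with labeled eigenstructure and noise scales.

    The *weak* eigenpair is the one with larger |lambda| (expected ~tangent to
    the GEM), the *strong* pair the smaller.  Eigenvector signs are normalized
    so that e_w . e_t >= 0 and e_s . e_n >= 0; theta_w is then a signed angle
    in (-90, 90] degrees and theta_s lies in [0, 180).  beta = sin(theta_s).
    sigma_nw, sigma_ns are RMS regression residuals in eigencoordinates.
    """

    B: np.ndarray
    lambda_w: float
    lambda_s: float
    e_w: np.ndarray
    e_s: np.ndarray
    theta_w_deg: float
    theta_s_deg: float
    beta: float
    sigma_nw: float = np.nan
    sigma_ns: float = np.nan
    residuals_eigen: np.ndarray | None = None

    @property
    def E(self) -> np.ndarray:
        """Eigenvector matrix with columns (e_w, e_s)."""
        return np.column_stack([self.e_w, self.e_s])

    def to_dict(self) -> dict:
        return {
            "B": self.B.tolist(),
            "lambda_w": self.lambda_w,
            "lambda_s": self.lambda_s,
            "theta_w_deg": self.theta_w_deg,
            "theta_s_deg": self.theta_s_deg,
            "beta": self.beta,
            "sigma_nw": self.sigma_nw,
            "sigma_ns": self.sigma_ns,
        }


def operating_point(series: TrialSeries) -> BodyState:
    """Sample-mean body state over all trials of the series."""
    if series.n_trials < 2:
        raise ValueError("operating_point: need at least 2 trials")
    x, v = series.states().mean(axis=0)
    return BodyState(x=float(x), v=float(v))


def fluctuations(
    series: TrialSeries,
    op_point: BodyState | None = None,
    trim_head: int = 4,
    use_first: int = 49,
) -> FluctuationSeries:
    """Extract fluctuations and the valid one-step regression pairs.

    Within each block, current states are trials ``trim_head + 1 .. use_first``
    (1-based) and successors the following trial; with the default 50-trial
    blocks this keeps trials 5-49 as current states, i.e. 45 pairs per block
    and 450 pairs for a 10-block series.  The first ``trim_head`` trials of
    each block are also dropped from the DFA concatenation (460 retained for
    full-length data).  Pairs never span block boundaries.
    """
    if op_point is None:
        op_point = operating_point(series)
    u = series.states() - op_point.as_array()
    block = series.block_index()

    pair_rows: list[tuple[int, int]] = []
    concat_rows: list[int] = []
    for b in series.blocks:
        idx = np.flatnonzero(block == b)
        n_b = len(idx)
        if n_b < trim_head + 2:
            raise ValueError(f"fluctuations: block {b} has {n_b} trials, needs >= {trim_head + 2}")
        last_current = min(use_first, n_b - 1)  # successor must exist
        for j in range(trim_head, last_current):
            pair_rows.append((idx[j], idx[j + 1]))
        concat_rows.extend(idx[trim_head:].tolist())

    return FluctuationSeries(
        u=u,
        pair_index=np.array(pair_rows, dtype=int),
        block=block,
        concat_index=np.array(concat_rows, dtype=int),
        op_point=op_point,
    )


def fit_update_matrix(pairs: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """OLS estimate of B minimizing the one-step mean-square prediction error.

    ``pairs`` is (current, next) with shapes (n, 2); the closed form is
    B = (sum u' u^T)(sum u u^T)^-1.  No intercept: fluctuations are defined
    about the sample mean.
    """
    X, Y = pairs
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) < 2:
        raise ValueError("fit_update_matrix: need at least 2 pairs")
    Sxx = X.T @ X
    if np.linalg.matrix_rank(Sxx) < 2 or np.linalg.cond(Sxx) > 1e12:
        raise np.linalg.LinAlgError("fit_update_matrix: current-state covariance is singular")
    return np.linalg.solve(Sxx, X.T @ Y).T


def eigenanalysis(B: np.ndarray, frame: GemFrame) -> LinearModel:
    """Labeled eigenstructure of B relative to the GEM frame.

    Requires real, distinct eigenvalues (the regime this analysis addresses);
    complex pairs raise :class:`ComplexEigenvaluesError` and repeated
    eigenvalues :class:`DegenerateEigenvaluesError`.
    """
    B = np.asarray(B, dtype=float)
    lam, vec = np.linalg.eig(B)
    scale = max(1.0, float(np.max(np.abs(lam))))
    if np.max(np.abs(lam.imag)) > _EIG_TOL * scale:
        raise ComplexEigenvaluesError(f"complex eigenvalues {lam}")
    lam = lam.real
    vec = vec.real
    if abs(lam[0] - lam[1]) <= _EIG_TOL:
        raise DegenerateEigenvaluesError(f"repeated eigenvalue {lam}")

    # weak = larger magnitude (ties broken toward larger algebraic value)
    mags = np.abs(lam)
    if mags[0] > mags[1] or (mags[0] == mags[1] and lam[0] > lam[1]):
        iw, is_ = 0, 1
    else:
        iw, is_ = 1, 0

    e_w = vec[:, iw] / np.linalg.norm(vec[:, iw])
    e_s = vec[:, is_] / np.linalg.norm(vec[:, is_])
    if e_w @ frame.e_t < 0:
        e_w = -e_w
    if e_s @ frame.e_n < 0:
        e_s = -e_s

    theta_w = np.degrees(np.arctan2(e_w @ frame.e_n, e_w @ frame.e_t))
    theta_s = np.degrees(np.arctan2(e_s @ frame.e_n, e_s @ frame.e_t)) % 180.0
    beta = float(np.sin(np.radians(theta_s)))

    return LinearModel(
        B=B,
        lambda_w=float(lam[iw]),
        lambda_s=float(lam[is_]),
        e_w=e_w,
        e_s=e_s,
        theta_w_deg=float(theta_w),
        theta_s_deg=float(theta_s),
        beta=beta,
    )


def to_eigencoordinates(u: np.ndarray, E: np.ndarray) -> np.ndarray:
    """z = E^-1 u for each row of u; inverse of u = E z."""
    u = np.asarray(u, dtype=float)
    return np.linalg.solve(E, u.T).T


def residual_noise(
    pairs: tuple[np.ndarray, np.ndarray], B: np.ndarray, E: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Regression residuals in eigencoordinates and their RMS scales.

    r[k] = E^-1 (u[k+1] - B u[k]); sigma_nw = RMS(r_w), sigma_ns = RMS(r_s).
    """
    X, Y = pairs
    r = to_eigencoordinates(np.asarray(Y) - np.asarray(X) @ np.asarray(B).T, E)
    sigma_nw = float(np.sqrt(np.mean(r[:, 0] ** 2)))
    sigma_ns = float(np.sqrt(np.mean(r[:, 1] ** 2)))
    return r, sigma_nw, sigma_ns


def steady_state_std(lam: float, sigma_n: float) -> float:
    """Stationary fluctuation scale sigma_n / sqrt(1 - lambda^2) of an AR(1) map."""
    if abs(lam) >= 1:
        raise ValueError(f"steady_state_std: |lambda| >= 1 (lambda={lam}), variance diverges")
    if sigma_n < 0:
        raise ValueError("steady_state_std: sigma_n must be >= 0")
    return sigma_n / np.sqrt(1.0 - lam * lam)


def fit_linear_model(flucts: FluctuationSeries, frame: GemFrame) -> LinearModel:
    """Convenience: OLS fit + eigenanalysis + residual noise in one call."""
    pairs = flucts.pairs()
    B = fit_update_matrix(pairs)
    model = eigenanalysis(B, frame)
    r, s_nw, s_ns = residual_noise(pairs, B, model.E)
    model.residuals_eigen = r
    model.sigma_nw = s_nw
    model.sigma_ns = s_ns
    return model
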