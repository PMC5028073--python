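"""Shuffleboard task geometry: goal function, GEM, and passive sensitivity.

The task is a one-dimensional shuffleboard game: a puck is released at
(dimensionless) position ``x`` with speed ``v`` and decelerates under Coulomb
friction ``mu`` until it stops.  The goal function

    f(x, v) = v**2 / mu + x - L_tilde

measures the (dimensionless) distance between the puck's stopping point and the
target at ``L_tilde = L/R``.  Its zero set is the *goal equivalent manifold*
(GEM), the parabola ``v**2 = mu * (L_tilde - x)`` of all perfectly executed
trials.  Everything in this module is a property of the task alone — it exists
before and independently of any inter-trial error correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "BodyState",
    "GemFrame",
    "goal_function",
    "nondimensionalize",
    "dimensionalize",
    "gem_speed",
    "gem_frame",
    "decompose_fluctuation",
    "friction_set",
]


@dataclass(frozen=True)
class TaskConfig:
    """Physical and dimensionless task parameters.

    Parameters
    ----------
    mu : float
        Coulomb (kinetic) friction coefficient between puck and board,
        dimensionless, > 0.
    L_cm : float
        Target distance in cm (default 200).
    R_cm : float
        Length scale used for nondimensionalization, cm (default 20).
    g : float
        Gravitational acceleration, cm/s^2 (default 981).
    """

    mu: float
    L_cm: float = 200.0
    R_cm: float = 20.0
    g: float = 981.0

    def __post_init__(self) -> None:
        for name in ("mu", "L_cm", "R_cm", "g"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"TaskConfig.{name} must be finite and > 0, got {val!r}")

    @property
    def L_tilde(self) -> float:
        """Dimensionless target distance L/R (10 for the default geometry)."""
        return self.L_cm / self.R_cm

    @property
    def v_scale(self) -> float:
        """Velocity scale sqrt(2 g R), cm/s."""
        return math.sqrt(2.0 * self.g * self.R_cm)


@dataclass(frozen=True)
class BodyState:
    """Release state (position, speed), dimensionless. Ordering is (x, v)."""

    x: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.v)):
            raise ValueError(f"BodyState must be finite, got ({self.x!r}, {self.v!r})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.v], dtype=float)


@dataclass(frozen=True)
class GemFrame:
    """Local GEM geometry at an operating point.

    Attributes
    ----------
    operating_point : BodyState
        The point (x*, v*) at which the goal-function Jacobian is evaluated.
    A : ndarray, shape (2,)
        Row of goal-function partial derivatives (df/dx, df/dv); maps
        body-level fluctuations u to goal-level error e = A @ u to first order.
    e_t, e_n : ndarray, shape (2,)
        Unit tangent and unit normal to the GEM at the operating point.
    s : float
        Passive sensitivity: the (single) singular value of A, >= 1.
    """

    operating_point: BodyState
    A: np.ndarray
    e_t: np.ndarray
    e_n: np.ndarray
    s: float

    def decompose(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Goal-relevant / goal-equivalent components, see decompose_fluctuation."""
        return decompose_fluctuation(u, self)


def goal_function(state, cfg: TaskConfig):
    """Dimensionless goal-level error of a release state.

    ``f(x, v) = v^2/mu + x - L_tilde``; zero exactly when the puck stops on the
    target, and equal to the stopping error in units of R otherwise.

    Accepts a :class:`BodyState` or array-likes ``(x, v)`` (broadcastable).
    """
    if isinstance(state, BodyState):
        x, v = state.x, state.v
    else:
        x, v = state
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise ValueError("goal_function: non-finite state")
    out = v * v / cfg.mu + x - cfg.L_tilde
    return float(out) if out.ndim == 0 else out


def nondimensionalize(x_cm, v_cm_s, e_cm, cfg: TaskConfig):
    """Rescale dimensional (cm, cm/s, cm) data to dimensionless units.

    x~ = x/R, v~ = v/sqrt(2 g R), e~ = e/R.
    """
    R = cfg.R_cm
    return (
        np.asarray(x_cm, dtype=float) / R,
        np.asarray(v_cm_s, dtype=float) / cfg.v_scale,
        np.asarray(e_cm, dtype=float) / R,
    )


def dimensionalize(x, v, e, cfg: TaskConfig):
    """Inverse of :func:`nondimensionalize`."""
    R = cfg.R_cm
    return (
        np.asarray(x, dtype=float) * R,
        np.asarray(v, dtype=float) * cfg.v_scale,
        np.asarray(e, dtype=float) * R,
    )


def gem_speed(x, cfg: TaskConfig):
    """On-GEM release speed at position x: v = sqrt(mu * (L_tilde - x)).

    Raises ``ValueError`` for x >= L_tilde (no real launch stops on the target
    from at or beyond it).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr > cfg.L_tilde):
        raise ValueError(f"gem_speed: x={x!r} is past the target (L_tilde={cfg.L_tilde})")
    out = np.sqrt(cfg.mu * (cfg.L_tilde - x_arr))
    return float(out) if out.ndim == 0 else out


def gem_frame(op_point: BodyState, cfg: TaskConfig) -> GemFrame:
    """Local GEM frame (A, tangent, normal, passive sensitivity) at a point.

    A = (1, 2 v*/mu); e_t spans its null space, e_n its row space, and the
    passive sensitivity s = |A| = sqrt(1 + (2 v*/mu)^2) is A's singular value.
    The operating point need not lie exactly on the GEM: A is evaluated at the
    given point regardless (tangent-to-error-contour and tangent-to-GEM frames
    coincide for this goal function).
    """
    vstar = op_point.v
    if vstar < 0:
        raise ValueError("gem_frame: operating-point speed must be >= 0")
    slope = 2.0 * vstar / cfg.mu  # df/dv at the operating point
    A = np.array([1.0, slope])
    s = math.hypot(1.0, slope)
    e_t = np.array([-slope, 1.0]) / s
    e_n = A / s
    return GemFrame(operating_point=op_point, A=A, e_t=e_t, e_n=e_n, s=s)


def decompose_fluctuation(u, frame: GemFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split fluctuations into goal-relevant and goal-equivalent components.

    ``u_R = u . e_n`` (normal to the GEM, produces goal error) and
    ``u_N = u . e_t`` (tangent, goal-equivalent).  ``u`` may be a single
    2-vector or an (n, 2) array.
    """
    u = np.asarray(u, dtype=float)
    u_R = u @ frame.e_n
    u_N = u @ frame.e_t
    return u_R, u_N


def friction_set(times, cfg: TaskConfig | None = None) -> np.ndarray:
    """Friction coefficients from ideal-trial stopping times.

    An ideal trial releases the puck at x = 0 (dimensional) with the speed that
    stops it exactly on the target; it then stops after t = sqrt(2L/(mu g)),
    so mu = 2L/(g t^2).  Longer stop time means lower friction.  The study
    protocol draws 8 times uniformly spaced on [3, 5] s; the 4 largest times
    (lowest mu) form the low-friction set, the 4 smallest the high-friction set.
    """
    if cfg is None:
        cfg = TaskConfig(mu=1.0)  # mu unused below; geometry defaults
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("friction_set: stop times must be positive and finite")
    return 2.0 * cfg.L_cm / (cfg.g * t * t)
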