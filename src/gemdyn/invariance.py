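"""Coordinate transformations of trial fluctuations and invariance checks.

Variance-based variability measures depend on the coordinates used to record
the task, but the stability properties of the inter-trial dynamics do not:
under a change of fluctuation coordinates u = T v the update matrix becomes
T^-1 B T, which has the same eigenvalues, and the GEM tangent maps to the
normalized T^-1-image of the original tangent, preserving the weak-tangent /
strong-transverse arrangement.  The PCA-whitening transform is the "worst
case" for variance-based inference: it makes the fluctuation cloud isotropic,
erasing the variance signature of the GEM while leaving the dynamics intact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .estimation import FluctuationSeries, eigenanalysis, fit_update_matrix
from .task import GemFrame

__all__ = [
    "CoordinateTransform",
    "transform_fluctuations",
    "transform_frame",
    "pca_whitening_transform",
    "invariance_check",
]


@dataclass(frozen=True)
class CoordinateTransform:
    """Fluctuation coordinate change u = T v (T: new -> old, nonsingular).

    For a differentiable nonlinear map, T is its Jacobian at the operating
    point; only the linearized action enters the analysis.
    """

    T: np.ndarray
    kind: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.shape != (2, 2):
            raise ValueError("CoordinateTransform: T must be 2x2")
        if not np.isfinite(np.linalg.cond(T)) or np.linalg.cond(T) > 1e12:
            raise ValueError("CoordinateTransform: T is singular or near-singular")
        object.__setattr__(self, "T", T)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.T))

    def to_dict(self) -> dict:
        return {
            "T": self.T.tolist(),
            "kind": self.kind,
            "description": self.description,
            "condition_number": self.condition_number,
        }


def transform_fluctuations(flucts: FluctuationSeries, transform: CoordinateTransform) -> FluctuationSeries:
    """Re-express fluctuations in new coordinates: v = T^-1 u (pairs preserved)."""
    Tinv = np.linalg.inv(transform.T)
    return dc_replace(flucts, u=flucts.u @ Tinv.T)


def transform_frame(frame: GemFrame, transform: CoordinateTransform) -> GemFrame:
    """GEM frame as seen in the new coordinates.

    The tangent direction maps as the normalized T^-1-image of the old
    tangent (directions transform contravariantly with the fluctuations); the
    normal is its orthogonal complement in the new coordinates.  A = A_old T
    maps new-coordinate fluctuations to goal error, and s is its norm.
    """
    Tinv = np.linalg.inv(transform.T)
    t_new = Tinv @ frame.e_t
    t_new = t_new / np.linalg.norm(t_new)
    A_new = frame.A @ transform.T
    s_new = float(np.linalg.norm(A_new))
    n_new = A_new / s_new
    return GemFrame(operating_point=frame.operating_point, A=A_new, e_t=t_new, e_n=n_new, s=s_new)


def pca_whitening_transform(flucts: FluctuationSeries) -> CoordinateTransform:
    """Transform whose new coordinates have identity sample covariance.

    Principal axes C (eigenvectors of the fluctuation covariance <u u^T>) and
    principal values d give new coordinates q = diag(1/sqrt(d)) C^T u, i.e.
    T = C diag(sqrt(d)) in the u = T q convention.  The new variance ellipse
    is a circle by construction.
    """
    u = flucts.u
    cov = (u - u.mean(axis=0)).T @ (u - u.mean(axis=0)) / len(u)
    d, C = np.linalg.eigh(cov)
    if np.min(d) <= 0 or np.max(d) / np.min(d) > 1e12:
        raise ValueError("pca_whitening_transform: rank-deficient fluctuation covariance")
    T = C @ np.diag(np.sqrt(d))
    return CoordinateTransform(T=T, kind="linear", description="PCA whitening (isotropic variance)")


def invariance_check(
    flucts: FluctuationSeries, frame: GemFrame, transform: CoordinateTransform
) -> dict:
    """Compare the fitted dynamics before and after a coordinate change.

    Fits the update matrix on the same deterministic pairs in both coordinate
    systems and reports the maximum eigenvalue discrepancy (similarity
    invariance predicts ~0), the GEM-relative angles in both frames (the
    weak-tangent / strong-transverse topology should survive), and the
    tangent/normal variance ratios (which need not survive — the whitening
    transform drives the ratio to ~1).
    """
    model = eigenanalysis(fit_update_matrix(flucts.pairs()), frame)
    flucts_t = transform_fluctuations(flucts, transform)
    frame_t = transform_frame(frame, transform)
    model_t = eigenanalysis(fit_update_matrix(flucts_t.pairs()), frame_t)

    def _var_ratio(fl, fr):
        u_N = fl.u @ fr.e_t
        u_R = fl.u @ fr.e_n
        return float(u_N.var(ddof=0) / u_R.var(ddof=0))

    lam_orig = sorted([model.lambda_w, model.lambda_s])
    lam_trans = sorted([model_t.lambda_w, model_t.lambda_s])
    return {
        "transform": transform.to_dict(),
        "max_eigenvalue_delta": float(max(abs(a - b) for a, b in zip(lam_orig, lam_trans))),
        "original": {
            "lambda_w": model.lambda_w,
            "lambda_s": model.lambda_s,
            "theta_w_deg": model.theta_w_deg,
            "theta_s_deg": model.theta_s_deg,
            "variance_ratio_tangent_normal": _var_ratio(flucts, frame),
        },
        "transformed": {
            "lambda_w": model_t.lambda_w,
            "lambda_s": model_t.lambda_s,
            "theta_w_deg": model_t.theta_w_deg,
            "theta_s_deg": model_t.theta_s_deg,
            "variance_ratio_tangent_normal": _var_ratio(flucts_t, frame_t),
        },
    }
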