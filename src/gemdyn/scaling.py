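"""Goal-level performance and the total body-goal sensitivity scaling law.

The theory predicts that RMS goal error scales with the strong-direction
intrinsic noise through the *total body-goal sensitivity*

    s_TOT = beta * s / sqrt(1 - lambda_s**2),

combining GEM geometry (beta = sin(theta_s)), passive sensitivity (s) and
active control strength (lambda_s).  Across conditions with different
friction, a linear fit sigma_e / sigma_ns = a * s_TOT + b is expected to give
a ~ 1, b ~ 0.  This module computes the per-condition quantities, the fit and
its bootstrap, and the structured H1-H4 hypothesis verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .estimation import FluctuationSeries, LinearModel
from .resampling import BootstrapDistribution, _resample_iterates
from .series import TrialSeries
from .task import GemFrame, decompose_fluctuation

__all__ = [
    "ScalingPoint",
    "ScalingFit",
    "s_total",
    "scaling_point",
    "fit_scaling",
    "bootstrap_scaling",
    "hypothesis_report",
    "DEFAULT_THRESHOLDS",
]


def s_total(beta: float, s: float, lambda_s: float) -> float:
    """Total body-goal sensitivity beta * s / sqrt(1 - lambda_s^2)."""
    if abs(lambda_s) >= 1:
        raise ValueError("s_total: |lambda_s| >= 1")
    return beta * s / np.sqrt(1.0 - lambda_s**2)


@dataclass
class ScalingPoint:
    """Per-condition performance quantities entering the scaling fit."""

    condition: str
    sigma_e: float
    sigma_R: float
    sigma_N: float
    sigma_ns: float
    s: float
    beta: float
    lambda_s: float
    mean_e: float  # skill diagnostic: 0 for performers perfect on average

    @property
    def s_tot(self) -> float:
        return s_total(self.beta, self.s, self.lambda_s)

    @property
    def ratio(self) -> float:
        if self.sigma_ns == 0:
            raise ZeroDivisionError("ScalingPoint: sigma_ns = 0, ratio undefined")
        return self.sigma_e / self.sigma_ns

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "sigma_e": self.sigma_e,
            "sigma_R": self.sigma_R,
            "sigma_N": self.sigma_N,
            "sigma_ns": self.sigma_ns,
            "s": self.s,
            "beta": self.beta,
            "lambda_s": self.lambda_s,
            "s_tot": self.s_tot,
            "ratio": self.ratio,
            "mean_e": self.mean_e,
        }


@dataclass
class ScalingFit:
    """Linear fit ratio = a * s_tot + b with optional bootstrap distributions."""

    a: float
    b: float
    r_squared: float
    points: list[ScalingPoint] = field(default_factory=list)
    dist_a: BootstrapDistribution | None = None
    dist_b: BootstrapDistribution | None = None

    def to_dict(self) -> dict:
        out = {"a": self.a, "b": self.b, "r_squared": self.r_squared}
        if self.dist_a is not None:
            out["a_ci"] = [self.dist_a.ci_low, self.dist_a.ci_high]
        if self.dist_b is not None:
            out["b_ci"] = [self.dist_b.ci_low, self.dist_b.ci_high]
        out["points"] = [p.to_dict() for p in self.points]
        return out


def scaling_point(series: TrialSeries, frame: GemFrame, model: LinearModel) -> ScalingPoint:
    """Performance quantities of one condition from its fitted model.

    sigma_e is the sample standard deviation of the goal error about its mean
    (the operating point is treated as on-GEM; the mean error is reported
    separately as a skill diagnostic); sigma_R/sigma_N are the stds of the
    goal-relevant/goal-equivalent fluctuation components.
    """
    if not np.isfinite(model.sigma_ns) or model.sigma_ns == 0:
        raise ZeroDivisionError("scaling_point: model has no residual noise scale")
    e = series.errors()
    u = series.states() - frame.operating_point.as_array()
    u_R, u_N = decompose_fluctuation(u, frame)
    return ScalingPoint(
        condition=series.condition,
        sigma_e=float(e.std(ddof=0)),
        sigma_R=float(u_R.std(ddof=0)),
        sigma_N=float(u_N.std(ddof=0)),
        sigma_ns=float(model.sigma_ns),
        s=float(frame.s),
        beta=float(model.beta),
        lambda_s=float(model.lambda_s),
        mean_e=float(e.mean()),
    )


def fit_scaling(points: list[ScalingPoint]) -> ScalingFit:
    """OLS fit of sigma_e/sigma_ns on s_tot across conditions."""
    if len(points) < 2:
        raise ValueError("fit_scaling: need at least 2 points")
    x = np.array([p.s_tot for p in points])
    y = np.array([p.ratio for p in points])
    if np.ptp(x) == 0:
        raise ValueError("fit_scaling: identical s_tot across points")
    res = scipy.stats.linregress(x, y)
    return ScalingFit(a=float(res.slope), b=float(res.intercept),
                      r_squared=float(res.rvalue**2), points=list(points))


def _condition_iterates(series, flucts, frame, n_iter, seed):
    """Per-iterate (ratio, s_tot) for one condition, with iterate ids.

    Each iterate resamples the condition's pairs (shared with the model
    bootstrap machinery) and recomputes sigma_e (std of goal error over the
    resampled current trials), sigma_ns, s (from the resampled mean release
    speed), beta and lambda_s.
    """
    per_iter, _ = _resample_iterates(flucts, frame, n_iter, seed)
    cur_rows = flucts.pair_index[:, 0]
    e_all = series.errors()[cur_rows]
    v_all = series.states()[cur_rows, 1]
    idx = per_iter["_idx"]

    e_b = e_all[idx]
    sigma_e = e_b.std(axis=1, ddof=0)
    v_star = v_all[idx].mean(axis=1)
    s = np.hypot(1.0, 2.0 * v_star / series.cfg.mu)
    s_tot = per_iter["beta"] * s / np.sqrt(1.0 - per_iter["lambda_s"] ** 2)
    ratio = sigma_e / per_iter["sigma_ns"]
    return ratio, s_tot, per_iter["_iter"]


def bootstrap_scaling(
    conditions: list[tuple[TrialSeries, FluctuationSeries, GemFrame]],
    n_iter: int = 10000,
    seed: int | None = None,
) -> ScalingFit:
    """Bootstrap the cross-condition scaling fit.

    Within each iterate, every condition's pairs are resampled and its
    (s_tot, sigma_e/sigma_ns) point recomputed; a line is fit across the
    conditions of that iterate.  Iterates where any condition had degenerate
    eigenvalues are dropped for all conditions to keep the fits aligned.
    The reported (a, b, r_squared) come from the single pooled fit over all
    iterate-points, which for this procedure agrees with the per-iterate mean.
    """
    if len(conditions) < 3:
        raise ValueError("bootstrap_scaling: need at least 3 conditions")
    seeds = np.random.SeedSequence(seed).generate_state(len(conditions)) % (2**31)
    ratios, stots, iters = [], [], []
    for (series, flucts, frame), s_c in zip(conditions, seeds):
        r, st, it = _condition_iterates(series, flucts, frame, n_iter, int(s_c))
        ratios.append(r)
        stots.append(st)
        iters.append(it)

    common = iters[0]
    for it in iters[1:]:
        common = np.intersect1d(common, it)
    X = np.empty((len(common), len(conditions)))
    Y = np.empty_like(X)
    for j, (r, st, it) in enumerate(zip(ratios, stots, iters)):
        pos = np.searchsorted(it, common)
        X[:, j] = st[pos]
        Y[:, j] = r[pos]

    xm = X.mean(axis=1, keepdims=True)
    ym = Y.mean(axis=1, keepdims=True)
    a_samp = np.sum((X - xm) * (Y - ym), axis=1) / np.sum((X - xm) ** 2, axis=1)
    b_samp = ym[:, 0] - a_samp * xm[:, 0]
    dist_a = BootstrapDistribution("a", a_samp, n_iter=n_iter, seed=seed)
    dist_b = BootstrapDistribution("b", b_samp, n_iter=n_iter, seed=seed)

    pooled = scipy.stats.linregress(X.ravel(), Y.ravel())
    return ScalingFit(
        a=float(pooled.slope),
        b=float(pooled.intercept),
        r_squared=float(pooled.rvalue**2),
        dist_a=dist_a,
        dist_b=dist_b,
    )


#: default hypothesis-test thresholds; deliberately loose relative to the
#: expected effect sizes, always reported alongside the raw values
DEFAULT_THRESHOLDS = {
    "theta_w_max_deg": 10.0,
    "lambda_s_max": 0.2,
    "angle_gap_min_deg": 15.0,
    "alpha_gap_min": 0.2,
    "alpha_s_target": 0.5,
}


def hypothesis_report(
    dists: dict[str, BootstrapDistribution],
    fit: ScalingFit | None = None,
    thresholds: dict | None = None,
) -> dict:
    """Structured verdicts for the four predictions of the fluctuation model.

    H1: weak control along the GEM — CI(lambda_w) inside (0, 1), weak
        eigenvector nearly tangent (|theta_w| small).
    H2: strong control transverse — |lambda_s| near 0, strong direction at a
        clearly larger angle than the weak one.
    H3: persistence consistent with stability — R_w(1) bounded away from 0,
        R_s(1) CI containing 0, alpha_s near 0.5, alpha_w clearly larger.
    H4: scaling — CI of the fitted slope a contains 1.

    Missing inputs are listed per hypothesis instead of raising.
    """
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    report: dict = {"thresholds": th}

    def get(name):
        return dists.get(name)

    def ci_contains(d, x):
        return d.ci_low <= x <= d.ci_high

    lw, ls = get("lambda_w"), get("lambda_s")
    tw, ts = get("theta_w_deg"), get("theta_s_deg")
    rw, rs = get("R_w1"), get("R_s1")
    aw, as_ = get("alpha_w"), get("alpha_s")

    missing = [n for n, d in [("lambda_w", lw), ("theta_w_deg", tw)] if d is None]
    if missing:
        report["H1"] = {"pass": None, "missing": missing}
    else:
        tmax = th["theta_w_max_deg"]
        report["H1"] = {
            "pass": bool(
                0 < lw.ci_low and lw.ci_high < 1
                and not (tw.ci_high < -tmax or tw.ci_low > tmax)
                and abs(tw.mean) < tmax
            ),
            "lambda_w": lw.to_dict(),
            "theta_w_deg": tw.to_dict(),
        }

    missing = [n for n, d in [("lambda_s", ls), ("theta_s_deg", ts), ("theta_w_deg", tw)] if d is None]
    if missing:
        report["H2"] = {"pass": None, "missing": missing}
    else:
        report["H2"] = {
            "pass": bool(
                abs(ls.mean) < th["lambda_s_max"]
                and ts.mean - abs(tw.mean) > th["angle_gap_min_deg"]
            ),
            "lambda_s": ls.to_dict(),
            "theta_s_deg": ts.to_dict(),
        }

    missing = [n for n, d in [("R_w1", rw), ("R_s1", rs), ("alpha_w", aw), ("alpha_s", as_)] if d is None]
    if missing:
        report["H3"] = {"pass": None, "missing": missing}
    else:
        report["H3"] = {
            "pass": bool(
                not ci_contains(rw, 0.0)
                and ci_contains(rs, 0.0)
                and ci_contains(as_, th["alpha_s_target"])
                and aw.mean - as_.mean > th["alpha_gap_min"]
            ),
            "R_w1": rw.to_dict(),
            "R_s1": rs.to_dict(),
            "alpha_w": aw.to_dict(),
            "alpha_s": as_.to_dict(),
        }

    if fit is None or fit.dist_a is None:
        report["H4"] = {"pass": None, "missing": ["scaling fit bootstrap"]}
    else:
        report["H4"] = {
            "pass": bool(ci_contains(fit.dist_a, 1.0)),
            "a": fit.dist_a.to_dict(),
            "b": fit.dist_b.to_dict() if fit.dist_b else None,
            "r_squared": fit.r_squared,
        }
    return report
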