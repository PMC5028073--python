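"""Bootstrap estimation of inter-trial dynamical quantities.

The resampling unit is the (current, next) state pair: each iterate draws the
full pair count with replacement, refits the update matrix by OLS, and
recomputes every downstream quantity (eigenvalues, GEM-relative angles, lag-1
autocorrelations, residual noise scales) from that iterate's fit.  For DFA,
each iterate's eigenvectors re-express the *entire* concatenated fluctuation
series in that iterate's eigencoordinates before the exponents are computed.
Percentile (2.5/97.5) intervals over iterates give the reported 95% CIs.

All per-iterate arithmetic is vectorized: the 2x2 OLS solve and eigenanalysis
are evaluated in closed form across the whole batch of iterates, which keeps
10000-iterate runs fast enough for the full 8-condition pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimation import FluctuationSeries
from .persistence import dfa_batch
from .task import GemFrame

__all__ = [
    "BootstrapDistribution",
    "bootstrap_model",
    "bootstrap_dfa",
    "pool",
    "MODEL_QUANTITIES",
]

logger = logging.getLogger(__name__)

#: quantities produced by bootstrap_model
MODEL_QUANTITIES = (
    "lambda_w", "lambda_s", "theta_w_deg", "theta_s_deg", "beta",
    "R_w1", "R_s1", "sigma_nw", "sigma_ns",
    "B11", "B12", "B21", "B22",
)

_EIG_TOL = 1e-9
_MAX_DROP_FRAC = 0.20
_CHUNK = 2000


class DegenerateBootstrapError(RuntimeError):
    """More than 20% of bootstrap iterates had complex/degenerate eigenvalues."""


@dataclass
class BootstrapDistribution:
    """Empirical bootstrap samples of one scalar quantity.

    ``ci_low``/``ci_high`` are the 2.5th and 97.5th percentiles (order
    statistics) of ``samples``; ``n_dropped`` counts iterates discarded for
    complex or repeated eigenvalues.
    """

    name: str
    samples: np.ndarray
    n_iter: int
    seed: int | None = None
    n_dropped: int = 0
    mean: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError(f"BootstrapDistribution {self.name!r}: no samples")
        self.mean = float(self.samples.mean())
        self.ci_low = float(np.percentile(self.samples, 2.5))
        self.ci_high = float(np.percentile(self.samples, 97.5))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mean": self.mean,
            "ci": [self.ci_low, self.ci_high],
            "n_iter": self.n_iter,
            "n_dropped": self.n_dropped,
        }


def _fit_B_batch(Xb: np.ndarray, Yb: np.ndarray) -> np.ndarray:
    """Closed-form OLS B per iterate: Xb, Yb are (m, n, 2); returns (m, 2, 2)."""
    Sxx = np.einsum("mni,mnj->mij", Xb, Xb, optimize=True)
    Sxy = np.einsum("mni,mnj->mij", Yb, Xb, optimize=True)
    # B Sxx = Sxy with Sxx symmetric: solve Sxx B^T = Sxy^T, transpose back
    Bt = np.linalg.solve(Sxx, np.transpose(Sxy, (0, 2, 1)))
    return np.transpose(Bt, (0, 2, 1))


def _eig2x2_batch(Bs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Real-distinct eigenanalysis of a batch of 2x2 matrices.

    Returns (lam, vecs, valid) where lam is (m, 2) sorted weak-first by
    |lambda|, vecs is (m, 2, 2) with unit eigenvector columns matching lam,
    and valid flags iterates with real, distinct eigenvalues.
    """
    a, b = Bs[:, 0, 0], Bs[:, 0, 1]
    c, d = Bs[:, 1, 0], Bs[:, 1, 1]
    tr = a + d
    det = a * d - b * c
    disc = tr * tr - 4 * det
    scale = np.maximum(1.0, np.abs(tr))
    valid = disc > (_EIG_TOL * scale) ** 2  # real AND distinct
    root = np.sqrt(np.where(valid, disc, 1.0))
    lam_p = (tr + root) / 2
    lam_m = (tr - root) / 2

    # weak = larger magnitude; ties broken toward larger algebraic value (lam_p)
    swap = np.abs(lam_m) > np.abs(lam_p)
    lam_w = np.where(swap, lam_m, lam_p)
    lam_s = np.where(swap, lam_p, lam_m)

    def _vec(lam):
        # eigenvector of [[a,b],[c,d]] for eigenvalue lam: (b, lam-a) or (lam-d, c)
        v1 = np.stack([b, lam - a], axis=1)
        v2 = np.stack([lam - d, c], axis=1)
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        v = np.where((n1 >= n2)[:, None], v1, v2)
        n = np.maximum(np.linalg.norm(v, axis=1), 1e-300)
        return v / n[:, None]

    vec_w = _vec(lam_w)
    vec_s = _vec(lam_s)
    lam = np.stack([lam_w, lam_s], axis=1)
    vecs = np.stack([vec_w, vec_s], axis=2)  # columns (e_w, e_s)
    return lam, vecs, valid


def _angles_from_vecs(vecs: np.ndarray, frame: GemFrame):
    """Sign-normalized eigenvectors and GEM-relative angles for a batch."""
    e_w = vecs[:, :, 0]
    e_s = vecs[:, :, 1]
    e_w = np.where((e_w @ frame.e_t >= 0)[:, None], e_w, -e_w)
    e_s = np.where((e_s @ frame.e_n >= 0)[:, None], e_s, -e_s)
    theta_w = np.degrees(np.arctan2(e_w @ frame.e_n, e_w @ frame.e_t))
    theta_s = np.degrees(np.arctan2(e_s @ frame.e_n, e_s @ frame.e_t)) % 180.0
    return e_w, e_s, theta_w, theta_s


def _inv2x2_batch(E: np.ndarray) -> np.ndarray:
    det = E[:, 0, 0] * E[:, 1, 1] - E[:, 0, 1] * E[:, 1, 0]
    inv = np.empty_like(E)
    inv[:, 0, 0] = E[:, 1, 1]
    inv[:, 0, 1] = -E[:, 0, 1]
    inv[:, 1, 0] = -E[:, 1, 0]
    inv[:, 1, 1] = E[:, 0, 0]
    return inv / det[:, None, None]


def _resample_iterates(flucts: FluctuationSeries, frame: GemFrame, n_iter: int, seed):
    """Core per-iterate quantities; yields a dict of (n_valid,) arrays.

    Also returns the per-iterate eigenvector matrices (for DFA reuse) and the
    number of dropped iterates.
    """
    X, Y = flucts.pairs()
    n = len(X)
    if n < 2:
        raise ValueError("bootstrap: need at least 2 valid pairs")
    rng = np.random.default_rng(seed)

    chunks: list[dict] = []
    n_dropped = 0
    for start in range(0, n_iter, _CHUNK):
        m = min(_CHUNK, n_iter - start)
        idx = rng.integers(0, n, size=(m, n))
        Xb = X[idx]
        Yb = Y[idx]
        Bs = _fit_B_batch(Xb, Yb)
        lam, vecs, valid = _eig2x2_batch(Bs)
        n_dropped += int(m - valid.sum())

        Bs, lam, vecs = Bs[valid], lam[valid], vecs[valid]
        Xb, Yb, idx_v = Xb[valid], Yb[valid], idx[valid]
        e_w, e_s, theta_w, theta_s = _angles_from_vecs(vecs, frame)
        E = np.stack([e_w, e_s], axis=2)
        Einv = _inv2x2_batch(E)

        # eigencoordinate series on the resampled pairs
        z_cur = np.einsum("mij,mnj->mni", Einv, Xb, optimize=True)
        z_next = np.einsum("mij,mnj->mni", Einv, Yb, optimize=True)
        zc = z_cur - z_cur.mean(axis=1, keepdims=True)
        zn = z_next - z_cur.mean(axis=1, keepdims=True)
        denom = np.sum(zc * zc, axis=1)
        R1 = np.sum(zn * zc, axis=1) / denom

        resid = Yb - np.einsum("mij,mnj->mni", Bs, Xb, optimize=True)
        r = np.einsum("mij,mnj->mni", Einv, resid, optimize=True)
        sigma = np.sqrt(np.mean(r * r, axis=1))

        chunks.append(
            {
                "lambda_w": lam[:, 0],
                "lambda_s": lam[:, 1],
                "theta_w_deg": theta_w,
                "theta_s_deg": theta_s,
                "beta": np.sin(np.radians(theta_s)),
                "R_w1": R1[:, 0],
                "R_s1": R1[:, 1],
                "sigma_nw": sigma[:, 0],
                "sigma_ns": sigma[:, 1],
                "B11": Bs[:, 0, 0],
                "B12": Bs[:, 0, 1],
                "B21": Bs[:, 1, 0],
                "B22": Bs[:, 1, 1],
                "_E": E,
                "_idx": idx_v,
                "_iter": np.flatnonzero(valid) + start,
            }
        )

    if n_dropped > _MAX_DROP_FRAC * n_iter:
        raise DegenerateBootstrapError(
            f"{n_dropped}/{n_iter} bootstrap iterates had complex/degenerate eigenvalues"
        )
    if n_dropped:
        logger.info("bootstrap: dropped %d/%d degenerate iterates", n_dropped, n_iter)
    out = {k: np.concatenate([ch[k] for ch in chunks]) for k in chunks[0]}
    return out, n_dropped


def bootstrap_model(
    flucts: FluctuationSeries,
    frame: GemFrame,
    n_iter: int = 10000,
    seed: int | None = None,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap distributions of the fitted model's scalar quantities.

    Returns one :class:`BootstrapDistribution` per quantity in
    :data:`MODEL_QUANTITIES`.  Deterministic under a fixed seed.
    """
    per_iter, n_dropped = _resample_iterates(flucts, frame, n_iter, seed)
    return {
        name: BootstrapDistribution(
            name=name, samples=per_iter[name], n_iter=n_iter, seed=seed, n_dropped=n_dropped
        )
        for name in MODEL_QUANTITIES
    }


def bootstrap_dfa(
    flucts: FluctuationSeries,
    frame: GemFrame,
    n_iter: int = 10000,
    seed: int | None = None,
    box_sizes=None,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap distributions of the DFA exponents alpha_w, alpha_s.

    Each iterate resamples pairs and refits the eigenvectors, then transforms
    the entire concatenated (unresampled) fluctuation series into that
    iterate's eigencoordinates and runs DFA per direction: the resampling
    feeds only the eigenbasis, never the temporal ordering DFA relies on.
    """
    u_concat = flucts.concatenated()
    if len(u_concat) < 100:
        raise ValueError("bootstrap_dfa: concatenated series shorter than 100 trials")
    per_iter, n_dropped = _resample_iterates(flucts, frame, n_iter, seed)
    E = per_iter["_E"]
    Einv = _inv2x2_batch(E)
    alphas = {"alpha_w": [], "alpha_s": []}
    for start in range(0, len(E), _CHUNK):
        z = np.einsum("mij,nj->mni", Einv[start : start + _CHUNK], u_concat, optimize=True)
        alphas["alpha_w"].append(dfa_batch(z[:, :, 0], box_sizes))
        alphas["alpha_s"].append(dfa_batch(z[:, :, 1], box_sizes))
    return {
        name: BootstrapDistribution(
            name=name,
            samples=np.concatenate(vals),
            n_iter=n_iter,
            seed=seed,
            n_dropped=n_dropped,
        )
        for name, vals in alphas.items()
    }


def pool(distributions: list[BootstrapDistribution], name: str | None = None) -> BootstrapDistribution:
    """Aggregate across conditions by concatenating raw bootstrap samples.

    The pooled mean and percentile CI reproduce the aggregate-over-conditions
    summaries (wide CIs where conditions disagree).
    """
    if not distributions:
        raise ValueError("pool: empty input")
    samples = np.concatenate([d.samples for d in distributions])
    return BootstrapDistribution(
        name=name or distributions[0].name,
        samples=samples,
        n_iter=sum(d.n_iter for d in distributions),
        seed=distributions[0].seed,
        n_dropped=sum(d.n_dropped for d in distributions),
    )
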