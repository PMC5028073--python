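"""Statistical persistence of eigencoordinate fluctuation series.

Two complementary measures: the normalized lag-1 autocorrelation R(1), which
for the diagonalized AR(1)-like inter-trial dynamics equals the eigenvalue of
the corresponding direction, and the exponent alpha of linearly detrended
fluctuation analysis (DFA), used here as a lag-independent overall persistence
measure (0.5 = uncorrelated, > 0.5 persistent, < 0.5 antipersistent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "PersistenceSummary",
    "lag1_autocorrelation",
    "default_box_sizes",
    "dfa",
    "dfa_batch",
    "persistence_summary",
]


@dataclass
class PersistenceSummary:
    """Per-direction persistence measures of an eigencoordinate series."""

    R_w1: float
    R_s1: float
    alpha_w: float
    alpha_s: float
    dfa_profile_w: np.ndarray  # (n_boxes, 2) columns (box size, F(n))
    dfa_profile_s: np.ndarray

    def to_dict(self) -> dict:
        return {
            "R_w1": self.R_w1,
            "R_s1": self.R_s1,
            "alpha_w": self.alpha_w,
            "alpha_s": self.alpha_s,
        }


def lag1_autocorrelation(series, block=None) -> float:
    """Normalized lag-1 autocorrelation R(1) = <z[k+1] z[k]> / <z[k]^2>.

    The series is mean-removed first; the denominator runs over the same
    current-state sample as the numerator (so an alternating series gives
    exactly -1, and for AR(1) data R(1) coincides with the autoregression OLS
    slope).  If ``block`` labels are given, lag-1 products never span a block
    boundary, mirroring the regression-pair convention.
    """
    z = np.asarray(series, dtype=float)
    if z.size < 3:
        raise ValueError("lag1_autocorrelation: need at least 3 samples")
    z = z - z.mean()
    if block is None:
        cur, nxt = z[:-1], z[1:]
    else:
        block = np.asarray(block)
        same = block[1:] == block[:-1]
        cur, nxt = z[:-1][same], z[1:][same]
    denom = np.sum(cur * cur)
    if denom == 0:
        raise ValueError("lag1_autocorrelation: zero variance")
    return float(np.sum(nxt * cur) / denom)


def default_box_sizes(n: int, n_sizes: int = 12, min_box: int = 4) -> np.ndarray:
    """~12 log-spaced integer box sizes in [min_box, n // 4], deduplicated."""
    max_box = n // 4
    if max_box < min_box:
        raise ValueError(f"default_box_sizes: series of length {n} too short")
    sizes = np.unique(
        np.round(np.geomspace(min_box, max_box, n_sizes)).astype(int)
    )
    return sizes


def _dfa_fluctuations(profiles: np.ndarray, box_sizes: np.ndarray) -> np.ndarray:
    """F(n) for each integrated profile row; profiles is (m, N)."""
    m, N = profiles.shape
    F = np.empty((m, len(box_sizes)))
    for j, n in enumerate(box_sizes):
        nbox = N // n
        seg = profiles[:, : nbox * n].reshape(m, nbox, n)
        # linear detrend within each box via the least-squares projection
        t = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), t])
        coeff = np.linalg.solve(X.T @ X, X.T)  # (2, n)
        resid = seg - np.einsum("mbn,kn,jk->mbj", seg, coeff, X, optimize=True)
        F[:, j] = np.sqrt(np.mean(resid**2, axis=(1, 2)))
    return F


def dfa(series, box_sizes=None) -> tuple[float, np.ndarray]:
    """Linearly detrended fluctuation analysis of a scalar series.

    Integrates the mean-removed series, partitions the profile into
    non-overlapping boxes of each size (tail remainder discarded), removes the
    least-squares line within each box, and takes F(n) as the RMS residual
    over all boxes.  alpha is the least-squares slope of log10 F vs log10 n.

    Returns ``(alpha, profile)`` where profile is an (n_boxes, 2) array of
    (box size, F(n)).
    """
    z = np.asarray(series, dtype=float)
    if box_sizes is None:
        box_sizes = default_box_sizes(len(z))
    box_sizes = np.asarray(box_sizes, dtype=int)
    if np.any(box_sizes < 4):
        raise ValueError("dfa: boxes must contain at least 4 samples")
    if len(z) < 4 * box_sizes.min():
        raise ValueError("dfa: series too short for the requested boxes")
    profile = np.cumsum(z - z.mean())[None, :]
    F = _dfa_fluctuations(profile, box_sizes)[0]
    if np.any(F <= 0):
        raise ValueError("dfa: degenerate series (zero fluctuation at some box size)")
    fit = scipy.stats.linregress(np.log10(box_sizes), np.log10(F))
    return float(fit.slope), np.column_stack([box_sizes, F])


def dfa_batch(series_batch: np.ndarray, box_sizes=None) -> np.ndarray:
    """DFA exponents for each row of an (m, N) batch (shared box sizes).

    Same algorithm as :func:`dfa`, vectorized across rows; used by the
    bootstrap where the same 460-trial series is re-expressed in many
    eigenbases.
    """
    zb = np.atleast_2d(np.asarray(series_batch, dtype=float))
    if box_sizes is None:
        box_sizes = default_box_sizes(zb.shape[1])
    box_sizes = np.asarray(box_sizes, dtype=int)
    profiles = np.cumsum(zb - zb.mean(axis=1, keepdims=True), axis=1)
    F = _dfa_fluctuations(profiles, box_sizes)
    logn = np.log10(box_sizes)
    logn = logn - logn.mean()
    logF = np.log10(F)
    return (logF @ logn) / (logn @ logn)


def persistence_summary(z_pairs, z_concat, block_concat=None, box_sizes=None) -> PersistenceSummary:
    """Persistence measures of a fitted model's eigencoordinate series.

    ``z_pairs`` is ((z_current, z_next)) on the regression-pair convention,
    each (n, 2); R(1) per direction is the pair-product ratio.  ``z_concat``
    is the (m, 2) eigencoordinate series under the concatenation rule (first
    four trials of each block removed; 460 trials for full-length data), on
    which DFA is run per direction.
    """
    zc, zn = z_pairs
    out = {}
    for i, d in enumerate("ws"):
        cur = zc[:, i] - zc[:, i].mean()
        nxt = zn[:, i] - zc[:, i].mean()
        out[f"R_{d}1"] = float(np.sum(nxt * cur) / np.sum(cur * cur))
    alpha_w, prof_w = dfa(z_concat[:, 0], box_sizes)
    alpha_s, prof_s = dfa(z_concat[:, 1], box_sizes)
    return PersistenceSummary(
        R_w1=out["R_w1"],
        R_s1=out["R_s1"],
        alpha_w=alpha_w,
        alpha_s=alpha_s,
        dfa_profile_w=prof_w,
        dfa_profile_s=prof_s,
    )
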