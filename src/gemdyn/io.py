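"""Readers and writers: trial CSVs, task configs, and the analysis report.

The interchange format is a plain CSV (UTF-8, header row, '.' decimal) with
columns ``participant, condition, block, trial, x, v, e`` in dimensionless
units, or ``x_cm, v_cm_s, e_cm`` in dimensional units (auto-rescaled through
the task config).  Deposited per-block data laid out differently should be
mapped onto this schema before analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import TrialSeries
from .task import TaskConfig, goal_function, nondimensionalize

__all__ = ["read_config", "write_config", "read_trials", "write_trials", "write_report"]

logger = logging.getLogger(__name__)

_DIMLESS = ["x", "v", "e"]
_DIMENSIONAL = ["x_cm", "v_cm_s", "e_cm"]


def read_config(path) -> TaskConfig:
    """Task config from YAML or JSON with keys mu, L_cm, R_cm, g_cm_s2."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a JSON superset
    try:
        return TaskConfig(
            mu=float(raw["mu"]),
            L_cm=float(raw.get("L_cm", 200.0)),
            R_cm=float(raw.get("R_cm", 20.0)),
            g=float(raw.get("g_cm_s2", 981.0)),
        )
    except KeyError as exc:
        raise ValueError(f"config {path}: missing key {exc}") from exc


def write_config(cfg: TaskConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {"mu": cfg.mu, "L_cm": cfg.L_cm, "R_cm": cfg.R_cm, "g_cm_s2": cfg.g},
            sort_keys=True,
        )
    )


def read_trials(path, cfg: TaskConfig, e_tol: float = 1e-6) -> TrialSeries:
    """Parse a trial CSV into a TrialSeries, validating the block structure.

    Dimensional columns are nondimensionalized through ``cfg``.  The goal
    error is recomputed from (x, v); rows disagreeing by more than ``e_tol``
    (dimensionless) are kept but logged.  Blocks of unequal length are kept
    with a warning (partial blocks occur in real data).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"block", "trial"} - cols:
        raise ValueError(f"{path}: missing columns {sorted({'block', 'trial'} - cols)}")
    if set(_DIMLESS) <= cols:
        x, v, e = (df[c] for c in _DIMLESS)
    elif set(_DIMENSIONAL) <= cols:
        x, v, e = nondimensionalize(df["x_cm"], df["v_cm_s"], df["e_cm"], cfg)
    else:
        raise ValueError(f"{path}: need columns {_DIMLESS} or {_DIMENSIONAL}")

    data = pd.DataFrame(
        {
            "block": pd.to_numeric(df["block"], errors="raise").astype(int),
            "trial": pd.to_numeric(df["trial"], errors="raise").astype(int),
            "x": pd.to_numeric(x, errors="raise").astype(float),
            "v": pd.to_numeric(v, errors="raise").astype(float),
            "e": pd.to_numeric(e, errors="raise").astype(float),
        }
    )
    bad = ~np.isfinite(data[["x", "v", "e"]]).all(axis=1)
    if bad.any():
        raise ValueError(f"{path}: non-finite values at rows {np.flatnonzero(bad).tolist()[:10]}")

    condition = str(df["condition"].iloc[0]) if "condition" in cols else path.stem
    lengths = data.groupby("block").size()
    if lengths.nunique() > 1:
        logger.warning(
            "%s (condition %s): unequal block lengths %s; partial blocks retained",
            path, condition, lengths.to_dict(),
        )

    e_check = goal_function((data["x"].to_numpy(), data["v"].to_numpy()), cfg)
    mism = np.abs(e_check - data["e"].to_numpy()) > e_tol
    if mism.any():
        logger.warning(
            "%s (condition %s): %d rows where e disagrees with goal_function(x, v) "
            "by > %g (max %.3g); stored e kept",
            path, condition, int(mism.sum()), e_tol, float(np.abs(e_check - data["e"]).max()),
        )

    data = data.sort_values(["block", "trial"], kind="stable")
    return TrialSeries(data=data, cfg=cfg, condition=condition, provenance=f"file:{path.name}")


def write_trials(series: TrialSeries, path) -> None:
    """Write a TrialSeries to the interchange CSV (round-trips with read_trials)."""
    df = series.data.copy()
    df.to_csv(path, index=False, float_format="%.12g")


def write_report(report: dict, path) -> None:
    """Serialize the analysis report as JSON with stable key ordering."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
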