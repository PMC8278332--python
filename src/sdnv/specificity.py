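"""Control analyses: what the SDNV pipeline should NOT predict, plus motion checks.

These analyses deliberately reuse the identical prediction engine
(`sdnv.prediction.loo_predict`) with substituted inputs, so a discrepancy
between the main result and a control can only come from the inputs:

* neural variability alone (no self-construal interaction) as the feature;
* the moderator alone, as a plain correlation with the outcome;
* alternative outcomes (first/second life-satisfaction assessment, place of
  origin, ethnic identity) in place of the change score;
* head-motion summaries (per-parameter maxima, their maxima/sums, and mean
  framewise displacement) screened against the outcome.

Framewise displacement follows the Power convention: the sum of absolute
frame-to-frame translation changes plus the absolute rotation changes
converted to arc length on a 50 mm sphere; rotations are read in degrees by
default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import PredictionResult, loo_predict
from .scales import zscore

MOTION_LIMIT_MM = 3.0
MOTION_LIMIT_DEG = 3.0
DEFAULT_FD_RADIUS_MM = 50.0

MOTION_SUMMARY_NAMES = [
    "max_abs_trans_x", "max_abs_trans_y", "max_abs_trans_z",
    "max_abs_rot_x", "max_abs_rot_y", "max_abs_rot_z",
    "max_all", "max_translation", "max_rotation",
    "sum_all", "sum_translation", "sum_rotation",
]


@dataclass
class MotionTrace:
    """Realignment parameters: volumes x 6 (3 translations mm, 3 rotations deg)."""

    params: np.ndarray
    participant_id: str = ""
    rotation_unit: str = "degrees"

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must have 6 columns (3 translations, 3 rotations)")
        if self.rotation_unit not in ("degrees", "radians"):
            raise ValueError("rotation_unit must be 'degrees' or 'radians'")


def nv_only_prediction(nv: np.ndarray, y, alpha: float = 0.05, **loo_kwargs) -> PredictionResult:
    """Run the leave-one-out analysis with z-scored NV columns instead of SDNV.

    Shares every stage (selection, strengths, models, skip rule) with the
    main analysis; only the feature matrix differs.
    """
    nv = np.asarray(nv, dtype=float)
    cols = []
    for k in range(nv.shape[1]):
        col = nv[:, k]
        cols.append(np.zeros(nv.shape[0]) if np.all(col == col[0]) else zscore(col))
    return loo_predict(np.column_stack(cols), y, alpha=alpha, **loo_kwargs)


def alternative_outcomes(sdnv, outcomes: dict[str, np.ndarray],
                         alpha: float = 0.05, **loo_kwargs) -> dict[str, PredictionResult]:
    """Rerun the prediction with each substituted outcome (e.g. ls_t1, origin)."""
    results = {}
    for name, y in outcomes.items():
        y = np.asarray(y, dtype=float)
        if np.unique(y[~np.isnan(y)]).size < 2:
            raise ValueError(f"outcome {name!r} is constant")
        results[name] = loo_predict(sdnv, y, alpha=alpha, **loo_kwargs)
    return results


def moderator_correlation(interdependence, y) -> tuple[float, float]:
    """Plain Pearson correlation (two-sided p) of the moderator with the outcome."""
    inter = np.asarray(interdependence, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(inter).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(inter, y)
    return float(r), float(p)


def motion_summaries(trace: MotionTrace) -> dict[str, float]:
    """Twelve per-participant motion scalars plus the exclusion flag.

    The six per-parameter maximum absolute values; the maximum over all six,
    over the three translations and over the three rotations; and the sum of
    all six maxima, of the translation maxima and of the rotation maxima.
    Units preserved (mm / degrees).  ``exceeds_limit`` flags any parameter
    beyond 3.0 mm or 3.0 degrees.
    """
    per_param = np.abs(trace.params).max(axis=0)
    trans, rot = per_param[:3], per_param[3:]
    out = dict(zip(MOTION_SUMMARY_NAMES,
                   [*per_param,
                    per_param.max(), trans.max(), rot.max(),
                    per_param.sum(), trans.sum(), rot.sum()]))
    out = {k: float(v) for k, v in out.items()}
    out["exceeds_limit"] = bool((trans > MOTION_LIMIT_MM).any() or (rot > MOTION_LIMIT_DEG).any())
    return out


def framewise_displacement(trace: MotionTrace,
                           radius_mm: float = DEFAULT_FD_RADIUS_MM) -> tuple[np.ndarray, float]:
    """Power-style FD per volume and its mean.

    FD_t = sum |delta translation| + radius * sum |delta rotation in radians|,
    with FD_1 = 0.  Invariant to constant offsets in any parameter column.
    """
    if trace.params.shape[0] < 2:
        raise ValueError("at least 2 volumes are required for framewise displacement")
    params = trace.params.copy()
    if trace.rotation_unit == "degrees":
        params[:, 3:] = np.deg2rad(params[:, 3:])
    deltas = np.abs(np.diff(params, axis=0))
    fd = np.zeros(trace.params.shape[0])
    fd[1:] = deltas[:, :3].sum(axis=1) + radius_mm * deltas[:, 3:].sum(axis=1)
    return fd, float(fd.mean())


def motion_outcome_screen(traces: list[MotionTrace], y,
                          radius_mm: float = DEFAULT_FD_RADIUS_MM) -> pd.DataFrame:
    """Correlate each motion scalar (12 summaries + mean FD) with the outcome.

    Two-sided Pearson p per variable, no multiplicity correction — this is a
    screen whose desired result is uniform non-significance.
    """
    if len(traces) == 0:
        raise ValueError("empty motion block: nothing to screen")
    y = np.asarray(y, dtype=float)
    if len(traces) != y.shape[0]:
        raise ValueError("one motion trace per outcome value is required")
    rows = []
    for trace in traces:
        s = motion_summaries(trace)
        _, mean_fd = framewise_displacement(trace, radius_mm=radius_mm)
        rows.append([s[name] for name in MOTION_SUMMARY_NAMES] + [mean_fd])
    mat = np.asarray(rows)
    records = []
    for j, name in enumerate(MOTION_SUMMARY_NAMES + ["mean_fd"]):
        col = mat[:, j]
        if np.unique(col).size < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(col, y)
        records.append({"variable": name, "r": r, "p": p,
                        "significant": bool(p < 0.05) if np.isfinite(p) else False})
    return pd.DataFrame(records)
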