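"""Questionnaire scoring: self-construal, life satisfaction, and z-normalization.

The two instruments handled here are the Self-Construal Scale (SCS; 12
interdependent + 12 independent items, 7-point Likert) and the Satisfaction
with Life Scale (SWLS; 5 items, 7-point Likert, administered twice).  The
moderator of the whole pipeline is the interdependence difference score
(mean interdependent minus mean independent item rating) and the outcome is
the life-satisfaction change score (second-assessment SWLS minus first).

SWLS is aggregated as the item *sum* (conventional 5-35 range).  Downstream
features are z-scored or enter correlations, so sum-vs-mean scoring does not
change any predictive statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCS_ITEMS_PER_SUBSCALE = 12
SWLS_ITEMS = 5
LIKERT_MIN, LIKERT_MAX = 1, 7

#: Behavioral CSV column names (one row per participant; missing cells empty).
SCS_INTER_COLS = [f"scs_inter_{i:02d}" for i in range(1, SCS_ITEMS_PER_SUBSCALE + 1)]
SCS_INDEP_COLS = [f"scs_indep_{i:02d}" for i in range(1, SCS_ITEMS_PER_SUBSCALE + 1)]
SWLS_T1_COLS = [f"swls_t1_{i}" for i in range(1, SWLS_ITEMS + 1)]
SWLS_T2_COLS = [f"swls_t2_{i}" for i in range(1, SWLS_ITEMS + 1)]


def _check_items(items: np.ndarray, n_expected: int, label: str, allow_missing: bool = False) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    if items.shape[-1] != n_expected:
        raise ValueError(f"{label}: expected {n_expected} items, got {items.shape[-1]}")
    missing = np.isnan(items)
    if missing.any() and not allow_missing:
        idx = int(np.argwhere(missing)[0][-1])
        raise ValueError(f"{label}: item {idx + 1} is missing")
    valid = items[~missing]
    bad = (valid < LIKERT_MIN) | (valid > LIKERT_MAX) | (valid != np.round(valid))
    if bad.any():
        flat_ok = ~np.isnan(items) & ((items < LIKERT_MIN) | (items > LIKERT_MAX) | (items != np.round(items)))
        idx = int(np.argwhere(flat_ok)[0][-1])
        raise ValueError(
            f"{label}: item {idx + 1} out of range (must be an integer in "
            f"[{LIKERT_MIN}, {LIKERT_MAX}], got {items[..., idx] if items.ndim == 1 else 'invalid'})"
        )
    return items


def score_scs(interdependent_items, independent_items) -> float | np.ndarray:
    """Interdependence difference score: mean(interdependent) - mean(independent).

    Positive values mean the self is construed through relationships and
    social contexts; the score lives in [-6, 6].  Accepts a single
    participant (length-12 vectors) or a batch (n x 12 arrays).
    """
    inter = _check_items(np.asarray(interdependent_items, dtype=float),
                         SCS_ITEMS_PER_SUBSCALE, "interdependent subscale")
    indep = _check_items(np.asarray(independent_items, dtype=float),
                         SCS_ITEMS_PER_SUBSCALE, "independent subscale")
    score = inter.mean(axis=-1) - indep.mean(axis=-1)
    return float(score) if np.ndim(score) == 0 else score


def score_swls(items) -> float | np.ndarray:
    """SWLS total: sum of the 5 items (range 5-35); any missing item -> NaN."""
    items = _check_items(np.asarray(items, dtype=float), SWLS_ITEMS, "SWLS", allow_missing=True)
    missing = np.isnan(items).any(axis=-1)
    total = items.sum(axis=-1)
    total = np.where(missing, np.nan, total)
    return float(total) if np.ndim(total) == 0 else total


def score_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Add scored columns (interdependence, ls_t1, ls_t2) to a raw item table."""
    out = table.copy()
    out["interdependence"] = score_scs(out[SCS_INTER_COLS].to_numpy(),
                                       out[SCS_INDEP_COLS].to_numpy())
    out["ls_t1"] = score_swls(out[SWLS_T1_COLS].to_numpy())
    out["ls_t2"] = score_swls(out[SWLS_T2_COLS].to_numpy())
    return out


def change_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Attach ls_change = ls_t2 - ls_t1 and an outcome-exclusion flag.

    Participants with a missing second assessment keep their row (the cohort
    record is never shrunk) but are flagged ``excluded_from_outcome`` so
    prediction analyses can drop them listwise.  Idempotent.
    """
    out = table.copy()
    if "ls_t1" not in out.columns or "ls_t2" not in out.columns:
        out = score_behavior(out)
    out["ls_change"] = out["ls_t2"] - out["ls_t1"]
    out["excluded_from_outcome"] = out["ls_change"].isna()
    return out


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd, n-1 divisor); NaNs propagate.

    The n-1 divisor matches common statistical software.  It rescales SDNV
    values but leaves every correlation-based statistic unchanged.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if mask.sum() < 2:
        raise ValueError("zscore needs at least 2 non-missing values")
    sd = np.std(x[mask], ddof=ddof)
    if sd == 0:
        raise ValueError("zscore undefined for a constant vector")
    out = np.full_like(x, np.nan)
    out[mask] = (x[mask] - x[mask].mean()) / sd
    return out
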