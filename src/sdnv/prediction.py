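"""SDNV features and the cross-validated predictive-modeling machinery.

The predictive feature is self-dependent neural variability (SDNV): per
participant and node, the product of the z-scored neural variability of the
node and the z-scored interdependence score — an interaction term encoding
"variable brain AND interdependent self" (or "stable brain AND independent
self") as a single signed quantity.

The modeling procedure is connectome-style leave-one-out cross-validation
with univariate feature selection:

1. feature selection — on the training participants, correlate each node's
   SDNV with the outcome; nodes with two-sided p < alpha join the positive
   or negative feature set according to the sign of r;
2. strength calculation — average SDNV over the selected nodes
   (sign-flipped for negative features) into positive / negative / total
   feature strengths;
3. model establishment — simple linear regression of the outcome on each
   strength (total, positive, negative models);
4. prediction — apply the fitted model to the held-out participant;
5. evaluation — predictive power is the Pearson correlation between the
   cross-validated predictions and the observed outcomes; success requires
   it to be significantly positive.

If any iteration yields an empty feature set for a model, that model is
skipped entirely so every reported model rests on the same number of
iterations.  Nodes selected in strictly more than 95% of iterations are
"important nodes".  Permutation tests, within-network restriction with
Benjamini-Hochberg correction, leave-two-out pairwise accuracy, a partial
mode that adjusts for neural variability and interdependence, and
simple-slopes moderation analysis complete the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .scales import zscore

MODEL_KINDS = ("total", "positive", "negative")

__all__ = [
    "MODEL_KINDS",
    "SDNVMatrix",
    "FeatureSelectionRecord",
    "ModelResult",
    "PredictionResult",
    "PermutationResult",
    "LeaveTwoOutResult",
    "SimpleEffectsResult",
    "compute_sdnv",
    "pearson_columns",
    "feature_select",
    "compute_strengths",
    "loo_predict",
    "permutation_test",
    "network_predict",
    "leave_two_out",
    "simple_effects",
]


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

@dataclass
class SDNVMatrix:
    """Participants x nodes SDNV values plus provenance and unusable-node flags."""

    values: np.ndarray
    unusable: np.ndarray  # boolean per node: constant NV column, never selectable
    provenance: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def compute_sdnv(nv: np.ndarray, interdependence: np.ndarray,
                 provenance: dict | None = None) -> SDNVMatrix:
    """SDNV per node: z(NV column) * z(interdependence), elementwise over participants.

    A participant exactly at the cohort mean of interdependence has an
    all-zero SDNV row.  Constant NV columns cannot be z-scored; they are
    flagged unusable (NaN values) rather than failing the whole cohort.
    """
    nv = np.asarray(nv, dtype=float)
    inter = np.asarray(interdependence, dtype=float)
    if nv.ndim != 2:
        raise ValueError("nv must be participants x nodes")
    if nv.shape[0] != inter.shape[0]:
        raise ValueError("nv and interdependence disagree on the number of participants")
    if np.unique(inter).size < 2:
        raise ValueError("interdependence is constant: the moderator is degenerate")
    z_inter = zscore(inter)
    values = np.full_like(nv, np.nan)
    unusable = np.zeros(nv.shape[1], dtype=bool)
    for k in range(nv.shape[1]):
        col = nv[:, k]
        if np.all(col == col[0]):
            unusable[k] = True
            continue
        values[:, k] = zscore(col) * z_inter
    return SDNVMatrix(values=values, unusable=unusable, provenance=provenance or {})


# ---------------------------------------------------------------------------
# selection and strengths
# ---------------------------------------------------------------------------

def pearson_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of every column of X against y (vectorized).

    Zero-variance columns get r = NaN, p = 1 so they are never selected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    bad = ~np.isfinite(r)
    r[bad] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, np.where(np.isnan(r), 1.0, 0.0))
    return r, p


@dataclass
class FeatureSelectionRecord:
    """One iteration's training-set selection: signed sets and per-node stats."""

    iteration: int
    positive_set: np.ndarray
    negative_set: np.ndarray
    r: np.ndarray
    p: np.ndarray
    excluded: np.ndarray  # nodes barred from candidacy (zero variance / unusable)


def feature_select(sdnv_train: np.ndarray, y_train: np.ndarray, alpha: float,
                   iteration: int = 0,
                   unusable: np.ndarray | None = None) -> FeatureSelectionRecord:
    """Univariate selection: two-sided p < alpha, sign of r assigns the set."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    r, p = pearson_columns(sdnv_train, y_train)
    barred = np.isnan(r)
    if unusable is not None:
        barred = barred | unusable
    sig = (p < alpha) & ~barred
    positive = np.flatnonzero(sig & (r > 0))
    negative = np.flatnonzero(sig & (r < 0))
    return FeatureSelectionRecord(iteration=iteration, positive_set=positive,
                                  negative_set=negative, r=r, p=p,
                                  excluded=np.flatnonzero(barred))


def compute_strengths(sdnv_rows: np.ndarray, record: FeatureSelectionRecord,
                      total_rule: str = "pooled") -> dict[str, np.ndarray | None]:
    """Per-participant feature strengths from one iteration's selection.

    positive = mean SDNV over the positive set; negative = mean of -SDNV over
    the negative set; total = mean of sign-weighted SDNV over the union
    (``pooled``) or the average of the two set strengths (``averaged``).
    An empty required set yields None (undefined), which feeds the skip rule;
    under ``pooled`` the total is defined whenever the union is nonempty,
    under ``averaged`` it needs both sets.
    """
    if total_rule not in ("pooled", "averaged"):
        raise ValueError("total_rule must be 'pooled' or 'averaged'")
    rows = np.atleast_2d(np.asarray(sdnv_rows, dtype=float))
    pos, neg = record.positive_set, record.negative_set
    positive = rows[:, pos].mean(axis=1) if pos.size else None
    negative = -rows[:, neg].mean(axis=1) if neg.size else None
    if total_rule == "pooled":
        if pos.size + neg.size:
            signed = np.concatenate([rows[:, pos], -rows[:, neg]], axis=1)
            total = signed.mean(axis=1)
        else:
            total = None
    else:
        total = (positive + negative) / 2.0 if (positive is not None and negative is not None) else None
    return {"total": total, "positive": positive, "negative": negative}


# ---------------------------------------------------------------------------
# leave-one-out engine
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    kind: str
    skipped: bool
    reason: str = ""
    predicted: np.ndarray | None = None
    r: float | None = None
    p: float | None = None
    significant: bool = False


@dataclass
class PredictionResult:
    models: dict[str, ModelResult]
    selection_records: list[FeatureSelectionRecord]
    important_nodes: dict[str, np.ndarray]
    selection_fraction: dict[str, np.ndarray]
    observed: np.ndarray
    config: dict

    @property
    def n_iterations(self) -> int:
        return len(self.selection_records)


def _fit_simple(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    vx = np.var(x)
    if vx == 0:
        raise FloatingPointError("constant strength in the training set")
    slope = np.cov(x, y, bias=True)[0, 1] / vx
    return slope, float(y.mean() - slope * x.mean())


def _partial_select(sdnv_train, nv_train, inter_train, y_train, alpha, iteration, unusable):
    """Selection on the SDNV coefficient of y ~ SDNV_k + NV_k + interdependence.

    Batched normal-equation solve over nodes; two-sided t test on the SDNV
    coefficient, sign of the coefficient assigns the set.
    """
    n, p_nodes = sdnv_train.shape
    ones = np.ones(n)
    coefs = np.full(p_nodes, np.nan)
    pvals = np.ones(p_nodes)
    barred = np.zeros(p_nodes, dtype=bool)
    if unusable is not None:
        barred |= unusable
    for k in range(p_nodes):
        if barred[k] or np.var(sdnv_train[:, k]) == 0:
            barred[k] = True
            continue
        X = np.column_stack([ones, sdnv_train[:, k], nv_train[:, k], inter_train])
        beta, res, rank, _ = np.linalg.lstsq(X, y_train, rcond=None)
        if rank < X.shape[1]:
            barred[k] = True
            continue
        resid = y_train - X @ beta
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[1, 1])
        tval = beta[1] / se if se > 0 else np.nan
        coefs[k] = beta[1]
        pvals[k] = 2.0 * stats.t.sf(abs(tval), df=dof) if np.isfinite(tval) else 1.0
    sig = (pvals < alpha) & ~barred & np.isfinite(coefs)
    positive = np.flatnonzero(sig & (coefs > 0))
    negative = np.flatnonzero(sig & (coefs < 0))
    return FeatureSelectionRecord(iteration=iteration, positive_set=positive,
                                  negative_set=negative, r=coefs, p=pvals,
                                  excluded=np.flatnonzero(barred))


def _loo_simple_engine(F: np.ndarray, y: np.ndarray, alpha: float, total_rule: str):
    """All-iterations leave-one-out selection + strengths + fits, vectorized.

    Uses sufficient-statistic downdates: the training-set Pearson r of every
    node in every iteration comes from full-sample sums minus the held-out
    row, and the per-iteration simple regressions are solved the same way.
    Numerically identical (to ~1e-12) to calling `feature_select` and
    `_fit_simple` per iteration; asserted against that path in the tests.
    Returns (pos_mask, neg_mask, r, pval, predictions, empty, failed).
    """
    n, p = F.shape
    n1 = n - 1
    sx = F.sum(axis=0)[None, :] - F                     # (n, p) train sums
    sxx = (F * F).sum(axis=0)[None, :] - F * F
    sy = y.sum() - y                                    # (n,)
    syy = (y * y).sum() - y * y
    sxy = (F.T @ y)[None, :] - F * y[:, None]
    cov = n1 * sxy - sx * sy[:, None]
    varx = n1 * sxx - sx ** 2
    vary = (n1 * syy - sy ** 2)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(varx * vary)
    r = np.clip(r, -1.0, 1.0)
    usable = np.isfinite(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n1 - 2) / (1.0 - r ** 2))
    pval = np.where(usable, 2.0 * stats.t.sf(np.abs(t), df=n1 - 2), 1.0)
    pval = np.where(usable & ~np.isfinite(t), 0.0, pval)

    sig = (pval < alpha) & usable
    pos = sig & (r > 0)
    neg = sig & (r < 0)
    pos_n = pos.sum(axis=1)
    neg_n = neg.sum(axis=1)

    # strength of participant j under iteration i's selection: S[j, i]
    M = pos.astype(float) - neg.astype(float)           # (n iterations, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        strengths = {
            "positive": (F @ pos.T.astype(float)) / pos_n,
            "negative": -(F @ neg.T.astype(float)) / neg_n,
        }
        if total_rule == "pooled":
            strengths["total"] = (F @ M.T) / (pos_n + neg_n)
        else:
            strengths["total"] = (strengths["positive"] + strengths["negative"]) / 2.0
    empty = {"positive": pos_n == 0, "negative": neg_n == 0}
    empty["total"] = (pos_n + neg_n == 0) if total_rule == "pooled" \
        else (empty["positive"] | empty["negative"])

    predictions: dict[str, np.ndarray] = {}
    failed: dict[str, bool] = {}
    idx = np.arange(n)
    for kind in MODEL_KINDS:
        S = strengths[kind]
        if empty[kind].any():
            predictions[kind] = np.full(n, np.nan)
            failed[kind] = False
            continue
        diag = S[idx, idx]
        a = S.sum(axis=0) - diag                        # train sums per iteration
        axx = (S * S).sum(axis=0) - diag ** 2
        axy = S.T @ y - diag * y
        var_s = n1 * axx - a ** 2
        if np.any(np.isclose(var_s, 0.0, atol=1e-14 * max(1.0, np.abs(axx).max()))):
            predictions[kind] = np.full(n, np.nan)
            failed[kind] = True
            continue
        slope = (n1 * axy - a * sy) / var_s
        intercept = (sy - slope * a) / n1
        predictions[kind] = slope * diag + intercept
        failed[kind] = False
    return pos, neg, r, pval, predictions, empty, failed


def _predictive_power(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    if np.var(pred) == 0:
        raise FloatingPointError("constant predictions: predictive power undefined")
    r, p = stats.pearsonr(pred, obs)
    return float(r), float(p)


def loo_predict(sdnv: SDNVMatrix | np.ndarray, y: np.ndarray, alpha: float = 0.05,
                mode: str = "simple", nv: np.ndarray | None = None,
                interdependence: np.ndarray | None = None,
                total_rule: str = "pooled",
                important_threshold: float = 0.95,
                power_alpha: float = 0.05) -> PredictionResult:
    """Leave-one-out cross-validated prediction with per-iteration feature selection.

    ``mode='simple'`` selects by Pearson correlation and fits y ~ strength;
    ``mode='partial'`` selects on the SDNV coefficient of a per-node multiple
    regression (SDNV + NV + interdependence) and fits
    y ~ strength + NV strength + interdependence, where the NV strength is
    built from the same selected features with the same sign-weighted
    averaging.  A model with any empty-selection iteration is skipped; nodes
    selected in strictly more than ``important_threshold`` of the iterations
    are returned as important nodes per sign.
    """
    if isinstance(sdnv, SDNVMatrix):
        features, unusable = sdnv.values, sdnv.unusable
    else:
        features = np.asarray(sdnv, dtype=float)
        unusable = None
    y = np.asarray(y, dtype=float)
    n, p_nodes = features.shape
    if n < 10:
        raise ValueError("at least 10 participants are required")
    if np.isnan(y).any():
        raise ValueError("y contains missing values; exclude flagged participants first")
    if np.unique(y).size < 2:
        raise ValueError("y is constant")
    if mode not in ("simple", "partial"):
        raise ValueError("mode must be 'simple' or 'partial'")
    if mode == "partial" and (nv is None or interdependence is None):
        raise ValueError("partial mode requires nv and interdependence")
    usable_features = features.copy()
    if unusable is not None and unusable.any():
        usable_features[:, unusable] = 0.0  # flagged columns never selectable

    records: list[FeatureSelectionRecord] = []
    if mode == "simple":
        pos_m, neg_m, r_mat, p_mat, predictions, empty_m, failed_m = \
            _loo_simple_engine(usable_features, y, alpha, total_rule)
        for i in range(n):
            barred = ~np.isfinite(r_mat[i])
            if unusable is not None:
                barred |= unusable
            records.append(FeatureSelectionRecord(
                iteration=i, positive_set=np.flatnonzero(pos_m[i]),
                negative_set=np.flatnonzero(neg_m[i]), r=r_mat[i], p=p_mat[i],
                excluded=np.flatnonzero(barred)))
        empty = {k: bool(empty_m[k].any()) for k in MODEL_KINDS}
        failed = {k: "constant strength in the training set" if failed_m[k] else ""
                  for k in MODEL_KINDS}
    else:
        predictions = {k: np.full(n, np.nan) for k in MODEL_KINDS}
        empty = {k: False for k in MODEL_KINDS}
        failed = {k: "" for k in MODEL_KINDS}
        z_nv = np.column_stack([
            np.zeros(n) if np.all(nv[:, k] == nv[0, k]) else zscore(nv[:, k])
            for k in range(p_nodes)
        ])
        inter = np.asarray(interdependence, dtype=float)
        for i in range(n):
            train = np.ones(n, dtype=bool)
            train[i] = False
            rec = _partial_select(usable_features[train], z_nv[train], inter[train],
                                  y[train], alpha, i, unusable)
            records.append(rec)
            s_train = compute_strengths(usable_features[train], rec, total_rule)
            s_test = compute_strengths(usable_features[i:i + 1], rec, total_rule)
            nv_train = compute_strengths(z_nv[train], rec, total_rule)
            nv_test = compute_strengths(z_nv[i:i + 1], rec, total_rule)
            for kind in MODEL_KINDS:
                if s_train[kind] is None:
                    empty[kind] = True
                    continue
                if empty[kind] or failed[kind]:
                    continue
                try:
                    X = np.column_stack([np.ones(train.sum()), s_train[kind],
                                         nv_train[kind], inter[train]])
                    beta, *_ = np.linalg.lstsq(X, y[train], rcond=None)
                    x_test = np.array([1.0, s_test[kind][0], nv_test[kind][0], inter[i]])
                    predictions[kind][i] = x_test @ beta
                except FloatingPointError as exc:
                    failed[kind] = str(exc)

    models: dict[str, ModelResult] = {}
    for kind in MODEL_KINDS:
        if empty[kind]:
            models[kind] = ModelResult(kind=kind, skipped=True,
                                       reason="no feature selected in at least one iteration")
        elif failed[kind]:
            models[kind] = ModelResult(kind=kind, skipped=True, reason=failed[kind])
        else:
            pred = predictions[kind]
            try:
                r, p = _predictive_power(pred, y)
            except FloatingPointError as exc:
                models[kind] = ModelResult(kind=kind, skipped=True, reason=str(exc))
                continue
            models[kind] = ModelResult(kind=kind, skipped=False, predicted=pred,
                                       r=r, p=p,
                                       significant=bool(r > 0 and p < power_alpha))

    pos_counts = np.zeros(p_nodes)
    neg_counts = np.zeros(p_nodes)
    for rec in records:
        pos_counts[rec.positive_set] += 1
        neg_counts[rec.negative_set] += 1
    frac = {"positive": pos_counts / n, "negative": neg_counts / n}
    important = {sign: np.flatnonzero(frac[sign] > important_threshold) for sign in frac}

    return PredictionResult(models=models, selection_records=records,
                            important_nodes=important, selection_fraction=frac,
                            observed=y,
                            config={"alpha": alpha, "mode": mode,
                                    "total_rule": total_rule,
                                    "important_threshold": important_threshold,
                                    "n_iterations": n})


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: PredictionResult
    null_r: dict[str, np.ndarray]          # valid-permutation predictive powers
    n_skipped: dict[str, int]              # permutations hitting the empty-feature rule
    p_values: dict[str, float | None]
    n_perm: int


def permutation_test(sdnv, y, alpha: float = 0.05, n_perm: int = 1000,
                     seed: int | np.random.Generator = 0, mode: str = "simple",
                     **loo_kwargs) -> PermutationResult:
    """Shuffle the outcome, rerun the full leave-one-out analysis, tabulate null powers.

    p = (1 + #{null r >= observed r}) / (1 + #valid permutations), one-sided,
    since only positive predictive power counts as success.  Permutations in
    which a model hits the empty-feature skip rule are excluded from that
    model's valid count and reported separately.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    observed = loo_predict(sdnv, y, alpha=alpha, mode=mode, **loo_kwargs)
    null_r: dict[str, list[float]] = {k: [] for k in MODEL_KINDS}
    n_skipped = {k: 0 for k in MODEL_KINDS}
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        res = loo_predict(sdnv, y_perm, alpha=alpha, mode=mode, **loo_kwargs)
        for kind in MODEL_KINDS:
            m = res.models[kind]
            if m.skipped:
                n_skipped[kind] += 1
            else:
                null_r[kind].append(m.r)
    p_values: dict[str, float | None] = {}
    null_arrays = {}
    for kind in MODEL_KINDS:
        arr = np.asarray(null_r[kind])
        null_arrays[kind] = arr
        obs = observed.models[kind]
        if obs.skipped or arr.size == 0:
            p_values[kind] = None
        else:
            p_values[kind] = float((1 + (arr >= obs.r).sum()) / (1 + arr.size))
    return PermutationResult(observed=observed, null_r=null_arrays,
                             n_skipped=n_skipped, p_values=p_values, n_perm=n_perm)


# ---------------------------------------------------------------------------
# network-restricted prediction
# ---------------------------------------------------------------------------

def network_predict(sdnv: SDNVMatrix | np.ndarray, y, alpha: float,
                    networks, exclude: tuple[str, ...] = ("uncertain",),
                    small_networks: str = "error",
                    **loo_kwargs) -> tuple[dict[str, PredictionResult], pd.DataFrame]:
    """Run the leave-one-out analysis within each network's node subset.

    Networks in ``exclude`` (default the "uncertain" label) are not tested.
    Benjamini-Hochberg FDR adjustment is applied across the tested networks
    separately within each model family (total / positive / negative);
    networks whose model is skipped carry no p-value and are left out of that
    family's adjustment.  A network needs at least 2 nodes: by default one
    with fewer is an error; ``small_networks='skip'`` drops it instead.
    """
    from statsmodels.stats.multitest import multipletests

    if isinstance(sdnv, SDNVMatrix):
        values, unusable = sdnv.values, sdnv.unusable
    else:
        values = np.asarray(sdnv, dtype=float)
        unusable = np.zeros(values.shape[1], dtype=bool)
    networks = np.asarray(networks)
    if networks.shape[0] != values.shape[1]:
        raise ValueError("one network label per node is required")
    results: dict[str, PredictionResult] = {}
    rows = []
    for name in pd.unique(networks):
        if str(name).lower() in {e.lower() for e in exclude}:
            continue
        idx = np.flatnonzero(networks == name)
        if idx.size < 2:
            if small_networks == "skip":
                continue
            raise ValueError(f"network {name!r} has {idx.size} node(s); at least 2 are required")
        sub = SDNVMatrix(values=values[:, idx], unusable=unusable[idx],
                         provenance={"network": str(name), "nodes": idx})
        res = loo_predict(sub, y, alpha=alpha, **loo_kwargs)
        results[str(name)] = res
        for kind in MODEL_KINDS:
            m = res.models[kind]
            rows.append({"network": str(name), "model": kind, "skipped": m.skipped,
                         "r": m.r, "p": m.p})
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    table["significant_fdr"] = False
    for kind in MODEL_KINDS:
        sel = (table["model"] == kind) & (~table["skipped"]) & table["p"].notna()
        if sel.sum() == 0:
            continue
        rej, p_adj, *_ = multipletests(table.loc[sel, "p"].to_numpy(), method="fdr_bh")
        table.loc[sel, "p_fdr"] = p_adj
        r_pos = table.loc[sel, "r"].to_numpy() > 0
        table.loc[sel, "significant_fdr"] = rej & r_pos
    return results, table


# ---------------------------------------------------------------------------
# leave-two-out accuracy
# ---------------------------------------------------------------------------

@dataclass
class LeaveTwoOutResult:
    accuracy: dict[str, float | None]
    n_pairs: int
    n_excluded_ties: int
    binomial_p: dict[str, float | None]
    skipped: dict[str, bool]


def leave_two_out(sdnv, y, alpha: float = 0.05, mode: str = "simple",
                  total_rule: str = "pooled") -> LeaveTwoOutResult:
    """Pairwise held-out ordering accuracy against a Binomial(n_pairs, 1/2) null.

    Every unordered participant pair with distinct outcomes is held out once;
    an iteration scores 1 when the predicted ordering matches the observed
    ordering (tied predictions score 0).  Mean accuracy is the predictive
    power; the one-sided binomial test asks whether it beats coin flipping.
    """
    if isinstance(sdnv, SDNVMatrix):
        features, unusable = sdnv.values, sdnv.unusable
    else:
        features = np.asarray(sdnv, dtype=float)
        unusable = None
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if np.unique(y).size < 2:
        raise ValueError("all outcomes are tied: no usable pairs")
    usable = features.copy()
    if unusable is not None and unusable.any():
        usable[:, unusable] = 0.0

    hits = {k: 0 for k in MODEL_KINDS}
    empty = {k: False for k in MODEL_KINDS}
    n_pairs = 0
    n_ties = 0
    for a, b in combinations(range(n), 2):
        if y[a] == y[b]:
            n_ties += 1
            continue
        n_pairs += 1
        train = np.ones(n, dtype=bool)
        train[[a, b]] = False
        rec = feature_select(usable[train], y[train], alpha, unusable=unusable)
        s_train = compute_strengths(usable[train], rec, total_rule)
        s_test = compute_strengths(usable[[a, b]], rec, total_rule)
        for kind in MODEL_KINDS:
            if s_train[kind] is None:
                empty[kind] = True
                continue
            if empty[kind]:
                continue
            try:
                slope, intercept = _fit_simple(s_train[kind], y[train])
            except FloatingPointError:
                empty[kind] = True
                continue
            pa, pb = slope * s_test[kind] + intercept
            if pa != pb and np.sign(pa - pb) == np.sign(y[a] - y[b]):
                hits[kind] += 1
    accuracy: dict[str, float | None] = {}
    binom: dict[str, float | None] = {}
    for kind in MODEL_KINDS:
        if empty[kind]:
            accuracy[kind] = None
            binom[kind] = None
        else:
            accuracy[kind] = hits[kind] / n_pairs
            binom[kind] = float(stats.binomtest(hits[kind], n_pairs, 0.5,
                                                alternative="greater").pvalue)
    return LeaveTwoOutResult(accuracy=accuracy, n_pairs=n_pairs,
                             n_excluded_ties=n_ties, binomial_p=binom,
                             skipped=empty)


# ---------------------------------------------------------------------------
# simple slopes (moderation)
# ---------------------------------------------------------------------------

@dataclass
class SimpleEffectsResult:
    """Conditional NV slopes at moderator = mean +/- SD, raw and standardized."""

    slopes: dict[str, dict[str, float]]          # 'high'/'low' -> b, se, p, ci_low, ci_high
    moderator_values: dict[str, float]           # evaluated interdependence levels
    coefficients: dict[str, float]               # raw-model b0..b3
    standardized: dict[str, dict[str, float]]    # same slopes with z-scored predictors


def simple_effects(nv_strength, interdependence, y,
                   max_condition_number: float = 1e8) -> SimpleEffectsResult:
    """Moderation analysis: y ~ NV strength * interdependence, slopes at M +/- SD.

    Fits y = b0 + b1*NVs + b2*Int + b3*NVs*Int by OLS; the conditional NV
    slope at moderator level m is b1 + b3*m with delta-method standard error
    sqrt(V11 + m^2 V33 + 2 m V13) and a normal-theory 95% CI.  Reported at
    m = mean(Int) + SD ("high", interdependent individuals) and
    m = mean(Int) - SD ("low", independent individuals), in both the raw and
    the z-scored-predictor parameterization.
    """
    import statsmodels.api as sm

    nvs = np.asarray(nv_strength, dtype=float)
    inter = np.asarray(interdependence, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, v in [("nv_strength", nvs), ("interdependence", inter), ("y", y)]:
        if np.isnan(v).any():
            raise ValueError(f"{name} contains missing values")
        if np.unique(v).size < 2:
            raise ValueError(f"{name} is constant")

    def _fit(xs, ms):
        X = sm.add_constant(np.column_stack([xs, ms, xs * ms]))
        cond = np.linalg.cond(X)
        if cond > max_condition_number:
            raise ValueError(f"collinear moderation design (condition number {cond:.3g})")
        fit = sm.OLS(y, X).fit()
        beta, cov = fit.params, fit.cov_params()
        out = {}
        for label, m in [("high", ms.mean() + ms.std(ddof=1)),
                         ("low", ms.mean() - ms.std(ddof=1))]:
            b = beta[1] + beta[3] * m
            se = float(np.sqrt(cov[1, 1] + m ** 2 * cov[3, 3] + 2 * m * cov[1, 3]))
            zval = b / se
            out[label] = {"b": float(b), "se": se,
                          "p": float(2 * stats.norm.sf(abs(zval))),
                          "ci_low": float(b - 1.959963984540054 * se),
                          "ci_high": float(b + 1.959963984540054 * se),
                          "moderator": float(m)}
        return beta, out

    beta_raw, slopes_raw = _fit(nvs, inter)
    _, slopes_std = _fit(zscore(nvs), zscore(inter))
    return SimpleEffectsResult(
        slopes=slopes_raw,
        moderator_values={k: v["moderator"] for k, v in slopes_raw.items()},
        coefficients={f"b{i}": float(beta_raw[i]) for i in range(4)},
        standardized=slopes_std,
    )
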