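import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sdnv import (compute_sdnv, compute_strengths, feature_select, leave_two_out,
                  loo_predict, network_predict, permutation_test, simple_effects,
                  zscore)
from sdnv.prediction import FeatureSelectionRecord, pearson_columns


def planted_features(n=58, p=40, n_signal=5, r_target=0.6, seed=0):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, p))
    y = F[:, :n_signal].mean(axis=1)
    y = r_target * zscore(y) + np.sqrt(1 - r_target ** 2) * rng.standard_normal(n)
    return F, y


# ---------------------------------------------------------------------------
# SDNV construction
# ---------------------------------------------------------------------------

def test_sdnv_rejects_constant_moderator():
    nv = np.random.default_rng(0).uniform(0, 1, (20, 5))
    with pytest.raises(ValueError, match="degenerate"):
        compute_sdnv(nv, np.full(20, 1.5))


def test_sdnv_row_zero_at_moderator_mean():
    rng = np.random.default_rng(1)
    nv = rng.uniform(0, 1, (11, 6))
    spread = rng.normal(size=5)
    # participant 0 sits exactly at the cohort mean of the moderator
    inter = np.concatenate([[0.0], spread, -spread])
    sdnv = compute_sdnv(nv, inter)
    assert np.allclose(sdnv.values[0], 0.0, atol=1e-12)


def test_sdnv_invariant_to_affine_nv_rescaling():
    rng = np.random.default_rng(2)
    nv = rng.uniform(0, 1, (25, 4))
    inter = rng.normal(size=25)
    base = compute_sdnv(nv, inter).values
    scaled = nv.copy()
    scaled[:, 2] = 3.3 * scaled[:, 2] + 0.7
    assert np.allclose(compute_sdnv(scaled, inter).values, base, atol=1e-10)


def test_sdnv_flags_constant_nv_column_unusable():
    rng = np.random.default_rng(3)
    nv = rng.uniform(0, 1, (20, 4))
    nv[:, 1] = 0.4
    sdnv = compute_sdnv(nv, rng.normal(size=20))
    assert sdnv.unusable[1] and not sdnv.unusable[[0, 2, 3]].any()
    res = loo_predict(sdnv, rng.normal(size=20), alpha=0.5)
    for rec in res.selection_records:
        assert 1 not in rec.positive_set and 1 not in rec.negative_set


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_perfect_feature_lands_in_positive_set():
    rng = np.random.default_rng(4)
    F = rng.standard_normal((30, 6))
    y = F[:, 3].copy()
    rec = feature_select(F, y, alpha=0.05)
    assert 3 in rec.positive_set
    assert rec.r[3] == pytest.approx(1.0)


def test_null_selection_count_matches_alpha():
    # pure-noise features: on average ~alpha * p nodes pass the two-sided
    # screen (13.2 of 264 at alpha=0.05); tabulated over 200 replicates
    rng = np.random.default_rng(5)
    counts = []
    for _ in range(200):
        F = rng.standard_normal((58, 264))
        y = rng.standard_normal(58)
        rec = feature_select(F, y, alpha=0.05)
        counts.append(rec.positive_set.size + rec.negative_set.size)
    assert 11.0 < np.mean(counts) < 16.0


@pytest.mark.parametrize("alpha", [0.10, 0.05, 0.01])
def test_selection_runs_at_robustness_thresholds(alpha):
    F, y = planted_features(seed=6)
    rec = feature_select(F, y, alpha=alpha)
    assert np.intersect1d(rec.positive_set, rec.negative_set).size == 0
    assert (rec.p[rec.positive_set] < alpha).all()
    assert (rec.r[rec.positive_set] > 0).all()


# ---------------------------------------------------------------------------
# strengths
# ---------------------------------------------------------------------------

def _record(pos, neg, p=6):
    return FeatureSelectionRecord(iteration=0, positive_set=np.asarray(pos, int),
                                  negative_set=np.asarray(neg, int),
                                  r=np.zeros(p), p=np.ones(p), excluded=np.array([], int))


def test_strengths_singleton_and_two_conventions():
    row = np.array([[0.7, 0.6, 0.2, -0.9, 0.0, 0.0]])
    single = compute_strengths(row, _record([0], []))
    assert single["positive"][0] == pytest.approx(0.7)
    assert single["total"][0] == pytest.approx(0.7)
    assert single["negative"] is None

    pooled = compute_strengths(row, _record([1, 2], [3]), total_rule="pooled")
    averaged = compute_strengths(row, _record([1, 2], [3]), total_rule="averaged")
    assert pooled["total"][0] == pytest.approx((0.6 + 0.2 + 0.9) / 3)
    assert averaged["total"][0] == pytest.approx((0.4 + 0.9) / 2)
    assert pooled["positive"][0] == averaged["positive"][0] == pytest.approx(0.4)
    assert pooled["negative"][0] == averaged["negative"][0] == pytest.approx(0.9)


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 10_000), st.integers(1, 4))
def test_pooled_equals_averaged_for_equal_set_sizes(seed, set_size):
    rng = np.random.default_rng(seed)
    row = rng.standard_normal((3, 10))
    rec = _record(list(range(set_size)), list(range(set_size, 2 * set_size)), p=10)
    pooled = compute_strengths(row, rec, "pooled")["total"]
    averaged = compute_strengths(row, rec, "averaged")["total"]
    assert np.allclose(pooled, averaged, atol=1e-12)


def test_empty_negative_set_flags_negative_model_only():
    row = np.array([[0.5, 0.3, 0.1, 0.2, 0.0, 0.0]])
    s = compute_strengths(row, _record([0, 1], []))
    assert s["negative"] is None
    assert s["positive"] is not None and s["total"] is not None
    assert s["total"][0] == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------

def test_loo_iteration_count_matches_cohort_size():
    F, y = planted_features(n=58, seed=7)
    res = loo_predict(F, y)
    assert res.n_iterations == 58
    assert res.config["n_iterations"] == 58


def test_noiseless_linear_outcome_recovered():
    rng = np.random.default_rng(8)
    F = rng.standard_normal((30, 12))
    y = 2.0 * F[:, 5] + 1.0
    res = loo_predict(F, y)
    assert all(5 in rec.positive_set for rec in res.selection_records)
    assert 5 in res.important_nodes["positive"]
    m = res.models["positive"]
    assert not m.skipped and m.r > 0.99 and m.significant


def test_skip_rule_consistent_iteration_count():
    # a cohort where no node ever passes the screen: every model is skipped
    rng = np.random.default_rng(9)
    F = rng.standard_normal((15, 3))
    y = rng.standard_normal(15)
    res = loo_predict(F, y, alpha=1e-6)
    for kind in ("total", "positive", "negative"):
        assert res.models[kind].skipped
        assert "no feature selected" in res.models[kind].reason
    assert res.n_iterations == 15   # iterations themselves still all run


def test_held_out_participant_never_touches_selection():
    F, y = planted_features(seed=10)
    res = loo_predict(F, y)
    for i in (0, 17, 57):
        corrupted = F.copy()
        corrupted[i] = 1e6 * np.arange(F.shape[1])
        train = np.ones(len(y), bool)
        train[i] = False
        rec = feature_select(corrupted[train], y[train], 0.05)
        assert np.array_equal(rec.positive_set, res.selection_records[i].positive_set)
        assert np.array_equal(rec.negative_set, res.selection_records[i].negative_set)


def test_loo_input_validation():
    rng = np.random.default_rng(11)
    with pytest.raises(ValueError, match="at least 10"):
        loo_predict(rng.standard_normal((5, 3)), rng.standard_normal(5))
    with pytest.raises(ValueError, match="constant"):
        loo_predict(rng.standard_normal((12, 3)), np.ones(12))
    with pytest.raises(ValueError, match="missing"):
        y = rng.standard_normal(12)
        y[3] = np.nan
        loo_predict(rng.standard_normal((12, 3)), y)


def test_important_nodes_strict_threshold():
    F, y = planted_features(n=20, p=8, n_signal=1, r_target=0.95, seed=12)
    res = loo_predict(F, y)
    for sign in ("positive", "negative"):
        frac = res.selection_fraction[sign]
        assert np.array_equal(res.important_nodes[sign], np.flatnonzero(frac > 0.95))


# ---------------------------------------------------------------------------
# permutation
# ---------------------------------------------------------------------------

def test_permutation_extreme_rank_add_one_rule():
    F, y = planted_features(n=40, p=15, r_target=0.9, seed=13)
    perm = permutation_test(F, y, n_perm=99, seed=14)
    n_valid = perm.null_r["total"].size
    assert n_valid + perm.n_skipped["total"] == 99
    obs = perm.observed.models["total"].r
    if (perm.null_r["total"] < obs).all():
        assert perm.p_values["total"] == pytest.approx(1.0 / (1 + n_valid))
    assert perm.p_values["total"] <= 3.0 / (1 + n_valid)


def test_permutation_rejects_zero_permutations():
    F, y = planted_features(seed=15)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(F, y, n_perm=0)


def test_permutation_null_calibrated_on_shuffled_outcomes():
    # feeding an already-shuffled outcome as "observed" gives roughly uniform
    # p-values: rejection near alpha over replicates
    rng = np.random.default_rng(16)
    F = rng.standard_normal((40, 150))
    y = rng.standard_normal(40)
    pvals = []
    for rep in range(40):
        y_shuf = rng.permutation(y)
        perm = permutation_test(F, y_shuf, n_perm=49, seed=100 + rep)
        if perm.p_values["total"] is not None:
            pvals.append(perm.p_values["total"])
    assert len(pvals) > 25
    assert 0.0 <= np.mean(np.asarray(pvals) < 0.2) <= 0.45   # ~0.2 expected


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def test_network_prediction_excludes_uncertain_and_small_networks(default_cohort, default_nv):
    c = default_cohort
    complete = ~c.behavior["excluded_from_outcome"].to_numpy()
    inter = c.behavior.loc[complete, "interdependence"].to_numpy(float)
    y = c.behavior.loc[complete, "ls_change"].to_numpy(float)
    sdnv = compute_sdnv(default_nv[complete], inter)
    results, table = network_predict(sdnv, y, 0.05, c.atlas["network"].to_numpy())
    assert len(results) == 13                       # 14 networks minus "uncertain"
    assert "uncertain" not in results
    assert set(table["network"]) == set(results)
    # the planted default-mode effect shows up in its own network
    dmn = table[(table["network"] == "default mode") & (table["model"] == "positive")]
    assert not dmn["skipped"].iloc[0]
    assert dmn["r"].iloc[0] > 0
    # BH adjustment is monotone within each family
    for kind in ("total", "positive", "negative"):
        sub = table[(table["model"] == kind) & table["p_fdr"].notna()]
        if len(sub) > 1:
            order = sub.sort_values("p")
            assert order["p_fdr"].is_monotonic_increasing


def test_single_node_network_rejected():
    rng = np.random.default_rng(17)
    F = rng.standard_normal((20, 5))
    y = rng.standard_normal(20)
    with pytest.raises(ValueError, match="at least 2"):
        network_predict(F, y, 0.05, np.array(["a", "a", "a", "a", "b"]))


# ---------------------------------------------------------------------------
# leave-two-out
# ---------------------------------------------------------------------------

def test_leave_two_out_perfect_ordering():
    rng = np.random.default_rng(18)
    F = rng.standard_normal((20, 6))
    y = 1.5 * F[:, 2]
    # strict alpha keeps chance selections out, so only the true feature drives
    res = leave_two_out(F, y, alpha=1e-6)
    assert res.accuracy["positive"] == 1.0
    assert res.binomial_p["positive"] < 1e-6


def test_leave_two_out_tie_counting():
    rng = np.random.default_rng(19)
    F = rng.standard_normal((12, 5))
    y = np.array([1, 1, 2, 3, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
    res = leave_two_out(F, y, alpha=0.9)
    assert res.n_excluded_ties == 2
    assert res.n_pairs == 12 * 11 // 2 - 2


def test_leave_two_out_rejects_constant_outcome():
    with pytest.raises(ValueError, match="tied"):
        leave_two_out(np.random.default_rng(20).standard_normal((12, 4)), np.ones(12))


# ---------------------------------------------------------------------------
# simple slopes
# ---------------------------------------------------------------------------

def normal_equations_moderation(x, m, y):
    X = np.column_stack([np.ones_like(x), x, m, x * m])
    return np.linalg.solve(X.T @ X, X.T @ y)


def test_simple_effects_match_normal_equations_oracle():
    rng = np.random.default_rng(21)
    x = rng.standard_normal(58)
    m = rng.standard_normal(58)
    y = 0.5 + 1.0 * x - 0.3 * m + 0.8 * x * m + 0.5 * rng.standard_normal(58)
    res = simple_effects(x, m, y)
    beta = normal_equations_moderation(x, m, y)
    for i in range(4):
        assert res.coefficients[f"b{i}"] == pytest.approx(beta[i], abs=1e-8)
    m_hi = m.mean() + m.std(ddof=1)
    assert res.slopes["high"]["b"] == pytest.approx(beta[1] + beta[3] * m_hi, abs=1e-8)
    assert res.moderator_values["high"] == pytest.approx(m_hi)


def test_no_moderation_gives_matching_slopes():
    rng = np.random.default_rng(22)
    x = rng.standard_normal(200)
    m = rng.standard_normal(200)
    y = 1.2 * x + 0.2 * rng.standard_normal(200)    # b3 = 0
    res = simple_effects(x, m, y)
    hi, lo = res.slopes["high"], res.slopes["low"]
    assert abs(hi["b"] - lo["b"]) < 2 * (hi["se"] + lo["se"])


def test_crossover_interaction_gives_opposite_slopes():
    rng = np.random.default_rng(23)
    x = rng.standard_normal(200)
    m = rng.standard_normal(200)
    y = 1.5 * x * m + 0.3 * rng.standard_normal(200)  # pure crossover, b1 = 0
    res = simple_effects(x, m, y)
    assert res.slopes["high"]["b"] > 0 > res.slopes["low"]["b"]
    assert res.standardized["high"]["b"] > 0 > res.standardized["low"]["b"]


def test_collinear_design_rejected():
    rng = np.random.default_rng(24)
    x = rng.standard_normal(30)
    with pytest.raises(ValueError, match="ondition number"):
        simple_effects(x, 1e7 * x + 1e7, x)
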