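"""Statistical harness: C-index oracle, comparisons, AUC, KM, cutoffs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from liverprog.evaluate import (
    RiskThresholds,
    compare_cindex,
    evaluate_model,
    harrell_cindex,
    km_logrank,
    optimal_cutoff,
    stratify,
    subgroup_evaluate,
    time_dependent_auc,
)


def exhaustive_cindex(r, t, e):
    num = den = 0.0
    for i, j in itertools.permutations(range(len(r)), 2):
        if t[i] < t[j] and e[i] == 1:
            den += 1
            num += 1.0 if r[i] > r[j] else (0.5 if r[i] == r[j] else 0.0)
    return num / den


# ---------------------------------------------------------------------------
# Harrell C


def test_cindex_perfect_concordance():
    assert harrell_cindex([3, 2, 1], [1, 2, 3], [1, 1, 1]).point == 1.0


def test_cindex_tie_and_incomparable_pairs():
    # pairs: (1,2) risk tie -> 1/2; (1,3) concordant; (2,3) censored -> excluded
    res = harrell_cindex([2, 2, 1], [1, 2, 3], [1, 0, 1])
    assert res.point == 0.75
    assert res.n_comparable == 2  # (1,2) and (1,3); (2,3) is incomparable


def test_cindex_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(2, 9))
        r = rng.choice([0.0, 0.5, 1.0, 2.0], n)
        t = rng.choice([1.0, 2.0, 3.0, 4.0], n)
        e = rng.integers(0, 2, n)
        if not np.any((e == 1) & (t < t.max())):
            continue
        assert harrell_cindex(r, t, e).point == pytest.approx(
            exhaustive_cindex(r, t, e), abs=1e-12)


def test_cindex_agrees_with_scikit_survival():
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(1)
    r = rng.normal(size=200)
    t = rng.exponential(10, 200)
    e = rng.integers(0, 2, 200)
    ours = harrell_cindex(r, t, e).point
    theirs = concordance_index_censored(e.astype(bool), t, r)[0]
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_cindex_null_risks_near_half():
    rng = np.random.default_rng(2)
    r = rng.normal(size=1000)
    t = rng.exponential(10, 1000)
    e = np.ones(1000, int)
    assert abs(harrell_cindex(r, t, e).point - 0.5) <= 0.04


def test_cindex_invariant_to_monotone_transform():
    rng = np.random.default_rng(3)
    r = rng.normal(size=50)
    t = rng.exponential(5, 50)
    e = rng.integers(0, 2, 50)
    e[0] = 1
    a = harrell_cindex(r, t, e).point
    b = harrell_cindex(np.exp(3 * r), t, e).point
    assert a == b


def test_cindex_no_comparable_pairs_errors():
    with pytest.raises(ValueError, match="comparable"):
        harrell_cindex([1, 2], [5, 3], [0, 0])


def test_cindex_bootstrap_ci_brackets_point():
    rng = np.random.default_rng(4)
    r = rng.normal(size=100)
    t = rng.exponential(10 * np.exp(-r), 100)
    res = harrell_cindex(r, t, np.ones(100, int), n_bootstrap=200, seed=0)
    assert res.ci_lower <= res.point <= res.ci_upper


# ---------------------------------------------------------------------------
# model comparison


def test_compare_identical_models_p_one():
    rng = np.random.default_rng(5)
    r = rng.normal(size=60)
    t = rng.exponential(10, 60)
    out = compare_cindex(r, r, t, np.ones(60, int), n_bootstrap=100)
    assert out["delta"] == 0.0 and out["p"] == 1.0


def test_compare_symmetry():
    rng = np.random.default_rng(6)
    a, b = rng.normal(size=80), rng.normal(size=80)
    t = rng.exponential(10, 80)
    e = np.ones(80, int)
    pa = compare_cindex(a, b, t, e, n_bootstrap=200, seed=1)["p"]
    pb = compare_cindex(b, a, t, e, n_bootstrap=200, seed=1)["p"]
    assert pa == pytest.approx(pb, abs=1e-12)


def test_compare_detects_true_signal():
    """True-LP model beats noise with p < 0.01 in >= 9/10 seeds (n=400)."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        lp = rng.normal(size=400)
        t = rng.exponential(10 * np.exp(-1.2 * lp), 400)
        noise = rng.normal(size=400)
        p = compare_cindex(lp, noise, t, np.ones(400, int),
                           n_bootstrap=300, seed=seed)["p"]
        wins += p < 0.01
    assert wins >= 9


def test_compare_requires_enough_bootstrap():
    with pytest.raises(ValueError, match="50"):
        compare_cindex([1], [2], [1.0], [1], n_bootstrap=10)


# ---------------------------------------------------------------------------
# time-dependent AUC


def test_ipcw_auc_equals_binary_auc_without_censoring():
    rng = np.random.default_rng(7)
    r = rng.normal(size=400)
    t = rng.exponential(12 * np.exp(-r), 400)
    h = float(np.median(t))
    ours = time_dependent_auc(r, t, np.ones(400, int), h)["auc"]
    binary = roc_auc_score((t <= h).astype(int), r)
    assert ours == pytest.approx(binary, abs=1e-10)


def test_auc_perfect_separation():
    t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    r = np.array([6.0, 5.0, 4.0, 1.0, 2.0, 3.0])
    out = time_dependent_auc(r, t, np.ones(6, int), 5.0)
    assert out["auc"] == pytest.approx(1.0)


def test_auc_null_risks_near_half():
    rng = np.random.default_rng(8)
    r = rng.normal(size=1000)
    t = rng.exponential(10, 1000)
    out = time_dependent_auc(r, t, np.ones(1000, int), float(np.median(t)))
    assert abs(out["auc"] - 0.5) <= 0.05


def test_auc_degenerate_horizon_errors():
    t = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="cases"):
        time_dependent_auc([1, 2, 3], t, [1, 1, 1], 0.5)
    with pytest.raises(ValueError, match="controls"):
        time_dependent_auc([1, 2, 3], t, [1, 1, 1], 5.0)


# ---------------------------------------------------------------------------
# KM / log-rank / HR


def test_logrank_type_one_error_calibrated():
    """Null rejection rate at alpha=0.05 stays within [0.03, 0.08]."""
    rejections = 0
    n_sim = 200
    for seed in range(n_sim):
        rng = np.random.default_rng(seed)
        t = rng.exponential(10, 400)
        strata = np.array(["a"] * 200 + ["b"] * 200)
        res = km_logrank(strata, t, np.ones(400, int))
        rejections += res["logrank_p"] < 0.05
    assert 0.03 <= rejections / n_sim <= 0.08


def test_hr_recovery_two_arms():
    rng = np.random.default_rng(9)
    t = np.concatenate([rng.exponential(10, 500), rng.exponential(5, 500)])
    strata = np.array(["low"] * 500 + ["high"] * 500)
    res = km_logrank(strata, t, np.ones(1000, int))
    assert 1.8 <= res["hr"] <= 2.2
    assert res["logrank_p"] < 1e-10


def test_km_survival_starts_at_one():
    res = km_logrank(np.array(["a", "a", "b", "b"]),
                     np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, int))
    for curve in res["curves"].values():
        assert curve["survival"].iloc[0] == 1.0


def test_km_median_not_reached_reported_as_none():
    t = np.array([10.0] * 5 + [1.0, 2.0, 3.0, 4.0, 5.0])
    e = np.array([0] * 5 + [1] * 5)
    strata = np.array(["cens"] * 5 + ["ev"] * 5)
    res = km_logrank(strata, t, e)
    assert res["medians"]["cens"] is None
    assert res["medians"]["ev"] == 3.0


def test_km_single_stratum_errors():
    with pytest.raises(ValueError, match="strata"):
        km_logrank(np.array(["a", "a"]), np.array([1.0, 2.0]), np.array([1, 1]))


# ---------------------------------------------------------------------------
# cutoffs and stratification


def test_cutoff_bimodal_risks_separating_hazards():
    rng = np.random.default_rng(10)
    r = np.array([0.0] * 50 + [10.0] * 50)
    t = np.concatenate([rng.exponential(20, 50), rng.exponential(5, 50)])
    cut = optimal_cutoff(r, t, np.ones(100, int))
    assert 0.0 < cut <= 10.0 and cut > 0.0
    assert set(stratify(r, cut)) == {"low", "high"}


def test_published_thresholds_stratify_example():
    thr = RiskThresholds()
    assert list(stratify([1.0, 1.3], thr.mmf_os)) == ["low", "high"]
    assert thr.mmf_pfs == 1.98 and thr.ensemble_os == 0.45 and \
        thr.ensemble_pfs == 0.90


def test_cutoff_rank_invariance():
    rng = np.random.default_rng(11)
    r = rng.normal(size=100)
    t = rng.exponential(10 * np.exp(-r), 100)
    e = np.ones(100, int)
    cut = optimal_cutoff(r, t, e)
    cut2 = optimal_cutoff(np.exp(r), t, e)  # strictly increasing transform
    assert np.array_equal(stratify(r, cut), stratify(np.exp(r), cut2))


def test_cutoff_constant_risks_error():
    with pytest.raises(ValueError, match="no admissible cutoff"):
        optimal_cutoff(np.ones(50), np.arange(1.0, 51.0), np.ones(50, int))


# ---------------------------------------------------------------------------
# subgroups / report


def _cohort_frame(n=120, seed=12):
    rng = np.random.default_rng(seed)
    r = rng.normal(size=n)
    t = rng.exponential(10 * np.exp(-r), n)
    e = rng.integers(0, 2, n)
    e[:10] = 1
    clin = pd.DataFrame({"age": rng.integers(30, 80, n)})
    return r, t, e, clin


def test_subgroup_all_patients_equals_global():
    r, t, e, clin = _cohort_frame()
    full = evaluate_model(r, t, e, n_bootstrap=0)
    sub = subgroup_evaluate(r, t, e, clin, np.ones(len(r), bool),
                            "all", n_bootstrap=0)
    assert sub.cindex.point == full.cindex.point
    assert sub.n_patients == full.n_patients


def test_subgroups_partition_cohort():
    r, t, e, clin = _cohort_frame()
    young = subgroup_evaluate(r, t, e, clin, lambda c: c["age"] < 55,
                              "age<55", n_bootstrap=0)
    old = subgroup_evaluate(r, t, e, clin, lambda c: c["age"] >= 55,
                            "age>=55", n_bootstrap=0)
    assert young.n_patients + old.n_patients == len(r)


def test_subgroup_empty_errors():
    r, t, e, clin = _cohort_frame()
    with pytest.raises(ValueError, match="empty subgroup"):
        subgroup_evaluate(r, t, e, clin, lambda c: c["age"] > 200, "impossible")


def test_subgroup_without_events_surfaces_error():
    r, t, e, clin = _cohort_frame()
    e = np.zeros_like(e)
    with pytest.raises(ValueError, match="no events"):
        subgroup_evaluate(r, t, e, clin, np.ones(len(r), bool), "all")


# ---------------------------------------------------------------------------
# property tests


from hypothesis import given, settings, strategies as hs


@settings(max_examples=40, deadline=None, derandomize=True)
@given(hs.integers(0, 10_000))
def test_cindex_rank_invariance_property(seed):
    """C-index depends only on the ranks of the risk scores."""
    rng = np.random.default_rng(seed)
    n = 20
    r = rng.normal(size=n)
    t = rng.exponential(5, n)
    e = rng.integers(0, 2, n)
    if not np.any((e == 1) & (t < t.max())):
        e[np.argmin(t)] = 1
    a = harrell_cindex(r, t, e).point
    b = harrell_cindex(3.0 * r + 7.0, t, e).point
    c = harrell_cindex(np.tanh(r), t, e).point
    assert a == b == c
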