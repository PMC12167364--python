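"""Three-step feature selection and the radiomics risk model."""

import numpy as np
import pandas as pd
import pytest

from liverprog.datatypes import SurvivalLabel
from liverprog.evaluate import harrell_cindex
from liverprog.radiomics import (
    RSFConfig,
    SelectionThresholds,
    SelectionTrace,
    fit_radiomics_model,
    rsf_importance_filter,
    run_selection,
    univariate_cox_filter,
    vif_filter,
)
from liverprog.synthetic import default_config

FAST_RSF = RSFConfig(n_estimators=150, min_samples_leaf=15, seed=0)


def _labels(t, e):
    return [SurvivalLabel(float(ti), int(ei)) for ti, ei in zip(t, e)]


def _signal_cohort(tabular_survival, n=200, seed=0):
    cfg = default_config()
    _, lp, t, e, os_l, _ = tabular_survival(cfg, n, seed)
    return lp, t, e, os_l


# ---------------------------------------------------------------------------
# step 1: univariate screen


def test_univariate_retains_true_lp(tabular_survival):
    lp, t, e, os_l = _signal_cohort(tabular_survival, 200, 1)
    table = pd.DataFrame({"lp_feature": lp})
    kept = univariate_cox_filter(table, os_l, t_uni=0.55)
    assert kept == ["lp_feature"]


def test_univariate_rejects_noise_features(tabular_survival):
    """A pure-noise feature is rejected in >= 90% of 50 replicates."""
    _, _, _, os_l = _signal_cohort(tabular_survival, 200, 2)
    rng = np.random.default_rng(0)
    rejected = 0
    for _ in range(50):
        table = pd.DataFrame({"noise": rng.normal(size=200)})
        if not univariate_cox_filter(table, os_l, t_uni=0.55):
            rejected += 1
    assert rejected >= 45


def test_univariate_unattainable_threshold(tabular_survival):
    lp, _, _, os_l = _signal_cohort(tabular_survival, 200, 3)
    assert univariate_cox_filter(pd.DataFrame({"f": lp}), os_l, t_uni=1.0) == []


def test_univariate_sign_invariance(tabular_survival):
    """An anti-concordant feature is retained like its negation."""
    lp, _, _, os_l = _signal_cohort(tabular_survival, 200, 4)
    table = pd.DataFrame({"pos": lp, "neg": -lp})
    kept = univariate_cox_filter(table, os_l, t_uni=0.55)
    assert set(kept) == {"pos", "neg"}


def test_univariate_needs_enough_events():
    labels = _labels(np.arange(1, 11), np.zeros(10))
    with pytest.raises(ValueError, match="events"):
        univariate_cox_filter(pd.DataFrame({"f": np.arange(10.0)}), labels, 0.55)


# ---------------------------------------------------------------------------
# step 2: VIF pruning


def test_vif_exact_duplicates_one_removed():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
    kept = vif_filter(table, t_vif=10.0)
    assert "c" in kept and len(kept) == 2


def test_vif_correlation_09_both_kept():
    """For two features, VIF = 1/(1 - r^2) = 5.26 at r = 0.9 -> both kept."""
    rng = np.random.default_rng(1)
    n = 20000
    x = rng.normal(size=n)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
    table = pd.DataFrame({"x": x, "y": y})
    from liverprog.radiomics import _vif_vector

    z = (table - table.mean()) / table.std(ddof=0)
    vifs = _vif_vector(z.to_numpy())
    assert np.allclose(vifs, 1.0 / (1.0 - 0.81), atol=0.3)
    assert set(vif_filter(table, 10.0)) == {"x", "y"}


def test_vif_orthogonal_all_kept():
    from scipy.linalg import hadamard

    H = np.repeat(hadamard(8)[:, 1:7].astype(float), 5, axis=0)  # orthogonal, mean 0
    table = pd.DataFrame(H, columns=[f"f{i}" for i in range(6)])
    from liverprog.radiomics import _vif_vector

    z = (table - table.mean()) / table.std(ddof=0)
    assert np.allclose(_vif_vector(z.to_numpy()), 1.0, atol=1e-6)
    assert len(vif_filter(table, t_vif=10.0)) == 6


def test_vif_constant_feature_removed_first():
    rng = np.random.default_rng(2)
    table = pd.DataFrame({"const": np.ones(50), "x": rng.normal(size=50)})
    trace = SelectionTrace(thresholds=SelectionThresholds())
    kept = vif_filter(table, 10.0, trace)
    assert kept == ["x"]
    assert trace.vif_removals[0][0] == "const"
    assert np.isinf(trace.vif_removals[0][1])


# ---------------------------------------------------------------------------
# step 3: RSF importance


def test_rsf_retains_informative_feature(tabular_survival):
    lp, t, e, os_l = _signal_cohort(tabular_survival, 200, 5)
    rng = np.random.default_rng(0)
    table = pd.DataFrame({"signal": lp + rng.normal(0, 0.1, 200)})
    kept = rsf_importance_filter(table, os_l, t_mul=0.05, rsf_config=FAST_RSF)
    assert kept == ["signal"]


def test_rsf_noise_rarely_retained(tabular_survival):
    """Over 20 seeds, on average <= 1 of 10 noise features survives."""
    _, _, _, os_l = _signal_cohort(tabular_survival, 200, 6)
    total = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(rng.normal(size=(200, 10)),
                             columns=[f"n{i}" for i in range(10)])
        cfg = RSFConfig(n_estimators=150, min_samples_leaf=15, seed=seed)
        total += len(rsf_importance_filter(table, os_l, 0.05, cfg))
    assert total / 20 <= 1.0


def test_rsf_infinite_threshold_empty(tabular_survival):
    lp, _, _, os_l = _signal_cohort(tabular_survival, 100, 7)
    table = pd.DataFrame({"f": lp})
    assert rsf_importance_filter(table, os_l, np.inf, FAST_RSF) == []


def test_rsf_all_censored_errors():
    labels = _labels(np.arange(1, 41), np.zeros(40))
    with pytest.raises(ValueError, match="censored"):
        rsf_importance_filter(pd.DataFrame({"f": np.arange(40.0)}), labels,
                              0.05, FAST_RSF)


# ---------------------------------------------------------------------------
# full selection


def test_selection_nesting_and_monotonicity(tabular_survival):
    """Raising any threshold never grows the surviving set."""
    lp, t, e, os_l = _signal_cohort(tabular_survival, 150, 8)
    rng = np.random.default_rng(1)
    table = pd.DataFrame({
        "signal": lp + rng.normal(0, 0.2, 150),
        "dup": lp + rng.normal(0, 0.2, 150),
        "noise1": rng.normal(size=150),
        "noise2": rng.normal(size=150),
    })
    base = run_selection(table, os_l, SelectionThresholds(0.55, 10.0, 0.0),
                         FAST_RSF)
    base.check_nesting()
    stricter = run_selection(table, os_l, SelectionThresholds(0.60, 5.0, 0.05),
                             FAST_RSF)
    assert set(stricter.f_uni) <= set(base.f_uni)
    assert set(stricter.f_mul) <= set(base.f_mul)


def test_threshold_validation():
    with pytest.raises(ValueError, match="t_uni"):
        SelectionThresholds(t_uni=0.4).validate()
    with pytest.raises(ValueError, match="t_vif"):
        SelectionThresholds(t_vif=0.5).validate()


# ---------------------------------------------------------------------------
# radiomics risk model


def test_radiomics_model_frozen_and_strict(tabular_survival):
    lp, t, e, os_l = _signal_cohort(tabular_survival, 150, 9)
    rng = np.random.default_rng(3)
    table = pd.DataFrame({"s": lp + rng.normal(0, 0.3, 150),
                          "n": rng.normal(size=150)})
    model = fit_radiomics_model(table, os_l, FAST_RSF)
    assert np.array_equal(model.score(table), model.score(table))
    with pytest.raises(KeyError, match="'s'"):
        model.score(table.drop(columns=["s"]))


def test_radiomics_model_learns_planted_signal(tabular_survival):
    lp, t, e, os_l = _signal_cohort(tabular_survival, 300, 10)
    rng = np.random.default_rng(4)
    table = pd.DataFrame({
        "tex1": lp + rng.normal(0, 0.5, 300),
        "tex2": lp + rng.normal(0, 0.5, 300),
        "n1": rng.normal(size=300),
    })
    model = fit_radiomics_model(table, os_l, FAST_RSF)
    c = harrell_cindex(model.score(table), t, e).point
    assert c > 0.65


def test_radiomics_model_null_heldout(tabular_survival):
    from liverprog.synthetic import null_signal_config

    cfg = null_signal_config()
    _, _, t, e, os_l, _ = tabular_survival(cfg, 300, 11)
    rng = np.random.default_rng(5)
    table = pd.DataFrame(rng.normal(size=(300, 5)),
                         columns=[f"f{i}" for i in range(5)])
    model = fit_radiomics_model(table.iloc[:150], [os_l[i] for i in range(150)],
                                FAST_RSF)
    held = model.score(table.iloc[150:])
    c = harrell_cindex(held, t[150:], e[150:]).point
    assert abs(c - 0.5) <= 0.07
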