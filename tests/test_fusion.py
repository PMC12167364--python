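"""Risk fusion: ensemble signature, multimodal score, comparator models."""

import numpy as np
import pandas as pd
import pytest

from liverprog.datatypes import SurvivalLabel
from liverprog.evaluate import harrell_cindex
from liverprog.fusion import (
    NETWORK_RISK_COLUMNS,
    encode_clinical,
    fit_benchmark,
    fit_ensemble_dl,
    fit_mmf,
    fit_mrecist_model,
    univariate_cox_prescreen,
)
from liverprog.radiomics import RSFConfig
from liverprog.synthetic import (
    clinical_only_signal_config,
    complementary_signal_config,
    default_config,
    null_signal_config,
)

FAST_RSF = RSFConfig(n_estimators=200, min_samples_leaf=20, seed=0)


def _risk_table(risks):
    return pd.DataFrame({c: r for c, r in zip(NETWORK_RISK_COLUMNS, risks)})


# ---------------------------------------------------------------------------
# Ensemble-DL signature


def test_ensemble_identical_copies_add_nothing(tabular_survival):
    """Three copies of the LP score within 0.02 of the single-input C-index."""
    cfg = default_config()
    _, lp, t, e, os_l, _ = tabular_survival(cfg, 300, 50)
    model = fit_ensemble_dl([lp, lp, lp], os_l, FAST_RSF)
    sig = model.score(_risk_table([lp, lp, lp]))
    c_sig = harrell_cindex(sig, t, e).point
    c_lp = harrell_cindex(lp, t, e).point
    assert abs(c_sig - c_lp) <= 0.02


def test_ensemble_denoises_noisy_copies(tabular_survival):
    """Fused signature >= best single noisy copy - 0.02 across 10 seeds."""
    cfg = default_config()
    wins = 0
    for seed in range(10):
        _, lp, t, e, os_l, _ = tabular_survival(cfg, 300, 200 + seed)
        rng = np.random.default_rng(seed)
        copies = [lp + rng.normal(0, lp.std(), len(lp)) for _ in range(3)]
        model = fit_ensemble_dl(copies, os_l, FAST_RSF)
        sig = model.score(_risk_table(copies))
        c_sig = harrell_cindex(sig, t, e).point
        c_best = max(harrell_cindex(c, t, e).point for c in copies)
        wins += c_sig >= c_best - 0.02
    assert wins >= 8


def test_ensemble_deterministic_and_aligned(tabular_survival):
    cfg = default_config()
    _, lp, t, e, os_l, _ = tabular_survival(cfg, 100, 51)
    model = fit_ensemble_dl([lp, lp * 0.5, -lp], os_l, FAST_RSF)
    tab = _risk_table([lp, lp * 0.5, -lp])
    assert np.array_equal(model.score(tab), model.score(tab))
    with pytest.raises(ValueError, match="misaligned"):
        fit_ensemble_dl([lp, lp[:-1], lp], os_l, FAST_RSF)
    with pytest.raises(ValueError, match="3 network"):
        fit_ensemble_dl([lp, lp], os_l, FAST_RSF)


# ---------------------------------------------------------------------------
# MMF


def _clinical_frame(lats):
    rows = []
    for l in lats:
        rows.append({
            "age": l["age"], "sex_male": int(l["sex"] == "M"),
            "afp_gt_400": l["afp_gt_400"], "hbv": l["hbv"],
            "cirrhosis": l["cirrhosis"], "child_pugh_ord": l["child_b"],
            "ecog": l["ecog1"], "bclc_ord": 2 if l["bclc"] == "C" else 1,
            "up_to_seven": 1, "tumor_size_cm": l["size_mm"] * 0.65,
            "tumor_number": l["n_lesions"], "pvtt": l["pvtt"],
            "lung_met": l["lung_met"], "bone_met": l["bone_met"],
            "lymph_met": l["lymph_met"], "therapy_line": l["therapy_line"],
            "prior_local_therapy": l["prior_local_therapy"],
        })
    return pd.DataFrame(rows, index=[f"pt{i:04d}" for i in range(len(lats))])


def test_mmf_combines_complementary_channels(tabular_survival):
    """In-sample MMF >= max(image-only, clinical-only) - 0.02 across 5 seeds."""
    cfg = complementary_signal_config()
    wins = 0
    for seed in range(5):
        lats, lp, t, e, os_l, _ = tabular_survival(cfg, 250, 300 + seed)
        img_lp = np.array([
            sum(cfg.hazard_coefficients[k] * l[k]
                for k in ("size_z", "eta_z", "extra_lesions")) for l in lats])
        clin = _clinical_frame(lats)
        rng = np.random.default_rng(seed)
        copies = [img_lp + rng.normal(0, img_lp.std(), len(lats))
                  for _ in range(3)]
        ens = fit_ensemble_dl(copies, os_l, FAST_RSF, fit_ids=list(clin.index))
        sig = ens.score(_risk_table(copies))
        bench = fit_benchmark(clin, os_l, FAST_RSF)
        mmf = fit_mmf(ens.normalized_train_signature(), clin, os_l, FAST_RSF,
                      clinical_columns=bench.feature_names)
        full = clin[bench.feature_names].copy()
        full.insert(0, "ensemble_dl_signature",
                    ens.score_normalized(_risk_table(copies)))
        mmf_score = mmf.rsf.predict(full.to_numpy(float))
        c = lambda r: harrell_cindex(r, t, e).point
        wins += c(mmf_score) >= max(c(sig), c(bench.score(clin))) - 0.02
    assert wins >= 4


def test_mmf_matches_benchmark_on_clinical_only_signal(tabular_survival):
    """With noise-only imaging, held-out MMF ~ benchmark within 0.03 (mean)."""
    cfg = clinical_only_signal_config()
    diffs = []
    for seed in range(3):
        lats, lp, t, e, os_l, _ = tabular_survival(cfg, 400, 400 + seed)
        clin = _clinical_frame(lats)
        rng = np.random.default_rng(seed)
        copies = [rng.normal(size=400) for _ in range(3)]  # image channel is noise
        tr = np.arange(200)
        va = np.arange(200, 400)
        tr_lab = [os_l[i] for i in tr]
        ens = fit_ensemble_dl([c[tr] for c in copies], tr_lab, FAST_RSF)
        bench = fit_benchmark(clin.iloc[tr], tr_lab, FAST_RSF)
        mmf = fit_mmf(ens.normalized_train_signature(), clin.iloc[tr], tr_lab,
                      FAST_RSF, clinical_columns=bench.feature_names)
        full = clin[bench.feature_names].copy()
        full.insert(0, "ensemble_dl_signature",
                    ens.score_normalized(_risk_table(copies)))
        mmf_s = mmf.rsf.predict(full.to_numpy(float))
        c_mmf = harrell_cindex(mmf_s[va], t[va], e[va]).point
        c_b = harrell_cindex(bench.score(clin)[va], t[va], e[va]).point
        diffs.append(abs(c_mmf - c_b))
    assert np.mean(diffs) <= 0.03


def test_mmf_missing_covariate_named(tabular_survival):
    cfg = default_config()
    lats, lp, t, e, os_l, _ = tabular_survival(cfg, 60, 52)
    clin = _clinical_frame(lats).drop(columns=["pvtt"])
    with pytest.raises(KeyError, match="pvtt"):
        fit_mmf(lp, clin, os_l, FAST_RSF)


def test_mmf_rejects_missing_values(tabular_survival):
    cfg = default_config()
    lats, lp, t, e, os_l, _ = tabular_survival(cfg, 60, 53)
    clin = _clinical_frame(lats)
    clin.loc[clin.index[0], "age"] = np.nan
    with pytest.raises(ValueError, match="age"):
        fit_mmf(lp, clin, os_l, FAST_RSF)


# ---------------------------------------------------------------------------
# benchmark


def test_benchmark_prescreen_finds_strong_covariate(tabular_survival):
    """A true-HR-3 covariate passes the p<0.05 prescreen in >= 95% of seeds."""
    cfg = null_signal_config()
    cfg.hazard_coefficients["pvtt"] = np.log(3.0)
    hits = 0
    for seed in range(20):
        lats, lp, t, e, os_l, _ = tabular_survival(cfg, 300, 500 + seed)
        clin = _clinical_frame(lats)
        kept = univariate_cox_prescreen(clin, os_l, ["pvtt"])
        hits += "pvtt" in kept
    assert hits >= 19


def test_benchmark_null_heldout_chance(tabular_survival):
    """All-noise covariates: held-out C-index near 0.5 (3-seed average)."""
    cfg = null_signal_config()
    devs = []
    for seed in (54, 55, 56):
        lats, lp, t, e, os_l, _ = tabular_survival(cfg, 400, seed)
        clin = _clinical_frame(lats)
        tr = np.arange(200)
        bench = fit_benchmark(clin.iloc[tr], [os_l[i] for i in tr], FAST_RSF)
        c = harrell_cindex(bench.score(clin)[200:], t[200:], e[200:]).point
        devs.append(abs(c - 0.5))
    assert np.mean(devs) <= 0.07


def test_benchmark_cv_reproducible(tabular_survival):
    cfg = default_config()
    lats, lp, t, e, os_l, _ = tabular_survival(cfg, 120, 55)
    clin = _clinical_frame(lats)
    a = fit_benchmark(clin, os_l, FAST_RSF)
    b = fit_benchmark(clin, os_l, FAST_RSF)
    assert a.cv_best == b.cv_best
    assert np.array_equal(a.score(clin), b.score(clin))


def test_benchmark_needs_thirty_patients(tabular_survival):
    cfg = default_config()
    lats, lp, t, e, os_l, _ = tabular_survival(cfg, 20, 56)
    with pytest.raises(ValueError, match="30"):
        fit_benchmark(_clinical_frame(lats), os_l, FAST_RSF)


# ---------------------------------------------------------------------------
# mRECIST comparator


def test_mrecist_progression_raises_risk():
    rng = np.random.default_rng(0)
    cats, times = [], []
    for i in range(400):
        if i % 2 == 0:
            cats.append("PR")
            times.append(rng.exponential(20))  # responders: hazard halved
        else:
            cats.append("PD")
            times.append(rng.exponential(10))
    labels = [SurvivalLabel(t + 0.01, 1) for t in times]
    model = fit_mrecist_model(cats, labels)
    scores = model.score(["PR", "PD"])
    assert scores[1] > scores[0]


def test_mrecist_single_category_uninformative():
    labels = [SurvivalLabel(float(i + 1), 1) for i in range(20)]
    model = fit_mrecist_model(["SD"] * 20, labels)
    scores = model.score(["SD"] * 20)
    assert np.all(scores == scores[0])
    t = np.arange(1.0, 21.0)
    assert harrell_cindex(scores + np.arange(20) * 0, t, np.ones(20, int)).point == 0.5


def test_mrecist_unseen_category_errors():
    labels = [SurvivalLabel(float(i + 1), 1) for i in range(10)]
    with pytest.raises(ValueError, match="unseen"):
        fit_mrecist_model(["XX"] * 10, labels)
    model = fit_mrecist_model(["PR", "PD"] * 5, labels)
    with pytest.raises(ValueError, match="unseen"):
        model.score(["??"])


def test_mrecist_deterministic():
    labels = [SurvivalLabel(float(i + 1), 1) for i in range(40)]
    cats = (["CR", "PR", "SD", "PD"] * 10)
    model = fit_mrecist_model(cats, labels)
    assert np.array_equal(model.score(cats), model.score(cats))


# ---------------------------------------------------------------------------
# hygiene and encoding


def test_fit_set_overlap_flagged(tabular_survival):
    cfg = default_config()
    _, lp, t, e, os_l, _ = tabular_survival(cfg, 80, 57)
    ids = [f"pt{i:04d}" for i in range(80)]
    model = fit_ensemble_dl([lp, lp, lp], os_l, FAST_RSF, fit_ids=ids)
    assert model.overlaps(["pt0003", "other"]) == ["pt0003"]
    assert model.overlaps(["nope"]) == []


def test_encode_clinical_roundtrip(small_cohort):
    (scans, clinical, *_), _ = small_cohort
    df = encode_clinical(clinical)
    assert len(df) == len(clinical)
    assert df["sex_male"].isin([0, 1]).all()
    assert df["child_pugh_ord"].isin([0, 1, 2]).all()
    assert (df["tumor_size_cm"] > 0).all()
    assert df.index[0] == clinical[0].patient_id
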