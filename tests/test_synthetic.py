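"""Generator fidelity: geometry, determinism, and survival-model recovery."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import liverprog.synthetic as syn
from liverprog.evaluate import harrell_cindex
from liverprog.synthetic import (
    ConfigurationError,
    GenerationError,
    SimulationConfig,
    default_config,
    null_signal_config,
    simulate_cohort,
    simulate_scan,
    simulate_survival,
)


def test_empty_cohort():
    scans, clinical, os_l, pfs_l, truth = simulate_cohort(
        default_config(n_patients=0))
    assert scans == [] and clinical == [] and os_l == [] and pfs_l == []
    assert len(truth.lp) == 0


@pytest.mark.parametrize("field,value", [
    ("n_patients", -1), ("volume_edge", 4), ("censoring_rate", 1.5),
    ("baseline_shape", 0.0),
])
def test_invalid_config_names_field(field, value):
    cfg = default_config()
    setattr(cfg, field, value)
    with pytest.raises(ConfigurationError, match=field):
        cfg.validate()


def test_seeded_determinism():
    cfg = default_config(n_patients=4, seed=7)
    a = simulate_cohort(cfg)
    b = simulate_cohort(default_config(n_patients=4, seed=7))
    for sa, sb in zip(a[0], b[0]):
        for ph in "AVD":
            assert np.array_equal(sa.phases[ph], sb.phases[ph])
        assert np.array_equal(sa.tumor_mask, sb.tumor_mask)
    assert [l.time for l in a[2]] == [l.time for l in b[2]]
    assert [r.to_dict() for r in a[1]] == [r.to_dict() for r in b[1]]


def test_weibull_median_matches_closed_form():
    """With all beta=0 and no censoring the KM median is the Weibull median."""
    cfg = null_signal_config(n_patients=2000, censoring_rate=0.0, seed=11,
                             render_images=False)
    _, _, os_l, _, _ = simulate_cohort(cfg)
    med = np.median([l.time for l in os_l])
    closed = cfg.baseline_scale * np.log(2.0) ** (1.0 / cfg.baseline_shape)
    assert abs(med - closed) / closed < 0.05


def test_no_censoring_all_events():
    cfg = default_config(n_patients=50, censoring_rate=0.0, seed=3,
                         render_images=False)
    _, _, os_l, pfs_l, _ = simulate_cohort(cfg)
    assert all(l.event == 1 for l in os_l) and all(l.event == 1 for l in pfs_l)


def test_censoring_rate_hit_in_expectation():
    cfg = default_config(n_patients=1500, seed=13, render_images=False)
    _, _, os_l, _, _ = simulate_cohort(cfg)
    frac = 1.0 - np.mean([l.event for l in os_l])
    assert abs(frac - cfg.censoring_rate) < 0.05


def test_pfs_never_after_os():
    _, _, os_l, pfs_l, _ = simulate_cohort(default_config(
        n_patients=100, seed=5, render_images=False))
    for o, p in zip(os_l, pfs_l):
        assert p.time <= o.time + 1e-9


def test_lp_clip_guard():
    cfg = default_config(seed=0)
    rng = np.random.default_rng(0)
    os_l, pfs_l, t_os, t_pfs, c = simulate_survival(np.inf, cfg, rng)
    assert np.isfinite(os_l.time) and np.isfinite(pfs_l.time)
    os_l2, *_ = simulate_survival(-np.inf, cfg, np.random.default_rng(0))
    assert np.isfinite(os_l2.time)


def test_ground_truth_lp_is_linear_combination():
    _, _, _, _, truth = simulate_cohort(default_config(
        n_patients=30, seed=9, render_images=False))
    recomputed = sum(beta * truth.covariates[name].to_numpy()
                     for name, beta in truth.coefficients.items())
    assert np.allclose(truth.lp, recomputed, atol=1e-12)


def test_censored_observation_below_true_time():
    _, _, os_l, _, truth = simulate_cohort(default_config(
        n_patients=200, seed=21, render_images=False))
    for label, true_t in zip(os_l, truth.true_os):
        if label.event == 0:
            assert true_t >= label.time - 1e-9
        else:
            assert abs(true_t - label.time) < 1e-6 or label.time == pytest.approx(
                true_t, abs=1e-5)


def test_cox_recovers_hr_two_groups():
    """LP contrast of log 2 recovers a hazard ratio of 2 at large n."""
    cfg = default_config(censoring_rate=0.2)
    rows = []
    for i, lp in enumerate([0.0, np.log(2.0)]):
        for j in range(5000):
            rng = syn._stream(900 + i, j, "survival")
            o, *_ = simulate_survival(lp, cfg, rng)
            rows.append({"T": o.time, "E": o.event, "g": i})
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame(rows), duration_col="T", event_col="E")
    hr = float(np.exp(cph.params_["g"]))
    assert 1.8 <= hr <= 2.2


# ---------------------------------------------------------------------------
# phantom geometry


def test_tumor_diameter_matches_size_covariate():
    cfg = default_config(volume_edge=48)
    cov = {"size_mm": 20.0, "eta": 1.0, "n_lesions": 1}
    scan = simulate_scan(np.random.default_rng(2), cov, cfg)
    idx = np.where(scan.tumor_mask)
    max_extent = max(i.max() - i.min() + 1 for i in idx)
    assert abs(max_extent - 20) <= 1


def test_eta_zero_tumor_sd_below_noise_floor():
    cfg = default_config(volume_edge=48)
    cov = {"size_mm": 16.0, "eta": 0.0, "n_lesions": 1}
    scan = simulate_scan(np.random.default_rng(4), cov, cfg)
    hu = scan.phases["A"][scan.tumor_mask.astype(bool)]
    assert hu.std() <= cfg.noise_floor


def test_heterogeneity_raises_tumor_variance():
    """Mean within-tumor HU variance is strictly larger for eta=5 vs eta=0."""
    cfg = default_config(volume_edge=32)
    cov = {"size_mm": 12.0, "n_lesions": 1}

    def mean_var(eta, base_seed):
        vs = []
        for k in range(50):
            scan = simulate_scan(np.random.default_rng(base_seed + k),
                                 {**cov, "eta": eta}, cfg)
            vs.append(scan.phases["V"][scan.tumor_mask.astype(bool)].var())
        return np.mean(vs)

    assert mean_var(5.0, 100) > mean_var(0.0, 100)


def test_tumor_larger_than_liver_errors():
    cfg = default_config(volume_edge=32)
    with pytest.raises(GenerationError, match="does not fit"):
        simulate_scan(np.random.default_rng(0),
                      {"size_mm": 40.0, "eta": 1.0, "n_lesions": 1}, cfg)


def test_masks_nested_and_binary(small_cohort):
    (scans, *_), _ = small_cohort
    for scan in scans:
        scan.validate()  # binary masks, tumor inside liver
        assert scan.tumor_mask.sum() > 0


def test_tissue_hu_within_downstream_window(small_cohort):
    """Liver/tumor voxels sit inside the [-200, 250] HU analysis window."""
    (scans, *_), _ = small_cohort
    for scan in scans[:5]:
        for ph in "AVD":
            inside = scan.phases[ph][scan.liver_mask.astype(bool)]
            assert inside.min() > -200 and inside.max() < 250


# ---------------------------------------------------------------------------
# parameter recovery


def test_cox_beta_coverage(tabular_survival):
    """Each nonzero beta is inside its 95% Wald CI in >= 90% of replicates."""
    cfg = default_config()
    names = [k for k, v in cfg.hazard_coefficients.items() if v != 0]
    hits = {k: 0 for k in names}
    n_rep = 20
    for rep in range(n_rep):
        lats, lp, t, e, *_ = tabular_survival(cfg, 500, 3000 + rep)
        df = pd.DataFrame([{k: l[k] for k in names} for l in lats])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        ci = cph.confidence_intervals_
        for k in names:
            lo, hi = ci.loc[k].iloc[0], ci.loc[k].iloc[1]
            if lo <= cfg.hazard_coefficients[k] <= hi:
                hits[k] += 1
    for k, n_hit in hits.items():
        assert n_hit >= 0.9 * n_rep, f"{k}: covered {n_hit}/{n_rep}"


def test_true_lp_cindex_exceeds_070(tabular_survival):
    """With the default coefficient budget the oracle LP discriminates well."""
    cfg = default_config()
    assert sum(abs(v) for v in cfg.hazard_coefficients.values()) >= 1.0
    _, lp, t, e, *_ = tabular_survival(cfg, 800, 42)
    # brute-force pair counting as the oracle
    num = den = 0.0
    for i in range(len(lp)):
        if e[i] != 1:
            continue
        for j in range(len(lp)):
            if t[i] < t[j]:
                den += 1
                num += 1.0 if lp[i] > lp[j] else (0.5 if lp[i] == lp[j] else 0.0)
    assert num / den > 0.70
    assert harrell_cindex(lp, t, e).point == pytest.approx(num / den)
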