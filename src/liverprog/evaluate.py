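"""Survival-model evaluation harness.

Implements the statistics used to compare prognostic models on
right-censored outcomes: Harrell's concordance index with percentile
bootstrap confidence intervals, paired-bootstrap z-tests between models,
IPCW cumulative/dynamic time-dependent AUC, Kaplan-Meier curves with
log-rank tests and Cox hazard ratios for risk strata, log-rank-driven
optimal cutoff search, and subgroup evaluation.

Conventions: a comparable pair is (i, j) with ``T_i < T_j`` and ``E_i = 1``
(a patient censored exactly at another's event time remains in the risk
set); tied predicted risks count 1/2.  The C-index here is an exact
vectorized pair count, cross-checked in the test suite against exhaustive
enumeration and against scikit-survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "CIndexResult",
    "RiskThresholds",
    "EvaluationReport",
    "harrell_cindex",
    "compare_cindex",
    "time_dependent_auc",
    "km_logrank",
    "optimal_cutoff",
    "stratify",
    "evaluate_model",
    "subgroup_evaluate",
    "DEFAULT_HORIZONS",
]

#: Default time-dependent-AUC horizons in months, per endpoint.
DEFAULT_HORIZONS = {"OS": (12.0, 24.0, 36.0), "PFS": (3.0, 6.0, 12.0)}


@dataclass
class RiskThresholds:
    """Published operating thresholds for the fused risk scores.

    High risk is ``score >= threshold``.  The defaults pair (OS, PFS) as
    (1.26, 1.98) for the multimodal-fusion score and (0.45, 0.90) for the
    ensemble deep-learning signature; they apply to models trained on the
    original clinical cohorts and are configurable for any other fit.
    """

    mmf_os: float = 1.26
    mmf_pfs: float = 1.98
    ensemble_os: float = 0.45
    ensemble_pfs: float = 0.90


@dataclass
class CIndexResult:
    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_comparable: int = 0

    def __float__(self) -> float:
        return self.point


def _pair_counts(risks: np.ndarray, time: np.ndarray, event: np.ndarray):
    comp = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    conc = risks[:, None] > risks[None, :]
    ties = risks[:, None] == risks[None, :]
    n_comp = int(comp.sum())
    if n_comp == 0:
        return 0.0, 0
    score = float((conc & comp).sum() + 0.5 * (ties & comp).sum())
    return score / n_comp, n_comp


def harrell_cindex(risks, time=None, event=None, n_bootstrap: int = 0,
                   seed: int = 0) -> CIndexResult:
    """Harrell's C-index; optional percentile-bootstrap 95% CI.

    ``risks`` may be an array (with ``time``/``event`` arrays) — higher
    risk is expected to fail earlier.  Requires at least one comparable
    pair.
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (len(r) == len(t) == len(e)):
        raise ValueError("risks, time and event must be aligned")
    c, n_comp = _pair_counts(r, t, e)
    if n_comp == 0:
        raise ValueError("no comparable pairs (need at least 2)")
    lo = hi = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(r), len(r))
            cb, nb = _pair_counts(r[idx], t[idx], e[idx])
            if nb > 0:
                boots.append(cb)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return CIndexResult(point=c, ci_lower=lo, ci_upper=hi, n_comparable=n_comp)


def compare_cindex(risks_a, risks_b, time, event, n_bootstrap: int = 1000,
                   seed: int = 0) -> dict:
    """Two-sided z-test on the C-index difference of two models.

    The standard error of ``C_A - C_B`` comes from a paired bootstrap
    (patients resampled jointly for both models).
    """
    if n_bootstrap < 50:
        raise ValueError(f"need >= 50 bootstrap replicates, got {n_bootstrap}")
    ra = np.asarray(risks_a, dtype=float)
    rb = np.asarray(risks_b, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not (len(ra) == len(rb) == len(t)):
        raise ValueError("both models must score the same patients")
    ca, _ = _pair_counts(ra, t, e)
    cb, _ = _pair_counts(rb, t, e)
    delta = ca - cb
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(t), len(t))
        da, na = _pair_counts(ra[idx], t[idx], e[idx])
        db, nb = _pair_counts(rb[idx], t[idx], e[idx])
        if na > 0 and nb > 0:
            deltas.append(da - db)
    se = float(np.std(deltas, ddof=1))
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = delta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"c_a": ca, "c_b": cb, "delta": delta, "se": se, "z": z,
            "p": min(max(p, np.finfo(float).tiny), 1.0)}


def time_dependent_auc(risks, time, event, horizon: float,
                       n_bootstrap: int = 0, seed: int = 0) -> dict:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW from the censoring KM."""
    r = np.asarray(risks, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if not np.any((t <= horizon) & (e == 1)):
        raise ValueError(f"no cases (events before {horizon}) at this horizon")
    if not np.any(t > horizon):
        raise ValueError(f"no controls (survivors past {horizon}) at this horizon")
    y = Surv.from_arrays(event=e.astype(bool), time=t)
    auc, _ = cumulative_dynamic_auc(y, y, r, [horizon])
    point = float(auc[0])
    lo = hi = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(t), len(t))
            ti, ei, ri = t[idx], e[idx], r[idx]
            if not (np.any((ti <= horizon) & (ei == 1)) and np.any(ti > horizon)):
                continue
            yi = Surv.from_arrays(event=ei.astype(bool), time=ti)
            try:
                a, _ = cumulative_dynamic_auc(yi, yi, ri, [horizon])
            except ValueError:
                continue
            if np.isfinite(a[0]):
                boots.append(float(a[0]))
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"horizon": horizon, "auc": point, "ci_lower": lo, "ci_upper": hi}


def km_logrank(strata, time, event) -> dict:
    """Kaplan-Meier curves, log-rank p, and high-vs-low Cox hazard ratio.

    ``strata`` is a per-patient label array with >= 2 nonempty levels.  For
    two strata the HR is high-vs-low from a single-covariate Cox fit (the
    level with higher mean risk ordering is whichever sorts last); medians
    that are never reached are reported as None.
    """
    s = np.asarray(strata)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    levels = [lv for lv in pd.unique(s)]
    if len(levels) < 2:
        raise ValueError(f"need >= 2 strata, got {levels}")
    for lv in levels:
        if (s == lv).sum() == 0:  # pragma: no cover - unique() excludes empties
            raise ValueError(f"stratum {lv} has zero patients")

    curves, medians = {}, {}
    for lv in levels:
        m = s == lv
        km = KaplanMeierFitter()
        km.fit(t[m], e[m], label=str(lv))
        med = km.median_survival_time_
        medians[str(lv)] = None if np.isinf(med) else float(med)
        curves[str(lv)] = pd.DataFrame({
            "time": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
        })

    if len(levels) == 2:
        res = logrank_test(t[s == levels[0]], t[s == levels[1]],
                           e[s == levels[0]], e[s == levels[1]])
    else:
        res = multivariate_logrank_test(t, s, e)
    p = float(res.p_value)

    hr = hr_lo = hr_hi = None
    if len(levels) == 2:
        if {str(l) for l in levels} == {"high", "low"}:
            high_level = [l for l in levels if str(l) == "high"][0]
        else:
            high_level = sorted(levels, key=str)[-1]
        ind = (s == high_level).astype(float)
        df = pd.DataFrame({"T": t, "E": e, "high": ind})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        hr = float(np.exp(cph.params_["high"]))
        ci = cph.confidence_intervals_
        hr_lo = float(np.exp(ci.iloc[0, 0]))
        hr_hi = float(np.exp(ci.iloc[0, 1]))

    med_vals = [m for m in medians.values() if m is not None]
    delta_median = (max(med_vals) - min(med_vals)) if len(med_vals) == len(levels) else None
    return {"curves": curves, "logrank_p": p, "hr": hr, "hr_ci": (hr_lo, hr_hi),
            "medians": medians, "delta_median": delta_median}


def optimal_cutoff(risks, time, event, min_group_frac: float = 0.10,
                   n_grid: int = 81) -> float:
    """Risk threshold maximizing the log-rank statistic.

    Searches a grid over the 10th-90th percentiles of the risks subject to
    each group holding >= ``min_group_frac`` of patients.  Rank-invariant
    and deterministic (first maximizer on the sorted grid wins).
    """
    r = np.asarray(risks, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if len(r) < 30 or e.sum() < 10:
        raise ValueError("cutoff search needs >= 30 patients and >= 10 events")
    if np.ptp(r) == 0:
        raise ValueError("no admissible cutoff: risks are constant")
    grid = np.unique(np.percentile(r, np.linspace(10, 90, n_grid)))
    best_stat, best_cut = -np.inf, None
    n = len(r)
    for cut in grid:
        high = r >= cut
        if high.sum() < min_group_frac * n or (~high).sum() < min_group_frac * n:
            continue
        res = logrank_test(t[high], t[~high], e[high], e[~high])
        stat = float(res.test_statistic)
        if stat > best_stat + 1e-12:
            best_stat, best_cut = stat, float(cut)
    if best_cut is None:
        raise ValueError("no admissible cutoff under the group-size constraint")
    return best_cut


def stratify(risks, threshold: float) -> np.ndarray:
    """Label patients 'high' (score >= threshold) or 'low'."""
    r = np.asarray(risks, dtype=float)
    return np.where(r >= threshold, "high", "low")


@dataclass
class EvaluationReport:
    """Per-model evaluation summary for one endpoint on one cohort."""

    model: str
    endpoint: str
    n_patients: int
    cindex: CIndexResult
    aucs: list = field(default_factory=list)
    cutoff: float | None = None
    stratification: dict | None = None
    subgroup: str | None = None
    hygiene_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "endpoint": self.endpoint,
            "n_patients": self.n_patients,
            "subgroup": self.subgroup,
            "cindex": self.cindex.point,
            "cindex_ci": [self.cindex.ci_lower, self.cindex.ci_upper],
            "aucs": self.aucs,
            "cutoff": self.cutoff,
            "logrank_p": (self.stratification or {}).get("logrank_p"),
            "hr": (self.stratification or {}).get("hr"),
            "medians": (self.stratification or {}).get("medians"),
            "delta_median": (self.stratification or {}).get("delta_median"),
            "hygiene_flags": self.hygiene_flags,
        }

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = [f"| {k} | {v} |" for k, v in d.items() if k not in ("aucs",)]
        auc_str = ", ".join(
            f"{a['horizon']:g}m: {a['auc']:.3f}" for a in self.aucs
        )
        return "\n".join(["| metric | value |", "|---|---|"] + lines +
                         [f"| AUC | {auc_str} |"])


def evaluate_model(risks, time, event, model: str = "model",
                   endpoint: str = "OS", horizons: Sequence[float] | None = None,
                   cutoff: float | None = None, n_bootstrap: int = 200,
                   seed: int = 0, hygiene_flags: Sequence[str] = ()) -> EvaluationReport:
    """Full report for one risk vector: C-index + CI, AUCs, stratification."""
    r = np.asarray(risks, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() == 0:
        raise ValueError("no events in cohort/subgroup: report undefined")
    res = harrell_cindex(r, t, e, n_bootstrap=n_bootstrap, seed=seed)
    horizons = DEFAULT_HORIZONS.get(endpoint, ()) if horizons is None else horizons
    aucs = []
    for h in horizons:
        try:
            aucs.append(time_dependent_auc(r, t, e, h, n_bootstrap=0))
        except ValueError:
            continue  # degenerate horizon for this cohort: skip, do not NaN
    strat = None
    if cutoff is None and len(r) >= 30 and e.sum() >= 10 and np.ptp(r) > 0:
        try:
            cutoff = optimal_cutoff(r, t, e)
        except ValueError:
            cutoff = None
    if cutoff is not None:
        labels = stratify(r, cutoff)
        if len(np.unique(labels)) == 2:
            strat = km_logrank(labels, t, e)
    return EvaluationReport(
        model=model, endpoint=endpoint, n_patients=len(r), cindex=res,
        aucs=aucs, cutoff=cutoff, stratification=strat,
        hygiene_flags=list(hygiene_flags),
    )


def subgroup_evaluate(risks, time, event, clinical: pd.DataFrame,
                      subgroup: Callable[[pd.DataFrame], pd.Series] | np.ndarray,
                      description: str = "subgroup", **kwargs) -> EvaluationReport:
    """Evaluate a model on the patients selected by ``subgroup``.

    ``subgroup`` is a boolean mask or a callable on the clinical table.
    Raises on an empty subgroup; a subgroup without events surfaces the
    underlying error rather than returning NaN statistics.
    """
    mask = subgroup(clinical) if callable(subgroup) else np.asarray(subgroup)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError(f"empty subgroup: {description}")
    report = evaluate_model(np.asarray(risks, dtype=float)[mask],
                            np.asarray(time, dtype=float)[mask],
                            np.asarray(event, dtype=int)[mask], **kwargs)
    report.subgroup = description
    return report
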