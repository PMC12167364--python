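"""Risk fusion: per-network risks -> ensemble signature -> multimodal score.

The ensemble deep-learning (Ensemble-DL) signature is a random survival
forest over the three per-network risk scores; the multimodal fusion (MMF)
score is a second RSF over the signature plus encoded clinical covariates.
Three comparators mirror the clinical baselines: a covariates-only
benchmark (univariate-Cox prescreen at p < 0.05, then an RSF tuned by
3-fold cross-validated concordance), a Cox model on the first-follow-up
mRECIST response, and the radiomics RSF (built in
:mod:`liverprog.radiomics`).

All fitted objects are frozen with the patient ids they were trained on;
scoring a patient contained in a model's fit set is flagged (not blocked)
for train/test-hygiene reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import KFold
from sksurv.util import Surv

from .datatypes import ClinicalRecord, SurvivalLabel, MRECIST_CATEGORIES, \
    labels_to_arrays
from .evaluate import harrell_cindex
from .radiomics import FrozenRSF, RSFConfig

__all__ = [
    "encode_clinical",
    "fit_ensemble_dl",
    "fit_mmf",
    "fit_benchmark",
    "fit_mrecist_model",
    "MRECISTModel",
    "BENCHMARK_COVARIATES",
]

#: Clinical columns entering the benchmark / fusion models, after encoding.
BENCHMARK_COVARIATES = [
    "age", "sex_male", "afp_gt_400", "hbv", "cirrhosis", "child_pugh_ord",
    "ecog", "bclc_ord", "up_to_seven", "tumor_size_cm", "tumor_number",
    "pvtt", "lung_met", "bone_met", "lymph_met", "therapy_line",
    "prior_local_therapy",
]

_CHILD_ORD = {"A": 0, "B": 1, "C": 2}
_BCLC_ORD = {"A": 0, "B": 1, "C": 2, "D": 3}


def encode_clinical(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Numeric design matrix: flags 0/1, Child-Pugh/BCLC ordinal, size/age raw."""
    rows = []
    for rec in records:
        rows.append({
            "patient_id": rec.patient_id,
            "age": rec.age,
            "sex_male": int(rec.sex == "M"),
            "afp_gt_400": rec.afp_gt_400,
            "hbv": rec.hbv,
            "cirrhosis": rec.cirrhosis,
            "child_pugh_ord": _CHILD_ORD[rec.child_pugh],
            "ecog": rec.ecog,
            "bclc_ord": _BCLC_ORD[rec.bclc],
            "up_to_seven": rec.up_to_seven,
            "tumor_size_cm": rec.tumor_size_cm,
            "tumor_number": rec.tumor_number,
            "pvtt": rec.pvtt,
            "lung_met": rec.lung_met,
            "bone_met": rec.bone_met,
            "lymph_met": rec.lymph_met,
            "therapy_line": rec.therapy_line,
            "prior_local_therapy": rec.prior_local_therapy,
            "mrecist": rec.mrecist,
        })
    return pd.DataFrame(rows).set_index("patient_id")


def _surv_y(labels):
    t, e = labels_to_arrays(labels)
    return Surv.from_arrays(event=e.astype(bool), time=t)


def _fusion_rsf_config(rsf_config: RSFConfig | None) -> RSFConfig:
    if rsf_config is not None:
        return rsf_config
    return RSFConfig(n_estimators=500, min_samples_leaf=20)


def _check_aligned(arrays, ids) -> None:
    n = len(ids)
    for a in arrays:
        if len(a) != n:
            raise ValueError(
                f"misaligned patient sets: {len(a)} risks for {n} patients"
            )


NETWORK_RISK_COLUMNS = ["net1_risk", "net2_risk", "net3_risk"]


def _ecdf_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map values to (0, 1) by the empirical CDF of ``reference``."""
    ref = np.sort(np.asarray(reference, dtype=float))
    return np.searchsorted(ref, np.asarray(values, dtype=float),
                           side="right") / (len(ref) + 1.0)


class EnsembleDLModel(FrozenRSF):
    """Ensemble-DL signature: RSF over the three network risks.

    The forest additionally sees the average of the three (z-scored) risks
    as a derived input: random forests split on one axis at a time, and the
    diagonal average is exactly the noise-cancelling direction of an
    ensemble, so exposing it lets shallow splits use it directly.
    """

    def __init__(self, rsf, fit_ids, endpoint, means, sds):
        super().__init__(NETWORK_RISK_COLUMNS, rsf, fit_ids, endpoint)
        self._means = means
        self._sds = sds

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise KeyError(f"feature {missing[0]!r} missing at scoring time")
        X = table[self.feature_names].to_numpy(dtype=float)
        Z = (X - self._means) / self._sds
        return np.column_stack([X, Z.mean(axis=1)])

    def score(self, table: pd.DataFrame) -> np.ndarray:
        return self.rsf.predict(self._design(table))

    def normalized_train_signature(self) -> np.ndarray:
        """Cross-fitted training signature mapped through its own ECDF.

        Cumulative-hazard sums from different forests live on different
        scales; rank-normalizing each signature against the scores of the
        model that produced it puts training (cross-fitted) and scoring
        (full-model) signatures on one [0, 1] scale, so the downstream
        fusion forest's split thresholds transfer.
        """
        cf = self.train_signature_.to_numpy()
        return _ecdf_map(cf, cf)

    def score_normalized(self, table: pd.DataFrame) -> np.ndarray:
        """Full-model signature mapped through its training-score ECDF."""
        return _ecdf_map(self.score(table), self.train_scores_)


def fit_ensemble_dl(net_risks: Sequence[np.ndarray],
                    labels: Sequence[SurvivalLabel],
                    rsf_config: RSFConfig | None = None,
                    fit_ids: Sequence[str] | None = None,
                    endpoint: str = "OS",
                    crossfit_folds: int = 3) -> EnsembleDLModel:
    """RSF over the three aligned per-network risks -> Ensemble-DL signature.

    Besides the full-split model, a cross-fitted signature for the training
    patients is computed (each fold scored by a forest that never saw it)
    and stored as ``model.train_signature_``.  Downstream fusers must train
    on that honest signature: a forest's scores on its own training set are
    partly memorized outcomes, and stacking on them leaks.
    """
    if len(net_risks) != 3:
        raise ValueError(f"expected 3 network risk vectors, got {len(net_risks)}")
    ids = list(fit_ids) if fit_ids is not None else [
        f"pt{i:04d}" for i in range(len(net_risks[0]))
    ]
    _check_aligned(list(net_risks) + [labels], ids)
    X = np.column_stack([np.asarray(r, dtype=float) for r in net_risks])
    means = X.mean(axis=0)
    sds = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    cfg = _fusion_rsf_config(rsf_config)
    rsf = cfg.build()
    model = EnsembleDLModel(rsf, ids, endpoint, means, sds)
    table = pd.DataFrame(X, columns=NETWORK_RISK_COLUMNS, index=ids)
    rsf.fit(model._design(table), _surv_y(labels))
    model.train_scores_ = model.score(table)

    labels = list(labels)
    crossfit = np.full(len(ids), np.nan)
    if crossfit_folds >= 2 and len(ids) >= 2 * crossfit_folds:
        kf = KFold(n_splits=crossfit_folds, shuffle=True, random_state=cfg.seed)
        for hold_in, hold_out in kf.split(X):
            sub = EnsembleDLModel(cfg.build(), [ids[i] for i in hold_in],
                                  endpoint, means, sds)
            sub.rsf.fit(sub._design(table.iloc[hold_in]),
                        _surv_y([labels[i] for i in hold_in]))
            crossfit[hold_out] = sub.score(table.iloc[hold_out])
    else:  # too few patients to cross-fit: fall back to in-sample scores
        crossfit = model.score(table)
    model.train_signature_ = pd.Series(crossfit, index=ids)
    return model


def fit_mmf(signature: np.ndarray, clinical: pd.DataFrame,
            labels: Sequence[SurvivalLabel],
            rsf_config: RSFConfig | None = None,
            clinical_columns: Sequence[str] | None = None,
            fit_ids: Sequence[str] | None = None,
            endpoint: str = "OS") -> FrozenRSF:
    """RSF over the Ensemble-DL signature plus encoded clinical covariates.

    ``clinical_columns`` selects the covariates entering the fusion
    (default: the benchmark covariate set); a missing covariate raises
    rather than being silently imputed.
    """
    cols = list(clinical_columns) if clinical_columns is not None else list(
        BENCHMARK_COVARIATES)
    missing = [c for c in cols if c not in clinical.columns]
    if missing:
        raise KeyError(f"missing covariate {missing[0]!r} in clinical table")
    if clinical[cols].isna().any().any():
        bad = clinical[cols].columns[clinical[cols].isna().any()][0]
        raise ValueError(f"covariate {bad!r} has missing values (no silent imputation)")
    ids = list(fit_ids) if fit_ids is not None else list(clinical.index)
    _check_aligned([signature, labels], ids)
    X = clinical[cols].copy()
    X.insert(0, "ensemble_dl_signature", np.asarray(signature, dtype=float))
    cfg = _fusion_rsf_config(rsf_config)
    rsf = cfg.build()
    rsf.fit(X.to_numpy(dtype=float), _surv_y(labels))
    return FrozenRSF(list(X.columns), rsf, ids, endpoint)


def univariate_cox_prescreen(clinical: pd.DataFrame,
                             labels: Sequence[SurvivalLabel],
                             columns: Sequence[str],
                             alpha: float = 0.05) -> list:
    """Covariates with univariate Cox Wald p < alpha on the training split."""
    t, e = labels_to_arrays(labels)
    kept = []
    for col in columns:
        x = clinical[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        df = pd.DataFrame({"T": t, "E": e, "x": (x - x.mean()) / x.std()})
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="T", event_col="E")
            p = float(cph.summary.loc["x", "p"])
        except Exception as err:  # degenerate covariate: drop with a warning
            warnings.warn(f"prescreen skipped {col}: {err}")
            continue
        if p < alpha:
            kept.append(col)
    return kept


def fit_benchmark(clinical: pd.DataFrame, labels: Sequence[SurvivalLabel],
                  rsf_config: RSFConfig | None = None,
                  fit_ids: Sequence[str] | None = None,
                  endpoint: str = "OS",
                  cv_grid: Sequence[int] = (5, 10, 20)) -> FrozenRSF:
    """Clinical benchmark: Cox prescreen (p < 0.05) then CV-tuned RSF.

    The minimum-leaf-size hyperparameter is chosen by 3-fold
    cross-validated concordance on the training split, then the forest is
    refit on the full split and frozen.  If nothing passes the prescreen
    the model falls back to all covariates with a warning.
    """
    if len(labels) < 30:
        raise ValueError(f"benchmark needs >= 30 training patients, got {len(labels)}")
    cfg = _fusion_rsf_config(rsf_config)
    cols = univariate_cox_prescreen(clinical, labels, BENCHMARK_COVARIATES)
    if not cols:
        warnings.warn("no covariate passed the univariate prescreen; using all")
        cols = list(BENCHMARK_COVARIATES)
    X = clinical[cols].to_numpy(dtype=float)
    t, e = labels_to_arrays(labels)
    y = _surv_y(labels)

    best = (-np.inf, cfg.min_samples_leaf)
    kf = KFold(n_splits=3, shuffle=True, random_state=cfg.seed)
    for leaf in cv_grid:
        scores = []
        for tr, te in kf.split(X):
            if e[te].sum() == 0 or e[tr].sum() == 0:
                continue
            rsf = cfg.build(min_samples_leaf=leaf)
            rsf.fit(X[tr], y[tr])
            try:
                c = harrell_cindex(rsf.predict(X[te]), t[te], e[te]).point
            except ValueError:
                continue
            scores.append(c)
        if scores and np.mean(scores) > best[0]:
            best = (float(np.mean(scores)), leaf)
    rsf = cfg.build(min_samples_leaf=best[1])
    rsf.fit(X, y)
    ids = list(fit_ids) if fit_ids is not None else list(clinical.index)
    model = FrozenRSF(cols, rsf, ids, endpoint)
    model.cv_best = best  # (mean CV C-index, chosen leaf size)
    return model


class MRECISTModel:
    """Cox model on the first-follow-up mRECIST category (CR reference)."""

    def __init__(self, cph: CoxPHFitter, categories: tuple, fit_ids: list,
                 endpoint: str):
        self.cph = cph
        self.categories = categories
        self.fit_ids = fit_ids
        self.endpoint = endpoint

    def _design(self, categories: Sequence[str]) -> pd.DataFrame:
        unseen = sorted(set(categories) - set(MRECIST_CATEGORIES))
        if unseen:
            raise ValueError(f"unseen mRECIST category {unseen[0]!r}")
        return pd.DataFrame({
            f"resp_{c}": [int(x == c) for x in categories]
            for c in MRECIST_CATEGORIES[1:]  # CR is the reference level
        })

    def score(self, categories: Sequence[str]) -> np.ndarray:
        X = self._design(categories)
        lp = np.zeros(len(X))
        if self.cph is None:  # zero-information fit (single training category)
            return lp
        for col in X.columns:
            if col in self.cph.params_.index:
                lp += self.cph.params_[col] * X[col].to_numpy(dtype=float)
        return lp

    def overlaps(self, ids):
        return sorted(set(ids) & set(self.fit_ids))


def fit_mrecist_model(categories: Sequence[str],
                      labels: Sequence[SurvivalLabel],
                      fit_ids: Sequence[str] | None = None,
                      endpoint: str = "OS") -> MRECISTModel:
    """Fit the ordinal-response comparator; emits a Cox linear predictor."""
    unseen = sorted(set(categories) - set(MRECIST_CATEGORIES))
    if unseen:
        raise ValueError(f"unseen mRECIST category {unseen[0]!r}")
    t, e = labels_to_arrays(labels)
    df = pd.DataFrame({
        f"resp_{c}": [int(x == c) for x in categories]
        for c in MRECIST_CATEGORIES[1:]
    })
    # drop degenerate indicator columns (absent or universal categories)
    df = df.loc[:, (df.sum(axis=0) > 0) & (df.sum(axis=0) < len(df))]
    ids = list(fit_ids) if fit_ids is not None else [f"pt{i:04d}" for i in range(len(t))]
    if df.shape[1] == 0:  # all patients in one category: zero information
        return MRECISTModel(None, MRECIST_CATEGORIES, ids, endpoint)
    df["T"], df["E"] = t, e
    cph = CoxPHFitter(penalizer=1e-6)
    cph.fit(df, duration_col="T", event_col="E")
    return MRECISTModel(cph, MRECIST_CATEGORIES, ids, endpoint)
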