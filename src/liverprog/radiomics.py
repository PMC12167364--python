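"""Radiomic feature extraction, three-step selection, and the RSF model.

Feature extraction produces 107 named features per (region, phase) — 14
shape + 18 first-order + 75 texture — from the tumor (``T``) and liver
(``L``) regions of each contrast phase (``A``/``V``/``D``): 214 per scan
and 642 per patient, named ``{region}_{phase}_{class}{Name}`` (e.g.
``T_D_glszmZoneVariance``, ``L_A_glrlmGrayLevelNonUniformity``).

Selection runs three steps on the training split only:

1. *Univariate screen*: keep features whose univariate Cox model exceeds a
   concordance threshold ``t_uni`` (default 0.55).  Because the C-index is
   rank-invariant and a univariate Cox fit orients the coefficient along
   the concordant direction, the model concordance equals
   ``max(c, 1 - c)`` of the raw feature — strongly anti-concordant
   features are retained.
2. *Redundancy pruning*: iteratively drop the feature with the largest
   variance inflation factor until all VIF <= ``t_vif`` (default 10).
3. *Multivariable screen*: keep features whose RSF permutation importance
   (drop in concordance when the feature is shuffled) exceeds ``t_mul``
   (default 0.05).

The surviving set feeds a random survival forest risk model, fitted per
endpoint and then frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .datatypes import SurvivalLabel, TriphasicScan, PHASES, labels_to_arrays
from .evaluate import harrell_cindex
from . import texture

__all__ = [
    "SelectionThresholds",
    "SelectionTrace",
    "RSFConfig",
    "FrozenRSF",
    "extract_features",
    "extract_feature_table",
    "univariate_cox_filter",
    "vif_filter",
    "rsf_importance_filter",
    "run_selection",
    "fit_radiomics_model",
    "FEATURES_PER_REGION_PHASE",
    "FEATURES_PER_SCAN",
    "FEATURES_PER_PATIENT",
]

REGIONS = ("T", "L")
FEATURES_PER_REGION_PHASE = sum(texture.FEATURE_CLASS_COUNTS.values())  # 107
FEATURES_PER_SCAN = FEATURES_PER_REGION_PHASE * len(REGIONS)            # 214
FEATURES_PER_PATIENT = FEATURES_PER_SCAN * len(PHASES)                  # 642


# ---------------------------------------------------------------------------
# extraction


def extract_features(scan: TriphasicScan, bin_width: float = 25.0) -> pd.Series:
    """All 642 radiomic features for one patient (2 regions x 3 phases).

    Shape features depend only on mask geometry, so they are computed once
    per region and repeated identically across phases.  Requires nonempty
    masks of at least 2 voxels (texture is undefined below that).
    """
    masks = {"T": scan.tumor_mask.astype(bool), "L": scan.liver_mask.astype(bool)}
    for region, mask in masks.items():
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"{scan.patient_id}: empty {region} mask")
        if n < 2:
            raise ValueError(
                f"{scan.patient_id}: {region} mask has {n} voxel(s); texture undefined"
            )
    shape_by_region = {
        region: texture.shape_features(mask, scan.spacing)
        for region, mask in masks.items()
    }
    values = {}
    for region, mask in masks.items():
        for phase in PHASES:
            vol = scan.phases[phase]
            feats = dict(shape_by_region[region])
            feats.update(texture.firstorder_features(vol, mask, scan.spacing, bin_width))
            feats.update(texture.all_texture_features(vol, mask, bin_width))
            for name, val in feats.items():
                values[f"{region}_{phase}_{name}"] = float(val)
    row = pd.Series(values, name=scan.patient_id)
    if row.isna().any():
        bad = row.index[row.isna()].tolist()
        raise ValueError(f"{scan.patient_id}: NaN features {bad[:5]}")
    if len(row) != FEATURES_PER_PATIENT:  # pragma: no cover - inventory guard
        raise AssertionError(f"expected {FEATURES_PER_PATIENT} features, got {len(row)}")
    return row


def extract_feature_table(scans: Sequence[TriphasicScan],
                          bin_width: float = 25.0) -> pd.DataFrame:
    """Patients x features table for a list of scans."""
    rows = [extract_features(s, bin_width) for s in scans]
    return pd.DataFrame(rows)


def feature_class(name: str) -> str:
    """Class tag of a ``{region}_{phase}_{class}{Name}`` feature name."""
    tail = name.split("_", 2)[2]
    for cls in texture.FEATURE_CLASS_COUNTS:
        if tail.startswith(cls):
            return cls
    raise ValueError(f"unrecognized feature name {name}")


# ---------------------------------------------------------------------------
# selection


@dataclass
class SelectionThresholds:
    t_uni: float = 0.55
    t_vif: float = 10.0
    t_mul: float = 0.05

    def validate(self) -> None:
        if not (0.5 < self.t_uni < 1.0):
            raise ValueError(f"t_uni must be in (0.5, 1), got {self.t_uni}")
        if not self.t_vif > 1.0:
            raise ValueError(f"t_vif must be > 1, got {self.t_vif}")
        if not self.t_mul >= 0.0:
            raise ValueError(f"t_mul must be >= 0, got {self.t_mul}")


@dataclass
class RSFConfig:
    """Random-survival-forest hyperparameters (shared by selection/fusion)."""

    n_estimators: int = 500
    min_samples_leaf: int = 15
    max_features: str | float = "sqrt"
    seed: int = 0
    n_permutations: int = 5

    def build(self, min_samples_leaf: int | None = None) -> RandomSurvivalForest:
        return RandomSurvivalForest(
            n_estimators=self.n_estimators,
            min_samples_leaf=min_samples_leaf or self.min_samples_leaf,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class SelectionTrace:
    """Ordered surviving sets and per-feature diagnostics of the 3 steps."""

    thresholds: SelectionThresholds
    f_uni: list = field(default_factory=list)
    f_vif: list = field(default_factory=list)
    f_mul: list = field(default_factory=list)
    univariate_cindex: dict = field(default_factory=dict)
    vif_removals: list = field(default_factory=list)  # (name, vif at removal)
    rsf_importance: dict = field(default_factory=dict)
    zscore_mean: dict = field(default_factory=dict)
    zscore_sd: dict = field(default_factory=dict)

    def check_nesting(self) -> None:
        assert set(self.f_mul) <= set(self.f_vif) <= set(self.f_uni)

    def to_json_dict(self) -> dict:
        return {
            "thresholds": vars(self.thresholds),
            "f_uni": self.f_uni,
            "f_vif": self.f_vif,
            "f_mul": self.f_mul,
            "univariate_cindex": self.univariate_cindex,
            "vif_removals": self.vif_removals,
            "rsf_importance": self.rsf_importance,
        }


def _surv_y(labels: Sequence[SurvivalLabel]):
    t, e = labels_to_arrays(labels)
    return Surv.from_arrays(event=e.astype(bool), time=t)


def zscore_fit(table: pd.DataFrame) -> tuple:
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0).replace(0.0, 1.0)
    return mean, sd


def univariate_cox_filter(table: pd.DataFrame, labels: Sequence[SurvivalLabel],
                          t_uni: float = 0.55,
                          trace: SelectionTrace | None = None) -> list:
    """Step 1: features whose univariate Cox concordance exceeds ``t_uni``."""
    t, e = labels_to_arrays(labels)
    if len(labels) < 20 or e.sum() < 5:
        raise ValueError(
            f"univariate screen needs >= 20 patients with >= 5 events, "
            f"got n={len(labels)}, events={int(e.sum())}"
        )
    kept = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            warnings.warn(f"feature {name} is non-finite; skipped")
            continue
        if np.ptp(x) == 0:
            c_model = 0.5  # constant feature carries no ordering
        else:
            c = harrell_cindex(x, t, e).point
            c_model = max(c, 1.0 - c)
        if trace is not None:
            trace.univariate_cindex[name] = float(c_model)
        if c_model > t_uni:  # strict, per the selection rule
            kept.append(name)
    return kept


def _vif_vector(z: np.ndarray) -> np.ndarray:
    """VIF of each column of a z-scored matrix (ridge-stabilized inverse)."""
    n, p = z.shape
    if p == 1:
        return np.ones(1)
    R = (z.T @ z) / n
    R_inv = np.linalg.inv(R + 1e-10 * np.eye(p))
    return np.clip(np.diag(R_inv), 1.0, None)


def vif_filter(table: pd.DataFrame, t_vif: float = 10.0,
               trace: SelectionTrace | None = None) -> list:
    """Step 2: greedy removal of the max-VIF feature until all VIF <= t_vif.

    The single-pass set subtraction of the printed rule is order-ambiguous;
    iterative greedy removal is deterministic and guarantees every
    surviving feature has VIF <= ``t_vif``.  Zero-variance features are
    removed first (their VIF is undefined/infinite).
    """
    names = list(table.columns)
    if not names:
        return []
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    for idx in np.where(sd == 0)[0][::-1]:
        if trace is not None:
            trace.vif_removals.append((names[idx], float("inf")))
        names.pop(idx)
    while len(names) > 1:
        sub = table[names].to_numpy(dtype=float)
        z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        vifs = _vif_vector(z)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= t_vif:
            break
        if trace is not None:
            trace.vif_removals.append((names[worst], float(vifs[worst])))
        names.pop(worst)
    return names


def rsf_importance_filter(table: pd.DataFrame, labels: Sequence[SurvivalLabel],
                          t_mul: float = 0.05,
                          rsf_config: RSFConfig | None = None,
                          trace: SelectionTrace | None = None) -> list:
    """Step 3: features with RSF permutation importance > ``t_mul``.

    Importance is the drop in training-split concordance when the feature's
    column is permuted (averaged over ``n_permutations`` shuffles, seeded).
    """
    rsf_config = rsf_config or RSFConfig()
    t, e = labels_to_arrays(labels)
    if e.sum() == 0:
        raise ValueError("degenerate labels: all patients censored")
    if table.shape[1] == 0:
        return []
    X = table.to_numpy(dtype=float)
    y = _surv_y(labels)
    rsf = rsf_config.build()
    rsf.fit(X, y)
    base = harrell_cindex(rsf.predict(X), t, e).point
    rng = np.random.default_rng(rsf_config.seed)
    kept = []
    for jdx, name in enumerate(table.columns):
        drops = []
        for _ in range(rsf_config.n_permutations):
            Xp = X.copy()
            Xp[:, jdx] = rng.permutation(Xp[:, jdx])
            drops.append(base - harrell_cindex(rsf.predict(Xp), t, e).point)
        score = float(np.mean(drops))
        if trace is not None:
            trace.rsf_importance[name] = score
        if score > t_mul:
            kept.append(name)
    return kept


def run_selection(table: pd.DataFrame, labels: Sequence[SurvivalLabel],
                  thresholds: SelectionThresholds | None = None,
                  rsf_config: RSFConfig | None = None) -> SelectionTrace:
    """Full three-step selection on the training split.

    Cox and VIF steps see z-scored features (training mean/sd, stored in
    the trace); the RSF step sees raw values (trees are scale-invariant).
    Applying the locked trace elsewhere is a pure column projection.
    """
    thresholds = thresholds or SelectionThresholds()
    thresholds.validate()
    trace = SelectionTrace(thresholds=thresholds)
    mean, sd = zscore_fit(table)
    trace.zscore_mean = mean.to_dict()
    trace.zscore_sd = sd.to_dict()
    z_table = (table - mean) / sd

    trace.f_uni = univariate_cox_filter(z_table, labels, thresholds.t_uni, trace)
    trace.f_vif = vif_filter(z_table[trace.f_uni], thresholds.t_vif, trace)
    trace.f_mul = rsf_importance_filter(table[trace.f_vif], labels,
                                        thresholds.t_mul, rsf_config, trace)
    trace.check_nesting()
    return trace


# ---------------------------------------------------------------------------
# frozen RSF risk model


class FrozenRSF:
    """A locked random-survival-forest risk scorer over named columns.

    ``score`` returns one risk per patient (sum of the predicted cumulative
    hazard; higher = worse) and refuses to run if a fitted-on feature is
    missing.  The ids the model was fitted on are recorded for
    train/test-hygiene reporting.
    """

    def __init__(self, feature_names: list, rsf: RandomSurvivalForest,
                 fit_ids: list, endpoint: str):
        self.feature_names = list(feature_names)
        self.rsf = rsf
        self.fit_ids = list(fit_ids)
        self.endpoint = endpoint

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise KeyError(f"feature {missing[0]!r} missing at scoring time")
        return self.rsf.predict(table[self.feature_names].to_numpy(dtype=float))

    def overlaps(self, ids: Sequence[str]) -> list:
        return sorted(set(ids) & set(self.fit_ids))


def fit_radiomics_model(table: pd.DataFrame, labels: Sequence[SurvivalLabel],
                        rsf_config: RSFConfig | None = None,
                        endpoint: str = "OS",
                        fit_ids: Sequence[str] | None = None) -> FrozenRSF:
    """Fit the RSF risk model on the selected features and freeze it."""
    if table.shape[1] == 0:
        raise ValueError("no features selected: cannot fit radiomics model")
    rsf_config = rsf_config or RSFConfig()
    rsf = rsf_config.build()
    rsf.fit(table.to_numpy(dtype=float), _surv_y(labels))
    ids = list(fit_ids) if fit_ids is not None else list(table.index)
    return FrozenRSF(list(table.columns), rsf, ids, endpoint)
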