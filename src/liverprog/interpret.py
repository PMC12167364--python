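"""Model interpretability: 3D Grad-CAM, Shapley attributions, correlations.

Three complementary views of what the fitted models use:

* :func:`gradcam3d` — gradient-weighted class-activation volumes for the
  survival networks, aligned to the preprocessed input cube (with the
  crop-box provenance retained for back-mapping);
* :func:`shap_attributions` — permutation-sampling Shapley values for the
  tabular fusion model, satisfying local accuracy by construction;
* :func:`signature_feature_correlation` — per-feature Spearman rank
  correlation between the ensemble deep-learning signature and the
  radiomic features (no multiplicity correction; raw p-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .nets import SurvivalNet, Linear

__all__ = [
    "ActivationMap",
    "AttributionReport",
    "gradcam3d",
    "shap_attributions",
    "signature_feature_correlation",
]


@dataclass
class ActivationMap:
    """Grad-CAM volume aligned to the (E, E, E) network input geometry."""

    map: np.ndarray
    network: str
    endpoint: str
    layer: str
    all_zero: bool = False
    provenance: dict = field(default_factory=dict)

    def to_nifti(self, path, affine=None) -> None:
        import nibabel as nib

        affine = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.map.astype(np.float32), affine), str(path))


def gradcam3d(net: SurvivalNet, model_input, endpoint: str = "OS",
              layer: str | None = None) -> ActivationMap:
    """Gradient-weighted activation volume for one patient.

    Channel weights are the spatial means of the gradient of the chosen
    endpoint's risk with respect to the requested convolutional feature
    map; the map is the rectified weighted channel sum, trilinearly
    upsampled to the input cube and min-max normalized.  A map whose
    pre-rectification response is entirely non-positive is returned
    all-zero with ``all_zero=True`` instead of being normalized.
    """
    from .preprocess import ModelInput

    if isinstance(model_input, ModelInput):
        x = model_input.array[None]
        mask = model_input.tumor_mask[None]
        provenance = dict(model_input.provenance)
    else:
        x = np.asarray(model_input, dtype=np.float32)
        x = x[None] if x.ndim == 4 else x
        mask = None
        provenance = {}
    layer = layer or net.default_cam_layer
    if layer in net.layers and isinstance(net.layers[layer], Linear):
        raise ValueError(f"layer {layer!r} has no spatial extent")

    out = net.forward(x, mask)
    if layer not in net._acts:
        raise ValueError(
            f"layer {layer!r} is not a captured convolutional feature map "
            f"(available: {sorted(net._acts)})"
        )
    act = net._acts[layer]
    ep_idx = {"OS": 0, "PFS": 1}[endpoint]
    seed = np.zeros_like(out.data)
    seed[0, ep_idx] = 1.0
    for p in net.params:
        p.zero_grad()
    act.grad = None
    out.backward(seed)

    A = act.data[0].astype(np.float64)       # (C, d, h, w)
    G = act.grad[0].astype(np.float64)
    weights = G.mean(axis=(1, 2, 3))         # spatially averaged gradients
    cam = np.maximum((weights[:, None, None, None] * A).sum(axis=0), 0.0)

    edge = x.shape[-1]
    factors = [edge / s for s in cam.shape]
    cam_up = ndimage.zoom(cam, factors, order=1, mode="nearest", grid_mode=True)
    cam_up = cam_up[:edge, :edge, :edge]

    if cam_up.max() <= 0:
        return ActivationMap(np.zeros((edge,) * 3), net.spec.architecture,
                             endpoint, layer, all_zero=True, provenance=provenance)
    lo, hi = cam_up.min(), cam_up.max()
    return ActivationMap((cam_up - lo) / (hi - lo), net.spec.architecture,
                         endpoint, layer, all_zero=False, provenance=provenance)


# ---------------------------------------------------------------------------
# Shapley attributions


@dataclass
class AttributionReport:
    """Per-feature Shapley values per patient, with sampling diagnostics."""

    attributions: pd.DataFrame     # patients x features
    baselines: np.ndarray          # per-patient expected model output
    predictions: np.ndarray        # f(x) per patient
    feature_values: pd.DataFrame
    mc_se: pd.DataFrame            # Monte-Carlo standard error per attribution
    n_samples: int

    def local_accuracy_gap(self) -> np.ndarray:
        return np.abs(self.attributions.sum(axis=1).to_numpy()
                      + self.baselines - self.predictions)

    def to_csv(self, path) -> None:
        self.attributions.to_csv(path)


def shap_attributions(model_fn: Callable[[pd.DataFrame], np.ndarray],
                      rows: pd.DataFrame, background: pd.DataFrame,
                      n_samples: int = 128, seed: int = 0) -> AttributionReport:
    """Permutation-sampling Shapley values for a tabular risk model.

    For each Monte-Carlo sample a feature permutation and a background row
    are drawn; features are switched from background to instance values in
    permutation order and the output deltas are credited to the switched
    feature.  Averaging over samples yields estimates satisfying local
    accuracy exactly against the sampled-background expectation.
    ``model_fn`` maps a feature DataFrame to a 1D score array.
    """
    if len(background) == 0:
        raise ValueError("background must be nonempty")
    p = rows.shape[1]
    if n_samples < 2 * p:
        raise ValueError(f"n_samples={n_samples} < 2 * n_features={2 * p}")
    rng = np.random.default_rng(seed)
    feats = list(rows.columns)
    bg = background[feats].to_numpy(dtype=float)

    phi = np.zeros((len(rows), p))
    phi_sq = np.zeros((len(rows), p))
    baselines = np.zeros(len(rows))
    preds = model_fn(rows).astype(float)

    for i in range(len(rows)):
        x = rows.iloc[i].to_numpy(dtype=float)
        perms = [rng.permutation(p) for _ in range(n_samples)]
        b_idx = rng.integers(0, len(bg), n_samples)
        # build the chain of composite inputs for all samples at once:
        # each sample contributes p+1 rows (background .. fully switched)
        composites = np.empty((n_samples * (p + 1), p))
        for s, perm in enumerate(perms):
            z = bg[b_idx[s]].copy()
            composites[s * (p + 1)] = z
            for step, j in enumerate(perm):
                z = z.copy()
                z[j] = x[j]
                composites[s * (p + 1) + step + 1] = z
        outs = model_fn(pd.DataFrame(composites, columns=feats)).astype(float)
        outs = outs.reshape(n_samples, p + 1)
        contrib = np.zeros((n_samples, p))
        for s, perm in enumerate(perms):
            deltas = np.diff(outs[s])
            contrib[s, perm] = deltas
        phi[i] = contrib.mean(axis=0)
        phi_sq[i] = contrib.std(axis=0, ddof=1) / np.sqrt(n_samples)
        baselines[i] = outs[:, 0].mean()

    return AttributionReport(
        attributions=pd.DataFrame(phi, index=rows.index, columns=feats),
        baselines=baselines,
        predictions=preds,
        feature_values=rows.copy(),
        mc_se=pd.DataFrame(phi_sq, index=rows.index, columns=feats),
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# signature <-> radiomics correlation


def signature_feature_correlation(signature, table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of the signature with each feature.

    Returns a DataFrame indexed by feature with columns ``r`` and ``p``
    (two-sided, t approximation, no multiplicity correction).  Constant
    features have undefined rank correlation and are reported as NaN with
    a ``constant`` flag.
    """
    sig = np.asarray(signature, dtype=float)
    if len(sig) < 10:
        raise ValueError(f"need >= 10 patients, got {len(sig)}")
    if len(sig) != len(table):
        raise ValueError("signature and feature table are misaligned")
    out = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(sig) == 0:
            out.append({"feature": name, "r": np.nan, "p": np.nan, "constant": True})
            continue
        r, p = stats.spearmanr(sig, x)
        out.append({"feature": name, "r": float(r), "p": float(p), "constant": False})
    return pd.DataFrame(out).set_index("feature")
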