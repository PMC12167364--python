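"""Three complementary 3D survival networks with multitask OS/PFS heads.

All three map a (3, E, E, E) triphasic input cube to two scalar risk
scores (OS and PFS; higher = worse) and are trained end to end with the
negative Cox partial log-likelihood (Breslow handling of tied event times,
averaged over events):

    L = -(1/N_E) * sum_{i: E_i=1} [ r_i - log sum_{j: T_j >= T_i} exp(r_j) ]

The architectures realize three complementary inductive biases:

* ``net1_local_cnn`` — an inverted-bottleneck convolutional encoder whose
  input is gated by a soft tumor-mask channel, focusing it on local
  intra-tumoral signal;
* ``net2_semisupervised`` — an encoder / bottleneck / decoder that is
  pretrained to reconstruct the input (unlabeled volumes) before a
  survival head on the bottleneck is fine-tuned, with the encoder at a
  reduced learning rate;
* ``net3_conv_attention`` — a convolutional stem whose feature map is
  mean-pooled into token sequences along the axial, coronal and sagittal
  axes, each processed by self-attention with learned positional
  encodings and concatenated into the heads.

Risk sets are formed over the full cohort each epoch (no within-batch
truncation at desk scale).  Everything is seeded and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, conv3d, concat, relu, sigmoid, softmax
from .datatypes import SurvivalLabel, labels_to_arrays

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "SurvivalNet",
    "cox_partial_likelihood_loss",
    "cox_loss_and_grad",
    "build_network",
    "pretrain_reconstruction",
    "train_multitask",
    "predict_risk",
]

ARCHITECTURES = ("net1_local_cnn", "net2_semisupervised", "net3_conv_attention")
ENDPOINTS = ("OS", "PFS")


# ---------------------------------------------------------------------------
# Cox partial likelihood


def cox_loss_and_grad(risks: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> tuple:
    """Negative Cox partial log-likelihood and its gradient w.r.t. risks.

    Breslow convention: the risk set of an event at time t is every patient
    with ``T_j >= t`` (tied events share the full denominator).  The loss
    is averaged over events; it is invariant to adding a constant to all
    risks.
    """
    r = np.asarray(risks, dtype=np.float64).ravel()
    t = np.asarray(time, dtype=np.float64)
    e = np.asarray(event, dtype=int)
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("no events in batch")
    shift = r.max()
    ex = np.exp(r - shift)

    order = np.argsort(-t, kind="stable")  # descending time
    ex_sorted = ex[order]
    cum = np.cumsum(ex_sorted)  # cum[k] = sum over the k+1 largest times
    t_sorted = t[order]

    # denominator for an event at time ti: sum over T_j >= ti
    t_desc = -t_sorted
    idx_events = np.where(e == 1)[0]
    # last position (in sorted order) with time >= ti
    pos = np.searchsorted(t_desc, -t[idx_events], side="right") - 1
    denoms = cum[pos]  # scaled by exp(-shift)
    loss = -np.sum((r[idx_events] - shift) - np.log(denoms)) / n_events

    # gradient: dL/dr_k = -(1/NE) [E_k - exp(r_k) * sum_{events i: T_i <= T_k} 1/denom_i]
    # times are sorted descending, so events with T_i <= T_k occupy sorted
    # positions >= the first position holding T_k; suffix-sum the 1/denom mass
    inv_at = np.zeros(len(r))
    np.add.at(inv_at, pos, 1.0 / denoms)
    suffix = np.cumsum(inv_at[::-1])[::-1]
    first_pos = np.searchsorted(t_desc, t_desc, side="left")
    per_patient = suffix[first_pos]  # sum of 1/denom over events with T_i <= T_k
    grad_sorted = ex_sorted * per_patient
    grad = np.zeros(len(r))
    grad[order] = grad_sorted
    grad = -(e - grad) / n_events
    return float(loss), grad


def cox_partial_likelihood_loss(risks, labels: Sequence[SurvivalLabel]) -> float:
    """Scalar negative Cox partial log-likelihood for a risk vector."""
    t, e = labels_to_arrays(labels)
    r = np.asarray([float(x) for x in np.asarray(risks).ravel()])
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite risks")
    loss, _ = cox_loss_and_grad(r, t, e)
    return loss


# ---------------------------------------------------------------------------
# parameters and layers


class Param(Tensor):
    __slots__ = ("lr_scale",)

    def __init__(self, data, name: str = "", lr_scale: float = 1.0):
        super().__init__(data, requires_grad=True, name=name)
        self.lr_scale = lr_scale


def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3dLayer:
    def __init__(self, rng, c_in, c_out, k=3, stride=1, name="conv",
                 lr_scale: float = 1.0):
        fan_in = c_in * k**3
        self.w = Param(_he(rng, (c_out, c_in, k, k, k), fan_in), f"{name}.w", lr_scale)
        self.b = Param(np.zeros(c_out, dtype=np.float32), f"{name}.b", lr_scale)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride)

    @property
    def params(self):
        return [self.w, self.b]


class Linear:
    def __init__(self, rng, d_in, d_out, name="fc", lr_scale: float = 1.0):
        self.w = Param(_he(rng, (d_in, d_out), d_in), f"{name}.w", lr_scale)
        self.b = Param(np.zeros(d_out, dtype=np.float32), f"{name}.b", lr_scale)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    @property
    def params(self):
        return [self.w, self.b]


# ---------------------------------------------------------------------------
# network specs and architectures


@dataclass
class NetworkSpec:
    architecture: str = "net1_local_cnn"
    edge: int = 32
    width: float = 1.0
    seed: int = 0
    n_heads: int = 2  # OS + PFS risk outputs
    mask_gate_floor: float = 0.2  # net1: input weight outside the tumor

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.edge < 8:
            raise ValueError(f"edge must be >= 8, got {self.edge}")


class SurvivalNet:
    """Base class: parameter registry + risk prediction interface."""

    #: name of the last convolutional block (default Grad-CAM target)
    default_cam_layer: str = ""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.layers: dict = {}
        self.frozen = False
        self._acts: dict = {}  # conv activations captured on the last forward

    def _capture(self, name: str, t: Tensor) -> Tensor:
        self._acts[name] = t
        return t

    @property
    def _last_conv_activation(self):
        return self._acts.get(self.default_cam_layer)

    @property
    def params(self):
        out = []
        for layer in self.layers.values():
            out.extend(layer.params)
        return out

    def encoder_params(self):
        return []

    def forward(self, x: np.ndarray, tumor_mask: np.ndarray | None = None,
                capture_layer: str | None = None) -> Tensor:
        raise NotImplementedError

    def predict(self, x: np.ndarray, tumor_mask: np.ndarray | None = None) -> np.ndarray:
        """Deterministic (N, 2) risk scores, no gradient tape kept."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 4
        if single:
            x = x[None]
            if tumor_mask is not None and tumor_mask.ndim == 3:
                tumor_mask = tumor_mask[None]
        if x.shape[2:] != (self.spec.edge,) * 3 or x.shape[1] != 3:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec (3, {self.spec.edge}^3)"
            )
        out = self.forward(x, tumor_mask)
        risks = out.data.astype(np.float64)
        if not np.all(np.isfinite(risks)):
            raise FloatingPointError("non-finite risk prediction")
        return risks[0] if single else risks


class Net1LocalCNN(SurvivalNet):
    """Inverted-bottleneck CNN on the tumor-gated input (local focus)."""

    default_cam_layer = "block2"

    def __init__(self, spec: NetworkSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        w = spec.width
        c1, c2, c3 = max(int(8 * w), 4), max(int(16 * w), 8), max(int(32 * w), 8)
        self.layers = {
            "stem": Conv3dLayer(rng, 3, c1, 3, stride=2, name="stem"),
            "b1_expand": Conv3dLayer(rng, c1, c2, 1, name="b1_expand"),
            "b1_conv": Conv3dLayer(rng, c2, c2, 3, stride=2, name="b1_conv"),
            "b1_skip": Conv3dLayer(rng, c1, c2, 1, stride=2, name="b1_skip"),
            "b2_expand": Conv3dLayer(rng, c2, c3, 1, name="b2_expand"),
            "b2_conv": Conv3dLayer(rng, c3, c3, 3, stride=2, name="b2_conv"),
            "b2_skip": Conv3dLayer(rng, c2, c3, 1, stride=2, name="b2_skip"),
            "head": Linear(rng, c3, spec.n_heads, name="head"),
        }

    def forward(self, x, tumor_mask=None, capture_layer=None):
        xt = Tensor(x)
        if tumor_mask is not None:
            floor = self.spec.mask_gate_floor
            gate = floor + (1.0 - floor) * np.asarray(tumor_mask, dtype=np.float32)
            xt = xt * Tensor(gate[:, None])
        h = self._capture("stem", relu(self.layers["stem"](xt)))
        h1 = relu(self.layers["b1_conv"](relu(self.layers["b1_expand"](h))))
        h = self._capture("block1", relu(h1 + self.layers["b1_skip"](h)))
        h2 = relu(self.layers["b2_conv"](relu(self.layers["b2_expand"](h))))
        h = self._capture("block2", relu(h2 + self.layers["b2_skip"](h)))
        pooled = h.mean(axis=(2, 3, 4))
        return self.layers["head"](pooled)


class Net2SemiSupervised(SurvivalNet):
    """Encoder-bottleneck-decoder with a survival head on the bottleneck."""

    default_cam_layer = "bottleneck"

    def __init__(self, spec: NetworkSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        w = spec.width
        c1, c2, c3 = max(int(8 * w), 4), max(int(16 * w), 8), max(int(32 * w), 8)
        self._encoder_names = ["enc1", "enc2", "enc3", "bottleneck"]
        self.layers = {
            "enc1": Conv3dLayer(rng, 3, c1, 3, stride=2, name="enc1"),
            "enc2": Conv3dLayer(rng, c1, c2, 3, stride=2, name="enc2"),
            "enc3": Conv3dLayer(rng, c2, c3, 3, stride=2, name="enc3"),
            "bottleneck": Conv3dLayer(rng, c3, c3, 3, name="bottleneck"),
            "dec1": Conv3dLayer(rng, c3, c2, 3, name="dec1"),
            "dec2": Conv3dLayer(rng, c2, c1, 3, name="dec2"),
            # 1x1x1 at full resolution: projection only, keeps the decoder cheap
            "dec3": Conv3dLayer(rng, c1, 3, 1, name="dec3"),
            "head": Linear(rng, c3, spec.n_heads, name="head"),
        }

    def encoder_params(self):
        out = []
        for name in self._encoder_names:
            out.extend(self.layers[name].params)
        return out

    def _encode(self, xt: Tensor) -> Tensor:
        h = self._capture("enc1", relu(self.layers["enc1"](xt)))
        h = self._capture("enc2", relu(self.layers["enc2"](h)))
        h = self._capture("enc3", relu(self.layers["enc3"](h)))
        return self._capture("bottleneck", relu(self.layers["bottleneck"](h)))

    def reconstruct(self, x: np.ndarray) -> tuple:
        """(bottleneck, reconstruction) tensors for pretraining."""
        xt = Tensor(x)
        z = self._encode(xt)
        h = relu(self.layers["dec1"](ad.upsample2(z)))
        h = relu(self.layers["dec2"](ad.upsample2(h)))
        return z, sigmoid(self.layers["dec3"](ad.upsample2(h)))

    def forward(self, x, tumor_mask=None, capture_layer=None):
        z = self._encode(Tensor(np.asarray(x, dtype=np.float32)))
        return self.layers["head"](z.mean(axis=(2, 3, 4)))


class Net3ConvAttention(SurvivalNet):
    """Conv stem + per-axis token self-attention (global context)."""

    default_cam_layer = "stem2"

    def __init__(self, spec: NetworkSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        w = spec.width
        c1, c2 = max(int(8 * w), 4), max(int(16 * w), 8)
        self.c2 = c2
        L = spec.edge // 4  # token sequence length per axis
        self.layers = {
            "stem1": Conv3dLayer(rng, 3, c1, 3, stride=2, name="stem1"),
            "stem2": Conv3dLayer(rng, c1, c2, 3, stride=2, name="stem2"),
            "head": Linear(rng, 3 * c2, spec.n_heads, name="head"),
        }
        for ax, axis_name in enumerate(("axial", "coronal", "sagittal")):
            self.layers[f"q_{ax}"] = Linear(rng, c2, c2, name=f"q_{axis_name}")
            self.layers[f"k_{ax}"] = Linear(rng, c2, c2, name=f"k_{axis_name}")
            self.layers[f"v_{ax}"] = Linear(rng, c2, c2, name=f"v_{axis_name}")
        self.posenc = [
            Param(0.02 * rng.standard_normal((L, c2)).astype(np.float32),
                  f"posenc_{ax}") for ax in range(3)
        ]

    @property
    def params(self):
        return super().params + self.posenc

    def forward(self, x, tumor_mask=None, capture_layer=None):
        h = self._capture("stem1", relu(self.layers["stem1"](
            Tensor(np.asarray(x, dtype=np.float32)))))
        h = self._capture("stem2", relu(self.layers["stem2"](h)))  # (N, C, L^3)
        pooled_axes = []
        spatial = [(3, 4), (2, 4), (2, 3)]  # pool over the other two axes
        for ax in range(3):
            tok = h.mean(axis=spatial[ax])        # (N, C, L)
            tok = tok.transpose((0, 2, 1))        # (N, L, C)
            tok = tok + self.posenc[ax]
            q = self.layers[f"q_{ax}"](tok)
            k = self.layers[f"k_{ax}"](tok)
            v = self.layers[f"v_{ax}"](tok)
            scores = q @ k.transpose((0, 2, 1)) * (1.0 / math.sqrt(self.c2))
            attn = softmax(scores, axis=-1)
            out = attn @ v                        # (N, L, C)
            pooled_axes.append(out.mean(axis=1))  # (N, C)
        return self.layers["head"](concat(pooled_axes, axis=-1))


def build_network(spec: NetworkSpec) -> SurvivalNet:
    """Instantiate one of the three architectures from its spec."""
    spec.validate()
    cls = {
        "net1_local_cnn": Net1LocalCNN,
        "net2_semisupervised": Net2SemiSupervised,
        "net3_conv_attention": Net3ConvAttention,
    }[spec.architecture]
    return cls(spec)


# ---------------------------------------------------------------------------
# optimization


class Adam:
    def __init__(self, params, lr=1e-2, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            scale = getattr(p, "lr_scale", 1.0)
            p.data = p.data - self.lr * scale * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainConfig:
    epochs: int = 40
    lr: float = 1e-2
    w_os: float = 0.5
    w_pfs: float = 0.5
    seed: int = 0
    encoder_lr_scale: float = 0.1  # net2 fine-tuning only


# ---------------------------------------------------------------------------
# pretraining and training


def pretrain_reconstruction(net: Net2SemiSupervised, volumes: np.ndarray,
                            epochs: int = 30, lr: float = 1e-2,
                            batch: int = 8, seed: int = 0) -> dict:
    """Autoencoder pretraining of the semi-supervised network.

    Minimizes mean squared reconstruction error on the (unlabeled) volumes;
    tracks the best-so-far MSE on a fixed held-in batch and restores that
    checkpoint.  Returns the loss history.
    """
    if epochs < 1:
        raise ValueError(f"epochs must be >= 1, got {epochs}")
    if not isinstance(net, Net2SemiSupervised):
        raise TypeError("reconstruction pretraining applies to net2 only")
    X = np.asarray(volumes, dtype=np.float32)
    if X.ndim == 4:
        X = X[None]
    ae_params = [p for name in ("enc1", "enc2", "enc3", "bottleneck",
                                "dec1", "dec2", "dec3")
                 for p in net.layers[name].params]
    opt = Adam(ae_params, lr=lr)
    rng = np.random.default_rng(seed)
    probe = X[: min(len(X), batch)]

    def probe_mse():
        _, rec = net.reconstruct(probe)
        return float(np.mean((rec.data - probe) ** 2))

    history = {"mse": [probe_mse()]}
    best = (history["mse"][0], [p.data.copy() for p in ae_params])
    for _ in range(epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), batch):
            xb = X[order[start:start + batch]]
            _, rec = net.reconstruct(xb)
            diff = rec.data - xb
            opt.zero_grad()
            rec.backward(2.0 * diff / diff.size)
            opt.step()
        mse = probe_mse()
        history["mse"].append(mse)
        if mse < best[0]:
            best = (mse, [p.data.copy() for p in ae_params])
    for p, d in zip(ae_params, best[1]):
        p.data = d
    history["best_mse"] = best[0]
    return history


def train_multitask(net: SurvivalNet, inputs: np.ndarray,
                    os_labels: Sequence[SurvivalLabel],
                    pfs_labels: Sequence[SurvivalLabel],
                    config: TrainConfig | None = None,
                    tumor_masks: np.ndarray | None = None,
                    val: tuple | None = None,
                    finetune_encoder_scale: bool = False) -> dict:
    """Train the OS+PFS heads with full-cohort Cox risk sets per epoch.

    Total loss is ``w_os * L_OS + w_pfs * L_PFS``.  If validation data
    ``(inputs, masks, os_labels, pfs_labels)`` is given, the checkpoint
    with the best validation OS C-index is restored; otherwise the final
    epoch is kept.  Returns the training curve; the net is frozen after.
    """
    from .evaluate import harrell_cindex

    config = config or TrainConfig()
    t_os, e_os = labels_to_arrays(os_labels)
    t_pfs, e_pfs = labels_to_arrays(pfs_labels)
    if config.w_os > 0 and e_os.sum() == 0:
        raise ValueError("all-censored OS endpoint")
    if config.w_pfs > 0 and e_pfs.sum() == 0:
        raise ValueError("all-censored PFS endpoint")
    X = np.asarray(inputs, dtype=np.float32)

    if finetune_encoder_scale and isinstance(net, Net2SemiSupervised):
        for p in net.encoder_params():
            p.lr_scale = config.encoder_lr_scale
    head_params = net.params
    opt = Adam(head_params, lr=config.lr)

    curve = {"loss": [], "train_cindex_os": [], "val_cindex_os": []}
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        out = net.forward(X, tumor_masks)
        risks = out.data.astype(np.float64)
        grad = np.zeros_like(risks)
        loss = 0.0
        if config.w_os > 0:
            l_os, g_os = cox_loss_and_grad(risks[:, 0], t_os, e_os)
            loss += config.w_os * l_os
            grad[:, 0] = config.w_os * g_os
        if config.w_pfs > 0:
            l_pfs, g_pfs = cox_loss_and_grad(risks[:, 1], t_pfs, e_pfs)
            loss += config.w_pfs * l_pfs
            grad[:, 1] = config.w_pfs * g_pfs
        opt.zero_grad()
        out.backward(grad)
        opt.step()
        curve["loss"].append(float(loss))
        c_tr = harrell_cindex(risks[:, 0], t_os, e_os).point
        curve["train_cindex_os"].append(c_tr)
        if val is not None:
            vx, vm, v_os, _ = val
            vt, ve = labels_to_arrays(v_os)
            v_risk = net.predict(vx, vm)[:, 0]
            c_val = harrell_cindex(v_risk, vt, ve).point
            curve["val_cindex_os"].append(c_val)
            if c_val > best[0]:
                best = (c_val, [p.data.copy() for p in net.params])
    if val is not None and best[1] is not None:
        for p, d in zip(net.params, best[1]):
            p.data = d
    net.frozen = True
    return curve


def predict_risk(net: SurvivalNet, inputs, tumor_mask=None) -> np.ndarray:
    """Risk scores (N, 2) or (2,) for one input; deterministic and finite."""
    from .preprocess import ModelInput

    if isinstance(inputs, ModelInput):
        tumor_mask = inputs.tumor_mask
        inputs = inputs.array
    return net.predict(np.asarray(inputs, dtype=np.float32), tumor_mask)
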