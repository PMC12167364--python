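"""End-to-end pipeline: simulate -> preprocess -> radiomics -> networks ->
fusion -> evaluation -> interpretability.

:class:`RunConfig` is the single schema-validated configuration object
(unknown keys are rejected); :func:`run_pipeline` executes the enabled
stages in order, persists every artifact under the output directory with
the resolved config and its hash, and halts with the failing stage's name
while keeping prior artifacts on disk.  With a fixed config (and seed) all
seeded outputs are bit-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion as fusion_mod
from . import interpret as interpret_mod
from . import nets as nets_mod
from . import radiomics as radiomics_mod
from .datatypes import labels_to_arrays
from .evaluate import DEFAULT_HORIZONS, evaluate_model
from .io import read_cohort, write_cohort
from .preprocess import preprocess_scan
from .radiomics import RSFConfig, SelectionThresholds
from .synthetic import SimulationConfig, simulate_cohort

log = logging.getLogger("liverprog")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (defaults = desk scale)."""

    output_dir: str = "runs/out"
    cohort_dir: str | None = None     # read cohort from here unless simulating
    simulate: bool = True
    n_patients: int = 60
    seed: int = 0
    edge: int = 32                    # network input cube edge
    apply_clahe: bool = True
    val_fraction: float = 0.2         # seeded 8:2 train/validation split
    # stage toggles
    run_radiomics: bool = True
    run_deep: bool = True
    run_fusion: bool = True
    run_evaluate: bool = True
    run_interpret: bool = True
    # stage parameters
    epochs: int = 5
    pretrain_epochs: int = 5
    lr: float = 1e-2
    bin_width: float = 25.0
    thresholds: dict = field(default_factory=lambda: dataclasses.asdict(
        SelectionThresholds()))
    rsf: dict = field(default_factory=lambda: {
        "n_estimators": 200, "min_samples_leaf": 10, "seed": 0})
    horizons: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_HORIZONS.items()})
    endpoints: tuple = ("OS", "PFS")
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["endpoints"] = list(self.endpoints)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _split(n: int, val_fraction: float, seed: int) -> tuple:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 8020]))
    order = rng.permutation(n)
    n_val = max(int(round(val_fraction * n)), 1) if n > 1 else 0
    return np.sort(order[n_val:]), np.sort(order[:n_val])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact dictionary."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    resolved["config_hash"] = config.config_hash()
    (out_dir / "config.resolved.json").write_text(json.dumps(resolved, indent=2))
    artifacts: dict = {"config_hash": resolved["config_hash"], "stages": {}}
    timings = {}

    def stage(name):
        def runner(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start (seed=%d)", name, config.seed)
            try:
                result = fn()
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: done in %.1fs", name, timings[name])
            artifacts["stages"][name] = True
            return result
        return runner

    # ---- cohort ----------------------------------------------------------
    def _cohort():
        if config.simulate:
            sim = SimulationConfig(n_patients=config.n_patients,
                                   volume_edge=config.edge, seed=config.seed,
                                   **config.simulation)
            scans, clinical, os_l, pfs_l, truth = simulate_cohort(sim)
            if config.cohort_dir:
                write_cohort(config.cohort_dir, scans, clinical, os_l, pfs_l, truth)
            return scans, clinical, os_l, pfs_l
        if not config.cohort_dir:
            raise ValueError("cohort_dir is required when simulate=False")
        return read_cohort(config.cohort_dir)

    scans, clinical, os_labels, pfs_labels = stage("cohort")(_cohort)
    ids = [s.patient_id for s in scans]
    t_os, e_os = labels_to_arrays(os_labels)
    t_pfs, e_pfs = labels_to_arrays(pfs_labels)
    train_idx, val_idx = _split(len(ids), config.val_fraction, config.seed)
    artifacts["split"] = {"train": [ids[i] for i in train_idx],
                          "val": [ids[i] for i in val_idx]}
    endpoint_arrays = {"OS": (t_os, e_os), "PFS": (t_pfs, e_pfs)}
    endpoint_labels = {"OS": os_labels, "PFS": pfs_labels}

    # ---- preprocess ------------------------------------------------------
    def _preprocess():
        return [preprocess_scan(s, edge=config.edge,
                                apply_clahe=config.apply_clahe) for s in scans]

    model_inputs = stage("preprocess")(_preprocess)
    X = np.stack([m.array for m in model_inputs])
    M = np.stack([m.tumor_mask for m in model_inputs])

    rsf_cfg = RSFConfig(n_estimators=config.rsf.get("n_estimators", 200),
                        min_samples_leaf=config.rsf.get("min_samples_leaf", 10),
                        seed=config.rsf.get("seed", 0))
    scores: dict = {ep: {} for ep in config.endpoints}

    # ---- radiomics -------------------------------------------------------
    if config.run_radiomics:
        def _radiomics():
            table = radiomics_mod.extract_feature_table(scans, config.bin_width)
            table.index = ids
            table.to_csv(out_dir / "features.tsv", sep="\t")
            thresholds = SelectionThresholds(**config.thresholds)
            out = {}
            for ep in config.endpoints:
                labels = endpoint_labels[ep]
                train_tab = table.iloc[train_idx]
                train_lab = [labels[i] for i in train_idx]
                trace = radiomics_mod.run_selection(train_tab, train_lab,
                                                    thresholds, rsf_cfg)
                (out_dir / f"selection_{ep}.json").write_text(
                    json.dumps(trace.to_json_dict(), indent=1))
                if trace.f_mul:
                    model = radiomics_mod.fit_radiomics_model(
                        train_tab[trace.f_mul], train_lab, rsf_cfg, endpoint=ep)
                    scores[ep]["radiomics"] = model.score(table)
                out[ep] = trace
            return out

        artifacts["selection"] = stage("radiomics")(_radiomics)

    # ---- deep networks ---------------------------------------------------
    if config.run_deep:
        def _deep():
            tr_os = [os_labels[i] for i in train_idx]
            tr_pfs = [pfs_labels[i] for i in train_idx]
            val = None
            if len(val_idx):
                val = (X[val_idx], M[val_idx],
                       [os_labels[i] for i in val_idx],
                       [pfs_labels[i] for i in val_idx])
            curves = {}
            for arch in nets_mod.ARCHITECTURES:
                spec = nets_mod.NetworkSpec(architecture=arch, edge=config.edge,
                                            seed=config.seed)
                net = nets_mod.build_network(spec)
                finetune = False
                if arch == "net2_semisupervised":
                    nets_mod.pretrain_reconstruction(
                        net, X[train_idx], epochs=config.pretrain_epochs,
                        seed=config.seed)
                    finetune = True
                tcfg = nets_mod.TrainConfig(epochs=config.epochs, lr=config.lr,
                                            seed=config.seed)
                masks = M[train_idx] if arch == "net1_local_cnn" else None
                curve = nets_mod.train_multitask(
                    net, X[train_idx], tr_os, tr_pfs, tcfg,
                    tumor_masks=masks, val=val if arch != "net1_local_cnn" else None,
                    finetune_encoder_scale=finetune)
                all_masks = M if arch == "net1_local_cnn" else None
                risks = net.predict(X, all_masks)
                short = arch.split("_")[0]
                scores["OS"][short] = risks[:, 0]
                scores["PFS"][short] = risks[:, 1]
                curves[arch] = curve
                pd.DataFrame(
                    {k: pd.Series(v) for k, v in curve.items()}
                ).to_csv(out_dir / f"curve_{arch}.csv", index=False)
                artifacts.setdefault("networks", {})[arch] = net
            return curves

        stage("deep")(_deep)

    # ---- fusion ----------------------------------------------------------
    clin_df = fusion_mod.encode_clinical(clinical)
    if config.run_fusion:
        def _fusion():
            models = {}
            for ep in config.endpoints:
                labels = endpoint_labels[ep]
                tr_lab = [labels[i] for i in train_idx]
                tr_ids = [ids[i] for i in train_idx]
                tr_clin = clin_df.iloc[train_idx]

                bench = fusion_mod.fit_benchmark(tr_clin, tr_lab, rsf_cfg,
                                                 fit_ids=tr_ids, endpoint=ep)
                scores[ep]["benchmark"] = bench.score(clin_df)
                models[f"benchmark_{ep}"] = bench

                mrec = fusion_mod.fit_mrecist_model(
                    [clinical[i].mrecist for i in train_idx], tr_lab,
                    fit_ids=tr_ids, endpoint=ep)
                scores[ep]["mrecist"] = mrec.score([c.mrecist for c in clinical])
                models[f"mrecist_{ep}"] = mrec

                net_keys = ("net1", "net2", "net3")
                if all(k in scores[ep] for k in net_keys):
                    tr_risks = [scores[ep][k][train_idx] for k in net_keys]
                    ens = fusion_mod.fit_ensemble_dl(tr_risks, tr_lab, rsf_cfg,
                                                     fit_ids=tr_ids, endpoint=ep)
                    full = pd.DataFrame(
                        {c: scores[ep][k] for c, k in
                         zip(fusion_mod.NETWORK_RISK_COLUMNS, net_keys)},
                        index=ids)
                    signature = ens.score(full)
                    scores[ep]["ensemble_dl"] = signature
                    models[f"ensemble_{ep}"] = ens

                    mmf = fusion_mod.fit_mmf(
                        ens.normalized_train_signature(), tr_clin, tr_lab,
                        rsf_cfg, clinical_columns=bench.feature_names,
                        fit_ids=tr_ids, endpoint=ep)
                    full_clin = clin_df[bench.feature_names].copy()
                    full_clin.insert(0, "ensemble_dl_signature",
                                     ens.score_normalized(full))
                    scores[ep]["mmf"] = mmf.rsf.predict(
                        full_clin.to_numpy(dtype=float))
                    models[f"mmf_{ep}"] = mmf
            return models

        artifacts["models"] = stage("fusion")(_fusion)

    # risk profile CSV (one row per patient, one column per score/endpoint)
    profile = pd.DataFrame(index=ids)
    profile["split"] = ["val" if i in set(val_idx) else "train"
                        for i in range(len(ids))]
    for ep in config.endpoints:
        for model_name, vec in scores[ep].items():
            profile[f"{model_name}_{ep}"] = np.asarray(vec, dtype=float)
    profile.to_csv(out_dir / "risk_profile.csv")
    artifacts["risk_profile"] = profile

    # ---- evaluation ------------------------------------------------------
    if config.run_evaluate:
        def _evaluate():
            reports = []
            for ep in config.endpoints:
                t, e = endpoint_arrays[ep]
                for model_name, vec in scores[ep].items():
                    vec = np.asarray(vec, dtype=float)
                    for split_name, idx in (("train", train_idx), ("val", val_idx)):
                        if len(idx) == 0 or e[idx].sum() == 0:
                            continue
                        flags = []
                        key = {"ensemble_dl": "ensemble", "mmf": "mmf",
                               "benchmark": "benchmark", "mrecist": "mrecist"}.get(
                            model_name)
                        model_obj = (artifacts.get("models") or {}).get(
                            f"{key}_{ep}") if key else None
                        if model_obj is not None:
                            overlap = model_obj.overlaps([ids[i] for i in idx])
                            if overlap:
                                flags = [f"scored {len(overlap)} patients from "
                                         f"the model's fit set"]
                        try:
                            rep = evaluate_model(
                                vec[idx], t[idx], e[idx], model=model_name,
                                endpoint=ep,
                                horizons=config.horizons.get(ep),
                                n_bootstrap=100, seed=config.seed,
                                hygiene_flags=flags)
                        except ValueError:
                            continue
                        d = rep.to_dict()
                        d["cohort"] = split_name
                        reports.append(d)
            (out_dir / "evaluation.json").write_text(
                json.dumps(reports, indent=1, default=float))
            lines = ["| model | endpoint | cohort | C-index | log-rank p |",
                     "|---|---|---|---|---|"]
            for d in reports:
                lines.append(
                    f"| {d['model']} | {d['endpoint']} | {d['cohort']} "
                    f"| {d['cindex']:.3f} | {d['logrank_p']} |")
            (out_dir / "evaluation.md").write_text("\n".join(lines))
            return reports

        artifacts["reports"] = stage("evaluate")(_evaluate)

    # ---- interpretability ------------------------------------------------
    if config.run_interpret and config.run_deep and "networks" in artifacts:
        def _interpret():
            net1 = artifacts["networks"]["net1_local_cnn"]
            cam = interpret_mod.gradcam3d(net1, model_inputs[0], endpoint="OS")
            cam.to_nifti(out_dir / "gradcam_net1.nii.gz")
            out = {"gradcam": cam}
            if "mmf" in scores["OS"] and "models" in artifacts:
                mmf = artifacts["models"]["mmf_OS"]
                cols = mmf.feature_names
                full = clin_df[ [c for c in cols if c != "ensemble_dl_signature"] ].copy()
                full.insert(0, "ensemble_dl_signature", scores["OS"]["ensemble_dl"])
                rows = full.iloc[list(val_idx)[:3] or [0]]
                bg = full.iloc[train_idx].head(50)
                rep = interpret_mod.shap_attributions(
                    lambda df: mmf.rsf.predict(df[cols].to_numpy(dtype=float)),
                    rows, bg, n_samples=max(2 * len(cols), 64), seed=config.seed)
                rep.to_csv(out_dir / "shap_mmf_os.csv")
                out["shap"] = rep
            if "ensemble_dl" in scores["OS"] and (out_dir / "features.tsv").exists():
                table = pd.read_csv(out_dir / "features.tsv", sep="\t", index_col=0)
                corr = interpret_mod.signature_feature_correlation(
                    scores["OS"]["ensemble_dl"], table)
                corr.to_csv(out_dir / "signature_correlation.csv")
                out["correlation"] = corr
            return out

        artifacts["interpret"] = stage("interpret")(_interpret)

    (out_dir / "timings.json").write_text(json.dumps(timings, indent=1))
    artifacts["timings"] = timings
    artifacts["scores"] = scores
    return artifacts
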