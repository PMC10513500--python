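"""End-to-end orchestration of the classification workflow.

simulate -> integrate (SNF label fusion) -> select-features (MAD + RF) ->
balance (SMOTE) -> train (7 families) -> evaluate, with every stage's
output persisted to a run directory together with a manifest of sha256
checksums and a log of all resolved parameters.

The fused labels are used for *training* only; evaluation always scores
predictions against the original labels (the label-switching asymmetry of
the fusion step must never leak into the reported metrics).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, features, integration, models, synthetic
from .config import RunConfig, dump_config

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic workflow; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("methsubtype")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: list[Path] = []
    try:
        logger.info("resolved config:\n%s", dump_config(cfg))
        (out / "config.yaml").write_text(dump_config(cfg))
        artifacts.append(out / "config.yaml")

        # ---- simulate ---------------------------------------------------
        spec = synthetic.SyntheticSpec(
            class_counts=cfg.class_counts,
            n_probes=cfg.n_probes,
            n_informative=cfg.n_informative,
            delta=cfg.delta,
            noise_sd=cfg.noise_sd,
            n_genes=cfg.n_genes,
            coupling=cfg.coupling,
            censor_rate=cfg.censor_rate,
            seed=cfg.stage_seed("simulate"),
        )
        omics = synthetic.generate_omics(spec)
        surv = synthetic.generate_survival(omics.labels, spec)
        paths = synthetic.write_dataset(omics, surv, out / "data")
        artifacts.extend(paths.values())
        logger.info("simulated cohort: %d samples, %d probes, %d genes",
                    len(omics.sample_ids), cfg.n_probes, cfg.n_genes)

        # ---- integrate --------------------------------------------------
        params = integration.SNFParams(
            K=cfg.k_neighbors, mu=cfg.mu, t=cfg.iterations, k_clusters=cfg.clusters
        )
        fused = integration.fuse_views(
            omics.beta.to_numpy().T, omics.expression.to_numpy().T, params
        )
        cluster_ids = integration.spectral_cluster(
            fused, cfg.clusters, seed=cfg.stage_seed("integrate")
        )
        fused_labels = integration.relabel_clusters(
            cluster_ids, omics.labels.to_numpy()
        )
        score = integration.nmi(fused_labels, omics.labels.to_numpy())
        logger.info("fusion NMI vs original labels: %.4f", score)
        labels_df = pd.DataFrame(
            {
                "sample_id": omics.sample_ids,
                "original": omics.labels.to_numpy(),
                "fused": fused_labels,
            }
        )
        labels_df.to_csv(out / "fused_labels.tsv", sep="\t", index=False)
        np.savetxt(out / "fused_affinity.tsv", fused, delimiter="\t")
        artifacts += [out / "fused_labels.tsv", out / "fused_affinity.tsv"]

        # ---- select features -------------------------------------------
        n_top = min(cfg.n_top, cfg.n_probes)
        mad_panel = features.mad_select(omics.beta, n_top=n_top)
        n_select = min(cfg.n_select, n_top)
        panel = features.rf_importance_select(
            omics.beta.loc[mad_panel],
            fused_labels,
            n_select=n_select,
            seed=cfg.stage_seed("select"),
        )
        (out / "panel.txt").write_text("\n".join(panel) + "\n")
        artifacts.append(out / "panel.txt")
        logger.info("feature chain: %d -> %d (MAD) -> %d (RF)",
                    cfg.n_probes, n_top, n_select)

        # ---- split + balance -------------------------------------------
        x = omics.beta.loc[panel].to_numpy().T
        y_train_source = fused_labels  # training labels come from the fusion
        y_original = omics.labels.to_numpy()
        split = features.split_data(
            x, y_original,
            features.SplitSpec(train_frac=cfg.train_frac, seed=cfg.stage_seed("split")),
        )
        smote_params = features.SmoteParams(
            k_neighbors=cfg.smote_k, perc_over=cfg.perc_over,
            seed=cfg.stage_seed("balance"),
        )
        counts = pd.Series(y_train_source[split["train"]]).value_counts()
        minority = counts.idxmin()
        if cfg.oversample_before_split:
            # oversample the full cohort before splitting (leakage-prone;
            # provided for workflow compatibility only)
            x_bal, y_bal = features.balance_classes(
                x, y_train_source, smote_params, minority=minority
            )
            x_train, y_train = x_bal, y_bal
            x_test, y_test = x[split["test"]], y_original[split["test"]]
        else:
            x_train, y_train = features.balance_classes(
                x[split["train"]], y_train_source[split["train"]],
                smote_params, minority=minority,
            )
            x_test, y_test = x[split["test"]], y_original[split["test"]]
        logger.info("training set after SMOTE: %d samples", len(y_train))

        # ---- train + evaluate ------------------------------------------
        metric_rows = {}
        for family in cfg.families:
            if family == "ANN":
                ann_cfg = models.AnnConfig(
                    layer_sizes=(40, 30, 10, len(np.unique(y_train))),
                    seed=cfg.stage_seed("train"),
                )
                model = models.train_ann(x_train, y_train, ann_cfg, feature_ids=panel)
            else:
                model = models.train_model(
                    x_train, y_train,
                    models.ModelConfig(family=family, seed=cfg.stage_seed("train")),
                    feature_ids=panel,
                )
            pred, probs, _ = models.predict(model, x_test)
            table = evaluate.metrics_table(y_test, pred, probs)
            table.to_csv(out / f"metrics_{family}.tsv", sep="\t")
            artifacts.append(out / f"metrics_{family}.tsv")
            metric_rows[family] = table.loc["macro"].to_dict()
            models.save_model(model, out / "models" / family)
        summary = pd.DataFrame(metric_rows).T
        summary.index.name = "family"
        summary.to_csv(out / "metrics_summary.tsv", sep="\t")
        artifacts.append(out / "metrics_summary.tsv")

        manifest = {
            "artifacts": {
                str(p.relative_to(out)): _checksum(p) for p in artifacts if p.exists()
            },
            "nmi_fused_vs_original": score,
            "n_samples": len(omics.sample_ids),
            "panel_size": len(panel),
            "seed": cfg.seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
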