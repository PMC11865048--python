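"""End-to-end orchestration of the synth -> preprocess -> augment -> split ->
train -> evaluate -> profile stages.

Each stage writes its artifacts (manifests, history, reports) under the
configured working directory together with the resolved configuration, so a
re-run with the same config and seed reproduces the manifests byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as aug
from . import preprocess as pre
from .config import PipelineConfig, save_config, stage_seed
from .evaluation import confusion_matrix, metrics_from_confusion
from .nn import build_network, mobilenet_v2_spec, profile, small_spec
from .synthetic import SyntheticSceneSpec, generate_dataset
from .training import evaluate_model, load_manifest_images, train

__all__ = ["run_pipeline", "STAGES", "network_spec_from_config"]

STAGES = ("synth", "preprocess", "augment", "split", "train", "evaluate", "profile")


class DependencyError(RuntimeError):
    """An upstream stage's artifact is missing."""


def network_spec_from_config(cfg: PipelineConfig):
    net = cfg.network
    if net.preset == "full":
        return mobilenet_v2_spec(net.n_classes, net.variant, net.input_size)
    if net.preset == "small":
        return replace(small_spec(net.n_classes, net.variant), input_size=net.input_size)
    raise ValueError(f"unknown network preset {net.preset!r}")


def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing artifact {path}; run the '{producer}' stage first")
    return path


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in canonical order; returns artifact paths."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    save_config(config, work / "config.yaml")
    artifacts: dict[str, object] = {"workdir": str(work)}

    if "synth" in stages:
        spec = SyntheticSceneSpec(
            image_size=(config.synth.image_size, config.synth.image_size),
            background_level=config.synth.background_level,
            n_classes=config.synth.n_classes)
        generate_dataset(spec, config.synth.counts_per_class, work / "raw",
                         seed=stage_seed(config.seed, "synth"),
                         class_names=config.synth.class_names)
        artifacts["raw_manifest"] = str(work / "raw" / "manifest.csv")

    if "preprocess" in stages:
        _need(work / "raw", "synth")
        pre.preprocess_directory(work / "raw", work / "crops", config.preprocess)
        artifacts["crop_manifest"] = str(work / "crops" / "manifest.csv")

    if "augment" in stages:
        src = _need(work / "crops" / "manifest.csv", "preprocess")
        manifest = pd.read_csv(src, dtype={"label": str}, keep_default_na=False)
        aug_cfg = replace(config.augment, rng_seed=stage_seed(config.seed, "augment"))
        aug.enhance_dataset(manifest, work / "enhanced", aug_cfg)
        artifacts["enhanced_manifest"] = str(work / "enhanced" / "manifest.csv")

    if "split" in stages:
        src = _need(work / "enhanced" / "manifest.csv", "augment")
        manifest = pd.read_csv(src, dtype={"label": str}, keep_default_na=False)
        parts = aug.split_dataset(manifest, config.split,
                                  seed=stage_seed(config.seed, "split"))
        for name, part in zip(("train", "val", "test"), parts):
            part.to_csv(work / f"{name}.csv", index=False)
            artifacts[f"{name}_manifest"] = str(work / f"{name}.csv")

    if "train" in stages:
        tr = _need(work / "train.csv", "split")
        va = _need(work / "val.csv", "split")
        train_manifest = pd.read_csv(tr, dtype={"label": str}, keep_default_na=False)
        val_manifest = pd.read_csv(va, dtype={"label": str}, keep_default_na=False)
        spec = network_spec_from_config(config)
        model = build_network(spec, seed=stage_seed(config.seed, "init"))
        cfg = replace(config.train, input_size=spec.input_size,
                      rng_seed=stage_seed(config.seed, "train"))
        history, best_state = train(model, train_manifest, val_manifest, cfg)
        history.to_csv(work / "history.csv", index=False)
        np.savez(work / "checkpoint.npz", **best_state)
        (work / "network_spec.json").write_text(spec.to_json())
        artifacts["history"] = str(work / "history.csv")
        artifacts["checkpoint"] = str(work / "checkpoint.npz")

    if "evaluate" in stages:
        te = _need(work / "test.csv", "split")
        ckpt = _need(work / "checkpoint.npz", "train")
        from .nn.network import NetworkSpec
        spec = NetworkSpec.from_json((work / "network_spec.json").read_text())
        model = build_network(spec, seed=0)
        with np.load(ckpt) as state:
            model.load_state_dict(dict(state))
        test_manifest = pd.read_csv(te, dtype={"label": str}, keep_default_na=False)
        images, labels, class_names = load_manifest_images(test_manifest, spec.input_size)
        loss, acc, preds = evaluate_model(model, images, labels)
        cm = confusion_matrix(labels, preds, spec.n_classes)
        metrics = metrics_from_confusion(cm)
        report = work / "report"
        report.mkdir(exist_ok=True)
        pd.DataFrame(cm, index=class_names, columns=class_names).to_csv(
            report / "confusion_matrix.csv")
        pd.DataFrame({
            "class": class_names,
            "accuracy": metrics.accuracy.round(3),
            "precision": metrics.precision.round(3),
            "recall": metrics.recall.round(3),
            "f1": metrics.f1.round(3),
        }).to_csv(report / "metrics.csv", index=False)
        summary = {"test_loss": loss, "test_accuracy": acc,
                   "macro_precision": metrics.macro_precision,
                   "macro_recall": metrics.macro_recall,
                   "macro_f1": metrics.macro_f1}
        (report / "summary.json").write_text(json.dumps(summary, indent=2))
        artifacts["report"] = str(report)

    if "profile" in stages:
        rows = []
        for variant in ("baseline", "hp"):
            spec = mobilenet_v2_spec(config.network.n_classes, variant,
                                     config.network.input_size)
            prof = profile(build_network(spec, seed=0), spec.input_size)
            rows.append({"variant": variant, "params": prof.params,
                         "params_m": prof.params_m, "flops": prof.flops,
                         "flops_g": prof.flops_g})
        table = pd.DataFrame(rows)
        table.to_csv(work / "profile.csv", index=False)
        artifacts["profile"] = str(work / "profile.csv")
        artifacts["profile_table"] = table

    return artifacts
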