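"""End-to-end orchestration: phantoms (or images) through to the model study.

Stage order: simulate/load -> preprocess -> augment -> segment ->
extract features -> split + normalise -> train the 11-model bank ->
accuracy-thresholded stacked ensembles -> feature selection -> K-fold sweep.
Every stage's output is a pure function of (inputs, config, seed); the run
directory receives each intermediate plus a manifest of content hashes and a
final JSON report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as aug
from . import ensemble as ens
from . import features as feat
from . import phantom as ph
from . import preprocess as pre
from . import roi as roi_mod
from .io import array_hash, write_gray, write_json, write_mask

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "simulate_phantom_dataset", "run_pipeline"]

CLASS_NAMES = ("BC", "BM", "MC", "MM")
# class-specific lesion radii: calcifications small, masses large,
# malignant larger than benign
CLASS_LESION_RADII = {"BC": 5, "BM": 11, "MC": 8, "MM": 15}


@dataclass
class PipelineConfig:
    """All parameters of a full run, with published defaults where they exist."""

    input_dir: str | None = None  # None -> simulate phantoms
    n_per_class: int = 30
    image_size: int = 224
    enhance: pre.EnhanceParams = field(default_factory=pre.EnhanceParams)
    augment_set: aug.AugmentSet = field(default_factory=aug.AugmentSet)
    do_augment: bool = True
    segment_before_augment: bool = False  # ablation flag
    roi_delta: int = 10
    roi_min_region: int = 10
    roi_connectivity: int = 8
    test_fraction: float = 0.2
    ensemble_thresholds: tuple[float, ...] = (90.0, 93.0, 95.0)
    stack_cv: int = 10
    k_values: tuple[int, ...] = ens.DEFAULT_K_VALUES
    sweep_members: tuple[str, ...] = ("RF", "XGB")
    feature_selections: tuple[ens.FeatureSelectionConfig, ...] = (
        ens.FeatureSelectionConfig("rf_importance", threshold=0.045),
        ens.FeatureSelectionConfig("univariate", k=12),
        ens.FeatureSelectionConfig("correlation", threshold=0.01),
        ens.FeatureSelectionConfig("pca", n_components=10),
        ens.FeatureSelectionConfig("wrapper", threshold=0.01),
    )
    seed: int = 0


def simulate_phantom_dataset(
    n_per_class: int, image_size: int = 224, seed: int = 0
) -> tuple[list[np.ndarray], list[str], list[ph.PhantomTruth]]:
    """Seeded phantom set with class-dependent lesion geometry.

    Lesion radius encodes the class (small calcifications, large masses) and
    the lesion centre jitters around the breast core, so the downstream
    feature table genuinely separates the four classes.
    """
    rng = np.random.default_rng(seed)
    scale = image_size / 224.0
    jitter = max(2, int(15 * scale))
    images, labels, truths = [], [], []
    for ci, cname in enumerate(CLASS_NAMES):
        for i in range(n_per_class):
            radius = max(3, round(CLASS_LESION_RADII[cname] * scale))
            phantom_seed = int(rng.integers(0, 2**31 - 1))
            truth = None
            for _ in range(20):  # rejection-sample a valid lesion placement
                jr = int(rng.integers(-jitter, jitter + 1))
                jc = int(rng.integers(-jitter, int(1.7 * jitter) + 1))
                spec = ph.PhantomSpec(
                    width=image_size,
                    height=image_size,
                    lesion_center=(
                        image_size // 2 + jr,
                        int(0.25 * image_size) + jc,
                    ),
                    lesion_radius=radius,
                    rng_seed=phantom_seed,
                )
                try:
                    truth = ph.generate_phantom(spec)
                    break
                except ValueError:
                    continue
            if truth is None:
                spec = ph.PhantomSpec(
                    width=image_size,
                    height=image_size,
                    lesion_radius=radius,
                    rng_seed=phantom_seed,
                )
                truth = ph.generate_phantom(spec)
            images.append(truth.image)
            labels.append(cname)
            truths.append(truth)
    return images, labels, truths


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> dict:
    """Execute every stage and write intermediates, manifest and report."""
    run_dir = Path(run_dir)
    if config.input_dir is not None and not Path(config.input_dir).is_dir():
        raise FileNotFoundError(f"input directory {config.input_dir} not found")
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}}
    report: dict = {}

    # --- stage A: inputs
    if config.input_dir is None:
        images, labels, _ = simulate_phantom_dataset(
            config.n_per_class, config.image_size, config.seed
        )
    else:
        from .io import read_gray

        images, labels = [], []
        for class_dir in sorted(Path(config.input_dir).iterdir()):
            if not class_dir.is_dir():
                continue
            for f in sorted(class_dir.glob("*.png")):
                images.append(read_gray(f))
                labels.append(class_dir.name)
    manifest["stages"]["inputs"] = {
        "n_images": len(images),
        "hash": array_hash(np.concatenate([i.ravel() for i in images])),
    }

    # --- stage B: preprocess
    processed = pre.MammogramPreprocessor(
        gamma=config.enhance.gamma,
        clip_limit=config.enhance.clip_limit,
        tile_grid=config.enhance.tile_grid,
        border_thickness=config.enhance.border_thickness,
    ).fit(images).transform(images)
    write_gray(run_dir / "preprocessed" / "img_0000.png", processed[0])
    manifest["stages"]["preprocess"] = {
        "hash": array_hash(np.concatenate([i.ravel() for i in processed]))
    }

    # --- stage C: augment
    if config.do_augment:
        augset = aug.augment_dataset(processed, labels, config.augment_set)
        aug_images, aug_labels = augset.images, augset.labels
    else:
        aug_images, aug_labels = processed, labels
    manifest["stages"]["augment"] = {"n_images": len(aug_images)}

    # --- stage D: segment
    segmenter = roi_mod.RegionGrowingSegmenter(
        delta=config.roi_delta,
        min_region=config.roi_min_region,
        connectivity=config.roi_connectivity,
    ).fit(aug_images)
    rois = segmenter.transform(aug_images)
    write_mask(run_dir / "masks" / "img_0000.png", rois[0].mask)
    diag_path = run_dir / "threshold_diagnostics.jsonl"
    with diag_path.open("w") as fh:
        import json

        for i, r in enumerate(rois):
            fh.write(json.dumps({"image": i, **r.diagnostics.as_dict()}) + "\n")

    # --- stage E: features
    table = feat.build_feature_table(rois, aug_labels)
    table.to_csv(run_dir / "features.csv", index=False)
    manifest["stages"]["features"] = {
        "n_rows": len(table),
        "hash": array_hash(table[list(feat.FEATURE_NAMES)].to_numpy()),
    }

    # --- stage F: split, normalise, train bank
    train, test = ens.split_dataset(table, config.test_fraction, config.seed)
    train_n, scaler = feat.minmax_normalize(train)
    test_n, _ = feat.minmax_normalize(test, scaler)
    bank_report = ens.train_bank(
        train_n, test_n, ens.ModelBankConfig(rng_seed=config.seed)
    )
    report["models"] = {
        k: {m: v[m] for m in ("t_acc", "te_acc", "te_mcc", "te_f1", "auc")}
        for k, v in bank_report.items()
    }

    # --- stage F2: stacked ensembles at each threshold
    report["ensembles"] = {}
    for thr in config.ensemble_thresholds:
        key = f"threshold_{thr:g}"
        try:
            spec = ens.select_by_accuracy(bank_report, thr)
            stacked = ens.train_stacked(
                train_n, test_n, spec, seed=config.seed, cv=config.stack_cv
            )
        except ValueError as exc:
            logger.warning("ensemble at threshold %s skipped: %s", thr, exc)
            report["ensembles"][key] = {"members": [], "skipped": str(exc)}
            continue
        report["ensembles"][key] = stacked

    # --- stage G: feature selection
    report["feature_selection"] = []
    for cfg in config.feature_selections:
        cfg = ens.FeatureSelectionConfig(**{**asdict(cfg), "rng_seed": config.seed})
        try:
            filled = ens.select_features(train_n, cfg)
        except ValueError as exc:
            logger.warning("feature selection %s failed: %s", cfg.method, exc)
            continue
        entry = {
            "method": filled.method,
            "threshold": filled.threshold,
            "k": filled.k,
            "n_components": filled.n_components,
            "n_selected": len(filled.selected),
            "selected": list(filled.selected),
        }
        if filled.method != "pca":
            cols = list(filled.selected) + ["label"]
            sub_tr, sub_te = train_n[cols], test_n[cols]
            spec = ens.EnsembleSpec(0.0, config.sweep_members)
            entry["stacked"] = ens.train_stacked(
                sub_tr, sub_te, spec, seed=config.seed, cv=config.stack_cv
            )
        report["feature_selection"].append(entry)

    # --- stage H: K-fold sweep of the headline stack
    table_n, _ = feat.minmax_normalize(table)
    sweep_model = ens.AccuracyThresholdStackingClassifier(
        members=config.sweep_members,
        accuracy_threshold=None,
        stack_cv=min(config.stack_cv, 3),
        random_state=config.seed,
    )
    usable_k = [
        k
        for k in config.k_values
        if k <= table_n["label"].value_counts().min() or k == len(table_n)
    ]
    sweep = ens.kfold_sweep(table_n, sweep_model, tuple(usable_k), seed=config.seed)
    sweep.to_csv(run_dir / "kfold_sweep.csv", index=False)
    report["kfold"] = sweep.to_dict(orient="records")

    write_json(run_dir / "report.json", report)
    write_json(run_dir / "manifest.json", manifest)
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
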