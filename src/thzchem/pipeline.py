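"""End-to-end benchmark: simulate, label, train, infer, evaluate.

The default protocol mirrors a blind-test study design: per chemical, two
training scenes and one disjoint-seed test scene are simulated at the
default 96-dB-equivalent noise level; concealed (paper-covered) scenes of
the four energetic materials are reserved exclusively for testing.  Both
networks are trained on the uncovered training scenes only and then
evaluated, with full decision fusion and spatial post-processing, on the
held-out uncovered and covered scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from . import __version__ as _pkg_version
from .config import RunConfig, TrainConfig, config_hash, to_dict
from .evaluation import ConfusionMatrix, average_accuracy, confusion, per_class_accuracy
from .extraction import extract_cube
from .fusion import infer_cube
from .labeling import label_cube, merge_datasets
from .materials import BACKGROUND, EXPLOSIVE_CLASSES, CLASS_NAMES
from .models import ClassNet, EdgeNet, SupervisedDataset, train_model
from .simulate import BenchmarkConfig, BenchmarkPlan, make_benchmark, simulate_scene

#: EdgeNet class convention: row 0 = Edge, row 1 = Other
EDGE_CLASS, OTHER_CLASS = 0, 1


def default_run_config(seed: int = 0) -> RunConfig:
    """Desk-scale run configuration: full architectures, reduced epochs."""
    cfg = RunConfig(seed=seed)
    cfg.classnet_train = TrainConfig(epochs=30, seed=_derive_seed(seed, 10))
    cfg.edgenet_train = TrainConfig(epochs=40, seed=_derive_seed(seed, 11))
    return cfg


def _derive_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0]
               % (2**31))


@dataclass
class TrainingArtifacts:
    classnet: ClassNet
    edgenet: EdgeNet
    classnet_history: object
    edgenet_history: object
    classnet_dataset: SupervisedDataset
    edgenet_dataset: SupervisedDataset


def build_training_data(plan: BenchmarkPlan, cfg: RunConfig
                        ) -> Tuple[SupervisedDataset, SupervisedDataset]:
    """Simulate and label every training scene, returning the per-pulse
    chemical dataset and the per-pixel edge dataset."""
    pulse_sets = []
    edge_X, edge_y, edge_groups = [], [], []
    for scene in plan.train:
        cube = simulate_scene(scene, cfg.acquisition)
        grid = extract_cube(cube, cfg.extraction)
        ds = label_cube(grid, cube.ground_truth, cube.material_map,
                        cfg.labeling, covered=scene.covered, scene_id=scene.seed)
        pulse_sets.append(ds)
        ny, nx = grid.grid_shape
        stacks = grid.stacks().reshape(ny * nx, 8, -1)
        edge_labels = np.where(ds.edge_map.ravel(), EDGE_CLASS, OTHER_CLASS)
        edge_X.append(stacks)
        edge_y.append(edge_labels)
        edge_groups.append(np.full(ny * nx, scene.seed))
    merged = merge_datasets(pulse_sets)
    keep = merged.training_mask(include_edge_pixels=False)
    class_ds = SupervisedDataset(
        X=merged.X[keep], y=merged.y[keep], groups=merged.scene_ids[keep])
    edge_ds = SupervisedDataset(
        X=np.concatenate(edge_X), y=np.concatenate(edge_y),
        groups=np.concatenate(edge_groups))
    return class_ds, edge_ds


def train_networks(plan: BenchmarkPlan, cfg: RunConfig) -> TrainingArtifacts:
    class_ds, edge_ds = build_training_data(plan, cfg)
    classnet = ClassNet(cfg.classnet, seed=cfg.classnet_train.seed)
    edgenet = EdgeNet(cfg.edgenet, seed=cfg.edgenet_train.seed)
    classnet, chist = train_model(class_ds, classnet, cfg.classnet_train)
    edgenet, ehist = train_model(edge_ds, edgenet, cfg.edgenet_train)
    return TrainingArtifacts(classnet, edgenet, chist, ehist, class_ds, edge_ds)


def evaluate_split(scenes, arts: TrainingArtifacts, cfg: RunConfig,
                   include_classes=None) -> Dict:
    """Infer every scene of a split and aggregate a confusion matrix."""
    total: Optional[ConfusionMatrix] = None
    n_pixels = 0
    for scene in scenes:
        cube = simulate_scene(scene, cfg.acquisition)
        cmap = infer_cube(cube, arts.classnet, arts.edgenet,
                          cfg.extraction, cfg.fusion)
        cm = confusion(cmap.labels, cube.ground_truth, include_edge=False)
        n_pixels += int(cm.counts.sum())
        total = cm if total is None else ConfusionMatrix(
            total.counts + cm.counts, total.classes)
    if total is None:
        raise ValueError("empty split")
    if include_classes is None:
        present = total.counts.sum(axis=1) > 0
        include_classes = [c for c, p in zip(total.classes, present)
                           if p and c != 9]
    acc = per_class_accuracy(total)
    per_class = {
        CLASS_NAMES[c]: (None if np.isnan(acc[i]) else round(float(acc[i]) * 100, 4))
        for i, c in enumerate(total.classes)
    }
    avg = average_accuracy(total, include_classes) * 100.0
    return {
        "confusion": total.counts.tolist(),
        "confusion_classes": [CLASS_NAMES[c] for c in total.classes],
        "per_class_accuracy_pct": per_class,
        "average_accuracy_pct": round(float(avg), 4),
        "evaluated_classes": [CLASS_NAMES[c] for c in include_classes],
        "n_pixels": n_pixels,
    }


def run_benchmark(cfg: Optional[RunConfig] = None,
                  bench: Optional[BenchmarkConfig] = None,
                  out_dir=None) -> Tuple[Dict, TrainingArtifacts]:
    """Full protocol: train on uncovered scenes, blind-test on held-out
    uncovered and covered scenes.  Returns (metrics, trained models)."""
    cfg = cfg or default_run_config()
    cfg.validate()
    bench = bench or BenchmarkConfig(base_seed=_derive_seed(cfg.seed, 20))
    plan = make_benchmark(bench)
    arts = train_networks(plan, cfg)
    metrics: Dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "seeds": plan.all_seeds(),
        "version": _pkg_version,
        "uncovered": evaluate_split(
            plan.test_uncovered, arts, cfg,
            include_classes=list(range(8)) + [BACKGROUND]),
    }
    if plan.test_covered:
        metrics["covered"] = evaluate_split(
            plan.test_covered, arts, cfg,
            include_classes=list(EXPLOSIVE_CLASSES) + [BACKGROUND])
    if plan.test_cracked:
        metrics["cracked"] = evaluate_split(plan.test_cracked, arts, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True)
        with open(out_dir / "run_record.json", "w") as fh:
            json.dump({"config": to_dict(cfg), "config_hash": config_hash(cfg),
                       "version": _pkg_version}, fh, indent=2, sort_keys=True)
        arts.classnet_history.to_csv(out_dir / "classnet_history.csv", index=False)
        arts.edgenet_history.to_csv(out_dir / "edgenet_history.csv", index=False)
    return metrics, arts
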