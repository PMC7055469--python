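"""End-to-end orchestration: synthetic scenes -> patch dataset -> training
-> whole-image prediction -> label reconstruction -> counting -> report.

Every stage materializes its artefacts inside the output directory and is
skipped on rerun if its outputs already exist, so a run is resumable from
any intermediate stage and any stage's products can be inspected.  The full
run configuration and package version are serialized next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from . import evaluation, models, reconstruct, siliques, synth, tiling
from .patches import (assemble_patchsets, annotation_summary,
                      fit_normalization, read_annotations, split_images,
                      NormalizationStats)

log = logging.getLogger("podquant")


@dataclass
class RunConfig:
    out_dir: str = "podquant_run"
    seed: int = 0
    log_level: str = "INFO"

    # scene generation
    n_train_scenes: int = 16
    n_eval_scenes: int = 30
    scene: dict = field(default_factory=dict)   # SceneSpec overrides
    eval_pods_range: tuple[int, int] = (5, 25)  # n_siliques drawn per eval scene

    # patch dataset
    fractions: tuple[float, float, float] = (0.65, 0.20, 0.15)
    augment_per_point: int = 4

    # model / training
    arch: str = "densenet"
    layers_per_block: int = 12
    dropout_rate: float = 0.2
    epochs: int | None = None       # default: 15 LeNet / 30 dense network
    batch_size: int | None = None   # default: 64 LeNet / 8 dense network

    # counting
    angle_threshold: float = 0.05
    min_region_area: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.eval_pods_range = tuple(cfg.eval_pods_range)
        cfg.fractions = tuple(cfg.fractions)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["eval_pods_range"] = list(self.eval_pods_range)
        d["fractions"] = list(self.fractions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def model_configs(self):
        if self.arch == "lenet":
            arch_cfg = models.LeNetConfig()
            epochs = 15 if self.epochs is None else self.epochs
            batch = 64 if self.batch_size is None else self.batch_size
        elif self.arch == "densenet":
            arch_cfg = models.DenseNetConfig(
                layers_per_block=self.layers_per_block,
                dropout_rate=self.dropout_rate)
            epochs = 30 if self.epochs is None else self.epochs
            batch = 8 if self.batch_size is None else self.batch_size
        else:
            raise ValueError(f"unknown arch {self.arch!r}")
        train_cfg = models.TrainConfig(epochs=epochs, batch_size=batch,
                                       seed=self.seed)
        return arch_cfg, train_cfg

    def counter(self) -> siliques.CounterConfig:
        return siliques.CounterConfig(angle_threshold=self.angle_threshold,
                                      min_region_area=self.min_region_area)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _scene_spec(config: RunConfig, seed: int, **overrides) -> synth.SceneSpec:
    params = dict(config.scene)
    params.update(overrides)
    params["seed"] = int(seed)
    return synth.SceneSpec(**params)


def generate_scene_pool(config: RunConfig, out: Path):
    """Stage 1: render the training pool and held-out evaluation scenes."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x11]))
    train_dir, eval_dir = out / "scenes_train", out / "scenes_eval"
    marker = out / "scenes.json"
    if marker.exists():
        log.info("scenes already generated; skipping")
        return json.loads(marker.read_text())
    seeds = rng.integers(0, 2 ** 31 - 1, size=config.n_train_scenes
                         + config.n_eval_scenes)
    lo, hi = config.eval_pods_range
    info = {"train": [], "eval": []}
    for i in range(config.n_train_scenes):
        spec = _scene_spec(config, seeds[i])
        truth = synth.generate_scene(spec, image_id=f"train_{i:03d}")
        synth.save_scene(train_dir, truth)
        info["train"].append(truth.image_id)
    for i in range(config.n_eval_scenes):
        n_pods = int(rng.integers(lo, hi + 1))
        spec = _scene_spec(config, seeds[config.n_train_scenes + i],
                           n_siliques=n_pods)
        truth = synth.generate_scene(spec, image_id=f"eval_{i:03d}")
        synth.save_scene(eval_dir, truth)
        info["eval"].append(truth.image_id)
    marker.write_text(json.dumps(info))
    return info


def build_patch_dataset(config: RunConfig, out: Path, scene_info):
    """Stage 2: image-level split, patch extraction/augmentation, stats."""
    dataset_path = out / "patches.npz"
    stats_path = out / "normalization.json"
    if dataset_path.exists() and stats_path.exists():
        log.info("patch dataset exists; skipping")
        with np.load(dataset_path) as z:
            sets = {name: (z[f"{name}_x"], z[f"{name}_y"])
                    for name in ("train", "val", "test")}
        return sets, NormalizationStats.from_json(stats_path)

    train_dir = out / "scenes_train"
    ids = scene_info["train"]
    images, annotations = {}, []
    for image_id in ids:
        images[image_id] = np.asarray(Image.open(train_dir / f"{image_id}.png"))
        annotations.extend(
            read_annotations(train_dir / f"{image_id}_annotations.csv"))
    split = split_images(ids, config.fractions, seed=config.seed)
    sets = assemble_patchsets(images, annotations, split,
                              augment_per_point=config.augment_per_point,
                              seed=config.seed)
    sets.pop("n_border_skipped", None)
    stats = fit_normalization(sets["train"][0])
    stats.to_json(stats_path)
    np.savez_compressed(dataset_path, **{
        f"{name}_{part}": arr
        for name, (x, y) in sets.items()
        for part, arr in (("x", x), ("y", y))})
    annotation_summary(annotations).to_csv(out / "annotation_counts.csv",
                                           header=["n_annotations"])
    (out / "split.json").write_text(json.dumps({
        "train": list(split.train_ids), "val": list(split.val_ids),
        "test": list(split.test_ids)}))
    return sets, stats


def train_stage(config: RunConfig, out: Path, sets, stats):
    """Stage 3: train the configured classifier, keep best-validation weights."""
    model_path = out / "model.npz"
    if model_path.exists():
        log.info("model exists; skipping training")
        model, _, stats = models.load_model(model_path)
        return model, stats
    arch_cfg, train_cfg = config.model_configs()
    model = models.build_model(arch_cfg, seed=config.seed)
    norm = lambda x: np.asarray(
        (x.astype(np.float32) - np.asarray(stats.channel_means, np.float32))
        / np.asarray(stats.channel_sds, np.float32)
        - np.asarray(stats.mean_patch, np.float32))
    model, history = models.train_classifier(
        model, (norm(sets["train"][0]), sets["train"][1]),
        (norm(sets["val"][0]), sets["val"][1]), train_cfg)
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    models.save_model(model_path, model, train_cfg, stats)
    return model, stats


def predict_and_count(config: RunConfig, out: Path, model, stats, scene_info):
    """Stages 4-5: tile, classify, reconstruct and count each eval scene."""
    eval_dir = out / "scenes_eval"
    grids_dir = out / "grids"
    labels_dir = out / "labels"
    grids_dir.mkdir(exist_ok=True)
    labels_dir.mkdir(exist_ok=True)
    counter = config.counter()
    rows = []
    for image_id in scene_info["eval"]:
        grid_path = grids_dir / f"{image_id}.npz"
        label_path = labels_dir / f"{image_id}.png"
        if grid_path.exists():
            grid = tiling.load_grid(grid_path)
        else:
            image = np.asarray(Image.open(eval_dir / f"{image_id}.png"))
            grid = tiling.predict_image(model, image, stats)
            tiling.save_grid(grid_path, grid)
        if label_path.exists():
            labels = reconstruct.load_label_image(label_path)
        else:
            image = np.asarray(Image.open(eval_dir / f"{image_id}.png"))
            labels = reconstruct.reconstruct_labels(grid)
            # plant area is segmented from background first; the 4-class
            # labelling applies only inside it
            labels = reconstruct.mask_background(labels, image)
            reconstruct.save_label_image(label_path, labels)
        result = siliques.count_image(labels, counter)
        truth = synth.load_truth_summary(eval_dir / f"{image_id}_truth.json")
        rows.append({"image_id": image_id,
                     "true_count": truth["true_count"],
                     **result.summary()})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig):
    """Execute every stage; returns (results DataFrame, report dict)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "runconfig.yaml")
    (out / "VERSION").write_text(__version__)

    scene_info = generate_scene_pool(config, out)
    sets, stats = build_patch_dataset(config, out, scene_info)
    model, stats = train_stage(config, out, sets, stats)
    results = predict_and_count(config, out, model, stats, scene_info)
    results.to_csv(out / "results.csv", index=False)

    report = {"n_images": int(len(results))}
    if len(results) >= 3 and results["predicted_count"].std() > 0:
        agreement = evaluation.count_agreement(
            results["predicted_count"].to_numpy(),
            results["true_count"].to_numpy())
        report.update({
            "correlation_coefficient": agreement.correlation_coefficient,
            "r_squared": agreement.r_squared,
            "rmse": agreement.rmse,
        })
        evaluation.scatter_plot(out / "scatter.png",
                                results["predicted_count"].to_numpy(),
                                results["true_count"].to_numpy())
        evaluation.histogram_plot(out / "error_histogram.png",
                                  agreement.errors)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline finished: %s", report)
    return results, report
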