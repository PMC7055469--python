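"""Annotation I/O, dataset splitting, patch extraction and normalization.

Supervision is a set of clicked points, each labelling one of four
structural classes of the inflorescence: base (0), body (1), stem (2) and
tip (3).  Training examples are 50x50 windows centred on annotated points,
reduced to 32x32 by random cropping with random mirroring and 90-degree
rotation; validation and test examples take the centred 32x32 crop with no
augmentation.

Conventions: coordinates are 0-based with x = column and y = row; windows
are half-open.  Annotations closer than half a window to any border are
skipped rather than padded (padding would fabricate plant tissue).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_NAMES = ("base", "body", "stem", "tip")
CLASS_TO_CODE = {name: i for i, name in enumerate(CLASS_NAMES)}
N_CLASSES = 4

TRAIN_WINDOW = 50
PATCH_SIZE = 32


@dataclass(frozen=True)
class PointAnnotation:
    """One clicked pixel location with its class label."""

    image_id: str
    x: int
    y: int
    label: int

    def __post_init__(self):
        if self.label not in range(N_CLASSES):
            raise ValueError(f"label must be one of 0..3, got {self.label}")

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.label]


@dataclass(frozen=True)
class NormalizationStats:
    """Training-set statistics: per-channel mean/sd on raw intensities, and
    the mean patch computed on channel-standardized training patches."""

    channel_means: np.ndarray  # (3,)
    channel_sds: np.ndarray    # (3,)
    mean_patch: np.ndarray     # (32, 32, 3), in z-scored units

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "channel_means": np.asarray(self.channel_means).tolist(),
            "channel_sds": np.asarray(self.channel_sds).tolist(),
            "mean_patch": np.asarray(self.mean_patch).tolist(),
        }))

    @classmethod
    def from_json(cls, path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(channel_means=np.array(d["channel_means"]),
                   channel_sds=np.array(d["channel_sds"]),
                   mean_patch=np.array(d["mean_patch"]))


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    seed: int

    def split_of(self, image_id: str) -> str:
        for name in ("train", "val", "test"):
            if image_id in getattr(self, f"{name}_ids"):
                return name
        raise KeyError(image_id)


# ---------------------------------------------------------------------------
# annotation CSV round trip
# ---------------------------------------------------------------------------

_HEADER = ["image_id", "x", "y", "class_name"]


def write_annotations(path, annotations: list[PointAnnotation]) -> None:
    df = pd.DataFrame(
        [(a.image_id, a.x, a.y, a.class_name) for a in annotations],
        columns=_HEADER,
    )
    df.to_csv(path, index=False)


def read_annotations(path) -> list[PointAnnotation]:
    """Parse an annotation CSV (columns image_id,x,y,class_name).

    Malformed rows and unknown class names raise ``ValueError`` naming the
    offending line number (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _HEADER:
        raise ValueError(f"expected header {','.join(_HEADER)} in {path}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            x, y = int(row.x), int(row.y)
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: bad coordinates "
                             f"({row.x!r}, {row.y!r})") from exc
        if row.class_name not in CLASS_TO_CODE:
            raise ValueError(
                f"{path}: line {i}: unknown class {row.class_name!r} "
                f"(expected one of {', '.join(CLASS_NAMES)})")
        out.append(PointAnnotation(row.image_id, x, y,
                                   CLASS_TO_CODE[row.class_name]))
    return out


def annotation_summary(annotations: list[PointAnnotation]) -> pd.Series:
    """Per-class annotation counts (bookkeeping mirrored in run reports)."""
    counts = pd.Series(0, index=list(CLASS_NAMES), dtype=int)
    for a in annotations:
        counts[a.class_name] += 1
    return counts


# ---------------------------------------------------------------------------
# image-level split
# ---------------------------------------------------------------------------

def _largest_remainder_sizes(n: int, fractions) -> list[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainder = n - sum(sizes)
    # distribute leftovers by largest fractional part, ties to later
    # partitions; round to suppress float noise in equal remainders
    order = sorted(range(len(fractions)),
                   key=lambda i: (round(exact[i] - sizes[i], 9), i),
                   reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_images(image_ids, fractions=(0.65, 0.20, 0.15), seed: int = 0
                 ) -> SplitAssignment:
    """Randomly split image ids into train/val/test at the image level.

    Sizes follow largest-remainder rounding with ties resolved in favour of
    later partitions; the assignment is invariant to the input ordering of
    ids (they are sorted before seeding) and deterministic for a fixed seed.
    """
    ids = sorted(set(map(str, image_ids)))
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(ids) < len(fractions):
        raise ValueError(f"need at least {len(fractions)} image ids, got {len(ids)}")
    sizes = _largest_remainder_sizes(len(ids), fractions)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5117]))
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    n_tr, n_va, _ = sizes
    return SplitAssignment(
        train_ids=tuple(shuffled[:n_tr]),
        val_ids=tuple(shuffled[n_tr:n_tr + n_va]),
        test_ids=tuple(shuffled[n_tr + n_va:]),
        fractions=tuple(fractions),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# patch extraction and augmentation
# ---------------------------------------------------------------------------

class BorderAnnotationError(ValueError):
    """Annotation too close to an image border for a full window."""


def extract_training_patch(image: np.ndarray, ann: PointAnnotation,
                           window: int = TRAIN_WINDOW) -> np.ndarray:
    """Window rows [y-w/2, y+w/2), cols [x-w/2, x+w/2) around the annotation."""
    half = window // 2
    h, w = image.shape[:2]
    if not (half <= ann.y <= h - (window - half)
            and half <= ann.x <= w - (window - half)):
        raise BorderAnnotationError(
            f"annotation at ({ann.x}, {ann.y}) within {half} px of border "
            f"of {w}x{h} image")
    return image[ann.y - half:ann.y + (window - half),
                 ann.x - half:ann.x + (window - half)].copy()


def augment(patch50: np.ndarray, rng: np.random.Generator,
            out_size: int = PATCH_SIZE) -> np.ndarray:
    """Random 32x32 crop, then mirror with probability 1/2, then k*90 rotation."""
    if patch50.shape[:2] != (TRAIN_WINDOW, TRAIN_WINDOW):
        raise ValueError(f"expected {TRAIN_WINDOW}x{TRAIN_WINDOW} input, "
                         f"got {patch50.shape[:2]}")
    max_off = TRAIN_WINDOW - out_size
    oy, ox = rng.integers(0, max_off + 1, size=2)
    out = patch50[oy:oy + out_size, ox:ox + out_size]
    if rng.random() < 0.5:
        out = out[:, ::-1]
    out = np.rot90(out, k=int(rng.integers(0, 4)))
    return np.ascontiguousarray(out)


def center_crop(patch50: np.ndarray, out_size: int = PATCH_SIZE) -> np.ndarray:
    """Centred 32x32 crop used for validation/test patches (no augmentation)."""
    if patch50.shape[:2] != (TRAIN_WINDOW, TRAIN_WINDOW):
        raise ValueError(f"expected {TRAIN_WINDOW}x{TRAIN_WINDOW} input")
    off = (TRAIN_WINDOW - out_size) // 2
    return np.ascontiguousarray(patch50[off:off + out_size, off:off + out_size])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def fit_normalization(train_patches: np.ndarray) -> NormalizationStats:
    """Fit channel mean/sd and the mean patch on training patches only.

    The mean patch is computed after channel standardization, matching the
    order in which the two normalizations are applied to every patch fed to
    a model (z-score, then mean-patch subtraction).
    """
    x = np.asarray(train_patches, dtype=np.float64)
    if x.ndim != 4 or x.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(f"expected (N, 32, 32, 3) patches, got {x.shape}")
    means = x.mean(axis=(0, 1, 2))
    sds = x.std(axis=(0, 1, 2))
    if np.any(sds <= 0):
        raise ValueError("zero channel standard deviation: degenerate "
                         "(constant) training data")
    z = (x - means) / sds
    return NormalizationStats(channel_means=means, channel_sds=sds,
                              mean_patch=z.mean(axis=0))


def apply_normalization(patch: np.ndarray, stats: NormalizationStats,
                        mode: str = "zscore_then_mean_patch") -> np.ndarray:
    """Normalize a patch (or a batch of patches).

    Modes: ``channel_zscore`` applies (x - mean)/sd per channel;
    ``mean_patch`` subtracts the mean patch; ``zscore_then_mean_patch``
    (default, the model-input pipeline) composes the two in that order.
    """
    x = np.asarray(patch, dtype=np.float32)
    if x.shape[-1] != 3:
        raise ValueError(f"expected trailing channel axis of 3, got {x.shape}")
    means = np.asarray(stats.channel_means, dtype=np.float32)
    sds = np.asarray(stats.channel_sds, dtype=np.float32)
    if mode == "channel_zscore":
        return (x - means) / sds
    mean_patch = np.asarray(stats.mean_patch, dtype=np.float32)
    if x.shape[-3:] != mean_patch.shape:
        raise ValueError(f"patch shape {x.shape} does not match mean patch "
                         f"{mean_patch.shape}")
    if mode == "mean_patch":
        return x - mean_patch
    if mode == "zscore_then_mean_patch":
        return (x - means) / sds - mean_patch
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def save_patchset_dir(out_dir, sets) -> "pd.DataFrame":
    """Write a patch dataset as a directory of PNGs plus an index CSV.

    The index has columns path,label,split; the NPZ-style bundle written
    by the pipeline is the compact alternative for the same data.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    k = 0
    for split_name in ("train", "val", "test"):
        x, y = sets[split_name]
        for patch, label in zip(x, y):
            rel = f"patch_{k:06d}.png"
            Image.fromarray(np.asarray(patch, dtype=np.uint8)).save(
                out_dir / rel)
            rows.append({"path": rel, "label": int(label),
                         "split": split_name})
            k += 1
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "index.csv", index=False)
    return index


def load_patchset_dir(in_dir):
    """Inverse of :func:`save_patchset_dir`."""
    from PIL import Image

    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "index.csv")
    sets = {}
    for split_name in ("train", "val", "test"):
        part = index[index["split"] == split_name]
        xs = [np.asarray(Image.open(in_dir / rel)) for rel in part["path"]]
        x = (np.stack(xs).astype(np.uint8) if xs
             else np.zeros((0, PATCH_SIZE, PATCH_SIZE, 3), dtype=np.uint8))
        sets[split_name] = (x, part["label"].to_numpy(dtype=np.int64))
    return sets


def assemble_patchsets(images: dict[str, np.ndarray],
                       annotations: list[PointAnnotation],
                       split: SplitAssignment,
                       augment_per_point: int = 4,
                       seed: int = 0):
    """Build (patches, labels) arrays per split.

    Training points contribute ``augment_per_point`` augmented 32x32 crops
    each; validation and test points contribute the single centred crop.
    Border-adjacent annotations are skipped.  Returns a dict
    ``{"train"|"val"|"test": (X, y)}`` with X uint8 (N, 32, 32, 3).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA6]))
    sets = {name: ([], []) for name in ("train", "val", "test")}
    membership = {}
    for name in ("train", "val", "test"):
        for image_id in getattr(split, f"{name}_ids"):
            membership[image_id] = name
    n_skipped = 0
    for ann in annotations:
        name = membership.get(ann.image_id)
        if name is None:
            continue
        try:
            p50 = extract_training_patch(images[ann.image_id], ann)
        except BorderAnnotationError:
            n_skipped += 1
            continue
        xs, ys = sets[name]
        if name == "train":
            for _ in range(augment_per_point):
                xs.append(augment(p50, rng))
                ys.append(ann.label)
        else:
            xs.append(center_crop(p50))
            ys.append(ann.label)
    out = {}
    for name, (xs, ys) in sets.items():
        x = (np.stack(xs).astype(np.uint8) if xs
             else np.zeros((0, PATCH_SIZE, PATCH_SIZE, 3), dtype=np.uint8))
        out[name] = (x, np.array(ys, dtype=np.int64))
    out["n_border_skipped"] = n_skipped
    return out
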