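"""Label-image reconstruction from overlapping tile predictions.

Because tiles overlap by 50% in both directions, every tile splits into
four 16x16 sub-patches, and each interior sub-patch is covered by four
tiles.  The sub-patch label is decided by majority vote over the argmax
classes of its covering foreground tiles; vote ties are broken by the
highest mean probability of the tied classes across those same tiles, and
a residual exact tie falls to the lowest class code (deterministic).
A sub-patch is background iff all covering tiles were background-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .tiling import PatchPredictionGrid

BACKGROUND = 255
N_CLASSES = 4

# overlay palette: tip red, body green, base blue, stem white on black
OVERLAY_COLORS = {
    0: (0, 0, 255),     # base
    1: (0, 255, 0),     # body
    2: (255, 255, 255),  # stem
    3: (255, 0, 0),     # tip
    BACKGROUND: (0, 0, 0),
}


@dataclass
class LabelImage:
    """Per-sub-patch class assignment at 16x16-pixel resolution."""

    labels: np.ndarray  # (rows, cols) uint8 in {0,1,2,3,255}
    votes: np.ndarray   # (rows, cols) uint8, contributing foreground tiles

    @property
    def shape(self):
        return self.labels.shape


def vote_subpatch(class_votes, prob_rows) -> int:
    """Decide one sub-patch label from <=4 covering foreground tiles.

    ``class_votes``: argmax labels of the covering tiles;
    ``prob_rows``: their 4-class probability rows (same order).
    """
    class_votes = list(class_votes)
    if not class_votes:
        return BACKGROUND
    counts = np.bincount(class_votes, minlength=N_CLASSES)
    top = counts.max()
    tied = np.where(counts == top)[0]
    if len(tied) == 1:
        return int(tied[0])
    mean_p = np.mean(np.asarray(prob_rows, dtype=float), axis=0)
    tied_p = mean_p[tied]
    # residual exact tie -> lowest class code (argmax picks first maximum)
    return int(tied[int(np.argmax(tied_p))])


def reconstruct_labels(grid: PatchPredictionGrid) -> LabelImage:
    """Fuse the tile-prediction grid into a sub-patch label image.

    Sub-patch (r, c) collects votes from the up-to-4 tiles whose footprint
    contains it: tiles (i, j) with i in {r-1, r}, j in {c-1, c}.
    """
    gr, gc = grid.probs.shape[:2]
    rows, cols = gr + 1, gc + 1
    probs = grid.probs
    fg = grid.foreground
    argmax = probs.argmax(axis=2)

    # accumulators over the four covering-tile offsets
    vote_counts = np.zeros((rows, cols, N_CLASSES), dtype=np.int32)
    prob_sums = np.zeros((rows, cols, N_CLASSES), dtype=np.float64)
    n_votes = np.zeros((rows, cols), dtype=np.int32)
    onehot = np.eye(N_CLASSES, dtype=np.int32)[argmax] * fg[..., None]
    masked_probs = probs * fg[..., None]
    for di in (0, 1):
        for dj in (0, 1):
            sl = (slice(di, di + gr), slice(dj, dj + gc))
            vote_counts[sl] += onehot
            prob_sums[sl] += masked_probs
            n_votes[sl] += fg

    labels = np.full((rows, cols), BACKGROUND, dtype=np.uint8)
    covered = n_votes > 0
    top = vote_counts.max(axis=2)
    is_top = vote_counts == top[..., None]
    single = is_top.sum(axis=2) == 1
    maj = covered & single
    labels[maj] = vote_counts[maj].argmax(axis=1)
    tie = covered & ~single
    if np.any(tie):
        # among tied classes, highest mean probability wins; np.argmax
        # resolves residual exact ties to the lowest class code
        mean_p = prob_sums[tie] / n_votes[tie][:, None]
        mean_p[~is_top[tie]] = -np.inf
        labels[tie] = mean_p.argmax(axis=1)
    return LabelImage(labels=labels,
                      votes=n_votes.astype(np.uint8))


def upsample_labels(label_image: LabelImage, subpatch_px: int = 16) -> np.ndarray:
    return np.kron(label_image.labels,
                   np.ones((subpatch_px, subpatch_px), dtype=np.uint8))


def render_overlay(label_image: LabelImage, subpatch_px: int = 16) -> np.ndarray:
    """Full-resolution RGB overlay (tip red, body green, base blue, stem white)."""
    up = upsample_labels(label_image, subpatch_px)
    rgb = np.zeros(up.shape + (3,), dtype=np.uint8)
    for code, color in OVERLAY_COLORS.items():
        rgb[up == code] = color
    return rgb


def save_label_image(path, label_image: LabelImage) -> None:
    Image.fromarray(label_image.labels).save(path)


def load_label_image(path) -> LabelImage:
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    votes = np.zeros_like(labels)
    votes[labels != BACKGROUND] = 4
    return LabelImage(labels=labels, votes=votes)


def mask_background(label_image: LabelImage, image: np.ndarray,
                    subpatch_px: int = 16, white_level: int = 230,
                    min_plant_fraction: float = 0.15) -> LabelImage:
    """Restrict class labels to plant regions found by pixel thresholding.

    Plant area is segmented from the white background first, by simple
    thresholding on raw intensities (a pixel is plant when its minimum
    channel falls below ``white_level``); the four-class labelling then
    applies only there.  Without this step, tiles that catch a sliver of a
    pod at their border spread class labels into the white halo around
    every organ, fusing neighbouring pods into single regions.

    Sub-patches whose pixel block holds less than ``min_plant_fraction``
    plant pixels become background; votes are zeroed there.
    """
    plant = (image.min(axis=-1) < white_level).astype(np.uint8)
    plant_frac = downsample_mask(
        np.where(plant, 0, BACKGROUND).astype(np.uint8),
        subpatch_px=subpatch_px, min_plant_fraction=min_plant_fraction)
    rows, cols = label_image.shape
    keep = np.zeros((rows, cols), dtype=bool)
    pr = min(rows, plant_frac.shape[0])
    pc = min(cols, plant_frac.shape[1])
    keep[:pr, :pc] = plant_frac.labels[:pr, :pc] != BACKGROUND
    labels = np.where(keep, label_image.labels, BACKGROUND).astype(np.uint8)
    votes = np.where(keep, label_image.votes, 0).astype(np.uint8)
    return LabelImage(labels=labels, votes=votes)


# ---------------------------------------------------------------------------
# ground-truth pathway: downsample a per-pixel mask to sub-patch labels
# ---------------------------------------------------------------------------

def downsample_mask(mask: np.ndarray, subpatch_px: int = 16,
                    min_plant_fraction: float = 0.15) -> LabelImage:
    """Reduce a per-pixel class mask to the sub-patch lattice.

    A sub-patch whose plant-pixel fraction reaches ``min_plant_fraction``
    takes the modal plant class of its block; otherwise it is background.
    This is the oracle pathway that lets the counting stage run on perfect
    labels, bypassing the classifier.
    """
    h, w = mask.shape
    hp = subpatch_px * int(np.ceil(h / subpatch_px))
    wp = subpatch_px * int(np.ceil(w / subpatch_px))
    padded = np.full((hp, wp), BACKGROUND, dtype=np.uint8)
    padded[:h, :w] = mask
    rows, cols = hp // subpatch_px, wp // subpatch_px
    blocks = padded.reshape(rows, subpatch_px, cols, subpatch_px)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(rows, cols, -1)
    counts = np.stack([(blocks == c).sum(axis=2) for c in range(N_CLASSES)],
                      axis=2)
    plant = counts.sum(axis=2)
    labels = np.full((rows, cols), BACKGROUND, dtype=np.uint8)
    enough = plant >= min_plant_fraction * subpatch_px * subpatch_px
    labels[enough] = counts[enough].argmax(axis=1)
    votes = np.where(labels != BACKGROUND, 4, 0).astype(np.uint8)
    return LabelImage(labels=labels, votes=votes)
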