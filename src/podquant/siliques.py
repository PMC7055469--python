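"""Silique assembly, overlap splitting, counting and length measurement.

A silique is an area composed of three interconnected parts — one tip, one
body and one base — with the body located between the tip and the base.
Candidate objects are grown from tip-body border contacts through shared
borders among plant-class regions; stem regions terminate growth (they
separate pods).  When a grown area holds multiple tips or bases, the
base-to-tip vectors of the potentially overlaid pods are compared: an
unsigned angle above the threshold (default 0.05 rad) keeps them as
distinct siliques, at or below it they are merged into one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .reconstruct import LabelImage, BACKGROUND

BASE, BODY, STEM, TIP = 0, 1, 2, 3
_PLANT_CLASSES = (BASE, BODY, STEM, TIP)
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class CounterConfig:
    angle_threshold: float = 0.05   # radians
    min_region_area: int = 2        # sub-patches
    subpatch_px: int = 16

    def __post_init__(self):
        if self.angle_threshold <= 0:
            raise ValueError("angle_threshold must be positive")


@dataclass(frozen=True)
class Region:
    """8-connected, single-class component of the label image."""

    cls: int
    cells: tuple[tuple[int, int], ...]  # (row, col) sub-patch coordinates

    @property
    def area(self) -> int:
        return len(self.cells)

    @property
    def centroid(self) -> np.ndarray:
        """(x, y) in sub-patch units."""
        arr = np.asarray(self.cells, dtype=float)
        return np.array([arr[:, 1].mean(), arr[:, 0].mean()])


@dataclass
class SiliqueObject:
    tip: Region
    base: Region
    bodies: tuple[Region, ...]
    vector: np.ndarray       # base centroid -> tip centroid, sub-patch units
    length: float            # full-resolution pixels
    merged_from: int = 1     # tip-base pairings merged by the angle rule

    @property
    def valid(self) -> bool:
        return self.length > 0

    @property
    def area(self) -> int:
        return self.tip.area + self.base.area + sum(b.area for b in self.bodies)


def extract_regions(labels: LabelImage, min_region_area: int = 2) -> list[Region]:
    """Per-class 8-connected components, dropping sub-threshold specks."""
    arr = labels.labels
    regions: list[Region] = []
    for cls in _PLANT_CLASSES:
        lab, n = ndimage.label(arr == cls, structure=_EIGHT)
        for idx in range(1, n + 1):
            cells = np.argwhere(lab == idx)
            if len(cells) < min_region_area:
                continue
            regions.append(Region(cls, tuple(map(tuple, cells))))
    return regions


def _adjacency(regions: list[Region]) -> dict[int, set[int]]:
    """8-adjacency between regions.

    Edge and corner contacts both count as shared borders: an elongated pod
    at a steep inclination regularly hands over from base to body (or body
    to tip) across a diagonal cell contact on the sub-patch lattice, and
    requiring an edge contact would sever such pods.
    """
    cellmap: dict[tuple[int, int], int] = {}
    for i, reg in enumerate(regions):
        for cell in reg.cells:
            cellmap[cell] = i
    adj: dict[int, set[int]] = {i: set() for i in range(len(regions))}
    for (r, c), i in cellmap.items():
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
            j = cellmap.get((r + dr, c + dc))
            if j is not None and j != i:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def build_candidates(regions: list[Region]) -> list[list[Region]]:
    """Grow candidate silique areas from tip-body contacts.

    Growth traverses shared borders between body and any of tip/body/base;
    stem regions are never traversed.  Each maximal grown set containing at
    least one tip, one body and one base is a candidate.
    """
    adj = _adjacency(regions)
    allowed: dict[int, set[int]] = {i: set() for i in range(len(regions))}
    for i, nbrs in adj.items():
        for j in nbrs:
            ci, cj = regions[i].cls, regions[j].cls
            if STEM in (ci, cj):
                continue
            if BODY in (ci, cj):  # body<->body, body<->tip, body<->base
                allowed[i].add(j)

    seen: set[int] = set()
    candidates = []
    for start in range(len(regions)):
        if start in seen or regions[start].cls == STEM:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in sorted(allowed[k]):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        classes = {regions[k].cls for k in comp}
        if {TIP, BODY, BASE} <= classes:
            candidates.append([regions[k] for k in sorted(comp)])
    return candidates


def pair_angle(u, v) -> float:
    """Unsigned angle between two vectors in [0, pi] via the cross product."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("pair_angle requires nonzero vectors")
    cross = u[0] * v[1] - u[1] * v[0]
    return float(np.arctan2(abs(cross), float(u @ v)))


def resolve_candidate(candidate: list[Region],
                      cfg: CounterConfig = CounterConfig()
                      ) -> list[SiliqueObject]:
    """Split or merge a candidate area into individual siliques.

    Each tip is paired with its nearest base (bases may be reused).  Any two
    pairings sharing a tip or base are compared by the unsigned angle of
    their base-to-tip vectors: above the threshold they stay distinct,
    otherwise they merge into one silique (the longer vector retained).
    Pairings are processed greedily in decreasing vector length.
    """
    tips = [r for r in candidate if r.cls == TIP]
    bases = [r for r in candidate if r.cls == BASE]
    bodies = tuple(r for r in candidate if r.cls == BODY)

    pairings = []
    for tip in tips:
        tc = tip.centroid
        dists = [np.linalg.norm(tc - b.centroid) for b in bases]
        base = bases[int(np.argmin(dists))]
        vec = tc - base.centroid
        pairings.append((tip, base, vec, float(np.linalg.norm(vec))))
    pairings.sort(key=lambda p: -p[3])

    siliques: list[SiliqueObject] = []
    for tip, base, vec, norm in pairings:
        merged = False
        for s in siliques:
            if s.tip is tip or s.base is base:
                if norm == 0 or np.linalg.norm(s.vector) == 0:
                    angle = 0.0
                else:
                    angle = pair_angle(vec, s.vector)
                if angle <= cfg.angle_threshold:
                    s.merged_from += 1
                    merged = True
                    break
        if not merged:
            siliques.append(SiliqueObject(
                tip=tip, base=base, bodies=bodies, vector=vec,
                length=norm * cfg.subpatch_px))
    return siliques


def measure_length(s: SiliqueObject, cfg: CounterConfig = CounterConfig()
                   ) -> float:
    """Euclidean base-to-tip centroid distance in full-resolution pixels."""
    return float(np.linalg.norm(s.vector) * cfg.subpatch_px)


@dataclass
class CountResult:
    count: int
    siliques: list[SiliqueObject]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.siliques if s.valid])

    def summary(self) -> dict:
        lengths = self.lengths
        return {
            "predicted_count": self.count,
            "mean_length_px": float(lengths.mean()) if lengths.size else np.nan,
            "max_length_px": float(lengths.max()) if lengths.size else np.nan,
            "min_length_px": float(lengths.min()) if lengths.size else np.nan,
        }


def count_image(labels: LabelImage,
                cfg: CounterConfig = CounterConfig()) -> CountResult:
    """Assemble, split and count siliques in a label image."""
    regions = extract_regions(labels, cfg.min_region_area)
    candidates = build_candidates(regions)
    siliques: list[SiliqueObject] = []
    for cand in candidates:
        siliques.extend(resolve_candidate(cand, cfg))
    return CountResult(count=len(siliques), siliques=siliques)


def silique_records(result: CountResult, image_id: str = "",
                    subpatch_px: int = 16):
    """Per-silique table: centroids (full-resolution px), vector, length."""
    import pandas as pd

    rows = []
    for s in result.siliques:
        bc = s.base.centroid * subpatch_px
        tc = s.tip.centroid * subpatch_px
        rows.append({
            "image_id": image_id,
            "base_x": bc[0], "base_y": bc[1],
            "tip_x": tc[0], "tip_y": tc[1],
            "vector_x": s.vector[0] * subpatch_px,
            "vector_y": s.vector[1] * subpatch_px,
            "length_px": s.length,
            "merged_from": s.merged_from,
        })
    return pd.DataFrame(rows, columns=["image_id", "base_x", "base_y",
                                       "tip_x", "tip_y", "vector_x",
                                       "vector_y", "length_px",
                                       "merged_from"])


def detection_overlay(labels: LabelImage, result: CountResult,
                      subpatch_px: int = 16) -> np.ndarray:
    """Binary full-resolution overlay with detected silique regions in white."""
    rows, cols = labels.shape
    out = np.zeros((rows, cols), dtype=np.uint8)
    for s in result.siliques:
        for reg in (s.tip, s.base, *s.bodies):
            for r, c in reg.cells:
                out[r, c] = 255
    return np.kron(out, np.ones((subpatch_px, subpatch_px), dtype=np.uint8))
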