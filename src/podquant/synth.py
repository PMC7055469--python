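"""Parametric synthetic inflorescence scenes with complete ground truth.

Scenes emulate flatbed scans of a mature *Arabidopsis* inflorescence on a
near-white background: a roughly vertical stem, and elongated pods
(siliques) attached to it by short pedicels, fanning upward-outward on
alternating sides.  Each pod is a capsule with a narrow pale stylar beak
at the distal end (tip class), blunt pale valve shoulders meeting the
pedicel at the proximal end (base class) and a chlorophyll-rich mid
section (body class).  Overlapping pod pairs share a base location with a
controlled inter-pod angle, the configuration the angle-threshold
splitting rule has to resolve downstream.

The two pod ends share one colour, so the hard tip-vs-base distinction is
separable only by end shape (thin beak vs wide shoulder with a stalk) and
the classifier is non-trivially exercised; body and stem carry their own
green hues, as in real maturing fruit.  The mask is rasterized without
anti-aliasing (hard labels); the photo image is rendered at 2x and
downsampled (anti-aliased), then perturbed with Gaussian intensity noise.

All randomness flows from the single integer seed in the scene spec.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .patches import PointAnnotation, write_annotations

# mask codes: {0 base, 1 body, 2 stem, 3 tip, 255 background}
BASE, BODY, STEM, TIP = 0, 1, 2, 3
BACKGROUND = 255

# Valves (body) are chlorophyll-rich; the stylar beak and the shoulder at
# the pedicel junction are paler, as in maturing fruit.  Tip and base share
# one colour, so that hard pair is separable by end shape only (beak vs
# shoulder+stalk); body and stem carry their own green hues.
END_COLOR = (96, 148, 72)    # tip and base
BODY_COLOR = (66, 134, 58)
STEM_COLOR = (50, 95, 50)

_MARGIN = 48          # px kept clear around the canvas
_STEM_WIDTH = 5
_PEDICEL_WIDTH = 3
_ANGLE_RANGE = (0.60, 1.15)   # pod inclination from vertical, radians
# Minimum capsule-to-capsule gap for pods not meant to overlap.  The label
# image downstream lives on a 16 px sub-patch lattice, and in the classifier
# pathway every 32 px tile votes its class onto all four of its sub-patches,
# so labelled regions dilate by up to ~1.5 cells on either side of a pod.
# Five cells of pixel clearance keep distinct pods from fusing into one
# region after that dilation.
_CLEARANCE = 80


class PlacementWarning(UserWarning):
    """Canvas could not accommodate every requested pod."""


@dataclass(frozen=True)
class SceneSpec:
    width: int = 1152
    height: int = 1536
    n_siliques: int = 12
    length_range: tuple[float, float] = (320.0, 460.0)
    pod_width_range: tuple[float, float] = (10.0, 14.0)
    n_overlap_pairs: int = 1
    overlap_angle_range: tuple[float, float] = (0.1, 0.5)
    tip_fraction: float = 0.15
    base_fraction: float = 0.14
    background_intensity: int = 245
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.tip_fraction + self.base_fraction < 1:
            raise ValueError("tip_fraction + base_fraction must lie in (0, 1)")
        lo, hi = self.overlap_angle_range
        if not (0 < lo <= hi < np.pi / 2):
            raise ValueError("overlap_angle_range must lie within (0, pi/2)")
        if self.n_siliques < 2 * self.n_overlap_pairs:
            raise ValueError("n_siliques must cover 2 pods per overlap pair")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] <= 0:
            raise ValueError("invalid length_range")
        if self.width < 2 * _MARGIN + 64 or self.height < 2 * _MARGIN + 64:
            raise ValueError("canvas too small")


@dataclass(frozen=True)
class PodGeometry:
    """Placement of one rendered pod; coordinates are (x, y) pixels."""

    attach: tuple[float, float]      # point on the stem
    base_start: tuple[float, float]  # proximal end of the capsule
    tip_end: tuple[float, float]     # apex
    length: float                    # drawn axis length, base_start -> apex
    width: float
    pair_id: int                     # -1 for singles; shared id within a pair

    @property
    def direction(self) -> np.ndarray:
        v = np.array(self.tip_end) - np.array(self.base_start)
        return v / np.linalg.norm(v)


@dataclass
class SceneTruth:
    image: np.ndarray                 # (H, W, 3) uint8
    mask: np.ndarray                  # (H, W) uint8, class codes above
    annotations: list[PointAnnotation]
    true_count: int
    silique_lengths: list[float]      # base-centre -> tip-centre distances
    pods: list[PodGeometry]
    spec: SceneSpec
    image_id: str
    n_requested: int

    @property
    def n_placed(self) -> int:
        return len(self.pods)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _seg_dist(p1, p2, q1, q2) -> float:
    """Minimum distance between 2D segments p1-p2 and q1-q2."""
    p1, p2, q1, q2 = (np.asarray(a, dtype=float) for a in (p1, p2, q1, q2))
    d1, d2 = p2 - p1, q2 - q1
    r = p1 - q1
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest = p1 + s * d1 - (q1 + t * d2)
    return float(np.linalg.norm(closest))


def _rotate(u: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])


def _in_bounds(points, width, height, margin=_MARGIN) -> bool:
    for x, y in points:
        if not (margin <= x <= width - margin and margin <= y <= height - margin):
            return False
    return True


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def scene_spec_for_count(n_siliques: int, seed: int, n_overlap_pairs: int = 0,
                         **overrides) -> SceneSpec:
    """A SceneSpec whose canvas height scales with the requested pod count.

    Attachment points alternate sides of the stem and same-side neighbours
    need enough vertical spacing to respect the placement clearance, so
    crowded scenes get a taller canvas instead of dropped pods.
    """
    n_attach = max(n_siliques - n_overlap_pairs, 1)
    height = max(1536, 100 * (n_attach - 1) + 520)
    height = 16 * int(np.ceil(height / 16))
    params = dict(n_siliques=n_siliques, n_overlap_pairs=n_overlap_pairs,
                  height=height, seed=seed)
    params.update(overrides)
    return SceneSpec(**params)


def generate_scene(spec: SceneSpec, image_id: str | None = None) -> SceneTruth:
    """Render one scene; bit-identical for a fixed ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5CE4]))
    if image_id is None:
        image_id = f"scene_{spec.seed:06d}"

    stem_pts = _stem_polyline(spec, rng)
    pods = _place_pods(spec, rng, stem_pts)
    if len(pods) < spec.n_siliques:
        warnings.warn(
            f"placed {len(pods)} of {spec.n_siliques} requested pods "
            f"(canvas too crowded)", PlacementWarning)

    image, mask = _rasterize(spec, rng, stem_pts, pods)

    truth = SceneTruth(
        image=image, mask=mask, annotations=[], true_count=len(pods),
        silique_lengths=[_truth_length(p, spec) for p in pods],
        pods=pods, spec=spec, image_id=image_id, n_requested=spec.n_siliques,
    )
    truth.annotations = scene_to_annotations(
        truth, points_per_body=len(pods), points_per_stem=len(pods))
    return truth


def _truth_length(pod: PodGeometry, spec: SceneSpec) -> float:
    """Ground-truth length: distance between the base-region and tip-region
    centres, the quantity the measurement stage estimates."""
    base_c = spec.base_fraction / 2.0
    tip_c = 1.0 - 2.0 * spec.tip_fraction / 3.0  # centroid of the tapered tip
    return float(pod.length * (tip_c - base_c))


def _stem_polyline(spec: SceneSpec, rng) -> np.ndarray:
    cx = spec.width / 2 + rng.uniform(-20, 20)
    ys = np.linspace(spec.height - _MARGIN, _MARGIN, 7)
    xs = cx + rng.uniform(-12, 12, size=ys.size)
    xs[0] = cx
    return np.column_stack([xs, ys])


def _stem_x_at(stem_pts: np.ndarray, y: float) -> float:
    return float(np.interp(y, stem_pts[::-1, 1], stem_pts[::-1, 0]))


def _place_pods(spec: SceneSpec, rng, stem_pts) -> list[PodGeometry]:
    n_pairs = spec.n_overlap_pairs
    n_attach = spec.n_siliques - n_pairs
    if n_attach == 0:
        return []
    lmax = spec.length_range[1]
    y_top = _MARGIN + (40 + lmax) * np.cos(0.85) + 10
    y_bot = spec.height - _MARGIN - 30
    ys = (np.linspace(y_bot, y_top, n_attach) if n_attach > 1
          else np.array([(y_bot + y_top) / 2]))
    spacing = (y_bot - y_top) / max(n_attach - 1, 1)
    ys = ys + rng.uniform(-0.15, 0.15, size=n_attach) * min(spacing, 40)
    sides = np.array([1 if i % 2 == 0 else -1 for i in range(n_attach)])

    # per-side inclination fan: lower pods more vertical, upper more
    # horizontal, so same-side neighbours diverge instead of crossing
    phis = np.empty(n_attach)
    for side in (1, -1):
        idx = np.where(sides == side)[0]  # ordered bottom -> top
        phis[idx] = np.sort(rng.uniform(*_ANGLE_RANGE, size=idx.size))

    pods: list[PodGeometry] = []
    for i in range(n_attach):
        attach_y = float(ys[i])
        attach = np.array([_stem_x_at(stem_pts, attach_y), attach_y])
        primary = _try_place(spec, rng, attach, sides[i], phis[i], pods,
                             exclude=None)
        if primary is not None:
            pods.append(primary)

    # attach overlap partners to whichever placed pods can host one
    for pair_id in range(n_pairs):
        # longer pods span more of the canopy and are the natural overlap
        # hosts; trying them first also keeps the paired tips resolvable
        hosts = sorted((k for k, p in enumerate(pods) if p.pair_id < 0),
                       key=lambda k: -pods[k].length)
        placed = False
        for host_idx in hosts:
            host = pods[host_idx]
            partner = _try_place_partner(spec, rng, host, pods, pair_id)
            if partner is not None:
                pods[host_idx] = PodGeometry(host.attach, host.base_start,
                                             host.tip_end, host.length,
                                             host.width, pair_id)
                pods.append(partner)
                placed = True
                break
        if not placed:
            break
    return pods


def _try_place(spec, rng, attach, side, phi, pods, exclude, tries=80):
    for attempt in range(tries):
        jitter = 0.06 + 0.004 * attempt  # widen the search as attempts fail
        phi_t = float(np.clip(phi + rng.uniform(-jitter, jitter), 0.3, 1.35))
        length = float(rng.uniform(*spec.length_range))
        width = float(rng.uniform(*spec.pod_width_range))
        ped = float(rng.uniform(32, 48))
        u = np.array([side * np.sin(phi_t), -np.cos(phi_t)])
        b = attach + ped * u
        t = b + length * u
        pod = PodGeometry(tuple(attach), tuple(b), tuple(t), length, width, -1)
        if _pod_ok(spec, pod, pods, exclude):
            return pod
    return None


def _try_place_partner(spec, rng, primary, pods, pair_id, tries=60):
    b = np.array(primary.base_start)
    u = primary.direction
    for attempt in range(tries):
        alpha = float(rng.uniform(*spec.overlap_angle_range))
        # overlapping pods grow from the same node and mature together, so
        # the partner's length stays close to its host's
        length = float(np.clip(primary.length - rng.uniform(0, 30),
                               *spec.length_range))
        for sign in rng.permutation([1.0, -1.0]):
            u2 = _rotate(u, sign * alpha)
            t2 = b + length * u2
            pod = PodGeometry(primary.attach, tuple(b), tuple(t2), length,
                              primary.width, pair_id)
            if _pod_ok(spec, pod, pods, exclude=primary):
                return pod
    return None


def _pod_ok(spec, pod, pods, exclude) -> bool:
    pts = [pod.base_start, pod.tip_end]
    if not _in_bounds(pts, spec.width, spec.height):
        return False
    for other in pods:
        if exclude is not None and other is exclude:
            continue
        d = _seg_dist(pod.base_start, pod.tip_end,
                      other.base_start, other.tip_end)
        if d < (pod.width + other.width) / 2 + _CLEARANCE:
            return False
    return True


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _capsule_quads(pod: PodGeometry, spec: SceneSpec):
    """Base quad, body quad, tip taper and beak for one pod (image coords)."""
    b = np.array(pod.base_start)
    u = pod.direction
    n = np.array([-u[1], u[0]]) * (pod.width / 2)
    p1 = b + spec.base_fraction * pod.length * u
    p2 = b + (1 - spec.tip_fraction) * pod.length * u
    t = np.array(pod.tip_end)
    # the proximal end carries blunt valve shoulders (the sepal-scar bulge
    # where the fruit meets its pedicel): slightly wider than the body and
    # rounded off.  This makes base ends blunt/bulged while tip ends taper
    # to a narrow beak, so the two pod ends stay distinguishable by shape
    # in any 32x32 window, exactly like real fruit.
    nb0 = n * 1.35
    base_quad = [tuple(b + nb0), tuple(p1 + n), tuple(p1 - n), tuple(b - nb0)]
    body_quad = [tuple(p1 + n), tuple(p2 + n), tuple(p2 - n), tuple(p1 - n)]
    # the distal segment is a narrow stylar beak: the valves shoulder in
    # abruptly at the tip onset and a thin pale spur runs to the apex, so
    # any window that contains tip pixels sees a thin pale line -- the
    # signature that separates tips from the wide pale base shoulders in
    # every orientation (stems and pedicels are thin but darker)
    shoulder = p2 + min(8.0, spec.tip_fraction * pod.length * 0.25) * u
    nb = n * (7.5 / max(pod.width, 1e-6))
    tip_tri = [tuple(p2 + n), tuple(shoulder + nb), tuple(shoulder - nb),
               tuple(p2 - n)]
    beak = (tuple(shoulder), tuple(t))
    return base_quad, body_quad, tip_tri, beak


def _rasterize(spec: SceneSpec, rng, stem_pts, pods):
    ss = 2  # supersampling factor for the photo image
    bg = int(spec.background_intensity)
    img = Image.new("RGB", (spec.width * ss, spec.height * ss), (bg, bg, bg))
    msk = Image.new("L", (spec.width, spec.height), BACKGROUND)
    di = ImageDraw.Draw(img)
    dm = ImageDraw.Draw(msk)

    def line(pts, width, color, code):
        pts_i = [tuple(np.asarray(p) * ss) for p in pts]
        di.line(pts_i, fill=color, width=int(round(width * ss)), joint="curve")
        dm.line([tuple(p) for p in pts], fill=code, width=int(round(width)),
                joint="curve")

    def poly(points, color, code):
        di.polygon([tuple(np.asarray(p) * ss) for p in points], fill=color)
        dm.polygon([tuple(p) for p in points], fill=code)

    def disc(center, radius, color, code):
        cx, cy = center
        di.ellipse([(cx - radius) * ss, (cy - radius) * ss,
                    (cx + radius) * ss, (cy + radius) * ss], fill=color)
        dm.ellipse([cx - radius, cy - radius, cx + radius, cy + radius],
                   fill=code)

    # draw order guarantees tips/bases are never buried under later bodies:
    # stem, pedicels, all bodies, all bases, all tips
    line([tuple(p) for p in stem_pts], _STEM_WIDTH, STEM_COLOR, STEM)
    geoms = [(_capsule_quads(p, spec), p) for p in pods]
    drawn_pairs = set()
    for (base_q, body_q, tip_t, beak), pod in geoms:
        if pod.pair_id < 0 or pod.pair_id not in drawn_pairs:
            # pedicels are stalk tissue: stem class, so they separate the
            # base blobs of neighbouring pods instead of chaining them
            line([pod.attach, pod.base_start], _PEDICEL_WIDTH, STEM_COLOR, STEM)
            drawn_pairs.add(pod.pair_id)
    for (base_q, body_q, tip_t, beak), pod in geoms:
        poly(body_q, BODY_COLOR, BODY)
    for (base_q, body_q, tip_t, beak), pod in geoms:
        poly(base_q, END_COLOR, BASE)
        # rounded shoulder cap at the pedicel junction
        disc(pod.base_start, pod.width * 0.68, END_COLOR, BASE)
    for (base_q, body_q, tip_t, beak), pod in geoms:
        poly(tip_t, END_COLOR, TIP)
        line(list(beak), 7.5, END_COLOR, TIP)

    image = np.asarray(
        img.resize((spec.width, spec.height), Image.BILINEAR), dtype=np.float64)
    if spec.noise_sd > 0:
        image = image + rng.normal(0, spec.noise_sd, size=image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    mask = np.asarray(msk, dtype=np.uint8)
    return image, mask


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def scene_to_annotations(truth: SceneTruth, points_per_body: int,
                         points_per_stem: int) -> list[PointAnnotation]:
    """Point annotations mirroring the sparse clicking style of a human
    annotator: one tip and one base point per pod (near the pod ends), plus
    randomly sampled interior body and stem points."""
    spec = truth.spec
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xA22]))
    anns: list[PointAnnotation] = []
    for pod in truth.pods:
        u = pod.direction
        # annotators click near the very ends: just inside the apex beak,
        # and on the shoulder right at the pedicel junction, so the
        # distinguishing end geometry sits inside the 32x32 crop window
        tip_pt = np.array(pod.tip_end) - 10.0 * u
        base_pt = np.array(pod.base_start) + 8.0 * u
        for pt, code in ((tip_pt, TIP), (base_pt, BASE)):
            x, y = int(round(pt[0])), int(round(pt[1]))
            x, y = _snap_to_class(truth.mask, x, y, code)
            anns.append(PointAnnotation(truth.image_id, x, y, code))
    # body points stay clear of the segment boundaries (shoulder and taper
    # onsets), where a window would straddle two classes
    exclude = []
    for pod in truth.pods:
        b = np.array(pod.base_start)
        u = pod.direction
        exclude.append(b + spec.base_fraction * pod.length * u)
        exclude.append(b + (1 - spec.tip_fraction) * pod.length * u)
    for code, n_points in ((BODY, points_per_body), (STEM, points_per_stem)):
        if n_points <= 0:
            continue
        anns.extend(_sample_class_points(
            truth, code, n_points, rng,
            exclude=exclude if code == BODY else None))
    return anns


def _snap_to_class(mask, x, y, code, radius=6):
    """Nudge a geometric point onto the nearest pixel of its class."""
    if mask[y, x] == code:
        return x, y
    h, w = mask.shape
    y0, y1 = max(0, y - radius), min(h, y + radius + 1)
    x0, x1 = max(0, x - radius), min(w, x + radius + 1)
    cand = np.argwhere(mask[y0:y1, x0:x1] == code)
    if cand.size == 0:  # fully overdrawn by a paired pod; keep original
        return x, y
    d = ((cand[:, 0] + y0 - y) ** 2 + (cand[:, 1] + x0 - x) ** 2)
    cy, cx = cand[np.argmin(d)]
    return int(cx + x0), int(cy + y0)


def _sample_class_points(truth: SceneTruth, code: int, n_points: int, rng,
                         exclude=None, exclude_radius: float = 22.0):
    h, w = truth.mask.shape
    pix = np.argwhere(truth.mask == code)
    if pix.size == 0:
        warnings.warn(f"class {code} absent from scene {truth.image_id}; "
                      "no annotations sampled", UserWarning)
        return []
    border = 26  # keep a full 50x50 window inside the canvas
    keep = ((pix[:, 0] >= border) & (pix[:, 0] < h - border)
            & (pix[:, 1] >= border) & (pix[:, 1] < w - border))
    pix = pix[keep]
    if exclude and len(pix):
        pts = np.asarray(exclude)  # (m, 2) as (x, y)
        d2 = ((pix[:, 1][:, None] - pts[None, :, 0]) ** 2
              + (pix[:, 0][:, None] - pts[None, :, 1]) ** 2)
        far = d2.min(axis=1) > exclude_radius ** 2
        if far.any():
            pix = pix[far]
    if len(pix) == 0:
        return []
    idx = rng.choice(len(pix), size=min(n_points, len(pix)), replace=False)
    return [PointAnnotation(truth.image_id, int(pix[i][1]), int(pix[i][0]), code)
            for i in idx]


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def save_scene(out_dir, truth: SceneTruth) -> dict[str, Path]:
    """Write image PNG, mask PNG, annotation CSV and a truth-summary JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{truth.image_id}.png",
        "mask": out_dir / f"{truth.image_id}_mask.png",
        "annotations": out_dir / f"{truth.image_id}_annotations.csv",
        "truth": out_dir / f"{truth.image_id}_truth.json",
    }
    Image.fromarray(truth.image).save(paths["image"])
    Image.fromarray(truth.mask).save(paths["mask"])
    write_annotations(paths["annotations"], truth.annotations)
    paths["truth"].write_text(json.dumps({
        "image_id": truth.image_id,
        "true_count": truth.true_count,
        "n_requested": truth.n_requested,
        "silique_lengths_px": truth.silique_lengths,
        "seed": truth.spec.seed,
    }, indent=2))
    return paths


def load_truth_summary(path) -> dict:
    return json.loads(Path(path).read_text())
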