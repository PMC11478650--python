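"""Synthetic dense-larvae scenes with exact ground truth.

The generator emulates top-lit grayscale photographs of shrimp larvae in a
shallow tray: each larva renders as a bright roughly circular head disc
(about 10x10 px) with a dimmer, tapering, slightly curved tail stroke on a
dark background.  Larvae deeper in the water render fainter (a per-larva
contrast factor), and global illumination scales the whole frame.  Ground
truth is one head box per larva — heads, not whole bodies, are annotated,
which is what a head-trained detector emits and what the stitching stage
consumes.

Three placement regimes mirror how real larvae arrange themselves:
isolated (head boxes disjoint from all others), clumped (placed within one
body length of an existing larva, head boxes still disjoint) and
overlapping (head box intersects an existing head box, as happens when
larvae at different depths project onto the same image location).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image

from .boxes import Box
from .formats import read_truth_csv, write_truth_csv, write_yolo_txt

ILLUMINATION_GAIN = {"bright": 1.25, "normal": 1.0, "dim": 0.6}

#: Study-scale field: 3000x3000 px ~ a 30x30 cm tray at 100 px/cm.
DEFAULT_FIELD_PX = 3000

#: Larvae per 3000x3000 px field at the four density levels.
DENSITY_LEVELS = {1: 1000, 2: 2300, 3: 4000, 4: 5000}
DENSITY_CLUMP_FRACTION = {1: 0.10, 2: 0.15, 3: 0.20, 4: 0.25}
DENSITY_OVERLAP_FRACTION = {1: 0.02, 2: 0.05, 3: 0.08, 4: 0.10}

PLACEMENT_RETRIES = 100


class SceneOverfullError(RuntimeError):
    """Raised when the requested density cannot be placed."""


@dataclass(frozen=True)
class SceneConfig:
    width_px: int = DEFAULT_FIELD_PX
    height_px: int = DEFAULT_FIELD_PX
    n_larvae: int = 1000
    clump_fraction: float = 0.10
    overlap_fraction: float = 0.02
    head_diameter_px: int = 10
    body_length_px: int = 30
    background_level: int = 40
    illumination: str = "normal"
    noise_sigma: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_larvae < 0:
            raise ValueError(f"n_larvae must be >= 0, got {self.n_larvae}")
        if self.head_diameter_px < 2:
            raise ValueError(f"head_diameter_px must be >= 2, got {self.head_diameter_px}")
        if self.width_px < self.head_diameter_px or self.height_px < self.head_diameter_px:
            raise ValueError("image dimensions must be >= head_diameter_px")
        for name in ("clump_fraction", "overlap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clump_fraction + self.overlap_fraction > 1.0 + 1e-12:
            raise ValueError("clump_fraction + overlap_fraction must be <= 1")
        if self.illumination not in ILLUMINATION_GAIN:
            raise ValueError(f"illumination must be one of {sorted(ILLUMINATION_GAIN)}")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be an intensity in [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.body_length_px < 1:
            raise ValueError("body_length_px must be >= 1")


@dataclass(frozen=True)
class LarvaInstance:
    head_center: Tuple[int, int]  # (x, y)
    orientation: float  # radians; direction the tail leaves the head
    body_length_px: int
    depth_factor: float  # contrast multiplier in (0, 1]; deeper = fainter
    curvature: float = 0.0  # tail bend, radians per pixel of arc length


@dataclass
class Scene:
    image: np.ndarray  # uint8, shape (height, width)
    truth_boxes: List[Box]
    instances: List[LarvaInstance]
    config: SceneConfig


def density_config(
    level: int,
    seed: int,
    field_px: int = DEFAULT_FIELD_PX,
    illumination: str = "normal",
) -> SceneConfig:
    """Study-condition config for one of the four density levels.

    ``n_larvae`` scales with field area so a smaller field keeps the same
    areal density as the 3000x3000 px reference.
    """
    if level not in DENSITY_LEVELS:
        raise ValueError(f"density level must be in {sorted(DENSITY_LEVELS)}, got {level}")
    scale = (field_px / DEFAULT_FIELD_PX) ** 2
    return SceneConfig(
        width_px=field_px,
        height_px=field_px,
        n_larvae=int(round(DENSITY_LEVELS[level] * scale)),
        clump_fraction=DENSITY_CLUMP_FRACTION[level],
        overlap_fraction=DENSITY_OVERLAP_FRACTION[level],
        illumination=illumination,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def _place_larvae(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer head centres; returns shape (n, 2) as (cx, cy)."""
    n = config.n_larvae
    h = config.head_diameter_px
    half = h // 2
    lo_x, hi_x = half, config.width_px - (h - half)  # inclusive range for cx
    lo_y, hi_y = half, config.height_px - (h - half)
    if hi_x < lo_x or hi_y < lo_y:
        raise SceneOverfullError("scene overfull: image smaller than one head box")

    n_overlap = int(round(config.overlap_fraction * n))
    n_clump = int(round(config.clump_fraction * n))
    if n_overlap + n_clump > n:
        n_clump = n - n_overlap
    categories = np.array([2] * n_overlap + [1] * n_clump + [0] * (n - n_overlap - n_clump))
    rng.shuffle(categories)

    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    for i in range(n):
        cat = int(categories[i]) if i > 0 else 0  # nothing to attach to yet
        placed = False
        for _ in range(PLACEMENT_RETRIES):
            if cat == 0:
                x = int(rng.integers(lo_x, hi_x + 1))
                y = int(rng.integers(lo_y, hi_y + 1))
            elif cat == 1:  # clumped: within one body length of an existing larva
                j = int(rng.integers(i))
                dist = rng.uniform(h, max(h + 1, config.body_length_px))
                ang = rng.uniform(0.0, 2.0 * math.pi)
                x = int(round(cx[j] + dist * math.cos(ang)))
                y = int(round(cy[j] + dist * math.sin(ang)))
            else:  # overlapping: head box intersects an existing head box
                j = int(rng.integers(i))
                x = int(cx[j] + rng.integers(-(h - 1), h))
                y = int(cy[j] + rng.integers(-(h - 1), h))
            if not (lo_x <= x <= hi_x and lo_y <= y <= hi_y):
                continue
            # head boxes are h-wide squares: two intersect iff both centre
            # offsets are < h; isolated and clumped larvae must stay disjoint
            if cat != 2 and i > 0:
                if np.any((np.abs(cx[:i] - x) < h) & (np.abs(cy[:i] - y) < h)):
                    continue
            cx[i], cy[i] = x, y
            placed = True
            break
        if not placed:
            raise SceneOverfullError(
                f"scene overfull: could not place larva {i + 1} of {n} "
                f"after {PLACEMENT_RETRIES} attempts"
            )
    return np.stack([cx, cy], axis=1)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _disk_offsets(radius: float) -> Tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    mask = (xx * xx + yy * yy) <= radius * radius
    return yy[mask].copy(), xx[mask].copy()


def _stamp_max(canvas: np.ndarray, cy: int, cx: int, radius: float, value: float) -> None:
    """Paint a disc by per-pixel maximum, clipped at the canvas edges."""
    dy, dx = _disk_offsets(radius)
    ys = dy + cy
    xs = dx + cx
    ok = (ys >= 0) & (ys < canvas.shape[0]) & (xs >= 0) & (xs < canvas.shape[1])
    ys, xs = ys[ok], xs[ok]
    canvas[ys, xs] = np.maximum(canvas[ys, xs], value)


def _render_larva(canvas: np.ndarray, larva: LarvaInstance, config: SceneConfig) -> None:
    bg = float(config.background_level)
    cx, cy = larva.head_center
    depth = larva.depth_factor
    head_radius = config.head_diameter_px / 2.0 - 0.5
    _stamp_max(canvas, cy, cx, head_radius, bg + 190.0 * depth)
    # tapering, gently curved tail drawn as a chain of small discs
    step = 1.5
    n_steps = max(2, int(round(larva.body_length_px / step)))
    theta = larva.orientation
    x = cx + head_radius * math.cos(theta)
    y = cy + head_radius * math.sin(theta)
    for k in range(n_steps):
        frac = k / max(1, n_steps - 1)
        radius = 2.0 if frac < 0.5 else 1.2
        value = bg + 70.0 * depth * (1.0 - 0.6 * frac)
        _stamp_max(canvas, int(round(y)), int(round(x)), radius, value)
        theta += larva.curvature * step
        x += step * math.cos(theta)
        y += step * math.sin(theta)


def generate_scene(config: SceneConfig) -> Scene:
    """Render a scene and its ground-truth head boxes, deterministically.

    The same seed and config always yield a byte-identical image and
    identical truth boxes.  Placement and per-larva appearance draws happen
    before illumination and noise, so varying only illumination (or only
    noise_sigma when sigma stays positive vs zero aside) leaves the truth
    boxes unchanged.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers = _place_larvae(config, rng)

    h = config.head_diameter_px
    half = h // 2
    img_bounds = Box(0, 0, config.width_px, config.height_px)
    truth: List[Box] = []
    instances: List[LarvaInstance] = []
    for cx, cy in centers:
        box = Box(cx - half, cy - half, cx - half + h, cy - half + h)
        clipped = box.clip(img_bounds)
        assert clipped is not None
        truth.append(clipped)
        instances.append(
            LarvaInstance(
                head_center=(int(cx), int(cy)),
                orientation=float(rng.uniform(0.0, 2.0 * math.pi)),
                body_length_px=config.body_length_px,
                depth_factor=float(rng.uniform(0.4, 1.0)),
                curvature=float(rng.uniform(-0.05, 0.05)),
            )
        )

    canvas = np.full((config.height_px, config.width_px), float(config.background_level))
    for inst in instances:
        _render_larva(canvas, inst, config)

    img = canvas * ILLUMINATION_GAIN[config.illumination]
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return Scene(image=image, truth_boxes=truth, instances=instances, config=config)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_scene(scene: Scene, image_path: Path, truth_path: Path) -> None:
    """Write the image as 8-bit grayscale PNG and the truth boxes twice: as
    CSV (exact pixel coordinates) and as YOLO darknet txt alongside the CSV
    (same stem, ``.txt`` suffix, normalised 6-decimal fixed point)."""
    image_path, truth_path = Path(image_path), Path(truth_path)
    try:
        Image.fromarray(scene.image, mode="L").save(image_path, format="PNG")
    except OSError as exc:
        raise OSError(f"cannot write image {image_path}: {exc}") from exc
    write_truth_csv(scene.truth_boxes, truth_path)
    yolo_path = truth_path.with_suffix(".txt")
    try:
        write_yolo_txt(
            scene.truth_boxes, yolo_path, scene.config.width_px, scene.config.height_px
        )
    except OSError as exc:
        raise OSError(f"cannot write YOLO txt {yolo_path}: {exc}") from exc


def load_scene_image(image_path: Path) -> np.ndarray:
    try:
        with Image.open(image_path) as im:
            return np.asarray(im.convert("L"))
    except OSError as exc:
        raise OSError(f"cannot read image {image_path}: {exc}") from exc


def load_truth(truth_path: Path) -> List[Box]:
    return read_truth_csv(truth_path)
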