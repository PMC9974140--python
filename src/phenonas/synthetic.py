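"""Synthetic rosette image generator.

Emulates the layout of top-down Arabidopsis thaliana phenotyping datasets
(CVPPP-style): for every plant an RGB image, a color-coded per-leaf label
image, and ground-truth genotype, leaf count and leaf area.  Five genotype
presets (col-0, ein2, pgm, ctr, adh1) differ in leaf-count range, leaf size,
shape and hue so that genotype is recoverable from the images by
construction.

Leaves are placed on a phyllotactic spiral: leaf ``i`` sits at azimuth
``i * phyllotaxis_angle`` (137.5 deg by default) with radial distance
increasing in ``i``, and is rendered as a filled ellipse.  Later leaves
occlude earlier ones; a leaf's area is its *visible* pixel count, and a leaf
occluded down to fewer than ``MIN_VISIBLE_PIXELS`` pixels is dropped from
both the label image and the ground truth.
"""

from __future__ import annotations

import colorsys
import csv
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GenotypeSpec",
    "LeafShape",
    "RosetteScene",
    "GroundTruth",
    "default_genotypes",
    "sample_scene",
    "render_scene",
    "generate_dataset",
    "MANIFEST_COLUMNS",
    "MIN_VISIBLE_PIXELS",
]

#: columns of the CSV manifest written by :func:`generate_dataset`
MANIFEST_COLUMNS = ("image_id", "genotype", "declared_leaf_count")

#: a leaf occluded below this visible-pixel count is removed from the
#: label image and from the ground truth
MIN_VISIBLE_PIXELS = 5

DEFAULT_CANVAS_SIZE = 128


@dataclass(frozen=True)
class GenotypeSpec:
    """Distributional parameters for one genotype's rosette geometry."""

    name: str
    leaf_count_range: tuple[int, int]
    leaf_length_scale: float  # semi-major axis scale, pixels
    leaf_aspect_ratio: float  # minor/major, dimensionless
    hue_range: tuple[float, float]  # degrees on the HSV wheel
    phyllotaxis_angle: float = 137.5  # degrees between successive leaves

    def __post_init__(self) -> None:
        lo, hi = self.leaf_count_range
        if not (1 <= lo <= hi):
            raise ValueError(f"leaf_count_range must satisfy 1 <= min <= max, got {self.leaf_count_range}")
        if self.leaf_length_scale <= 0:
            raise ValueError("leaf_length_scale must be positive")
        if not (0 < self.leaf_aspect_ratio <= 1):
            raise ValueError("leaf_aspect_ratio must be in (0, 1]")


def default_genotypes() -> list[GenotypeSpec]:
    """The five genotype presets, with pairwise-distinct (count range,
    length scale) combinations so the classes are separable from
    (leaf_count, leaf_area) alone."""
    return [
        GenotypeSpec("col-0", (8, 11), 30.0, 0.45, (95.0, 115.0)),
        GenotypeSpec("ein2", (4, 6), 38.0, 0.55, (85.0, 105.0)),
        GenotypeSpec("pgm", (10, 13), 22.0, 0.40, (100.0, 120.0)),
        GenotypeSpec("ctr", (5, 7), 26.0, 0.62, (90.0, 110.0)),
        GenotypeSpec("adh1", (12, 16), 16.0, 0.35, (105.0, 125.0)),
    ]


@dataclass(frozen=True)
class LeafShape:
    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (major, minor) pixels
    orientation: float  # radians, major-axis direction
    z_order: int  # draw rank; larger is drawn later (on top)
    hue: float = 110.0  # degrees, for RGB rendering

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be strictly positive")


@dataclass(frozen=True)
class RosetteScene:
    genotype_name: str
    leaves: tuple[LeafShape, ...]
    canvas_size: int

    def __post_init__(self) -> None:
        ranks = [leaf.z_order for leaf in self.leaves]
        if len(set(ranks)) != len(ranks):
            raise ValueError("z_order must be unique within a scene")
        for leaf in self.leaves:
            x, y = leaf.center
            if not (0 <= x < self.canvas_size and 0 <= y < self.canvas_size):
                raise ValueError(f"leaf center {leaf.center} outside canvas of size {self.canvas_size}")


@dataclass(frozen=True)
class GroundTruth:
    genotype_index: int  # 0..4 in default_genotypes order
    leaf_count: int  # visible leaves after occlusion
    leaf_area: int  # visible foreground pixels
    leaf_area_normalized: float  # leaf_area / canvas_size**2, in [0, 1]


def sample_scene(spec: GenotypeSpec, seed: int, canvas_size: int = DEFAULT_CANVAS_SIZE) -> RosetteScene:
    """Draw one rosette from a genotype's distribution.

    Deterministic given ``(spec, seed)``.  Leaf ``i`` is placed at azimuth
    ``i * spec.phyllotaxis_angle`` degrees; the radial distance of the leaf
    base grows strictly with ``i`` so younger leaves sit further out, as on
    a real rosette viewed top-down.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.leaf_count_range
    n_leaves = int(rng.integers(lo, hi + 1))
    cx = cy = canvas_size / 2.0

    # radial step sized so the outermost leaf tip stays inside the canvas
    max_radius = canvas_size / 2.0 - 2.0
    step = min(spec.leaf_length_scale * 0.22, (max_radius - spec.leaf_length_scale * 1.3) / max(n_leaves, 1))
    step = max(step, 0.5)

    leaves = []
    for i in range(n_leaves):
        azimuth = math.radians((i * spec.phyllotaxis_angle) % 360.0)
        base_r = 2.0 + step * i + float(rng.uniform(-0.3, 0.3)) * step
        major = spec.leaf_length_scale * float(rng.uniform(0.75, 1.05))
        minor = major * spec.leaf_aspect_ratio * float(rng.uniform(0.9, 1.1))
        # ellipse center sits one semi-major axis beyond the base point
        r_center = min(base_r + major, max_radius - 1.0)
        x = cx + r_center * math.cos(azimuth)
        y = cy + r_center * math.sin(azimuth)
        hue = float(rng.uniform(*spec.hue_range))
        leaves.append(
            LeafShape(
                center=(x, y),
                semi_axes=(major, max(minor, 1.0)),
                orientation=azimuth,
                z_order=i,
                hue=hue,
            )
        )
    return RosetteScene(genotype_name=spec.name, leaves=tuple(leaves), canvas_size=canvas_size)


def _ellipse_mask(leaf: LeafShape, size: int) -> np.ndarray:
    """Boolean mask of a rotated filled ellipse on a size x size canvas."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x0, y0 = leaf.center
    a, b = leaf.semi_axes
    ct, st = math.cos(leaf.orientation), math.sin(leaf.orientation)
    u = (xx - x0) * ct + (yy - y0) * st
    v = -(xx - x0) * st + (yy - y0) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _scene_digest(scene: RosetteScene, size: int) -> int:
    """Stable integer digest of scene geometry, used to seed render noise."""
    h = hashlib.sha256()
    h.update(scene.genotype_name.encode())
    h.update(np.int64(size).tobytes())
    for leaf in scene.leaves:
        h.update(np.array([*leaf.center, *leaf.semi_axes, leaf.orientation, leaf.hue], dtype=np.float64).tobytes())
    return int.from_bytes(h.digest()[:4], "little")


_BACKGROUND_RGB = np.array([38, 26, 18], dtype=np.float64)  # dark soil


def render_scene(scene: RosetteScene, size: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Paint a scene into ``(rgb_image, label_image)``.

    The label image is a ``size x size`` uint8 index map: 0 is background and
    each visible leaf holds one index in ``1..k``, assigned in z-order after
    dropping leaves occluded below :data:`MIN_VISIBLE_PIXELS`.  The RGB image
    is rendered from the same index map, so labels and pixels agree exactly;
    additive Gaussian noise is applied to the RGB channels only.
    """
    size = scene.canvas_size if size is None else size
    if size < 16:
        raise ValueError("render size must be >= 16")
    for leaf in scene.leaves:
        x, y = leaf.center
        if not (0 <= x < size and 0 <= y < size):
            raise ValueError(f"leaf center {leaf.center} outside canvas of size {size}")

    raw = np.zeros((size, size), dtype=np.int32)
    ordered = sorted(scene.leaves, key=lambda leaf: leaf.z_order)
    for idx, leaf in enumerate(ordered, start=1):
        raw[_ellipse_mask(leaf, size)] = idx

    # drop sub-threshold slivers, then compact indices to 1..k
    label = np.zeros_like(raw, dtype=np.uint8)
    kept: list[LeafShape] = []
    for idx, leaf in enumerate(ordered, start=1):
        visible = raw == idx
        if visible.sum() >= MIN_VISIBLE_PIXELS:
            kept.append(leaf)
            label[visible] = len(kept)

    rgb = np.tile(_BACKGROUND_RGB, (size, size, 1)).copy()
    for new_idx, leaf in enumerate(kept, start=1):
        r, g, b = colorsys.hsv_to_rgb(leaf.hue / 360.0, 0.75, 0.55)
        rgb[label == new_idx] = np.array([r, g, b]) * 255.0

    noise_rng = np.random.default_rng(_scene_digest(scene, size))
    rgb = rgb + noise_rng.normal(0.0, 4.0, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb, label


def ground_truth(label_image: np.ndarray, genotype_index: int) -> GroundTruth:
    """Derive the three task labels from a rendered label image."""
    values = np.unique(label_image)
    count = int((values != 0).sum())
    area = int((label_image != 0).sum())
    n = label_image.shape[0] * label_image.shape[1]
    return GroundTruth(genotype_index, count, area, area / n)


# 32-entry palette for indexed-color label PNGs; index 0 is black background.
def _label_palette(n: int = 32) -> list[int]:
    palette = [0, 0, 0]
    for i in range(1, n):
        r, g, b = colorsys.hsv_to_rgb((i * 0.37) % 1.0, 1.0, 1.0)
        palette += [int(r * 255), int(g * 255), int(b * 255)]
    return palette + [0] * (768 - 3 * n)


def save_label_png(label: np.ndarray, path: str | Path) -> None:
    img = Image.fromarray(label.astype(np.uint8), mode="P")
    img.putpalette(_label_palette())
    img.save(path)


def load_label_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as img:
        if img.mode != "P":
            raise ValueError(f"{path}: expected an indexed-color label PNG, got mode {img.mode}")
        return np.asarray(img, dtype=np.uint8)


def generate_dataset(
    out_dir: str | Path,
    n_plants: int,
    genotype_specs: list[GenotypeSpec] | None = None,
    seed: int = 0,
    canvas_size: int = DEFAULT_CANVAS_SIZE,
) -> list[dict]:
    """Write ``n_plants`` synthetic plants to ``out_dir``.

    Produces per plant ``<id>_rgb.png`` and ``<id>_label.png`` plus a
    ``manifest.csv`` with columns ``image_id,genotype,declared_leaf_count``.
    Genotypes are assigned round-robin; everything is deterministic given
    ``seed``.  Returns the manifest rows as a list of dicts.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    specs = list(default_genotypes() if genotype_specs is None else genotype_specs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_plants) % (2**31)
    rows: list[dict] = []
    for j in range(n_plants):
        spec = specs[j % len(specs)]
        scene = sample_scene(spec, int(child_seeds[j]), canvas_size)
        rgb, label = render_scene(scene)
        gt = ground_truth(label, specs.index(spec))
        image_id = f"plant_{j:04d}"
        Image.fromarray(rgb, mode="RGB").save(out_dir / f"{image_id}_rgb.png")
        save_label_png(label, out_dir / f"{image_id}_label.png")
        rows.append(
            {
                "image_id": image_id,
                "genotype": spec.name,
                "declared_leaf_count": gt.leaf_count,
            }
        )

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    return rows


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != MANIFEST_COLUMNS:
            raise ValueError(f"unexpected manifest columns: {reader.fieldnames}")
        return [
            {**row, "declared_leaf_count": int(row["declared_leaf_count"])}
            for row in reader
        ]
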