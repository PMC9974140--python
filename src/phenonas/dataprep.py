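"""Annotation pipeline: per-leaf masks, COCO JSON, Pascal VOC XML, cleaning.

Splits a color-coded segmentation label image into one binary mask per leaf,
serializes plant annotations to a single COCO JSON document (bounding box +
pixel area per leaf; genotype as a per-image attribute), converts that to
one Pascal-VOC-style XML per image, reads the XML back, and applies the
leaf-count consistency filter: a plant is kept only when the leaf count
derived from its label image equals the count declared in the dataset
manifest.

Coordinate conventions: internally bounding boxes are 0-based half-open
``(x_min, y_min, x_end, y_end)``; COCO uses ``[x, y, width, height]``; VOC
XML uses 1-based inclusive ``xmin/ymin/xmax/ymax``.  The VOC dialect here
adds one nonstandard ``area_px`` element per object so per-leaf pixel areas
survive the XML round trip.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import default_genotypes

__all__ = [
    "LeafInstance",
    "PlantAnnotation",
    "split_label_image",
    "annotate_plant",
    "to_coco",
    "coco_to_voc",
    "read_voc",
    "clean",
    "build_training_arrays",
    "KNOWN_GENOTYPES",
]

#: recognized genotype labels, index order fixed by the generator presets
KNOWN_GENOTYPES = tuple(g.name for g in default_genotypes())

_MAX_LABEL_COLORS = 64  # more distinct colors than this smells of antialiasing


@dataclass
class LeafInstance:
    """One leaf: binary mask, tight bounding box, pixel area.

    ``bbox`` is 0-based half-open ``(x_min, y_min, x_end, y_end)``.  ``mask``
    may be ``None`` for annotations reconstructed from formats that carry
    only boxes and areas (VOC).
    """

    leaf_id: int
    mask: np.ndarray | None
    bbox: tuple[int, int, int, int]
    area_px: int

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("area_px must be positive")
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if self.mask is not None:
            if int(self.mask.sum()) != self.area_px:
                raise ValueError("area_px does not match mask pixel count")


@dataclass
class PlantAnnotation:
    image_id: str
    image_path: str
    genotype: str
    width: int
    height: int
    leaf_instances: list[LeafInstance] = field(default_factory=list)
    declared_leaf_count: int | None = None

    def __post_init__(self) -> None:
        ids = [inst.leaf_id for inst in self.leaf_instances]
        if len(set(ids)) != len(ids):
            raise ValueError("leaf_ids must be unique within a plant")
        if self.genotype not in KNOWN_GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; known: {KNOWN_GENOTYPES}")

    @property
    def leaf_count(self) -> int:
        return len(self.leaf_instances)

    @property
    def total_area_px(self) -> int:
        return sum(inst.area_px for inst in self.leaf_instances)


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(mask)
    return (int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1)


def split_label_image(label_image: np.ndarray) -> list[LeafInstance]:
    """Split a label image into per-leaf binary masks.

    Accepts a 2-D index map (background 0) or a 3-D RGB array (background
    black).  Instances are ordered by the raster position of each color's
    first pixel; masks are pairwise disjoint by construction.  Truecolor
    input with an implausible number of distinct colors (antialiased edges)
    is rejected, naming the offending colors.
    """
    label_image = np.asarray(label_image)
    if label_image.ndim == 2:
        flat = label_image.astype(np.int64)
    elif label_image.ndim == 3 and label_image.shape[2] == 3:
        arr = label_image.astype(np.int64)
        flat = (arr[..., 0] << 16) | (arr[..., 1] << 8) | arr[..., 2]
        n_colors = len(np.unique(flat)) - int(0 in flat)
        if n_colors > _MAX_LABEL_COLORS:
            offenders = [v for v in np.unique(flat)[:8] if v != 0]
            named = ", ".join(f"#{v:06x}" for v in offenders)
            raise ValueError(
                f"truecolor label image has {n_colors} distinct non-background colors "
                f"(antialiased edges?); first offenders: {named}"
            )
    else:
        raise ValueError(f"expected a 2-D index map or HxWx3 RGB array, got shape {label_image.shape}")

    instances: list[LeafInstance] = []
    # first-occurrence raster order without a Python pixel loop
    raveled = flat.ravel()
    first_idx: dict[int, int] = {}
    values, first_positions = np.unique(raveled, return_index=True)
    for value, pos in zip(values, first_positions):
        if value != 0:
            first_idx[int(value)] = int(pos)
    for leaf_id, (value, _) in enumerate(sorted(first_idx.items(), key=lambda kv: kv[1]), start=1):
        mask = flat == value
        instances.append(
            LeafInstance(leaf_id=leaf_id, mask=mask, bbox=_tight_bbox(mask), area_px=int(mask.sum()))
        )
    return instances


def annotate_plant(
    image_id: str,
    image_path: str | Path,
    label_image: np.ndarray,
    genotype: str,
    declared_leaf_count: int | None = None,
) -> PlantAnnotation:
    """Convenience wrapper: split a label image and package the result."""
    h, w = np.asarray(label_image).shape[:2]
    return PlantAnnotation(
        image_id=image_id,
        image_path=str(image_path),
        genotype=genotype,
        width=w,
        height=h,
        leaf_instances=split_label_image(label_image),
        declared_leaf_count=declared_leaf_count,
    )


# ---------------------------------------------------------------------------
# COCO
# ---------------------------------------------------------------------------

def to_coco(annotations: list[PlantAnnotation]) -> dict:
    """Build a COCO document: one ``leaf`` category, bbox + area per leaf,
    genotype stored as a per-image attribute."""
    if not annotations:
        raise ValueError("annotations must be non-empty")
    ids = [a.image_id for a in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate image_ids: {dupes}")

    doc: dict = {
        "images": [],
        "annotations": [],
        "categories": [{"id": 1, "name": "leaf", "supercategory": "plant"}],
    }
    ann_id = 1
    for img_num, plant in enumerate(annotations, start=1):
        doc["images"].append(
            {
                "id": img_num,
                "file_name": plant.image_path,
                "plant_id": plant.image_id,
                "width": plant.width,
                "height": plant.height,
                "genotype": plant.genotype,
                "declared_leaf_count": plant.declared_leaf_count,
            }
        )
        for inst in plant.leaf_instances:
            x0, y0, x1, y1 = inst.bbox
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_num,
                    "category_id": 1,
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": inst.area_px,
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    return doc


# ---------------------------------------------------------------------------
# VOC
# ---------------------------------------------------------------------------

def coco_to_voc(coco_document: dict, out_dir: str | Path) -> list[Path]:
    """Write one Pascal-VOC-style XML per COCO image.

    Boxes become 1-based inclusive; each ``object`` additionally carries an
    ``area_px`` element (dialect extension, see module docstring).  Returns
    the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_image: dict[int, list[dict]] = {}
    for ann in coco_document.get("annotations", []):
        by_image.setdefault(ann["image_id"], []).append(ann)

    paths: list[Path] = []
    for image in coco_document["images"]:
        if "genotype" not in image or image["genotype"] is None:
            raise ValueError(f"image {image.get('plant_id', image['id'])} lacks a genotype attribute")
        root = ET.Element("annotation")
        ET.SubElement(root, "folder").text = str(out_dir)
        ET.SubElement(root, "filename").text = image["file_name"]
        ET.SubElement(root, "plant_id").text = str(image["plant_id"])
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(image["width"])
        ET.SubElement(size, "height").text = str(image["height"])
        ET.SubElement(size, "depth").text = "3"
        ET.SubElement(root, "genotype").text = image["genotype"]
        if image.get("declared_leaf_count") is not None:
            ET.SubElement(root, "declared_leaf_count").text = str(image["declared_leaf_count"])
        for ann in sorted(by_image.get(image["id"], []), key=lambda a: a["id"]):
            x, y, w, h = ann["bbox"]
            obj = ET.SubElement(root, "object")
            ET.SubElement(obj, "name").text = "leaf"
            bnd = ET.SubElement(obj, "bndbox")
            ET.SubElement(bnd, "xmin").text = str(x + 1)
            ET.SubElement(bnd, "ymin").text = str(y + 1)
            ET.SubElement(bnd, "xmax").text = str(x + w)
            ET.SubElement(bnd, "ymax").text = str(y + h)
            ET.SubElement(obj, "area_px").text = str(ann["area"])
        tree = ET.ElementTree(root)
        ET.indent(tree)
        path = out_dir / f"{image['plant_id']}.xml"
        tree.write(path, encoding="unicode")
        paths.append(path)
    return paths


def read_voc(xml_path: str | Path) -> PlantAnnotation:
    """Reconstruct a :class:`PlantAnnotation` (boxes and areas, no masks)
    from an XML file written by :func:`coco_to_voc`."""
    root = ET.parse(xml_path).getroot()

    def req(elem: ET.Element, tag: str) -> str:
        child = elem.find(tag)
        if child is None or child.text is None:
            raise ValueError(f"{xml_path}: missing <{tag}> element")
        return child.text

    declared = root.find("declared_leaf_count")
    instances: list[LeafInstance] = []
    for leaf_id, obj in enumerate(root.findall("object"), start=1):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{xml_path}: object without <bndbox>")
        xmin, ymin = int(req(bnd, "xmin")), int(req(bnd, "ymin"))
        xmax, ymax = int(req(bnd, "xmax")), int(req(bnd, "ymax"))
        instances.append(
            LeafInstance(
                leaf_id=leaf_id,
                mask=None,
                bbox=(xmin - 1, ymin - 1, xmax, ymax),
                area_px=int(req(obj, "area_px")),
            )
        )
    return PlantAnnotation(
        image_id=req(root, "plant_id"),
        image_path=req(root, "filename"),
        genotype=req(root, "genotype"),
        width=int(req(root.find("size"), "width")),
        height=int(req(root.find("size"), "height")),
        leaf_instances=instances,
        declared_leaf_count=None if declared is None else int(declared.text),
    )


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def clean(
    annotations: list[PlantAnnotation],
    manifest: list[dict] | dict[str, int],
) -> tuple[list[PlantAnnotation], list[dict]]:
    """Leaf-count consistency filter.

    A plant is kept iff its derived leaf count (number of instances) equals
    the declared count from the manifest.  Returns ``(kept, dropped)`` where
    each dropped entry records both counts for reporting.
    """
    if isinstance(manifest, dict):
        declared_by_id = dict(manifest)
    else:
        declared_by_id = {row["image_id"]: int(row["declared_leaf_count"]) for row in manifest}
    kept: list[PlantAnnotation] = []
    dropped: list[dict] = []
    for plant in annotations:
        if plant.image_id not in declared_by_id:
            raise KeyError(f"annotation {plant.image_id!r} has no manifest row")
        declared = declared_by_id[plant.image_id]
        if plant.leaf_count == declared:
            kept.append(plant)
        else:
            dropped.append(
                {"image_id": plant.image_id, "derived": plant.leaf_count, "declared": declared}
            )
    return kept, dropped


# ---------------------------------------------------------------------------
# Training arrays
# ---------------------------------------------------------------------------

def build_training_arrays(
    annotations: list[PlantAnnotation],
    target_size: int = 28,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Materialize the three task targets alongside resized images.

    Returns ``(images, genotype_indices, leaf_counts, normalized_areas)``:
    images are ``n x target_size x target_size x 3`` floats in [0, 1]
    (bilinear resize), genotype indices follow :data:`KNOWN_GENOTYPES`
    order, counts are floats, and areas are total visible foreground pixels
    normalized by the original canvas area.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    images, genotypes, counts, areas = [], [], [], []
    for plant in annotations:
        with Image.open(plant.image_path) as img:
            rgb = img.convert("RGB").resize((target_size, target_size), Image.BILINEAR)
        images.append(np.asarray(rgb, dtype=np.float32) / 255.0)
        genotypes.append(KNOWN_GENOTYPES.index(plant.genotype))
        counts.append(float(plant.leaf_count))
        areas.append(plant.total_area_px / float(plant.width * plant.height))
    return (
        np.stack(images),
        np.asarray(genotypes, dtype=np.int64),
        np.asarray(counts, dtype=np.float32),
        np.asarray(areas, dtype=np.float32),
    )
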