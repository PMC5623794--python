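"""Whole-body phantom template: stitching, anatomical regions, annotation.

The matching template is a whole-body radiograph of an imaging phantom (a
physical human-body analog), stitched from per-part exposures. Named
anatomical bounding boxes drawn on the template turn a matched rectangle
into human-readable anatomy ("this exposure covers the head and the upper
lungs").

Region configs store corners the way a diagnostician writes them on the
template: (column, row) pairs, 1-based and inclusive. All internal
arithmetic uses 0-based, row-major, half-open boxes ``(row0, col0, rows,
cols)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from skimage import transform

from .io_prep import (
    FULL_RANGE_16,
    POSITIONS,
    RadiographImage,
    ValidationError,
    _round_half_up,
    read_image,
    stretch_histogram,
    write_image,
)

logger = logging.getLogger(__name__)

#: Default template geometry: 2000 rows x 800 cols for a 165 cm body.
DEFAULT_TEMPLATE_SHAPE = (2000, 800)
DEFAULT_BODY_HEIGHT_CM = 165.0

Box = tuple[int, int, int, int]  # (row0, col0, rows, cols), 0-based half-open


@dataclass
class AnatomicalRegion:
    """A named rectangle on the template, stored in config convention.

    ``corner1``/``corner2`` are (column, row), 1-based inclusive.
    """

    name: str
    corner1: tuple[int, int]
    corner2: tuple[int, int]

    def __post_init__(self) -> None:
        c1, r1 = self.corner1
        c2, r2 = self.corner2
        if c1 > c2 or r1 > r2:
            raise ValidationError(
                f"region {self.name!r}: corner1 must be upper-left of corner2"
            )
        if c1 < 1 or r1 < 1:
            raise ValidationError(f"region {self.name!r}: corners are 1-based, got {self.corner1}")

    @property
    def box(self) -> Box:
        """0-based half-open (row0, col0, rows, cols)."""
        c1, r1 = self.corner1
        c2, r2 = self.corner2
        return (r1 - 1, c1 - 1, r2 - (r1 - 1), c2 - (c1 - 1))


def box_area(box: Box) -> int:
    return box[2] * box[3]


def box_intersection(a: Box, b: Box) -> Optional[Box]:
    """Rectangle intersection, or None when empty."""
    r0 = max(a[0], b[0])
    c0 = max(a[1], b[1])
    r1 = min(a[0] + a[2], b[0] + b[2])
    c1 = min(a[1] + a[3], b[1] + b[3])
    if r1 <= r0 or c1 <= c0:
        return None
    return (r0, c0, r1 - r0, c1 - c0)


def box_iou(a: Box, b: Box) -> float:
    inter = box_intersection(a, b)
    ia = box_area(inter) if inter else 0
    union = box_area(a) + box_area(b) - ia
    return ia / union if union else 0.0


@dataclass
class PhantomTemplate:
    """The whole-body template image plus its anatomical definitions."""

    image: RadiographImage
    body_height_cm: float = DEFAULT_BODY_HEIGHT_CM
    regions: list[AnatomicalRegion] = field(default_factory=list)
    position_names: tuple[str, ...] = POSITIONS

    def __post_init__(self) -> None:
        if len(self.position_names) != 6:
            raise ValidationError("exactly six position names required")
        names = [r.name for r in self.regions]
        dups = {n for n in names if names.count(n) > 1}
        if dups:
            raise ValidationError(f"duplicate region names: {sorted(dups)}")
        rows, cols = self.image.shape
        for reg in self.regions:
            r0, c0, h, w = reg.box
            if r0 + h > rows or c0 + w > cols:
                raise ValidationError(
                    f"region {reg.name!r} box {reg.corner1}-{reg.corner2} exceeds "
                    f"template extent {rows}x{cols}"
                )
        if not self.regions:
            warnings.warn(
                "template has no anatomical regions; annotation disabled",
                RuntimeWarning,
                stacklevel=2,
            )

    def region_by_name(self, name: str) -> AnatomicalRegion:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise ValidationError(f"no region named {name!r}")


def load_template(
    image_path: str | Path,
    regions_config: str | Path,
    expected_shape: Optional[tuple[int, int]] = None,
) -> PhantomTemplate:
    """Load template image plus YAML/JSON regions config.

    Config layout::

        template: {rows: 2000, cols: 800, body_height_cm: 165}
        regions:
          - {name: head, corner1: [260, 1], corner2: [540, 285]}
    """
    img = read_image(image_path)
    cfg = yaml.safe_load(Path(regions_config).read_text())
    tpl = cfg.get("template", {})
    rows = int(tpl.get("rows", img.shape[0]))
    cols = int(tpl.get("cols", img.shape[1]))
    if img.shape != (rows, cols):
        raise ValidationError(
            f"template image shape {img.shape} != configured {rows}x{cols}"
        )
    if expected_shape is not None and img.shape != expected_shape:
        raise ValidationError(f"template shape {img.shape} != expected {expected_shape}")
    regions = [
        AnatomicalRegion(
            name=str(rec["name"]),
            corner1=tuple(int(v) for v in rec["corner1"]),
            corner2=tuple(int(v) for v in rec["corner2"]),
        )
        for rec in cfg.get("regions", [])
    ]
    return PhantomTemplate(
        image=img,
        body_height_cm=float(tpl.get("body_height_cm", DEFAULT_BODY_HEIGHT_CM)),
        regions=regions,
    )


def save_template(
    template: PhantomTemplate, image_path: str | Path, regions_config: str | Path
) -> None:
    """Write the template image (16-bit PNG) and its regions config (YAML)."""
    write_image(template.image, image_path)
    rows, cols = template.image.shape
    doc = {
        "template": {
            "rows": rows,
            "cols": cols,
            "body_height_cm": template.body_height_cm,
        },
        "regions": [
            {
                "name": reg.name,
                "corner1": list(reg.corner1),
                "corner2": list(reg.corner2),
            }
            for reg in template.regions
        ],
    }
    Path(regions_config).write_text(yaml.safe_dump(doc, sort_keys=True))


def stitch_parts(
    parts: Sequence[tuple[RadiographImage, int, int, float]],
    canvas_shape: tuple[int, int],
) -> RadiographImage:
    """Fit per-part radiographs into one whole-body canvas.

    Each part is histogram-stretched, rescaled (bilinear) by its factor and
    pasted at its (row, col) offset; where parts overlap, the per-pixel mean
    of contributors is taken. Untouched canvas stays 0.
    """
    rows, cols = canvas_shape
    acc = np.zeros(canvas_shape, dtype=np.float64)
    cnt = np.zeros(canvas_shape, dtype=np.int64)
    for i, (img, r_off, c_off, scale) in enumerate(parts):
        if scale <= 0:
            raise ValidationError(f"part {i}: scale must be positive, got {scale}")
        f = stretch_histogram(img).astype_float()  # constant parts map to 0
        if scale != 1:
            out_shape = (
                max(1, int(round(f.shape[0] * scale))),
                max(1, int(round(f.shape[1] * scale))),
            )
            f = transform.resize(f, out_shape, order=1, anti_aliasing=scale < 1)
        h, w = f.shape
        if r_off < 0 or c_off < 0 or r_off + h > rows or c_off + w > cols:
            raise ValidationError(
                f"part {i} ({h}x{w} at offset ({r_off},{c_off})) exceeds canvas {rows}x{cols}"
            )
        acc[r_off : r_off + h, c_off : c_off + w] += f
        cnt[r_off : r_off + h, c_off : c_off + w] += 1
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    out = _round_half_up(np.clip(out, 0, FULL_RANGE_16))
    return RadiographImage(pixels=out, bit_depth=16)


def annotate_region(
    template: PhantomTemplate, box: Box
) -> list[tuple[str, float]]:
    """Anatomical labels covered by a matched box.

    Returns every region intersecting ``box`` with its overlap fraction
    ``|intersection| / |box|``, sorted descending (name breaks exact ties).
    """
    r0, c0, h, w = box
    if h <= 0 or w <= 0:
        raise ValidationError(f"degenerate zero-area box {box}")
    rows, cols = template.image.shape
    if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
        raise ValidationError(f"box {box} outside template extent {rows}x{cols}")
    area = box_area(box)
    hits: list[tuple[str, float]] = []
    for reg in template.regions:
        inter = box_intersection(box, reg.box)
        if inter is not None:
            hits.append((reg.name, box_area(inter) / area))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
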