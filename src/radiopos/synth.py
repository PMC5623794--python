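"""Synthetic whole-body phantom and position-labelled radiograph generator.

No reference phantom radiographs ship with the package, so this module is
its data source: it renders a whole-body template with six structurally
distinct anatomical zones and cuts position-labelled, noise- and
exposure-perturbed crops from it, emulating the variability of clinical
acquisitions (exposure gain, Gaussian detector noise, salt-and-pepper
impulses, framing jitter).

Zone design mirrors what each body part contributes spectrally:

* head    — bright skull ellipse with a smooth interior (low-frequency mass)
* lungs   — two dark fields filled with band-limited mid-low-frequency
            texture (the synthetic analogue of lung markings)
* lumbar  — vertically periodic bright vertebral blocks
* pelvis  — a bright ring
* joint   — two bright rods meeting at a knee, with fine high-frequency
            trabecular texture around the joint space
* limbs   — long thin bright rods on a dark field

so the six low-frequency signatures are pairwise distinguishable and two
zones (lungs, joint) carry characteristic band-pass texture.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .io_prep import (
    FULL_RANGE_16,
    POSITIONS,
    RadiographImage,
    ValidationError,
    _round_half_up,
    write_image,
)
from .phantom_atlas import (
    AnatomicalRegion,
    Box,
    PhantomTemplate,
    save_template,
)

logger = logging.getLogger(__name__)

#: Zone extents as (row_lo, row_hi, col_lo, col_hi) fractions of the canvas.
ZONE_FRACTIONS: dict[str, tuple[float, float, float, float]] = {
    "head": (0.010, 0.150, 0.300, 0.700),
    "lungs": (0.170, 0.320, 0.150, 0.850),
    "lumbar": (0.340, 0.480, 0.380, 0.620),
    "pelvis": (0.500, 0.630, 0.200, 0.800),
    "joint": (0.660, 0.790, 0.300, 0.700),
    "limbs": (0.810, 0.985, 0.250, 0.750),
}

#: Shipped-atlas geometry (matches the matching template's native scale).
ATLAS_SHAPE = (2000, 800)
#: Small geometry for fast unit-test runs.
TEST_SHAPE = (500, 200)

_MIN_SHAPE = (100, 50)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data.

    ``noise_sigma`` is the Gaussian noise level as a fraction of the 16-bit
    intensity range; ``gain_range`` the multiplicative exposure variation;
    ``impulse_fraction`` the fraction of salt-and-pepper pixels;
    ``jitter_fraction`` the maximum framing shift as a fraction of zone size.
    """

    seed: int = 0
    template_shape: tuple[int, int] = TEST_SHAPE
    noise_sigma: float = 0.05
    gain_range: tuple[float, float] = (0.8, 1.2)
    impulse_fraction: float = 0.001
    n_per_position: int = 30
    n_library: int = 10
    jitter_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        lo, hi = self.gain_range
        if not (0 < lo <= hi):
            raise ValidationError(f"need 0 < gain lo <= hi, got {self.gain_range}")
        if not (0 <= self.impulse_fraction <= 0.1):
            raise ValidationError(
                f"impulse_fraction must lie in [0, 0.1], got {self.impulse_fraction}"
            )
        if not (0 <= self.jitter_fraction <= 0.5):
            raise ValidationError(
                f"jitter_fraction must lie in [0, 0.5], got {self.jitter_fraction}"
            )
        if self.n_per_position < 1:
            raise ValidationError("n_per_position must be >= 1")
        if not (0 <= self.n_library <= self.n_per_position):
            raise ValidationError("need 0 <= n_library <= n_per_position")
        rows, cols = self.template_shape
        if rows < _MIN_SHAPE[0] or cols < _MIN_SHAPE[1]:
            raise ValidationError(
                f"template shape {self.template_shape} too small to place zones "
                f"(minimum {_MIN_SHAPE[0]}x{_MIN_SHAPE[1]})"
            )


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _ellipse_rho(shape: tuple[int, int], center: tuple[float, float],
                 semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.sqrt(((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2)


def _band_noise(shape: tuple[int, int], rng: np.random.Generator,
                low: float, high: float, order: int = 2) -> np.ndarray:
    """Unit-variance noise whose spectral energy lies in a radial band."""
    white = rng.standard_normal(shape)
    spec = np.fft.fft2(white)
    fu = np.fft.fftfreq(shape[0])
    fv = np.fft.fftfreq(shape[1])
    r = np.hypot(fu[:, None], fv[None, :])
    k2 = 2 * order
    with np.errstate(divide="ignore"):
        h = np.where(r > 0, 1.0 / (1.0 + (low / np.where(r > 0, r, 1.0)) ** k2), 0.0)
    h *= 1.0 / (1.0 + (r / high) ** k2)
    out = np.fft.ifft2(spec * h).real
    sd = out.std()
    return out / sd if sd > 0 else out


def zone_boxes(template_shape: tuple[int, int]) -> dict[str, Box]:
    """0-based half-open zone boxes for a given canvas shape."""
    rows, cols = template_shape
    boxes: dict[str, Box] = {}
    for name, (rl, rh, cl, ch) in ZONE_FRACTIONS.items():
        r0, r1 = int(round(rl * rows)), int(round(rh * rows))
        c0, c1 = int(round(cl * cols)), int(round(ch * cols))
        boxes[name] = (r0, c0, r1 - r0, c1 - c0)
    return boxes


# Every renderer keeps its structure inside a ~12% margin of the zone box:
# the magnitude spectrum is translation-invariant, so a jittered crop window
# (jitter <= 10%) then sees the same structure merely shifted and the
# position's signature stays stable under framing variation.
_MARGIN = 0.13


def _render_head(canvas: np.ndarray, box: Box, rng: np.random.Generator) -> None:
    r0, c0, h, w = box
    sub = canvas[r0 : r0 + h, c0 : c0 + w]
    rho = _ellipse_rho(sub.shape, (h / 2, w / 2), (0.36 * h, 0.36 * w))
    interior = rho <= 0.82
    ring = (rho > 0.82) & (rho <= 1.0)
    sub[interior] = 22000 + 9000 * (1 - rho[interior])
    sub[ring] = 52000


def _render_lungs(canvas: np.ndarray, box: Box, rng: np.random.Generator) -> None:
    r0, c0, h, w = box
    sub = canvas[r0 : r0 + h, c0 : c0 + w]
    thorax = _ellipse_mask(sub.shape, (0.5 * h, 0.5 * w), (0.37 * h, 0.37 * w))
    sub[thorax] = 24000  # soft tissue
    # bright diaphragm dome under the fields: strong large-scale contrast
    dome = thorax & (_ellipse_rho(sub.shape, (0.87 * h, 0.5 * w), (0.30 * h, 0.37 * w)) <= 1.0)
    sub[dome] = 42000
    texture = _band_noise(sub.shape, rng, low=0.02, high=0.12)
    for cx in (0.33 * w, 0.67 * w):
        lung = _ellipse_mask(sub.shape, (0.47 * h, cx), (0.30 * h, 0.15 * w))
        sub[lung] = np.clip(3000 + 4200 * texture[lung], 0, FULL_RANGE_16)
    # mediastinal column between the fields
    col = _ellipse_mask(sub.shape, (0.47 * h, 0.5 * w), (0.31 * h, 0.045 * w))
    sub[col] = 34000


def _render_lumbar(canvas: np.ndarray, box: Box, rng: np.random.Generator) -> None:
    r0, c0, h, w = box
    sub = canvas[r0 : r0 + h, c0 : c0 + w]
    top0, bot0 = int(round(_MARGIN * h)), int(round((1 - _MARGIN) * h))
    n_blocks = 5
    period = (bot0 - top0) / n_blocks
    block_h = int(round(0.62 * period))
    cw0, cw1 = int(round(0.34 * w)), int(round(0.66 * w))
    for b in range(n_blocks):
        top = top0 + int(round(b * period))
        sub[top : min(top + block_h, bot0), cw0:cw1] = 48000
    # transverse processes: thin bright wings on alternating vertebrae
    wing = int(round(0.10 * w))
    for b in range(0, n_blocks, 2):
        top = top0 + int(round(b * period + 0.2 * period))
        bot = min(top + max(1, block_h // 3), bot0)
        sub[top:bot, cw0 - wing : cw0] = 36000
        sub[top:bot, cw1 : cw1 + wing] = 36000


def _render_pelvis(canvas: np.ndarray, box: Box, rng: np.random.Generator) -> None:
    r0, c0, h, w = box
    sub = canvas[r0 : r0 + h, c0 : c0 + w]
    # wide, flat, *thin* pelvic ring: its oscillatory annulus spectrum is
    # decorrelated from the smooth blob spectra of head and lungs
    rho = _ellipse_rho(sub.shape, (0.46 * h, 0.5 * w), (0.27 * h, 0.37 * w))
    ring = (rho > 0.88) & (rho <= 1.0)
    sub[ring] = 50000
    for cx in (0.24 * w, 0.76 * w):
        hip = _ellipse_mask(sub.shape, (0.70 * h, cx), (0.10 * h, 0.055 * w))
        sub[hip] = 50000
    # sacral wedge at the ring centre
    wedge = _ellipse_mask(sub.shape, (0.42 * h, 0.5 * w), (0.16 * h, 0.09 * w))
    sub[wedge] = 34000


def _render_joint(canvas: np.ndarray, box: Box, rng: np.random.Generator) -> None:
    r0, c0, h, w = box
    sub = canvas[r0 : r0 + h, c0 : c0 + w]
    top0, bot0 = int(round(_MARGIN * h)), int(round((1 - _MARGIN) * h))
    rod_w = max(2, int(round(0.17 * w)))
    cmid = w // 2
    # femur comes in slightly lateral, tibia leaves slightly medial
    upper_c = cmid - rod_w
    lower_c = cmid - rod_w // 3
    gap = max(2, int(round(0.02 * h)))
    sub[top0 : h // 2 - gap, upper_c : upper_c + rod_w] = 54000
    sub[h // 2 + gap : bot0, lower_c : lower_c + rod_w] = 54000
    # bulbous condyles at the joint line
    for cy, cx in ((h // 2 - gap, upper_c + rod_w / 2), (h // 2 + gap, lower_c + rod_w / 2)):
        sub[_ellipse_mask(sub.shape, (cy, cx), (0.06 * h, 0.14 * w))] = 54000
    # trabecular texture around the joint space: fine high-frequency grain
    fine = _band_noise(sub.shape, rng, low=0.15, high=0.38)
    jr0, jr1 = int(0.3 * h), int(0.7 * h)
    jc0, jc1 = max(0, cmid - 2 * rod_w), min(w, cmid + 2 * rod_w)
    region = sub[jr0:jr1, jc0:jc1]
    bone = region >= 45000
    region[bone] = np.clip(region[bone] + 5200 * fine[jr0:jr1, jc0:jc1][bone], 0, FULL_RANGE_16)


def _render_limbs(canvas: np.ndarray, box: Box, rng: np.random.Generator) -> None:
    r0, c0, h, w = box
    sub = canvas[r0 : r0 + h, c0 : c0 + w]
    top0, bot0 = int(round(_MARGIN * h)), int(round((1 - _MARGIN) * h))
    # an even comb of thin bones: the periodic structure lives well above
    # the lowest radial band, so the limb signature's in-band curve (and
    # AUC) stays far below every other position's
    rod_w = max(2, int(round(0.022 * w)))
    for k in range(6):
        cx = int(round((0.19 + 0.105 * k) * w))
        sub[top0:bot0, cx : cx + rod_w] = 27000
        core = max(1, rod_w // 3)
        sub[top0:bot0, cx + (rod_w - core) // 2 : cx + (rod_w - core) // 2 + core] = 23000


_RENDERERS = {
    "head": _render_head,
    "lungs": _render_lungs,
    "lumbar": _render_lumbar,
    "pelvis": _render_pelvis,
    "joint": _render_joint,
    "limbs": _render_limbs,
}


def make_phantom(cfg: SynthConfig) -> PhantomTemplate:
    """Render the whole-body phantom template and its region definitions.

    Deterministic for a fixed ``cfg.seed``.
    """
    rows, cols = cfg.template_shape
    rng = np.random.default_rng([int(cfg.seed) % (1 << 31), 7])
    canvas = np.full((rows, cols), 2000.0)
    # body silhouette: soft-tissue column with a mild vertical gradient
    body_c0, body_c1 = int(0.15 * cols), int(0.85 * cols)
    grad = 1.0 + 0.1 * np.linspace(0, 1, rows)[:, None]
    canvas[:, body_c0:body_c1] = 12000.0 * grad
    boxes = zone_boxes(cfg.template_shape)
    for name in POSITIONS:
        _RENDERERS[name](canvas, boxes[name], rng)
    pixels = _round_half_up(np.clip(canvas, 0, FULL_RANGE_16))
    regions = [
        AnatomicalRegion(
            name=name,
            corner1=(boxes[name][1] + 1, boxes[name][0] + 1),
            corner2=(boxes[name][1] + boxes[name][3], boxes[name][0] + boxes[name][2]),
        )
        for name in POSITIONS
    ]
    image = RadiographImage(pixels=pixels, bit_depth=16)
    return PhantomTemplate(image=image, regions=regions)


@dataclass
class PositionSample:
    """One generated labelled radiograph with its ground truth."""

    image: RadiographImage
    position: str
    true_box: Box  # source crop in template pixels, 0-based half-open
    gain: float
    index: int


def make_position_image(
    template: PhantomTemplate,
    position: str,
    cfg: SynthConfig,
    index: int,
) -> PositionSample:
    """Cut one noisy, exposure-varied crop of a position's zone.

    Deterministic for fixed (cfg.seed, position, index). The crop window is
    the zone rectangle shifted by a uniform jitter of at most
    ``jitter_fraction`` of the zone size, clipped to the template.
    """
    if position not in POSITIONS:
        raise ValidationError(f"unknown position {position!r}")
    rng = np.random.default_rng(
        [int(cfg.seed) % (1 << 31), 101 + POSITIONS.index(position), int(index)]
    )
    reg = template.region_by_name(position)
    r0, c0, h, w = reg.box
    rows, cols = template.image.shape
    max_dr = int(cfg.jitter_fraction * h)
    max_dc = int(cfg.jitter_fraction * w)
    dr = int(rng.integers(-max_dr, max_dr + 1)) if max_dr else 0
    dc = int(rng.integers(-max_dc, max_dc + 1)) if max_dc else 0
    rr0 = min(max(r0 + dr, 0), rows - h)
    cc0 = min(max(c0 + dc, 0), cols - w)
    crop = template.image.pixels[rr0 : rr0 + h, cc0 : cc0 + w].astype(np.float64)
    gain = float(rng.uniform(*cfg.gain_range))
    out = crop * gain
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma * FULL_RANGE_16, size=out.shape)
    n_imp = int(round(cfg.impulse_fraction * out.size))
    if n_imp > 0:
        flat = out.reshape(-1)
        idx = rng.choice(out.size, size=n_imp, replace=False)
        flat[idx] = rng.integers(0, 2, size=n_imp) * FULL_RANGE_16
    pixels = _round_half_up(np.clip(out, 0, FULL_RANGE_16))
    img = RadiographImage(pixels=pixels, bit_depth=16, label=position)
    return PositionSample(
        image=img, position=position, true_box=(rr0, cc0, h, w), gain=gain, index=index
    )


@dataclass
class DatasetRecord:
    """One manifest row of a generated dataset."""

    filename: str
    position: str
    split: str  # "library" | "eval"
    true_box: Box
    gain: float
    index: int


MANIFEST_FIELDS = (
    "filename", "position", "split", "row0", "col0", "rows", "cols", "gain", "seed", "index",
)


def make_dataset(
    template: PhantomTemplate,
    cfg: SynthConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[list[DatasetRecord], list[PositionSample]]:
    """Generate ``n_per_position`` labelled crops per position.

    The first ``n_library`` indices per position form the library-building
    split; the remainder is the evaluation split. Library images emulate
    *reference* acquisitions — nominal exposure (gain 1) and a fixed
    coordinate frame (no framing jitter), as reference curves are averaged
    from repeat exposures of the same view — while evaluation images carry
    the full clinical variability (gain range, jitter). Detector noise and
    impulses affect both splits. When ``out_dir`` is given, 16-bit PNGs and
    a ``manifest.csv`` are written there.
    """
    records: list[DatasetRecord] = []
    samples: list[PositionSample] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "images").mkdir(parents=True, exist_ok=True)
    reference_cfg = replace(cfg, gain_range=(1.0, 1.0), jitter_fraction=0.0)
    for position in POSITIONS:
        for index in range(cfg.n_per_position):
            split = "library" if index < cfg.n_library else "eval"
            sample = make_position_image(
                template, position, reference_cfg if split == "library" else cfg, index
            )
            filename = f"images/{position}_{index:03d}.png"
            rec = DatasetRecord(
                filename=filename,
                position=position,
                split=split,
                true_box=sample.true_box,
                gain=sample.gain,
                index=index,
            )
            records.append(rec)
            samples.append(sample)
            if out_path is not None:
                write_image(sample.image, out_path / filename)
    if out_path is not None:
        with open(out_path / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(MANIFEST_FIELDS)
            for rec in records:
                r0, c0, h, w = rec.true_box
                writer.writerow(
                    [rec.filename, rec.position, rec.split, r0, c0, h, w,
                     f"{rec.gain:.6f}", cfg.seed, rec.index]
                )
    return records, samples


def read_manifest(path: str | Path) -> list[DatasetRecord]:
    """Parse a dataset manifest back into records."""
    records: list[DatasetRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                DatasetRecord(
                    filename=row["filename"],
                    position=row["position"],
                    split=row["split"],
                    true_box=(
                        int(row["row0"]), int(row["col0"]),
                        int(row["rows"]), int(row["cols"]),
                    ),
                    gain=float(row["gain"]),
                    index=int(row["index"]),
                )
            )
    return records


def simulate(cfg: SynthConfig, out_dir: str | Path) -> PhantomTemplate:
    """Write the full synthetic study to ``out_dir``: atlas, config, dataset."""
    out_path = Path(out_dir)
    out_path.mkdir(parents=True, exist_ok=True)
    template = make_phantom(cfg)
    save_template(template, out_path / "atlas.png", out_path / "regions.yaml")
    make_dataset(template, cfg, out_dir=out_path)
    return template
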