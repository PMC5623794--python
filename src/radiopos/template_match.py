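"""Localization on the phantom template by sliding-window gray matching.

Two score maps are computed over every valid placement of the input image I
on the template window W:

    M(offset) = sum(I * W) / sum(I^2)        (energy-normalized matrix product)
    R(offset) = Pearson correlation of I, W  (affine-intensity invariant)

R is invariant to gain/offset changes of either image; M is not, but is
sensitive to absolute intensity agreement — the two fail differently, so
the recognized region T is the intersection of the input-sized rectangles
at the two maps' maxima (falling back to the R rectangle when they are
disjoint). Both images are downscaled by a common factor before the search
to keep the sweep cheap; the result is reported in full-resolution template
pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from skimage import transform

from .classifier import ClassificationResult, classify
from .freq_signature import SignatureLibrary, compute_signature
from .io_prep import (
    FULL_RANGE_16,
    RadiographImage,
    ValidationError,
    _round_half_up,
    preprocess,
)
from .phantom_atlas import (
    Box,
    PhantomTemplate,
    annotate_region,
    box_area,
    box_intersection,
)

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-9  # below this, a window is treated as zero-variance (r = 0)


def downscale(img: RadiographImage, factor: float) -> RadiographImage:
    """Bilinear resampling by the same factor on both axes (factor <= 1)."""
    if not (0 < factor <= 1):
        raise ValidationError(f"factor must lie in (0, 1], got {factor}")
    if factor == 1:
        return img.with_pixels(img.pixels.copy())
    m, n = img.shape
    out_shape = (int(round(m * factor)), int(round(n * factor)))
    if out_shape[0] < 8 or out_shape[1] < 8:
        raise ValidationError(
            f"downscaled shape {out_shape} smaller than 8x8; use a larger factor"
        )
    f = transform.resize(
        img.astype_float(), out_shape, order=1, anti_aliasing=True
    )
    out = _round_half_up(np.clip(f, 0, (1 << img.bit_depth) - 1))
    return img.with_pixels(out)


@dataclass
class ScoreMaps:
    """Matrix-product and correlation maps over all valid top-left offsets."""

    m_map: np.ndarray
    r_map: np.ndarray
    scale: float
    input_shape_scaled: tuple[int, int]

    def __post_init__(self) -> None:
        if self.m_map.shape != self.r_map.shape:
            raise ValidationError("m_map and r_map shapes differ")


def _window_sums(t: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Sliding sums of t and t^2 over windows of the given shape (valid mode).

    Integral images over integer-valued pixels: every partial sum stays an
    exactly representable float64 integer, so flat windows get an exactly
    zero variance (unlike an FFT-based sliding sum).
    """
    h, w = shape

    def _integral(a: np.ndarray) -> np.ndarray:
        c = np.pad(np.cumsum(np.cumsum(a, axis=0), axis=1), ((1, 0), (1, 0)))
        return c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]

    return _integral(t), _integral(t * t)


def score_maps(
    input_img: RadiographImage,
    template_img: RadiographImage,
    scale: float = 1.0,
) -> ScoreMaps:
    """Compute both score maps for every valid offset of input on template."""
    inp = downscale(input_img, scale)
    tpl = downscale(template_img, scale)
    (mi, ni), (mt, nt) = inp.shape, tpl.shape
    if mi >= mt or ni >= nt:
        raise ValidationError(
            f"scaled input {mi}x{ni} must be strictly smaller than template {mt}x{nt}"
        )
    i = inp.astype_float()
    t = tpl.astype_float()
    k = i.size
    flipped = i[::-1, ::-1]
    cross = fftconvolve(t, flipped, mode="valid")  # sum(I * W) per offset
    denom = float((i * i).sum())
    if denom == 0:
        raise ValidationError("input image is identically zero; matrix score undefined")
    m_map = cross / denom

    i_centered = i - i.mean()
    i_var = float((i_centered * i_centered).sum())
    s1, s2 = _window_sums(t, i.shape)
    # k*s2 - s1^2 is exact integer arithmetic: zero iff the window is flat
    w_var_scaled = np.maximum(k * s2 - s1 * s1, 0.0)
    num = fftconvolve(t, i_centered[::-1, ::-1], mode="valid")
    denom_r = np.sqrt(w_var_scaled / k * i_var)
    flat = w_var_scaled == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_map = np.where(flat, 0.0, num / np.where(flat, 1.0, denom_r))
    if i_var <= _VAR_EPS * k:  # constant input: correlation undefined everywhere
        r_map = np.zeros_like(m_map)
    r_map = np.clip(r_map, -1.0, 1.0)
    return ScoreMaps(
        m_map=m_map, r_map=r_map, scale=scale, input_shape_scaled=(mi, ni)
    )


@dataclass
class MatchRegion:
    """Localized region in full-resolution template pixels."""

    box: Box
    m_argmax_box: Box
    r_argmax_box: Box
    overlap_fraction: float
    fallback_used: bool = False

    def to_dict(self) -> dict:
        return {
            "box": list(self.box),
            "m_argmax_box": list(self.m_argmax_box),
            "r_argmax_box": list(self.r_argmax_box),
            "overlap_fraction": self.overlap_fraction,
            "fallback_used": self.fallback_used,
        }


def _argmax_rowmajor(a: np.ndarray) -> tuple[int, int]:
    """First occurrence of the maximum in row-major order."""
    idx = int(np.argmax(a))
    return idx // a.shape[1], idx % a.shape[1]


def _to_full_res(offset: tuple[int, int], shape: tuple[int, int], scale: float,
                 template_shape: tuple[int, int]) -> Box:
    r0 = int(round(offset[0] / scale))
    c0 = int(round(offset[1] / scale))
    h, w = shape
    rows, cols = template_shape
    r0 = min(max(r0, 0), max(rows - h, 0))
    c0 = min(max(c0, 0), max(cols - w, 0))
    return (r0, c0, h, w)


def locate(
    input_img: RadiographImage,
    template: PhantomTemplate,
    scale: float = 0.25,
) -> MatchRegion:
    """Find the input's region on the template via both score maps.

    The input-sized rectangles at the maxima of M and R are intersected;
    when they are disjoint the (affine-invariant) R rectangle is used and
    the fallback is recorded.
    """
    maps = score_maps(input_img, template.image, scale)
    full_shape = input_img.shape
    tpl_shape = template.image.shape
    m_box = _to_full_res(_argmax_rowmajor(maps.m_map), full_shape, scale, tpl_shape)
    r_box = _to_full_res(_argmax_rowmajor(maps.r_map), full_shape, scale, tpl_shape)
    inter = box_intersection(m_box, r_box)
    if inter is None:
        logger.info("score maxima disjoint; falling back to correlation rectangle")
        box, fallback = r_box, True
        inter_area = 0
    else:
        box, fallback = inter, False
        inter_area = box_area(inter)
    union = box_area(m_box) + box_area(r_box) - inter_area
    overlap = box_area(box) / union if union else 0.0
    return MatchRegion(
        box=box,
        m_argmax_box=m_box,
        r_argmax_box=r_box,
        overlap_fraction=overlap,
        fallback_used=fallback,
    )


@dataclass
class MatchResult:
    """End-to-end recognition output: position, region, anatomical labels."""

    classification: ClassificationResult
    match: MatchRegion
    regions: list[tuple[str, float]]

    def to_dict(self) -> dict:
        return {
            "position": self.classification.chosen,
            "decided_by": self.classification.decided_by,
            "mean_variances": {
                k: self.classification.mean_variances[k]
                for k in sorted(self.classification.mean_variances)
            },
            "cosines": {
                k: self.classification.cosines[k]
                for k in sorted(self.classification.cosines)
            },
            "box": list(self.match.box),
            "m_argmax_box": list(self.match.m_argmax_box),
            "r_argmax_box": list(self.match.r_argmax_box),
            "fallback_used": self.match.fallback_used,
            "regions": [{"name": n, "overlap": f} for n, f in self.regions],
        }


def recognize(
    img: RadiographImage,
    lib: SignatureLibrary,
    template: PhantomTemplate,
    *,
    threshold: float = 0.02,
    tiebreak_mode: str = "both_below",
    scale: float = 0.25,
    apply_clahe_flag: bool = False,
) -> MatchResult:
    """The full workflow: preprocess, classify by signature, locate, annotate."""
    stage = "preprocess"
    try:
        pre = preprocess(img, apply_clahe_flag=apply_clahe_flag)
        stage = "signature"
        sig = compute_signature(pre, fraction=lib.fraction, n_bins=lib.n_bins)
        stage = "classify"
        cls = classify(sig, lib, threshold=threshold, tiebreak_mode=tiebreak_mode)
        stage = "locate"
        match = locate(pre, template, scale=scale)
        stage = "annotate"
        regions = annotate_region(template, match.box)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return MatchResult(classification=cls, match=match, regions=regions)
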