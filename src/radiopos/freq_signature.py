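"""Spectral signatures: 2D Fourier magnitude, low-frequency curves, band filters.

A radiograph's anatomical content is concentrated in the lowest radial
frequencies of its 2D spectrum. The classification feature is therefore a
1D curve: the normalized Fourier magnitude

    F(u, v) = (1 / MN) * sum_x sum_y f(x, y) * exp(-j 2 pi (u x / M + v y / N))

is reduced to ring means over the lowest ``fraction`` (default 2%) of the
radial frequency range, with the DC term excluded so that exposure offset
does not dominate similarity. The area under that curve (AUC) is an
auxiliary scalar that separates positions whose curve shapes are similar.

Band-limited texture (lung markings, bone trabeculae) is extracted by a
radial Butterworth band-pass applied in the frequency domain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_prep import (
    FULL_RANGE_16,
    POSITIONS,
    RadiographImage,
    ValidationError,
    _round_half_up,
    preprocess,
)

logger = logging.getLogger(__name__)


@dataclass
class FrequencySignature:
    """A fixed-length low-frequency amplitude curve and its AUC."""

    curve: np.ndarray
    n_bins: int
    fraction: float
    auc: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.curve, dtype=np.float64)
        if c.ndim != 1 or c.size != self.n_bins:
            raise ValidationError(f"curve length {c.size} != n_bins {self.n_bins}")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValidationError("curve entries must be finite and non-negative")
        self.curve = c

    @staticmethod
    def from_curve(
        curve: np.ndarray, fraction: float, label: Optional[str] = None
    ) -> "FrequencySignature":
        curve = np.asarray(curve, dtype=np.float64)
        return FrequencySignature(
            curve=curve,
            n_bins=curve.size,
            fraction=fraction,
            auc=float(np.trapezoid(curve)),
            label=label,
        )


@dataclass
class BandSpec:
    """Radial band-pass specification in normalized frequency (cycles/pixel).

    ``low_cut = 0`` disables the high-pass roll-off (the DC term is removed
    regardless, since the pass band is open at zero); ``high_cut = 0.5``
    (Nyquist) disables the low-pass roll-off.
    """

    low_cut: float
    high_cut: float
    order: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut < self.high_cut <= 0.5):
            raise ValidationError(
                f"need 0 <= low_cut < high_cut <= 0.5, got ({self.low_cut}, {self.high_cut})"
            )
        if self.order < 1:
            raise ValidationError(f"order must be >= 1, got {self.order}")


def fft_magnitude(img: RadiographImage) -> np.ndarray:
    """Centred 2D Fourier magnitude |F(u,v)| with 1/(MN) normalization.

    The centre cell (zero frequency) equals the image mean.
    """
    f = img.astype_float()
    return np.abs(np.fft.fftshift(np.fft.fft2(f))) / f.size


def _radial_frequency_grid(shape: tuple[int, int]) -> np.ndarray:
    """Per-cell radial frequency sqrt((u/M)^2 + (v/N)^2), centred like fftshift."""
    m, n = shape
    fu = np.fft.fftshift(np.fft.fftfreq(m))
    fv = np.fft.fftshift(np.fft.fftfreq(n))
    return np.hypot(fu[:, None], fv[None, :])


def low_freq_curve(
    mag: np.ndarray,
    fraction: float = 0.02,
    n_bins: int = 256,
    label: Optional[str] = None,
) -> FrequencySignature:
    """Reduce a centred magnitude grid to ring means over the lowest band.

    Cells whose radial frequency r satisfies ``0 < r <= fraction * r_max``
    (r_max the largest radial frequency on the grid) are binned into
    ``n_bins`` equal-width rings; each curve entry is the mean magnitude of
    its ring, with empty rings linearly interpolated from their populated
    neighbours (endpoints replicated). The DC cell is excluded.
    """
    mag = np.asarray(mag, dtype=np.float64)
    if mag.ndim != 2:
        raise ValidationError("magnitude grid must be 2D")
    if not (0 < fraction <= 0.5):
        raise ValidationError(f"fraction must lie in (0, 0.5], got {fraction}")
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    r = _radial_frequency_grid(mag.shape)
    r_lim = fraction * r.max()
    sel = (r > 0) & (r <= r_lim)
    if not sel.any():
        raise ValidationError(
            "no spectral cells inside the low-frequency band; "
            "increase fraction or use a larger image"
        )
    ring = np.minimum((r[sel] / r_lim * n_bins).astype(np.int64), n_bins - 1)
    sums = np.bincount(ring, weights=mag[sel], minlength=n_bins)
    counts = np.bincount(ring, minlength=n_bins)
    populated = counts > 0
    if populated.sum() < 2:
        raise ValidationError(
            "fewer than 2 radial rings populated; increase fraction or reduce n_bins"
        )
    curve = np.empty(n_bins, dtype=np.float64)
    curve[populated] = sums[populated] / counts[populated]
    idx = np.arange(n_bins)
    curve[~populated] = np.interp(idx[~populated], idx[populated], curve[populated])
    return FrequencySignature.from_curve(curve, fraction=fraction, label=label)


def compute_signature(
    img: RadiographImage,
    fraction: float = 0.02,
    n_bins: int = 256,
) -> FrequencySignature:
    """Signature of an (already preprocessed) radiograph."""
    return low_freq_curve(fft_magnitude(img), fraction=fraction, n_bins=n_bins, label=img.label)


def butterworth_band(img: RadiographImage, band: BandSpec) -> RadiographImage:
    """Band-limited texture extraction via a radial Butterworth band-pass.

    The centred spectrum is multiplied by
    ``H(r) = [1 / (1 + (low/r)^{2k})] * [1 / (1 + (r/high)^{2k})]``
    (each factor dropped at its open edge, see :class:`BandSpec`), inverse
    transformed, clipped to [0, 65535] and rounded.
    """
    f = img.astype_float()
    spec = np.fft.fftshift(np.fft.fft2(f))
    r = _radial_frequency_grid(f.shape)
    h = np.ones_like(r)
    k2 = 2 * band.order
    if band.low_cut > 0:
        with np.errstate(divide="ignore"):
            h *= np.where(r > 0, 1.0 / (1.0 + (band.low_cut / np.where(r > 0, r, 1.0)) ** k2), 0.0)
    if band.high_cut < 0.5:
        h *= 1.0 / (1.0 + (r / band.high_cut) ** k2)
    h[r == 0] = 0.0  # pass band is open at zero: DC always removed
    out = np.fft.ifft2(np.fft.ifftshift(spec * h)).real
    out = _round_half_up(np.clip(out, 0, FULL_RANGE_16))
    return img.with_pixels(out, bit_depth=16)


@dataclass
class SignatureLibrary:
    """The six position-labelled reference curves used for classification.

    ``norm`` is the global amplitude scale (maximum amplitude over all
    library curves); curves are divided by it before the mean-variance
    comparison so the decision threshold lives on a fixed scale.
    """

    entries: dict[str, FrequencySignature]
    fraction: float
    n_bins: int
    norm: float

    def __post_init__(self) -> None:
        if set(self.entries) != set(POSITIONS):
            raise ValidationError(
                f"library must contain exactly {sorted(POSITIONS)}, got {sorted(self.entries)}"
            )
        lengths = {sig.curve.size for sig in self.entries.values()}
        if lengths != {self.n_bins}:
            raise ValidationError(f"curve lengths {lengths} != n_bins {self.n_bins}")
        if self.norm <= 0:
            raise ValidationError("library norm must be positive")

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "n_bins": self.n_bins,
            "norm": self.norm,
            "positions": {
                name: {"curve": sig.curve.tolist(), "auc": sig.auc}
                for name, sig in self.entries.items()
            },
        }

    @staticmethod
    def from_dict(d: dict) -> "SignatureLibrary":
        entries = {
            name: FrequencySignature(
                curve=np.asarray(rec["curve"], dtype=np.float64),
                n_bins=int(d["n_bins"]),
                fraction=float(d["fraction"]),
                auc=float(rec["auc"]),
                label=name,
            )
            for name, rec in d["positions"].items()
        }
        return SignatureLibrary(
            entries=entries,
            fraction=float(d["fraction"]),
            n_bins=int(d["n_bins"]),
            norm=float(d["norm"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "SignatureLibrary":
        return SignatureLibrary.from_dict(json.loads(Path(path).read_text()))

    def export_csv(self, path: str | Path) -> None:
        """Curves as CSV (position, bin_index, amplitude) for plotting."""
        lines = ["position,bin_index,amplitude"]
        for name in POSITIONS:
            for i, a in enumerate(self.entries[name].curve):
                lines.append(f"{name},{i},{a!r}")
        Path(path).write_text("\n".join(lines) + "\n")


def build_library(
    groups: Mapping[str, Sequence[RadiographImage]],
    fraction: float = 0.02,
    n_bins: int = 256,
    apply_clahe_flag: bool = False,
) -> SignatureLibrary:
    """Build the reference library: per position, the mean of member curves.

    Each member image goes through the standard preprocessing chain before
    its curve is computed.
    """
    missing = [p for p in POSITIONS if p not in groups or len(groups[p]) == 0]
    if missing:
        raise ValidationError(f"missing images for positions: {missing}")
    extra = sorted(set(groups) - set(POSITIONS))
    if extra:
        raise ValidationError(f"unknown position names: {extra}")
    entries: dict[str, FrequencySignature] = {}
    for name in POSITIONS:
        curves = []
        for img in groups[name]:
            pre = preprocess(img, apply_clahe_flag=apply_clahe_flag)
            curves.append(compute_signature(pre, fraction=fraction, n_bins=n_bins).curve)
        mean_curve = np.mean(curves, axis=0)
        entries[name] = FrequencySignature.from_curve(mean_curve, fraction=fraction, label=name)
    norm = max(float(sig.curve.max()) for sig in entries.values())
    if norm <= 0:
        raise ValidationError("all library curves are identically zero")
    return SignatureLibrary(entries=entries, fraction=fraction, n_bins=n_bins, norm=norm)
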