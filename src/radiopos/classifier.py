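"""Position classification by curve similarity against the reference library.

Two similarity scores compare an input curve f(w) with a library curve F(w):

    a        = sqrt( sum_i (f_i - F_i)^2 / n )          (root-mean-square difference)
    cos(theta) = (f . F) / (||f|| ||F||)                (angle between the curves)

Smaller ``a`` and cosine closer to 1 both mean greater similarity. The six
``a`` values are ranked ascending; normally the smallest wins. When the two
best matches are both very close (both ``a`` below a threshold on the
library's normalized amplitude scale, 0.02 by default), the cosine decides
between them — curve *shape* breaks the near-tie that raw amplitude cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_prep import POSITIONS, ValidationError
from .freq_signature import FrequencySignature, SignatureLibrary

logger = logging.getLogger(__name__)

TIEBREAK_MODES = ("both_below", "gap_below")


def mean_variance(f: np.ndarray, F: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length amplitude vectors."""
    f = np.asarray(f, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    if f.shape != F.shape or f.ndim != 1 or f.size == 0:
        raise ValidationError(f"vector shapes differ or empty: {f.shape} vs {F.shape}")
    d = f - F
    return float(np.sqrt(np.dot(d, d) / f.size))


def cosine_similarity(f: np.ndarray, F: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    f = np.asarray(f, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    if f.shape != F.shape or f.ndim != 1 or f.size == 0:
        raise ValidationError(f"vector shapes differ or empty: {f.shape} vs {F.shape}")
    nf = np.linalg.norm(f)
    nF = np.linalg.norm(F)
    if nf == 0 or nF == 0:
        raise ValidationError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(f, F) / (nf * nF), -1.0, 1.0))


@dataclass
class ClassificationResult:
    """Full audit record of one classification decision."""

    chosen: str
    mean_variances: dict[str, float]
    cosines: dict[str, float]
    decided_by: str  # "mean_variance" | "cosine_tiebreak"
    ranking: list[str]  # positions by ascending mean-variance

    def to_dict(self) -> dict:
        return {
            "chosen": self.chosen,
            "decided_by": self.decided_by,
            "ranking": list(self.ranking),
            "mean_variances": {k: self.mean_variances[k] for k in sorted(self.mean_variances)},
            "cosines": {k: self.cosines[k] for k in sorted(self.cosines)},
        }


def rank_positions(
    sig: FrequencySignature, lib: SignatureLibrary
) -> list[tuple[str, float]]:
    """All six mean-variance scores, ascending; ties broken by canonical order.

    Both the input curve and each library curve are divided by the library's
    global amplitude norm first, so scores live on a fixed scale.
    """
    if sig.n_bins != lib.n_bins:
        raise ValidationError(f"signature n_bins {sig.n_bins} != library n_bins {lib.n_bins}")
    f = sig.curve / lib.norm
    scores = {
        name: mean_variance(f, lib.entries[name].curve / lib.norm) for name in POSITIONS
    }
    order = sorted(POSITIONS, key=lambda nm: (scores[nm], POSITIONS.index(nm)))
    return [(nm, scores[nm]) for nm in order]


def classify(
    sig: FrequencySignature,
    lib: SignatureLibrary,
    threshold: float = 0.02,
    tiebreak_mode: str = "both_below",
) -> ClassificationResult:
    """Decide the radiographic position of a signature.

    With ``tiebreak_mode="both_below"`` the cosine decides between the two
    best-ranked positions when both of their mean-variance scores fall below
    ``threshold``; with ``"gap_below"`` it decides when the *difference*
    between them falls below ``threshold``. Otherwise the smallest
    mean-variance wins outright.
    """
    if tiebreak_mode not in TIEBREAK_MODES:
        raise ValidationError(f"tiebreak_mode must be one of {TIEBREAK_MODES}")
    ranked = rank_positions(sig, lib)
    scores = dict(ranked)
    cosines = {
        name: cosine_similarity(sig.curve, lib.entries[name].curve) for name in POSITIONS
    }
    (first, a1), (second, a2) = ranked[0], ranked[1]
    if tiebreak_mode == "both_below":
        tie = a1 < threshold and a2 < threshold
    else:
        tie = (a2 - a1) < threshold
    if tie:
        chosen = first if cosines[first] >= cosines[second] else second
        decided_by = "cosine_tiebreak"
    else:
        chosen = first
        decided_by = "mean_variance"
    return ClassificationResult(
        chosen=chosen,
        mean_variances=scores,
        cosines=cosines,
        decided_by=decided_by,
        ranking=[nm for nm, _ in ranked],
    )
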