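"""Binarized choroid layer (BCL) extraction.

The choroid band of a preprocessed B-scan is binarized into vessel lumens
(dark in OCT) versus stroma (bright) by power-law enhancement followed by
global Otsu thresholding, then restricted to the band between the choroid
inner boundary (CIB) and choroid outer boundary (COB).  Lumen polarity is
fixed to ``True`` immediately after restriction so every downstream module
sees one convention.

CIB/COB detection itself is out of scope: boundaries are normally provided
as CSV inputs; :func:`fallback_choroid_boundaries` is a crude gradient
fallback provided only so the CLI can run end-to-end without them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt
from skimage.filters import threshold_otsu

from .io import BoundaryCurve, BoundaryKind, ValidationError, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "BinarizedChoroid",
    "exponential_enhance",
    "threshold_binarize",
    "restrict_to_choroid",
    "fallback_choroid_boundaries",
]


@dataclass(frozen=True)
class BinarizedChoroid:
    """Binary raster restricted to the choroid band; True = vessel lumen."""

    mask: np.ndarray
    cib: BoundaryCurve
    cob: BoundaryCurve

    @property
    def band_indicator(self) -> np.ndarray:
        rows = np.arange(self.mask.shape[0])[:, None]
        lo = round_half_up(self.cib.rows)[None, :]
        hi = round_half_up(self.cob.rows)[None, :]
        return (rows >= lo) & (rows <= hi)


def exponential_enhance(image: np.ndarray, exponent: float = 2.0) -> np.ndarray:
    """Pointwise power-law enhancement ``v -> v**exponent`` rescaled to [0,1].

    Exponents above 1 darken the (already dark) lumens relative to stroma,
    widening the bimodal gap before thresholding.
    """
    image = np.asarray(image, dtype=float)
    if exponent <= 0:
        raise ValidationError("exponent must be > 0")
    out = np.power(np.clip(image, 0.0, 1.0), exponent)
    rng = np.ptp(out)
    if rng > 0:
        out = (out - out.min()) / rng
    return out


def threshold_binarize(image: np.ndarray) -> np.ndarray:
    """Global Otsu threshold; returns True where the pixel is dark (lumen).

    The below-threshold class is mapped directly to True, i.e. the
    complement step that marks vessel cross-sections white is fused in.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        logger.warning("threshold_binarize: constant image, all-false mask")
        return np.zeros_like(image, dtype=bool)
    t = threshold_otsu(image, nbins=256)
    return image <= t


def restrict_to_choroid(
    binary: np.ndarray, cib: BoundaryCurve, cob: BoundaryCurve
) -> BinarizedChoroid:
    """Zero the lumen mask outside the band [cib(c), cob(c)] at each column."""
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ValidationError("binary mask must be 2D")
    if cib.width != binary.shape[1] or cob.width != binary.shape[1]:
        raise ValidationError("boundary width does not match image width")
    if np.any(cib.rows > cob.rows):
        raise ValidationError("CIB lies below COB at some column")
    bcl = BinarizedChoroid(mask=binary, cib=cib, cob=cob)
    masked = binary & bcl.band_indicator
    return BinarizedChoroid(mask=masked, cib=cib, cob=cob)


def fallback_choroid_boundaries(
    image: np.ndarray,
    margin_px: int = 3,
    depth_px: int = 150,
    median_size: int = 15,
) -> tuple[BoundaryCurve, BoundaryCurve]:
    """Crude CIB/COB estimate so the CLI can run without boundary files.

    CIB is placed just below the per-column brightest row in the upper
    half of the scan (the RPE, the most hyper-reflective band in a
    B-scan) offset by ``margin_px``; COB is CIB plus a constant
    ``depth_px``.  Both curves are median filtered.  This is a FALLBACK
    convenience, not a validated detector.
    """
    image = np.asarray(image, dtype=float)
    n_rows, width = image.shape
    if median_size % 2 == 0:
        median_size += 1
    if np.ptp(image) == 0:
        logger.warning(
            "fallback_choroid_boundaries: constant image, flat default curves (FALLBACK)"
        )
        cib_row = min(n_rows // 4, n_rows - 2)
        cob_row = min(cib_row + depth_px, n_rows - 1)
        return (
            BoundaryCurve(np.full(width, float(cib_row)), BoundaryKind.CIB),
            BoundaryCurve(np.full(width, float(cob_row)), BoundaryKind.COB),
        )
    logger.warning("using FALLBACK brightest-row choroid boundaries")
    upper = image[: max(1, n_rows // 2), :]
    cib_rows = upper.argmax(axis=0).astype(float) + margin_px
    cib_rows = medfilt(cib_rows, kernel_size=median_size)
    cob_rows = np.clip(cib_rows + depth_px, 0, n_rows - 1)
    cib_rows = np.clip(cib_rows, 0, n_rows - 1)
    return (
        BoundaryCurve(cib_rows, BoundaryKind.CIB),
        BoundaryCurve(cob_rows, BoundaryKind.COB),
    )
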