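"""Haller/Sattler boundary construction from the large-vessel set.

The boundary is built by a two-stage interpolation through one anchor per
large vessel — its innermost (minimum-row) pixel: first piecewise-linear
interpolation across columns, then robust locally weighted linear
regression (LOWESS with tricube weights and bisquare robustness
reweighting) with a span of one fifth of the scan width.  The result is
clamped into the choroid band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    BoundaryCurve,
    BoundaryKind,
    PipelineConfig,
    ValidationError,
    clamp_to_band,
)
from .vessels import LargeVesselSet, VesselLabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "HallerBoundary",
    "anchor_points",
    "interpolate_linear",
    "smooth_rloess",
    "demarcate_haller",
]


@dataclass(frozen=True)
class HallerBoundary:
    curve: BoundaryCurve
    anchor_points: tuple[tuple[int, int], ...]
    fallback_used: bool = False

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_points)


def anchor_points(
    large: LargeVesselSet, vessels: VesselLabelMap
) -> list[tuple[int, int]]:
    """Innermost pixel of each large vessel, column-sorted.

    Ties on the minimum row are broken by minimum column; should two
    vessels anchor at the same column, the smaller (inner) row wins.
    """
    pts = [vessels.innermost_px[k] for k in sorted(large.label_ids)]
    pts.sort(key=lambda rc: (rc[1], rc[0]))
    dedup: dict[int, int] = {}
    for r, c in pts:
        if c not in dedup or r < dedup[c]:
            dedup[c] = r
    return [(r, c) for c, r in sorted(dedup.items())]


def interpolate_linear(
    anchors: list[tuple[int, int]], width: int
) -> BoundaryCurve:
    """Piecewise-linear curve through the anchors, constant beyond the ends."""
    if not anchors:
        raise ValidationError("interpolate_linear needs at least one anchor")
    cols = np.asarray([c for _, c in anchors], dtype=float)
    rows = np.asarray([r for r, _ in anchors], dtype=float)
    dense = np.interp(np.arange(width, dtype=float), cols, rows)
    return BoundaryCurve(rows=dense, kind=BoundaryKind.HALLER)


def _weighted_linear_fit(xw: np.ndarray, yw: np.ndarray, w: np.ndarray,
                         x0: float) -> float:
    sw = w.sum()
    xm = (w * xw).sum() / sw
    ym = (w * yw).sum() / sw
    sxx = (w * (xw - xm) ** 2).sum()
    if sxx <= 1e-12:
        return ym
    slope = (w * (xw - xm) * (yw - ym)).sum() / sxx
    return ym + slope * (x0 - xm)


def smooth_rloess(
    curve: BoundaryCurve, window_frac: float = 0.2, iterations: int = 3
) -> BoundaryCurve:
    """Robust LOWESS smoothing of a dense boundary curve.

    Degree-1 local fits with tricube distance weights over the
    ``round(window_frac * width)`` nearest columns, followed by
    ``iterations`` bisquare robustness passes that downweight points by
    their residual relative to 6x the median absolute residual (Cleveland's
    scheme).  The robustness scale is floored a little above machine
    precision so an isolated outlier on an otherwise exact curve is still
    rejected rather than poisoning the scale estimate.  A locally linear
    fit reproduces affine curves exactly, so smoothing never bends a
    straight boundary.
    """
    if not (0 < window_frac <= 1):
        raise ValidationError("window_frac must be in (0, 1]")
    y = np.asarray(curve.rows, dtype=float)
    n = y.size
    k = int(round(window_frac * n))
    if k < 3:
        raise ValidationError("smoothing window spans fewer than 3 columns")
    k = min(k, n)
    x = np.arange(n, dtype=float)
    delta = np.ones(n)
    fit = y.copy()
    scale_floor = 1e-8 * max(1.0, float(np.median(np.abs(y))))
    for pass_idx in range(iterations + 1):
        for i in range(n):
            lo = min(max(i - (k - 1) // 2, 0), n - k)
            sl = slice(lo, lo + k)
            d = np.abs(x[sl] - x[i])
            dmax = d.max()
            if dmax == 0:
                fit[i] = y[i]
                continue
            w = (1.0 - (d / dmax) ** 3) ** 3 * delta[sl]
            if w.sum() <= 0:  # whole window robust-rejected: distance only
                w = (1.0 - (d / dmax) ** 3) ** 3
            fit[i] = _weighted_linear_fit(x[sl], y[sl], w, x[i])
        if pass_idx == iterations:
            break
        resid = y - fit
        cutoff = max(6.0 * float(np.median(np.abs(resid))), scale_floor)
        delta = np.clip(1.0 - (resid / cutoff) ** 2, 0.0, 1.0) ** 2
    return BoundaryCurve(rows=np.maximum(fit, 0.0), kind=curve.kind)


def demarcate_haller(
    large: LargeVesselSet,
    vessels: VesselLabelMap,
    cib: BoundaryCurve,
    cob: BoundaryCurve,
    config: PipelineConfig | None = None,
) -> HallerBoundary:
    """Two-stage interpolation of the Haller boundary, clamped into the band.

    With no large vessels the boundary degenerates to the COB (a Haller
    layer of zero thickness) and ``fallback_used`` is set.
    """
    cfg = config or PipelineConfig()
    if cib.width != cob.width:
        raise ValidationError("CIB/COB widths differ")
    anchors = anchor_points(large, vessels)
    if not anchors:
        logger.warning("no large vessels: Haller boundary falls back to COB")
        return HallerBoundary(
            curve=BoundaryCurve(rows=cob.rows.copy(), kind=BoundaryKind.HALLER),
            anchor_points=(),
            fallback_used=True,
        )
    linear = interpolate_linear(anchors, width=cob.width)
    smooth = smooth_rloess(linear, window_frac=cfg.smooth_window_frac)
    clamped = clamp_to_band(smooth, cib, cob)
    return HallerBoundary(
        curve=clamped, anchor_points=tuple(anchors), fallback_used=False
    )
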