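"""Synthetic B-scan phantoms with known choroid anatomy.

A phantom draws a choroid band between two smooth boundary curves on a
dark background: bright stroma with dark elliptical vessel lumens whose
caliber increases with depth, mirroring choroidal anatomy — small
choriocapillaris vessels near the inner boundary, medium Sattler-layer
vessels in the middle, and large Haller-layer vessels adjoining the
choroid-sclera interface.  Multiplicative L-look gamma speckle (mean 1,
shape = number of looks) models OCT coherent noise.

The ground-truth Haller boundary is constructed with the *same* two-stage
interpolation the pipeline applies (linear through the planted large
vessels' innermost pixels, then robust LOWESS), so recovery tests isolate
segmentation error from curve-construction convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .demarcate import interpolate_linear, smooth_rloess
from .io import (
    BoundaryCurve,
    BoundaryKind,
    BScan,
    PipelineConfig,
    ValidationError,
    clamp_to_band,
    round_half_up,
)

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "Vessel", "PhantomTruth", "GenerationError",
           "generate_phantom", "degrade"]


class GenerationError(RuntimeError):
    """Raised when vessels cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of a phantom B-scan."""

    width: int = 512
    height: int = 256
    cib_depth: float = 50.0
    choroid_thickness: float = 150.0
    n_large: int = 4
    n_medium: int = 8
    n_small: int = 30
    large_radius_range: tuple[float, float] = (12.0, 20.0)
    medium_radius_range: tuple[float, float] = (5.0, 10.0)
    small_radius_range: tuple[float, float] = (1.0, 3.0)
    stroma_level: float = 0.65
    lumen_level: float = 0.15
    # surround, mimicking the tissues framing the choroid in a B-scan:
    # dark vitreous, moderately reflective retina, a thin bright RPE band
    # just above the CIB, and moderately bright sclera below the COB.
    vitreous_level: float = 0.05
    retina_level: float = 0.50
    rpe_level: float = 0.85
    sclera_level: float = 0.70
    retina_thickness: int = 35
    rpe_thickness: int = 3
    speckle_looks: int = 4
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.small_radius_range[1] < self.medium_radius_range[0]
                and self.medium_radius_range[1] < self.large_radius_range[0]):
            raise ValidationError(
                "radius ranges must be strictly ordered: small < medium < large"
            )
        for lo, hi in (self.small_radius_range, self.medium_radius_range,
                       self.large_radius_range):
            if not (0 < lo <= hi):
                raise ValidationError("radius ranges must be positive")
        if self.width < 32 or self.height < 32:
            raise ValidationError("phantom must be at least 32x32")
        if self.speckle_looks < 1:
            raise ValidationError("speckle_looks must be >= 1")


@dataclass(frozen=True)
class Vessel:
    center_row: float
    center_col: float
    radius_row: float
    radius_col: float
    stratum: str  # "large" | "medium" | "small"


@dataclass(frozen=True)
class PhantomTruth:
    image: BScan
    cib: BoundaryCurve
    cob: BoundaryCurve
    haller_truth: BoundaryCurve
    vessels: tuple[Vessel, ...]
    spec: PhantomSpec
    lumen_mask: np.ndarray = field(repr=False, default=None)


def _smooth_curve(rng: np.random.Generator, width: int, base: float,
                  amplitude: float) -> np.ndarray:
    """Low-frequency sum of 1-3-period sinusoids around a base depth."""
    x = np.arange(width, dtype=float) / width
    curve = np.full(width, base, dtype=float)
    for k in (1, 2, 3):
        amp = rng.uniform(0.2, 1.0) * amplitude / k
        phase = rng.uniform(0, 2 * np.pi)
        curve += amp * np.sin(2 * np.pi * k * x + phase)
    return curve


def _ellipses_clear(v: Vessel, placed: list[Vessel], margin: float) -> bool:
    for u in placed:
        dr = (v.center_row - u.center_row) / (v.radius_row + u.radius_row + margin)
        dc = (v.center_col - u.center_col) / (v.radius_col + u.radius_col + margin)
        if dr * dr + dc * dc < 1.0:
            return False
    return True


def _place_stratum(
    rng: np.random.Generator,
    spec: PhantomSpec,
    cib: np.ndarray,
    cob: np.ndarray,
    stratum: str,
    count: int,
    radius_range: tuple[float, float],
    depth_frac: tuple[float, float],
    placed: list[Vessel],
    margin: float = 5.0,
    max_attempts: int = 1000,
) -> list[Vessel]:
    new: list[Vessel] = []
    # large vessels get jittered even column spacing so anchors span the scan
    slots = None
    if stratum == "large" and count > 0:
        edge = radius_range[1] + 2
        slots = np.linspace(edge, spec.width - 1 - edge, count)
    for i in range(count):
        for attempt in range(max_attempts):
            r_col = rng.uniform(*radius_range)
            r_row = r_col * rng.uniform(0.7, 1.0)
            if slots is not None:
                spread = (slots[1] - slots[0]) / 3 if count > 1 else spec.width / 6
                c = float(np.clip(slots[i] + rng.uniform(-spread, spread),
                                  r_col + 1, spec.width - 2 - r_col))
            else:
                c = rng.uniform(r_col + 1, spec.width - 2 - r_col)
            ci = int(round(c))
            band_lo, band_hi = cib[ci], cob[ci]
            thickness = band_hi - band_lo
            if stratum == "large":
                # bottom edge hugs the COB: gap of 1-4 px
                gap = rng.uniform(1.0, 4.0)
                r = band_hi - gap - r_row
            else:
                frac = rng.uniform(*depth_frac)
                r = band_lo + frac * thickness
            if r - r_row < band_lo + 1 or r + r_row > band_hi - 1:
                continue
            v = Vessel(r, c, r_row, r_col, stratum)
            if _ellipses_clear(v, placed + new, margin):
                new.append(v)
                break
        else:
            raise GenerationError(
                f"could not place {stratum} vessel {i + 1}/{count} after "
                f"{max_attempts} attempts; try smaller counts"
            )
    return new


def _render(spec: PhantomSpec, cib: np.ndarray, cob: np.ndarray,
            vessels: list[Vessel]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(spec.height)[:, None]
    cib_i = round_half_up(cib)[None, :]
    cob_i = round_half_up(cob)[None, :]
    band = (rows >= cib_i) & (rows <= cob_i)
    rpe_top = cib_i - spec.rpe_thickness
    retina_top = rpe_top - spec.retina_thickness
    img = np.full((spec.height, spec.width), spec.vitreous_level)
    img[(rows >= retina_top) & (rows < rpe_top)] = spec.retina_level
    img[(rows >= rpe_top) & (rows < cib_i)] = spec.rpe_level
    img[rows > cob_i] = spec.sclera_level
    img[band] = spec.stroma_level
    lumen = np.zeros_like(band)
    rr = np.arange(spec.height, dtype=float)[:, None]
    cc = np.arange(spec.width, dtype=float)[None, :]
    for v in vessels:
        inside = (((rr - v.center_row) / v.radius_row) ** 2
                  + ((cc - v.center_col) / v.radius_col) ** 2) <= 1.0
        lumen |= inside
    lumen &= band
    img[lumen] = spec.lumen_level
    return img, lumen


def _haller_truth(spec: PhantomSpec, lumen_by_vessel: list[np.ndarray],
                  cib: BoundaryCurve, cob: BoundaryCurve,
                  large: list[Vessel]) -> BoundaryCurve:
    anchors = []
    for mask in lumen_by_vessel:
        rrr, ccc = np.nonzero(mask)
        if rrr.size == 0:
            continue
        top = rrr.min()
        anchors.append((int(top), int(ccc[rrr == top].min())))
    anchors.sort(key=lambda rc: rc[1])
    linear = interpolate_linear(anchors, width=spec.width)
    cfg = PipelineConfig()
    smooth = smooth_rloess(linear, window_frac=cfg.smooth_window_frac)
    return clamp_to_band(smooth, cib, cob).with_kind(BoundaryKind.HALLER)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Deterministically render a phantom B-scan with full ground truth."""
    rng = np.random.default_rng(spec.seed)
    cib_rows = _smooth_curve(rng, spec.width, spec.cib_depth, amplitude=8.0)
    thickness = _smooth_curve(rng, spec.width, spec.choroid_thickness, amplitude=3.0)
    cib_rows = np.clip(cib_rows, 2, spec.height - 4)
    cob_rows = np.clip(cib_rows + thickness, cib_rows + 8, spec.height - 2)

    placed: list[Vessel] = []
    large = _place_stratum(rng, spec, cib_rows, cob_rows, "large",
                           spec.n_large, spec.large_radius_range, (0.66, 0.95), placed)
    placed += large
    medium = _place_stratum(rng, spec, cib_rows, cob_rows, "medium",
                            spec.n_medium, spec.medium_radius_range, (0.35, 0.62), placed)
    placed += medium
    small = _place_stratum(rng, spec, cib_rows, cob_rows, "small",
                           spec.n_small, spec.small_radius_range, (0.04, 0.30), placed)
    placed += small

    img, lumen = _render(spec, cib_rows, cob_rows, placed)

    if not spec.noise_free:
        looks = float(spec.speckle_looks)
        img = img * rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    cib = BoundaryCurve(cib_rows, BoundaryKind.CIB)
    cob = BoundaryCurve(cob_rows, BoundaryKind.COB)

    rr = np.arange(spec.height, dtype=float)[:, None]
    cc = np.arange(spec.width, dtype=float)[None, :]
    large_masks = []
    for v in large:
        m = (((rr - v.center_row) / v.radius_row) ** 2
             + ((cc - v.center_col) / v.radius_col) ** 2) <= 1.0
        large_masks.append(m)
    haller = (_haller_truth(spec, large_masks, cib, cob, large)
              if large else cob.with_kind(BoundaryKind.HALLER))

    scan = BScan(pixels=img, source_path=f"<phantom seed={spec.seed}>")
    return PhantomTruth(
        image=scan, cib=cib, cob=cob, haller_truth=haller,
        vessels=tuple(placed), spec=spec, lumen_mask=lumen,
    )


def degrade(phantom: PhantomTruth, contrast_drop: float) -> PhantomTruth:
    """Compress lumen/stroma separation by ``contrast_drop`` before speckle.

    Geometry and all truths are unchanged (the spec's seed fixes vessel
    placement independently of intensity levels).
    """
    if not (0.0 <= contrast_drop < 1.0):
        raise ValidationError("contrast_drop must be in [0, 1)")
    if contrast_drop == 0.0:
        return phantom
    spec = phantom.spec
    gap = spec.stroma_level - spec.lumen_level
    new_lumen = spec.lumen_level + gap * contrast_drop
    return generate_phantom(replace(spec, lumen_level=new_lumen))
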