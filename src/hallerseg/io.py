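"""Domain types and file I/O for OCT B-scans and boundary curves.

Conventions used throughout the package:

* Row 0 is the innermost (vitreous-side) row of a B-scan; larger row
  indices are deeper (scleral side).  "Innermost" therefore always means
  the smaller row index.
* Rows and columns are 0-based.  Boundary curves store one fractional row
  position per image column; rounding to integer pixels happens only when
  a curve is used to index a raster, using round-half-up.
* Pixel intensities are normalized to [0, 1] on load.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryKind",
    "BScan",
    "BoundaryCurve",
    "PipelineConfig",
    "ValidationError",
    "read_bscan",
    "read_boundary_csv",
    "write_boundary_csv",
    "round_half_up",
    "clamp_to_band",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def round_half_up(values: np.ndarray | float) -> np.ndarray:
    """Round fractional row positions to integer pixel rows, halves up."""
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(int)


class BoundaryKind(enum.Enum):
    CIB = "cib"          # choroid inner boundary
    COB = "cob"          # choroid outer boundary (choroid-sclera interface)
    HALLER = "haller"    # Haller/Sattler boundary
    MANUAL = "manual"    # a manual marking of the Haller boundary


@dataclass(frozen=True)
class BScan:
    """A single OCT B-scan: rows are axial depth, columns lateral position."""

    pixels: np.ndarray
    axial_scale_um: float = 2.6
    lateral_scale_um: float = 2.6
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError(f"B-scan must be 2D, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValidationError(
                f"B-scan must be at least 32x32 pixels, got {px.shape}"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("B-scan intensities must lie in [0, 1]")
        if self.axial_scale_um <= 0:
            raise ValidationError("axial_scale_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BoundaryCurve:
    """One axial (row) position per image column; fractional rows allowed."""

    rows: np.ndarray
    kind: BoundaryKind = BoundaryKind.HALLER

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 1 or rows.size == 0:
            raise ValidationError("boundary curve must be a non-empty 1D sequence")
        if not np.all(np.isfinite(rows)) or rows.min() < 0:
            raise ValidationError("boundary rows must be finite and non-negative")
        object.__setattr__(self, "rows", rows)

    @property
    def width(self) -> int:
        return self.rows.size

    def validate_for(self, scan: BScan) -> None:
        if self.width != scan.width:
            raise ValidationError(
                f"curve width {self.width} != scan width {scan.width}"
            )
        if self.rows.max() > scan.n_rows - 1:
            raise ValidationError("boundary curve leaves the image")

    def with_kind(self, kind: BoundaryKind) -> "BoundaryCurve":
        return BoundaryCurve(rows=self.rows, kind=kind)


def clamp_to_band(
    curve: BoundaryCurve, cib: BoundaryCurve, cob: BoundaryCurve
) -> BoundaryCurve:
    """Clamp a curve column-wise into the choroid band [cib, cob]."""
    if not (curve.width == cib.width == cob.width):
        raise ValidationError("curve widths do not match")
    rows = np.clip(curve.rows, cib.rows, cob.rows)
    return BoundaryCurve(rows=rows, kind=curve.kind)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the demarcation pipeline.

    Defaults follow the published recipe where it states a value
    (5x5 Wiener window, 8x8 equalization tiling, 5x5 closing element,
    5-pixel CSI proximity, smoothing span of one fifth of the scan width);
    the remaining knobs carry this package's documented defaults.
    """

    wiener_window: int = 5
    log_domain_wiener: bool = True
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.002
    enhance_exponent: float = 2.0
    opening_se: int = 5
    closing_se: int = 5
    hminima_depth: float = 2.0
    csi_proximity_px: int = 5
    min_vessel_px: int = 5
    smooth_window_frac: float = 0.2
    axial_scale_um: float = 2.6

    def __post_init__(self) -> None:
        if self.wiener_window < 3 or self.wiener_window % 2 == 0:
            raise ValidationError("wiener_window must be odd and >= 3")
        if min(self.clahe_tiles) < 1:
            raise ValidationError("clahe_tiles must be positive")
        if self.closing_se < 1 or self.csi_proximity_px < 0:
            raise ValidationError("closing_se must be >= 1, csi_proximity_px >= 0")
        if not (0.0 < self.smooth_window_frac <= 1.0):
            raise ValidationError("smooth_window_frac must be in (0, 1]")
        if self.hminima_depth <= 0 or self.enhance_exponent <= 0:
            raise ValidationError("hminima_depth and enhance_exponent must be > 0")
        if self.axial_scale_um <= 0:
            raise ValidationError("axial_scale_um must be positive")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _to_unit_interval(arr: np.ndarray, path: str) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        divisor = float(np.iinfo(arr.dtype).max)
    else:
        divisor = None
    if arr.ndim == 3:  # RGB(A): luminance by plain channel average
        arr = arr[..., :3].mean(axis=2)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"{path}: expected a 2D grayscale image")
    arr = arr.astype(float)
    if divisor is not None:
        return arr / divisor
    if arr.max() > 1.0:  # float TIFF stored on an integer scale
        arr = arr / arr.max()
    return arr


def read_bscan(path: str | Path, config: PipelineConfig | None = None) -> BScan:
    """Read an 8/16-bit grayscale PNG or TIFF B-scan, normalized to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        with Image.open(path) as im:
            if im.mode in {"I;16", "I;16B", "I"}:
                arr = np.asarray(im, dtype=np.uint16)
            else:
                arr = np.asarray(im)
    pixels = _to_unit_interval(np.asarray(arr), str(path))
    cfg = config or PipelineConfig()
    return BScan(
        pixels=pixels,
        axial_scale_um=cfg.axial_scale_um,
        source_path=str(path),
    )


def read_boundary_csv(
    path: str | Path,
    width: int,
    kind: BoundaryKind = BoundaryKind.MANUAL,
) -> BoundaryCurve:
    """Read a "column,row" CSV into a dense curve of the requested width.

    Missing interior columns are filled by linear interpolation between the
    nearest present columns; columns beyond the first/last present column
    take the nearest present value.
    """
    path = Path(path)
    cols: list[int] = []
    rows: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty boundary CSV")
        for rec in reader:
            if not rec or not rec[0].strip():
                continue
            cols.append(int(float(rec[0])))
            rows.append(float(rec[1]))
    if not cols:
        raise ValidationError(f"{path}: boundary CSV has no data rows")
    order = np.argsort(cols)
    cols_arr = np.asarray(cols, dtype=float)[order]
    rows_arr = np.asarray(rows, dtype=float)[order]
    if rows_arr.min() < 0:
        raise ValidationError(f"{path}: boundary rows must be non-negative")
    dense = np.interp(np.arange(width, dtype=float), cols_arr, rows_arr)
    return BoundaryCurve(rows=dense, kind=kind)


def write_boundary_csv(curve: BoundaryCurve, path: str | Path) -> Path:
    """Write a curve to the "column,row" CSV dialect (LF endings, UTF-8)."""
    path = Path(path)
    with path.open("w", newline="\n", encoding="utf-8") as fh:
        fh.write("column,row\n")
        for c, r in enumerate(curve.rows):
            fh.write(f"{c},{format(float(r), '.17g')}\n")
    return path
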