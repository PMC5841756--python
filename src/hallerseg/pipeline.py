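"""End-to-end segmentation chain: preprocess → binarize → vessels → demarcate."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .binarize import (
    BinarizedChoroid,
    exponential_enhance,
    restrict_to_choroid,
    threshold_binarize,
)
from .demarcate import HallerBoundary, demarcate_haller
from .io import BoundaryCurve, BScan, PipelineConfig
from .preprocess import PreprocessedBScan, preprocess
from .vessels import (
    LargeVesselSet,
    VesselLabelMap,
    classify_large,
    morphological_close,
    morphological_open,
    watershed_separate,
)

logger = logging.getLogger(__name__)

__all__ = ["SegmentationResult", "segment_bscan"]


@dataclass(frozen=True)
class SegmentationResult:
    """All intermediates of one B-scan segmentation run."""

    preprocessed: PreprocessedBScan
    enhanced: "np.ndarray"
    bcl: BinarizedChoroid
    vessels: VesselLabelMap
    large: LargeVesselSet
    haller: HallerBoundary


def segment_bscan(
    scan: BScan,
    cib: BoundaryCurve,
    cob: BoundaryCurve,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """Demarcate the Haller/Sattler boundary of one B-scan.

    Requires the choroid band (CIB/COB) as input; returns every stage so
    callers can inspect or dump intermediates.
    """
    cfg = config or PipelineConfig()
    cib.validate_for(scan)
    cob.validate_for(scan)
    pre = preprocess(scan.pixels, cfg)
    enhanced = exponential_enhance(pre.pixels, exponent=cfg.enhance_exponent)
    lumen = threshold_binarize(enhanced)
    bcl = restrict_to_choroid(lumen, cib, cob)
    # opening removes speckle residue too thin to hold the structuring
    # element; running it before the closing keeps the closing from welding
    # that residue into false vessel cross-sections
    cleaned = morphological_open(bcl.mask, se=cfg.opening_se)
    closed = morphological_close(cleaned, se=cfg.closing_se)
    bcl_closed = restrict_to_choroid(closed, cib, cob)
    vessel_map = watershed_separate(
        bcl_closed, h=cfg.hminima_depth, min_vessel_px=cfg.min_vessel_px
    )
    large = classify_large(
        vessel_map, cob=cob, proximity_px=cfg.csi_proximity_px
    )
    haller = demarcate_haller(large, vessel_map, cib, cob, cfg)
    return SegmentationResult(
        preprocessed=pre,
        enhanced=enhanced,
        bcl=bcl_closed,
        vessels=vessel_map,
        large=large,
        haller=haller,
    )
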