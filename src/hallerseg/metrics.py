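"""Agreement statistics between Haller boundaries.

Automated demarcations are scored against the manual reference (the
column-wise average of two manual markings) with three per-scan metrics:

* **AD** — mean per-column absolute row difference, converted to μm with
  the axial pixel scale;
* **CC** — Pearson correlation of the two boundary row vectors;
* **DC** — Dice coefficient of the two rasterized Haller-layer regions,
  each region being the band from the Haller boundary down to the COB.

Cohort summaries report mean, sample SD (n-1), min, max and the
coefficient of variation CV = SD/mean per metric, separately for the
automated-vs-reference (P vs M) and manual-vs-manual (M1 vs M2)
comparisons, plus quotient measures.  The quotient of CV is always
QCV = CV_auto / CV_manual.  The quotient of mean depends on the metric's
sense: for error metrics (AD) it is the plain ratio of means; for
similarity metrics on a 0-100% scale (CC, DC) it is taken on the
complement scale, QM = (100 - mean_auto) / (100 - mean_manual), so that a
value near 1 again means parity with manual grading.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BoundaryCurve, ValidationError, round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "MetricKind",
    "ScanAgreement",
    "MetricStats",
    "CohortSummary",
    "manual_reference",
    "absolute_difference",
    "boundary_correlation",
    "dice_layers",
    "scan_agreement",
    "quotient_measures",
    "summarize_cohort",
]


class MetricKind(enum.Enum):
    ERROR = "error"            # smaller is better (AD)
    SIMILARITY = "similarity"  # percentage in [0, 100], larger is better


@dataclass(frozen=True)
class ScanAgreement:
    """Per-scan agreement: AD in μm, CC and DC as fractions."""

    ad_um: float
    cc: float
    dc: float


def _check_widths(a: BoundaryCurve, b: BoundaryCurve) -> None:
    if a.width != b.width:
        raise ValidationError(f"curve widths differ: {a.width} vs {b.width}")


def manual_reference(m1: BoundaryCurve, m2: BoundaryCurve) -> BoundaryCurve:
    """Column-wise arithmetic mean of two manual markings."""
    _check_widths(m1, m2)
    return BoundaryCurve(rows=(m1.rows + m2.rows) / 2.0, kind=m1.kind)


def absolute_difference(
    a: BoundaryCurve, b: BoundaryCurve, axial_scale_um: float
) -> float:
    """Mean per-column absolute row difference, in μm."""
    _check_widths(a, b)
    return float(np.mean(np.abs(a.rows - b.rows)) * axial_scale_um)


def boundary_correlation(a: BoundaryCurve, b: BoundaryCurve) -> float:
    """Pearson correlation of the two boundary row vectors (NaN if constant)."""
    _check_widths(a, b)
    if np.ptp(a.rows) == 0 or np.ptp(b.rows) == 0:
        logger.warning("boundary_correlation: constant curve, correlation undefined")
        return float("nan")
    return float(np.corrcoef(a.rows, b.rows)[0, 1])


def dice_layers(
    haller_a: BoundaryCurve,
    haller_b: BoundaryCurve,
    cib: BoundaryCurve,
    cob: BoundaryCurve,
) -> float:
    """Dice coefficient of the two rasterized Haller-layer regions.

    Each region is {(r, c) : haller(c) <= r <= cob(c)} on the integer pixel
    grid (round half-up).  Computed column-wise as interval overlaps, which
    equals the brute-force pixel count.
    """
    _check_widths(haller_a, haller_b)
    _check_widths(haller_a, cob)
    ha = round_half_up(haller_a.rows)
    hb = round_half_up(haller_b.rows)
    hc = round_half_up(cob.rows)
    count_a = np.clip(hc - ha + 1, 0, None)
    count_b = np.clip(hc - hb + 1, 0, None)
    inter = np.clip(hc - np.maximum(ha, hb) + 1, 0, None)
    denom = int(count_a.sum() + count_b.sum())
    if denom == 0:
        logger.warning("dice_layers: both regions empty, DC defined as 1")
        return 1.0
    return float(2.0 * inter.sum() / denom)


def scan_agreement(
    auto: BoundaryCurve,
    ref: BoundaryCurve,
    cib: BoundaryCurve,
    cob: BoundaryCurve,
    axial_scale_um: float,
) -> ScanAgreement:
    return ScanAgreement(
        ad_um=absolute_difference(auto, ref, axial_scale_um),
        cc=boundary_correlation(auto, ref),
        dc=dice_layers(auto, ref, cib, cob),
    )


def quotient_measures(
    auto: tuple[float, float],
    manual: tuple[float, float],
    metric_kind: MetricKind,
) -> tuple[float, float]:
    """Quotients (QM, QCV) of automated vs manual summary statistics.

    ``auto`` and ``manual`` are (mean, CV) pairs.  Similarity means must be
    on the 0-100% scale; their QM is computed on the complement scale.
    """
    mean_a, cv_a = auto
    mean_m, cv_m = manual
    if cv_m == 0:
        raise ValidationError("manual CV is zero: QCV undefined")
    qcv = cv_a / cv_m
    if metric_kind is MetricKind.ERROR:
        if mean_m == 0:
            raise ValidationError("manual mean is zero: QM undefined")
        qm = mean_a / mean_m
    else:
        if mean_m == 100.0:
            raise ValidationError("manual similarity mean is 100%: QM undefined")
        qm = (100.0 - mean_a) / (100.0 - mean_m)
    return qm, qcv


@dataclass(frozen=True)
class MetricStats:
    mean: float
    sd: float
    min: float
    max: float

    @property
    def cv(self) -> float:
        return self.sd / self.mean if self.mean != 0 else float("nan")


_METRIC_KINDS = {
    "AD": MetricKind.ERROR,
    "CC": MetricKind.SIMILARITY,
    "DC": MetricKind.SIMILARITY,
}


@dataclass(frozen=True)
class CohortSummary:
    """Cohort statistics for both comparisons plus quotient measures.

    ``auto`` and ``manual`` map metric name ("AD" in μm; "CC", "DC" in %)
    to :class:`MetricStats`; ``qm``/``qcv`` hold the quotients (NaN when a
    denominator degenerates).
    """

    auto: dict[str, MetricStats]
    manual: dict[str, MetricStats]
    qm: dict[str, float]
    qcv: dict[str, float]
    n_scans: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("AD", "CC", "DC"):
            unit = "um" if metric == "AD" else "%"
            for method, stats in (("P vs M", self.auto[metric]),
                                  ("M1 vs M2", self.manual[metric])):
                rows.append({
                    "metric": metric, "method": method, "unit": unit,
                    "mean": stats.mean, "sd": stats.sd,
                    "min": stats.min, "max": stats.max, "cv": stats.cv,
                })
            rows.append({
                "metric": metric, "method": "quotient", "unit": "ratio",
                "mean": self.qm[metric], "sd": self.qcv[metric],
                "min": math.nan, "max": math.nan, "cv": math.nan,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def _s(st: MetricStats) -> dict:
            return {"mean": st.mean, "sd": st.sd, "min": st.min,
                    "max": st.max, "cv": st.cv}
        return {
            "n_scans": self.n_scans,
            "auto": {k: _s(v) for k, v in self.auto.items()},
            "manual": {k: _s(v) for k, v in self.manual.items()},
            "qm": dict(self.qm),
            "qcv": dict(self.qcv),
        }


def _stats(values: np.ndarray) -> MetricStats:
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return MetricStats(
        mean=float(values.mean()),
        sd=sd,
        min=float(values.min()),
        max=float(values.max()),
    )


def summarize_cohort(
    auto_vs_ref: list[ScanAgreement],
    m1_vs_m2: list[ScanAgreement],
) -> CohortSummary:
    """Cohort summary mirroring the AD/CC/DC statistics table.

    CC and DC are reported on the percent scale.  Degenerate quotient
    denominators (e.g. identical comparisons with zero spread) yield NaN
    quotients with a logged warning rather than an error.
    """
    if not auto_vs_ref or not m1_vs_m2:
        raise ValidationError("cohorts must be non-empty")
    if len(auto_vs_ref) != len(m1_vs_m2):
        raise ValidationError("comparison lists must have equal length")

    def _values(agreements: list[ScanAgreement], metric: str) -> np.ndarray:
        if metric == "AD":
            return np.asarray([a.ad_um for a in agreements])
        if metric == "CC":
            return np.asarray([a.cc for a in agreements]) * 100.0
        return np.asarray([a.dc for a in agreements]) * 100.0

    auto: dict[str, MetricStats] = {}
    manual: dict[str, MetricStats] = {}
    qm: dict[str, float] = {}
    qcv: dict[str, float] = {}
    for metric, kind in _METRIC_KINDS.items():
        auto[metric] = _stats(_values(auto_vs_ref, metric))
        manual[metric] = _stats(_values(m1_vs_m2, metric))
        try:
            qm[metric], qcv[metric] = quotient_measures(
                (auto[metric].mean, auto[metric].cv),
                (manual[metric].mean, manual[metric].cv),
                kind,
            )
        except ValidationError as exc:
            logger.warning("quotients for %s degenerate: %s", metric, exc)
            qm[metric], qcv[metric] = float("nan"), float("nan")
    return CohortSummary(
        auto=auto, manual=manual, qm=qm, qcv=qcv, n_scans=len(auto_vs_ref)
    )
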