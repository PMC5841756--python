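# Methods

This note records the model behind each pipeline stage, the parameters
that matter, the numerical choices made where the design was open, and
what the synthetic phantoms do and do not establish.

## Coordinate and intensity conventions

Row 0 is the vitreous-side (innermost) row; larger rows are deeper.
Boundary curves hold one fractional row per column and are rounded
half-up only when indexing a raster.  Images load into [0, 1]
(8-bit ÷ 255, 16-bit ÷ 65535, RGB by channel average).

## Despeckling

OCT speckle is multiplicative: for an L-look intensity image the
observed value is the underlying reflectivity times a Gamma(L, 1/L)
variate, so the noise standard deviation scales with the signal.  The
adaptive (local-statistics) Wiener filter used here,

    out = m + max(0, v − nv) / max(v, nv) · (x − m),

with local mean `m` and variance `v` over a `wiener_window`² window
(default 5, edge-replicated borders) and noise floor `nv` = image-wide
mean of local variances, assumes level-independent additive noise.
`preprocess` therefore applies it homomorphically by default
(`log_domain_wiener=True`): in the log domain multiplicative speckle
becomes additive with constant variance trigamma(L), exactly the
filter's model, and homogeneous regions collapse to their (geometric)
local mean while strong edges — where `v` far exceeds `nv` — are
preserved.  In the linear domain the filter retains roughly half the
stroma speckle because it reads the level-dependent variance as signal.
The operator `wiener_denoise` itself always implements the formula above
verbatim.

## Contrast enhancement

Contrast-limited adaptive histogram equalization over `clahe_tiles`
(default 8×8) with bilinear blending between tile mappings.  The clip
limit (skimage normalization) defaults to 0.002: equalization of a
statistically homogeneous despeckled region is pure noise amplification,
and 0.002 is the largest value in our sweeps that leaves the subsequent
lumen/stroma threshold intact while still lifting genuine low-contrast
structure.  A constant image is returned unchanged (degenerate
histogram).

## Binarization

`exponential_enhance` applies v → v^exponent (default 2.0) and rescales
to [0, 1]; exponents above 1 push the already-dark lumens toward 0 and
widen the bimodal gap.  `threshold_binarize` takes a global 256-bin Otsu
threshold and maps the dark class to True (lumen).  The mask is then
zeroed outside the band [CIB(c), COB(c)] per column.  The exact
enhancement recipe is deliberately split into two small operators so an
alternative (e.g. a local threshold) is a drop-in replacement.

## Morphological cleanup

Two dual steps with 5×5 square structuring elements on the lumen-true
mask:

* **opening** (`opening_se`, default 5) removes foreground specks too
  thin to contain the element — the residue that pixelwise thresholding
  of speckle inevitably leaves in the stroma.  Removing "tiny spurious
  structures" is an opening on this polarity; a closing applied first
  would weld the specks into false vessels instead.
* **closing** (`closing_se`, default 5) then fills sub-element gaps and
  pepper inside lumens.

Both are computed on a zero-padded copy so they are the true
opening/closing of the finite foreground set (closing extensive, opening
anti-extensive, no border erosion).  The opening also removes vessels of
radius ≲ 2 px; these are choriocapillaris-scale structures at or below
the resolving power assumed here and play no role in the Haller
boundary.

## Vessel separation

Relief = −EDT(mask) (exact Euclidean distance transform).  Markers are
the **extended minima** at depth `hminima_depth` (default 2.0 px of
distance): regional minima of the reconstruction-by-erosion of
relief + h over relief.  Note this is the merged-plateau semantics —
basins separated by a ridge shallower than h yield a single marker —
which is what suppresses over-segmentation of one vessel with several
shallow distance maxima.  (A residue-based variant that marks only the
original basin pixels gives two markers in that situation and re-splits
the vessel.)  The default h = 2 was calibrated on phantoms so
overlapping equal disks split while single disks do not.

Flooding uses 4-connectivity with watershed lines; ridge pixels are
removed (`mask AND NOT w`) and components labeled with 8-connectivity.
Components under `min_vessel_px` (default 5) are discarded.  Vessels
clipped by the lateral borders are retained.

## Large-vessel rule

Per label, the distance to the CSI is the minimum over its pixels of the
*vertical* gap COB(c) − r (a depth statement, stable under lateral
anisotropy).  Step 1 admits labels within `csi_proximity_px` (default
5).  Step 2 computes the median area of the step-1 set (even count →
mean of the middle pair) and admits remaining labels with area
*strictly* greater.  With no CSI-adjacent vessels the set is empty and
the boundary falls back to the COB (zero-thickness Haller layer) with a
warning; healthy scans do not hit this branch.

## Boundary construction

One anchor per large vessel: its minimum-row pixel, ties broken by
minimum column; duplicate columns collapse to the smaller row.
Piecewise-linear interpolation through the anchors (constant extension
beyond the outermost anchors — linear extrapolation explodes when two
anchors sit close to a border), then robust locally weighted linear
regression: span = `smooth_window_frac` × width (default 1/5), tricube
distance weights, 3 bisquare robustness passes with cutoff
6 × median |residual|.  The robustness scale is floored at
1e−8 · max(1, median |y|): without the floor, an isolated outlier anchor
on an otherwise exact curve drives the median residual to machine zero
and the outlier is never rejected (a failure mode we measured in an
off-the-shelf implementation, which is why the smoother is implemented
here and cross-checked against both a naive reference and statsmodels
in the tests).  Local linear fits reproduce affine curves exactly, so
smoothing never bends a straight boundary.  The result is clamped into
[CIB, COB].

## Agreement metrics

* AD = mean per-column |Δrow| × `axial_scale_um`.  The axial scale is a
  config parameter (default 2.6 μm/px, a typical swept-source value);
  no vendor value is asserted.
* CC = Pearson correlation of the two row vectors (undefined for a
  constant curve → NaN with a warning).
* DC = Dice coefficient of the rasterized regions
  {(r, c) : haller(c) ≤ r ≤ COB(c)} — the Haller layer itself.  Which
  region the original evaluation rasterized is not stated; the Haller
  region is the documented choice here and is isolated in one function.
* Cohort summary: mean, sample SD (n−1; a single scan reports SD = 0),
  min, max, CV = SD/mean, per comparison (automated-vs-reference and
  manual-vs-manual).  QCV = CV_auto / CV_manual for every metric.
  QM = mean ratio for error metrics; for similarity metrics on the
  percent scale QM = (100 − M_auto)/(100 − M_manual), so that QM → 1
  again means parity.  Degenerate denominators yield NaN quotients with
  a warning rather than an error at the cohort level.

## Synthetic phantoms

`PhantomSpec` defaults render a 512×256 scan: smooth sinusoidal CIB
(depth 50 ± ~8 px) and COB (thickness 150 ± ~3 px); stroma 0.65, lumen
0.15; surround mimicking the tissues framing the choroid — vitreous
0.05, retina 0.50, a 3-px RPE stripe 0.85 just above the CIB, sclera
0.70 below the COB.  (A pitch-black surround is unrealistic and creates
two phantom-only artifacts: a dark fringe hugging the band after any
smoothing, and an Otsu histogram dominated by background.)  Vessels are
non-overlapping ellipses (≥ 5 px clearance) in three strata: small
(r 1–3) in the inner 4–30% of the band, medium (r 5–10) mid-band, large
(r 12–20) with their outer edge 1–4 px above the COB, mirroring the
anatomical caliber ordering.  Large-vessel columns are evenly spaced
with jitter so anchors span the scan.  Speckle is multiplicative
Gamma(L, 1/L) with L = `speckle_looks` (default 4); `noise_free`
disables it.  Everything is driven by one `numpy` Generator seeded from
`spec.seed`, so regeneration is bit-identical.

The ground-truth Haller boundary is built by the *same* two-stage
interpolation the pipeline applies, from the true innermost pixels of
the planted large vessels — recovery error therefore measures
segmentation quality, not curve-construction convention.

What the phantoms do **not** emulate: depth-dependent attenuation and
shadowing under large vessels, spatially correlated speckle grain,
motion artifacts, real retinal layering, or diseased-eye morphology.
Passing the recovery suite shows the algorithm is correct under its
stated model, not that it meets the published clinical agreement levels
on real scans.

## Problem sizes in the test suite

Operator-oracle equivalence runs on ≤ 64×64 instances against explicit
loop/flood/enumeration references.  Recovery uses 20 speckled and 20
noise-free 512×256 phantoms (3–6 large, 6–10 medium, 20–40 small
vessels, 4-look speckle), the cohort sizes the acceptance properties
are stated over; measured recovery is ~0.4 px mean boundary error
speckled and ~0.2 px noise-free, with layer Dice ≥ 0.97.

## Known limitations

* CIB/COB detection is out of scope; the built-in fallback (brightest
  row in the upper half as an RPE proxy + constant depth) is plumbing
  for end-to-end runs, not a validated detector.
* The binarization recipe (power + global Otsu) is this package's
  documented stand-in for an incompletely specified published recipe;
  both knobs are exposed.
* Large/medium classification inherits the median criterion's
  assumption that CSI-adjacent calibers represent Haller's layer; eyes
  with pathology violating that ordering need a different rule.
* Single B-scans only; no cross-scan (volumetric) smoothness.
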