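# Methods

## Scope and model of the data

`octaquant` quantifies delineated mCNV lesions in 8-bit en-face OCTA
rasters with a known pixel scale (px/mm; default 170, i.e. a 1024×1024
export spans ≈ 6.02 mm). The lesion ROI is taken either from an explicit
binary mask file or, following the cleared-background convention, as the
nonzero support of the input. All biomarkers are restricted to the ROI.
Coordinates are row-major with origin at the top-left; physical lengths are
pixel quantities divided by the scale.

## Preprocessing

1. Multi-channel inputs collapse to grayscale by an equal-weight channel
   mean (OCTA exports are pseudo-gray, so luminance weighting is moot).
2. `to_8bit`: linear min–max rescale onto [0, 255], rounded; a constant
   image maps to zeros by convention.
3. Percentile contrast stretch: the `saturation_fraction` (default 0.0035)
   and `1 − saturation_fraction` quantiles of ROI intensities map to 0 and
   255 with clipping. 0.0035 is the common "auto" convention of
   interactive brightness/contrast tools; degenerate ranges pass through.
   Contrast precedes both filter branches.

## Branch 1 — vessel area

**Gaussian (1A).** Convolution with the normalized kernel
G(x,y) = (1/2πσ²)e^(−(x²+y²)/2σ²), σ = 1 px default. Borders replicate
edge values (avoids dark halos that would bias vessel area at the lesion
boundary); output is rounded back to 8-bit, so constants are preserved and
no pixel leaves the input range.

**Frangi vesselness (1B).** Scale-normalized Hessian eigenvalues
|λ₁| ≤ |λ₂| (second Gaussian derivatives × σ²) give, per pixel and scale,

    V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²))   if λ₂ < 0, else 0

with R_B = λ₁/λ₂, S = √(λ₁²+λ₂²). Bright vessels on a dark ground require
λ₂ < 0. Defaults: scales {1, 1.5, 2, 2.5, 3} px (covering the 3–9 px
calibers seen at 170 px/mm), β = 0.5, and c set per scale to half the
maximum S over the image when not given. The response is the maximum over
scales, rescaled to 8-bit. Numerical note: the image mean is subtracted
before filtering — analytically a no-op for the Hessian, but it zeroes the
truncated-kernel residue (otherwise a constant-99 image yields |λ| ≈ 7e-3
of pure numerical noise that rescaling would blow up to full range) and
makes invariance to constant shifts bit-exact.

**Local median threshold (1C).** A pixel is vessel iff its intensity is
strictly greater than the median of its (2r+1)×(2r+1) window (r = 8)
minus `offset` (default 0). The window is clipped at the image bounds —
border pixels use their true, smaller neighborhoods, and an even sample
count averages the two middle values. Ties go to background, which makes
exactly-flat regions all-background. Outside-ROI pixels are always
background. Vessel area is the vessel pixel count / scale²; density is
its ratio to the mCNV area.

## Branch 2 — skeleton morphometry

**Mexican hat (2A).** Convolution with the 2D Ricker wavelet
ψ(x,y) = (1/πσ⁴)(1−(x²+y²)/2σ²)e^(−(x²+y²)/2σ²), truncated to a
(2r+1)×(2r+1) window (r = 13) and re-centered to exactly zero sum, with
σ = r/3 so the wavelet decays to ≈ 0 at the window edge (σ separately
overridable). Negative responses clip to 0; the rest rescales to 8-bit.
The kernel is radially symmetric, so responses commute with 90° rotations.

**Binarize, thin, tag, prune (2B).** The Ricker response is binarized with
the same median thresholder, then thinned to a 1-px, 8-connected skeleton
(a subset of the foreground, component-count preserving, idempotent).
Skeleton pixels are classified by 8-neighbor count: 1 → endpoint, 2 →
slab, ≥ 3 → junction pixel; 8-connected junction-pixel clumps merge into
single junction nodes (thinning routinely produces 2–5 px clumps; counting
pixels would inflate the junction biomarker). Slab runs between nodes
become branches; geodesic length is the chain-code sum (1 px per axial
step, √2 px per diagonal) over the path including the touching node
pixels; Euclidean length is the straight-line distance between the path's
end pixels, so geodesic ≥ Euclidean always holds. Pure cycles (no node)
are reported as loop branches with zero Euclidean length. "Thin input" is
validated as "fixed point of the thinning algorithm"; thick inputs raise.

Pruning removes 8-connected components smaller than
`min_component_pixels` (default 5 — speckle flecks), and, only when a
positive `prune_end_branches_shorter_than` (mm) is configured, iteratively
deletes terminal branches shorter than the threshold, re-thinning and
re-tagging to a deterministic fixed point. End-branch pruning defaults to
off: deleting every terminal branch indiscriminately would iterate any
tree to nothing.

## Derived biomarkers

- vessel length = Σ branch geodesic lengths (mm);
- junctions = number of junction nodes (missing-value conventions: zero
  length makes junction density and diameter undefined → empty CSV cell);
- junction density = junctions / length (n/mm);
- vessel diameter = vessel area / vessel length × 1000 (μm) — the standard
  mean-caliber estimator;
- tortuosity = unweighted mean over branches of geodesic/Euclidean length,
  loops excluded (a length-weighted variant is available);
- fractal dimension = least-squares slope of log N(s) against log(1/s),
  N(s) the number of occupied s×s cells of a grid anchored at the image
  origin, sizes {2, 3, 4, 6, 8, 12, 16, 32, 64} clipped to half the
  smaller image side (no grid-offset averaging, matching common plugin
  behavior). Computed on the pruned skeleton.

A consistency layer enforces the defining identities (density =
area-ratio, junction density = junctions/length, tortuosity ≥ 1,
0 ≤ FD ≤ 2 + 0.01 — the small allowance exists because partial cells at
the far edges count fully, pushing a filled plane's slope to 2.0007).

## Known measurement biases

- **Chain-code length bias.** The (1, √2) step metric overestimates the
  length of smooth digital curves by ≈ 5% averaged over orientations (the
  classical perimeter bias; exact on axial and 45° lines, worst near
  22.5°). A rasterized half-circle therefore measures arc-chord
  tortuosity ≈ 1.63–1.64 rather than π/2 ≈ 1.571. The raw chain code is
  kept because it is the standard skeleton-analysis metric and is exact on
  the battery's straight phantoms; tortuosity values carry this uniform
  upward bias.
- **Filter-determined diameter.** Branch-1 segmentation width is set by
  the λ₂ < 0 support of the largest Frangi scale
  (≈ 2√(σ_max² + (w/2)²) px), not by the true caliber: widths 3/5/9 px
  all read back ≈ 42 μm at the defaults. The diameter biomarker is
  therefore best interpreted as a filter-referenced caliber index — its
  near-constancy across lesions is a property of the method, not of the
  vasculature. Computed from correct vessel masks (the phantom ground
  truth), the estimator itself recovers true widths within ~3%.
- **Median thresholding under noise.** With offset 0 and strict >, a local
  median threshold admits the upper ~half of any non-degenerate intensity
  distribution; only exactly-flat backgrounds are fully rejected. On
  speckled images the branch-2 binary map therefore accretes noise blobs
  whose skeletons carry spurious junctions and length. Noiseless phantoms
  and strongly vesselized ROIs are unaffected; see the phantom section for
  what this implies for tests.

## Synthetic phantoms

The generator renders analytic primitives (segments and arcs with round
caps, filled discs) as bright plateaus (intensity 200) on a dark
background (20) inside a rectangular ROI (primitive bounding box + 15 px
margin), optionally multiplied by uniform speckle 1 ± strength, clipped to
8-bit, cleared outside the ROI. Ground truth — centerline length, junction
and endpoint counts, width, per-branch arc-chord ratios — is computed from
the continuous geometry before rasterization, so recovery tolerances
honestly absorb discretization; only the reference vessel mask and ROI
area are pixel-counted (they are defined on the pixel grid). Geometry is
seed-independent; the seed drives only the noise realization.

The standard battery (line, half-circle, cross, H, 2-level bifurcating
tree with 3 internal nodes, filled disc, plus speckle-0.2 variants of
each) ships as `octaquant phantom`. Default canvas 1024×1024 at 170 px/mm
with 5-px-wide vessels; sizes scale with the canvas so reduced-resolution
batteries (used in the test suite for speed) keep the same topology.

What the phantoms do *not* emulate: Gaussian-profile vessels, flow-signal
dropout, projection artifacts, correlated OCTA decorrelation speckle, or
lesion-shaped ROIs. Passing tests therefore demonstrate geometric and
topological correctness of the measurement chain, not clinical accuracy
on real angiograms.

## Problem sizes and determinism

Unit and property tests run phantoms at 256–512 px; one end-to-end check
runs a full 1024×1024 image (≈ 4 s on one CPU; the whole pipeline is
pure function evaluation with no randomness, so identical input and
configuration reproduce byte-identical CSVs). Brute-force oracles
(windowed median, box counting) run on 32×32 and 64×64 random images.
`scripts/acceptance.py` re-derives every reported quantity from scratch at
these sizes with all randomness seeded from `--seed`.
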