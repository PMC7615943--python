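# Methods

## Overview

`radrank` quantifies how stable the cohort-level rank ordering of CT
texture features is under the discretization choices a radiomics
pipeline must make. The unit of analysis is a *feature × arm
comparison*: one arm fixes a quantizer (global/fixed-bin-width vs
individual/fixed-bin-count), a threshold state (−200..300 HU
re-segmentation on or off), and a matrix-aggregation dialect (merged
vs averaged over the 13 directions); the comparison statistic is
Spearman's r_s between the case orderings two arms induce for that
feature.

## Pipeline and conventions

All arrays use a single (x, y, z) axis convention with a matching
voxel-spacing triple; direction offsets, run walks, and connectivity
all live in this frame. Per ROI the pipeline is:

1. **Threshold re-segmentation** (optional): keep in-mask voxels with
   lo ≤ HU ≤ hi, both bounds inclusive. Inclusivity is a convention
   choice made once so results are bit-reproducible. Thresholding
   precedes quantization, and the re-segmented mask defines the
   intensity range the individual quantizer sees. ROIs that fall under
   10 voxels are flagged with a warning; empty ROIs are an error.
2. **First-order features** on the raw (unquantized) HU values of the
   re-segmented ROI: population variance, skewness m₃/m₂^1.5, Pearson
   (non-excess) kurtosis m₄/m₂². A constant ROI returns (0, 0, 0).
   Because these never see the quantizer, their cross-quantizer r_s is
   1 by construction — a useful internal control.
3. **Quantization** to 1-based labels 1..Ng (Ng = 128 by default):
   * IUQ: label(x) = min(⌊Ng·(x−m)/(M−m)⌋+1, Ng) with m, M this ROI's
     min/max; constant ROIs map to level 1. Exactly invariant under
     x → a·x + b (a > 0), which propagates to all 40 matrix features.
   * GUQ: bin width W = (hi−lo)/Ng over a *shared* range; label(x) =
     clamp(⌊(x−lo)/W⌋+1, 1, Ng). The shared range is the threshold
     window when thresholding is on, otherwise the cohort-global
     in-mask min/max computed in a first pass — a deterministic
     realization of "the same quantizer applied to every scan".
     Out-of-range intensities are clamped and counted in a warning.
   * Both quantizers close the top bin (the maximum maps to Ng, never
     to a phantom level Ng+1) and are monotone in intensity.
4. **Texture matrices**, all 3D: GLCM pair counts per direction,
   symmetrized; GLRLM maximal collinear runs per direction (label-0
   voxels — outside the re-segmented mask — break runs); GLSZM
   26-connected equal-label zones (direction-free); NGTDM per-level
   occurrence/probability/summed-deviation triples over in-mask
   26-neighborhoods. Matrix column extents are sized to the observed
   maximum run/zone, never padded. Offset distance is fixed at 1 voxel
   (configurable, untested beyond 1).
5. **Features** (43 total). Indices i, j in every weight are the
   1-based labels, not HU. Entropy uses log₂ with 0·log 0 := 0.

## The aggregation dialects

"Merged" accumulates GLCM/GLRLM counts over all 13 directions into one
matrix before computing features (the MATLAB-toolkit convention);
"averaged" computes features per direction and takes the arithmetic
mean (the Pyradiomics convention). GLSZM and NGTDM have no directional
degree of freedom. The merged/averaged pair stands in for a genuine
cross-implementation comparison inside one engine — the two real
toolkits cannot both be vendored — and the import path
(`read_feature_table`, `radrank compare`) accepts external CSVs with
the canonical 43 column names so real toolkit outputs can replace
either dialect when available.

Two dialect details are deliberate choices:

* In the averaged dialect a direction with no valid voxel pair is
  dropped from the GLCM average rather than contributing 0/0; a NaN
  from a degenerate direction (e.g. constant marginal → undefined
  Correlation) propagates to the averaged value, consistent with the
  NaN policy below.
* Run Percentage in the merged dialect is normalized by
  13·n_voxels — each direction's runs partition the ROI once, so the
  merged run total covers 13 voxel slots per voxel. This keeps
  RP ∈ (0, 1] in both dialects (the per-direction definition Nr/n_voxels
  is unchanged).

Note the two dialects agree exactly on constant ROIs for GLCM features
but *not* in general for GLRLM: even a perfectly symmetric constant
ROI decomposes into different run-length distributions along axial and
diagonal directions, so the pooled and direction-averaged summaries
differ. The test suite asserts cross-dialect equality only where it
truly holds.

## Formula variants pinned here

Feature definitions differ subtly across ecosystems; where the common
43-feature set is ambiguous the following forms are normative in this
package (each is pinned by a literal-transcription oracle test):

* GLCM Sum Average = Σ p(i,j)·(i+j)/2 (the marginal gray-level mean
  for a symmetric GLCM).
* GLCM Variance = Σ p(i,j)·(i−μ)² with μ = Σ p(i,j)·i the joint
  gray-level mean.
* GLRLM/GLSZM GLV and RLV/ZSV are variances of gray level and
  run-length/zone-size over the run/zone probability distribution.
* NGTDM Coarseness = 1/Σ p_i s_i, capped at 10⁶ (the cap applies
  overall, so a constant ROI — zero denominator — reports 10⁶).
  NGTDM Strength is 0 when Σ s_i = 0 (its numerator also vanishes).

**NaN policy.** Degenerate quantities (no valid pairs/runs/zones,
fewer than two occupied NGTDM levels, zero marginal SD) are NaN, never
silent zeros; the rank-correlation stage excludes NaNs pairwise and
records n_pairs. Undefined r_s (constant feature vector or < 2 pairs)
is reported distinctly and never counts as reproducible. Bounds known
in closed form (Energy, Homogeneity, SRE, SZE, RP, ZP ∈ (0,1];
|Correlation| ≤ 1) are asserted on every extraction.

## The reproducibility statistic

Cases are ranked per feature with average ranks for ties (the standard
convention, and required for r_s = 1 on identical tied vectors); r_s is
the Pearson correlation of the two rank vectors. The classification
rule is a conjunction: a with-threshold tick needs all four thresholded
IUQ-vs-GUQ comparisons (scan 1, scan 2 × merged, averaged) at
r_s ≥ cutoff, inclusively; the all-data tick needs both threshold
states. Classification is monotone in the cutoff. Because no single
cutoff is canonical in practice, 0.75 and 0.8 are both first-class and
the default report prints both.

## The phantom cohort

Each case is an ellipsoidal lesion (default semiaxes 9×8×7 mm on a
32³ grid at 1 mm isotropic spacing) of spatially correlated texture on
a −800 HU background. The texture is white Gaussian noise smoothed
with a Gaussian kernel (sd = correlation length, default 3 mm) and
re-standardized to zero mean, unit variance; lesion HU = mean
(default 50) + amplitude (default range 120 HU) / 2 × field. Scan 2
adds independent N(0, sd²) noise inside the lesion (default 5 HU — a
plausible CT repeat-scan perturbation, *not* an estimate of any real
archive's test–retest variability, which is unpublished). With sd = 0
scan 2 is bit-identical to scan 1, which anchors the end-to-end
identity r_s = 1 in every arm.

Cohort-level heterogeneity comes from per-case jitters: the lesion
mean shifts uniformly by ±30 HU and the texture amplitude and
correlation length each scale uniformly by ±25%. Without such jitter
every case would be an exchangeable realization of the same process
and rank orderings would be dominated by sampling noise (and r_s
unstable/undefined in degenerate limits). The defaults keep lesion HU
inside the −200..300 HU window; the one-voxel mask dilation ring
(default on) emulates manual-outlining slop and sweeps in −800 HU
background voxels, so threshold re-segmentation has a real effect.
Seeding is splittable: every draw comes from a SeedSequence spawned
from (master seed, case index, stream), so any case regenerates
independently of order.

**What the phantom does and does not show.** It exercises every
contract of the pipeline — determinism, quantizer algebra, matrix
definitions, rank statistics — but it is not anatomically or
radiometrically realistic: no acquisition physics, no partial-volume
gradient, no scanner-dependent noise texture, one lesion geometry. In
particular, on phantoms the *un*-thresholded arms are more concordant
between quantizers than the thresholded arms, the reverse of what has
been reported on clinical cohorts: the −800 HU slop ring stretches
every ROI's intensity range to nearly the same span, so the individual
and global quantizers produce nearly identical label maps until the
threshold removes the ring. Passing tests therefore validate the
machinery, not any claim about which features are stable in real
tumors; dataset-dependent counts and per-feature r_s values require
real cohorts and are exactly what the CSV import path is for.

## Problem sizes and numerics

The demo design uses 12 cases × 2 scans × 8 arms; the retest-noise
study uses 30-case cohorts at noise 0/5/20 HU over 5 master seeds —
sizes chosen to keep a full desk run around a minute while leaving
rank statistics non-trivial (n = 12 and n = 30 orderings). Volumes are
written as float64 NIfTI so write→read round-trips are exact; feature
CSVs serialize at 17 significant digits (lossless for float64); NIfTI
reads are guarded against silently truncated payloads. Resampling
(trilinear for volumes, nearest-neighbor for masks, output voxel
centers confined to the input center domain so interpolation never
extrapolates padding) is available but off by default — phantoms are
generated isotropic, and whether real archives should be resampled
before extraction is left to the user's configuration.

## Known limitations

* The 59 features unique to Pyradiomics (shape, GLDM, extra classes)
  are out of scope, as are DICOM/RTSTRUCT parsing, PET, and outcome
  modelling.
* The equal-probability quantizer is not implemented; both provided
  quantizers are equal-width, and the comparison design assumes that.
* Offset distance > 1 and 2D slice-wise modes are untested/out of
  scope respectively.
* Confidence intervals and ICC/CCC-style repeatability metrics are
  not provided; r_s is the sole statistic.
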