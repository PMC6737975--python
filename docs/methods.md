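# Methods

## Scope and conventions

The package analyzes multi-channel 3D fluorescence z-stacks in which each
mRNA molecule appears as one diffraction-limited dot. Stacks are assumed to
be deconvolved upstream (an optional Gaussian pre-smoothing,
`DetectionConfig.smooth_sigma`, default off, is available for raw stacks).
Axis order is `(z, y, x)` everywhere; coordinates are 0-based and extents
half-open. ROIs default to 300×300-pixel lateral windows through the full z
range, the window size used when quantifying distinct segments of a 3D
structure. Multi-channel TIFFs require an explicit channel index on read —
channels are never paired by file order, which prevents silent channel
swaps.

## Spot detection

**Threshold scan.** For each channel, `n_threshold_levels` (default 100)
evenly spaced levels strictly between the stack minimum and maximum are
scanned. At each level the stack is binarized (foreground strictly greater
than the threshold; ties go to background, so the rule is deterministic and
documented), 3D connected components are labeled, components outside
`[min_volume, max_volume]` voxels are discarded, and the surviving count is
recorded. Filtering *before* counting means the curve reflects final spot
counts; the curve is therefore not monotone — raising the threshold can
split a merged blob into several valid dots or shrink dots below the
minimum volume.

**Threshold selection.** The count curve is smoothed with a centered moving
average (`smoothing_window`, default 5 levels) and differentiated against
the threshold. Because the volume filter removes the single giant background
component at very low thresholds, the curve has a degenerate near-zero flat
region *below* the noise peak; the search is therefore restricted to the
falling branch at or above the curve maximum. Within that branch, excluding
the outermost 5% of levels, the level minimizing |slope| is selected, ties
broken toward the lower threshold. This plateau-center criterion is the
standard operational reading of the count curve's "inflection point": the
level where the detected count is insensitive to the threshold. If the whole
searched region is flat, the lowest eligible level is returned with
`flat_warning` set, and the batch runner persists that flag per ROI. A
`manual_threshold` override bypasses selection entirely.

**Connectivity and volume bounds.** Default connectivity is 26
(diagonal-touching voxels of one PSF belong to one dot); 6 is available.
Default volume bounds are 2–200 voxels: single-voxel components are almost
always noise, and components above 200 voxels are implausibly large for a
diffraction-limited dot at typical sampling. Both are exposed in config
because the right values depend on magnification and PSF sampling.

**Measurement.** Surviving components are renumbered consecutively and
measured with volume, total and peak intensity, and an intensity-weighted
centroid. Weighted centroids give subvoxel accuracy, which matters for a
3-voxel pairing cutoff; a binary-mask centroid is available
(`weighted_centroid: false`) for strict parity with unweighted analyses.

## Co-localization

Distances between centroids are Euclidean in voxel units, the z index
counted one unit per plane; an optional per-axis anisotropy scale is
provided but off by default because the pairing cutoff is stated in voxels.
Dots pair when their distance is strictly below `d_max` (default 3 voxels);
"below the threshold" is read as strict inequality and boundary-tested.
Candidate pairs are sorted by ascending distance (ties: lower A label, then
lower B label) and accepted greedily, each dot pairable at most once. Greedy
ascending-distance is the minimal reading of the at-most-one-partner rule;
the test suite keeps a maximum-cardinality matching oracle alongside to
quantify any divergence (on random small instances the gap is rare and never
negative). Directional ratios are pairs/|A| and pairs/|B|; an empty
reference channel makes the ratio undefined (an error), never silently 0.

## Quantification

All derived quantities are exact quotients of integer counts and therefore
bit-reproducible: mRNA per cell (spots/nuclei per ROI), normalized
expression (target count / reference count in the same ROI — the matched-ROI
pairing of the two channels is assumed), and region ratios between two named
ROIs. Zero or missing denominators raise `UndefinedRatioError`; the batch
runner records the failure for that ROI and continues. Manual nucleus counts
from the ROI table always take precedence; the optional automatic counter
(Otsu threshold + 3D components + volume band) exists so synthetic scenes
run end-to-end, and its results are flagged `automatic` in reports. Group
statistics (ANOVA, t-tests) are deliberately out of scope; the CSV outputs
are designed to drop into any statistics environment.

### QC

`qc_summary` reports the dot-volume histogram at a fixed bin width of 1
voxel, a mode count, and the Pearson correlation between dot volume and
integrated intensity. Healthy single-molecule detections show a unimodal
volume distribution and a strong linear volume–intensity relationship
(r ≥ 0.8); merged dots or admitted noise break both. Because a raw unit-bin
histogram of a few hundred dots is ragged, modes are counted on a moving
average of the histogram (window 5 bins, zero-padded ends) and only peaks
with prominence of at least 10% of the smoothed maximum qualify. Fewer than
10 spots yields an `insufficient` flag instead of statistics.

## Synthetic scenes

The generator emulates what the algorithms consume, not the full optics:

* dots are anisotropic 3D Gaussians (default σ = (1.0, 1.5, 1.5) voxels;
  the axial σ is the larger one in physical units once the coarser z step is
  counted) rendered at subvoxel positions and truncated at 3σ;
* the default geometry is a 12-plane, 300×300 stack — roughly an 18 µm range
  at 1.5 µm steps — with 200 dots per channel (1.85×10⁻⁴ dots/voxel),
  amplitudes N(200, 20²) over a uniform background of 20 with Gaussian noise
  of sd 10 (SNR ≈ 20). Gaussian noise stands in for Poisson–Gaussian noise;
  at these counts the difference is immaterial to thresholding and keeps
  seeds portable;
* a fraction *f* of dots is shared between channels; channel B carries the
  shared dots at the channel-A position plus per-axis Gaussian jitter
  (default sd 0.5 voxel, emulating registration error plus localization
  noise). Shared count = round(f · n_spots). Amplitudes are drawn
  independently per channel (different probe sets and fluorophores);
* dot positions are drawn uniformly with a minimum pairwise separation of 8
  voxels (so neighboring PSFs do not merge at plateau thresholds) inside a
  2σ border; the border keeps edge truncation below ~1% of a dot's mass
  while letting dots occupy essentially the whole depth of the thin stack,
  as in real samples. Placement is rejection sampling with bounded retries;
  infeasible densities raise `PlacementError`;
* nuclei are non-touching constant-intensity ellipsoids (default radii
  (2, 8, 8) voxels) in a counterstain channel.

What passing on these scenes shows: the thresholding, segmentation,
matching and arithmetic behave exactly as specified under realistic dot
densities, SNR and jitter. What it does not show: robustness to structured
background (autofluorescence, Matrigel remnants), depth-dependent
attenuation, overlapping dots at high expression, or nuclei that touch —
real-data performance on those axes is not claimed.

## Problem sizes and numerical choices

Validation uses 10 independent seeds per condition: detection
precision/recall/RMSE on the default 200-dot scenes; co-localization
recovery over f ∈ {0, 0.25, 0.5, 0.75, 1}; the independent-channel (f = 0)
chance-pairing rate at 10⁻⁴ dots/voxel (108 dots in the default volume);
threshold selection on 50-dot scenes in a (12, 150, 150) volume; matcher and
labeler checks on 500 and 200 random small instances respectively. The
recovered co-localization fraction is compared with truth within three
binomial standard errors (n = dots per channel × seeds); for f = 0 that band
is degenerate, so the chance-pairing bound (≤ 5%) applies, and for f = 1 the
check demands exact recovery, which holds at the generator's SNR and
separation. Recovered fractions sit very slightly above f for intermediate
fractions because coincidental pairings among the independent dots add
~1–2% — the same bias any distance-cutoff co-localization measure carries at
these densities.

## Known limitations

* The inflection-point criterion assumes the count curve has a falling
  branch with a plateau; stacks with no true dots select a threshold on
  whatever flat region exists (typically yielding zero spots after volume
  filtering, the correct outcome, but the `flat_warning` flag should be
  checked).
* Greedy matching is order-dependent in principle; determinism is guaranteed
  by the distance/label sort, and equality with exhaustive greedy
  recomputation is asserted over random instances, but it can fall one pair
  short of the maximum-cardinality matching in rare geometries.
* The automatic nucleus counter is a convenience for synthetic counterstains
  only; it makes no attempt at splitting touching nuclei.
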