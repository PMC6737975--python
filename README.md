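# smfish3d

3D analysis of single-molecule RNA FISH (smFISH) z-stacks: per-channel spot
detection by inflection-point thresholding, dual-channel object-based
co-localization, and transcript quantification. Built for experiments that
validate smFISH specificity in thick samples (e.g. colon organoids) by
labeling one transcript with two independent probe sets in two colors and
asking how often the resulting dots coincide in 3D.

## Who it is for

Anyone counting diffraction-limited mRNA dots in multi-channel fluorescence
z-stacks: each mature transcript appears as one bright dot, so transcript
abundance is a dot count, probe specificity is a dot-pairing rate across two
channels, and expression per cell is a dot count divided by a nucleus count.

## The method

For each channel the raw stack is binarized at a channel-specific intensity
threshold *t*. Candidate thresholds are scanned on an even grid between the
stack minimum and maximum; at each level, 3D connected components
(26-connectivity by default) are extracted and filtered to a plausible dot
volume range, and the surviving count *N(t)* is recorded. *N(t)* rises while
background noise breaks into countable specks, peaks, falls steeply, and then
plateaus at the true molecule count before decaying as real dots are lost.
The selected threshold is the inflection point of this curve — operationally,
the level on the falling branch where the smoothed |dN/dt| is smallest, i.e.
where the count is insensitive to the choice.

Each surviving component is one spot, summarized by its intensity-weighted
(subvoxel) centroid, volume, and total/peak intensity. Two channels are then
compared by the pairwise Euclidean distance between centroids, in voxel units
with the z index counted one unit per plane. Dots co-localize when their
distance is strictly below 3 voxels; candidate pairs are accepted greedily in
ascending distance, and every dot can be paired to at most one dot in the
other channel. Both directional fractions (A-dots paired / all A, and the
converse) are reported.

Derived per-ROI quantities are exact quotients of integer counts: mRNA per
cell (spot count / nucleus count), normalized expression (target channel
count / reference channel count), and region ratios (e.g. organoid body vs
crypt counts). QC follows the expected physics of single-molecule dots: the
volume distribution should be unimodal, and volume should correlate linearly
with integrated intensity.

A ground-truth scene generator (`smfish3d.synthetic`) renders dual-channel
stacks — anisotropic 3D Gaussian dots at subvoxel positions, a chosen shared
fraction with positional jitter, Gaussian background noise, ellipsoidal
nuclei — so the whole pipeline is testable without microscope data.

## Worked example

```python
import smfish3d as sm

# a synthetic two-channel scene: 200 dots/channel, half shared between
# channels with 0.5-voxel jitter, SNR ~ 20
scene = sm.simulate_scene(sm.SceneParams(seed=3, coloc_fraction=0.5))

spots_a = sm.detect_spots(scene.stack_a)
spots_b = sm.detect_spots(scene.stack_b)
print(len(spots_a), round(spots_a.threshold_used, 1))
# 200 66.3       <- all 200 dots found; selected binarization threshold

result = sm.match_spots(spots_a, spots_b, d_max=3.0)
print(result.n_pairs, round(result.ratio_a_in_b, 3), round(result.ratio_b_in_a, 3))
# 102 0.51 0.51  <- ~half the dots pair up, matching the simulated fraction

score = sm.evaluate_detection(spots_a, scene.truth.positions("a"))
print(score.recall, round(score.rmse, 3))
# 1.0 0.091      <- every true dot recovered, centroids within ~0.1 voxel
```

The same steps are available from a shell (`smfish3d simulate`, `detect`,
`coloc`, `quantify`) and as a batch pipeline over a YAML config and an ROI
table with manual nucleus counts (`smfish3d run --config run.yaml`), which
writes per-ROI spot tables, threshold curves, pair lists, quantification
CSVs and a machine-readable `summary.json`.

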