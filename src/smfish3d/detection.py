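"""Per-channel spot segmentation.

The detection pipeline for one channel is:

1. scan a grid of binarization thresholds between the stack minimum and
   maximum, counting volume-filtered 3D connected components at each level
   (:func:`scan_thresholds`);
2. pick the threshold at the inflection point of the count-vs-threshold
   curve, operationalized as the flattest point of the smoothed curve — the
   plateau where the detected count is insensitive to the threshold
   (:func:`select_threshold`);
3. binarize (foreground strictly greater than threshold), label connected
   components under 6- or 26-connectivity, discard components outside the
   configured volume bounds, and measure the survivors
   (:func:`filter_and_measure`).

Every connected component that survives the volume filter is taken to be a
single mRNA dot. Centroids are intensity-weighted by default, giving subvoxel
positions for the downstream 3-voxel co-localization rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateInputError, FormatError
from .io_roi import ImageStack


@dataclass
class DetectionConfig:
    """Tunables for per-channel spot detection.

    ``min_volume``/``max_volume`` (voxels) bound plausible dot sizes; the
    defaults drop single-voxel noise and implausibly large blobs. The volume
    filter is applied before counting, so the threshold curve reflects final
    spot counts. ``manual_threshold`` bypasses the curve entirely.
    """

    n_threshold_levels: int = 100
    connectivity: int = 26
    min_volume: int = 2
    max_volume: int = 200
    smoothing_window: int = 5
    manual_threshold: Optional[float] = None
    weighted_centroid: bool = True
    #: optional Gaussian pre-smoothing sigma (voxels) for non-deconvolved
    #: input; 0 disables it
    smooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.min_volume <= self.max_volume):
            raise FormatError(
                f"require 0 < min_volume <= max_volume, got "
                f"({self.min_volume}, {self.max_volume})"
            )
        if self.n_threshold_levels < 10:
            raise FormatError("n_threshold_levels must be >= 10")
        if self.connectivity not in (6, 26):
            raise FormatError("connectivity must be 6 or 26")
        if self.smoothing_window < 1:
            raise FormatError("smoothing_window must be >= 1")


@dataclass
class ThresholdCurve:
    """Spot count as a function of the binarization threshold."""

    thresholds: np.ndarray
    counts: np.ndarray
    smoothing_window: int = 5
    selected_index: Optional[int] = None
    flat_warning: bool = False

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.thresholds.ndim != 1 or self.thresholds.shape != self.counts.shape:
            raise FormatError("thresholds and counts must be 1D arrays of equal length")
        if len(self.thresholds) >= 2 and not np.all(np.diff(self.thresholds) > 0):
            raise FormatError("thresholds must be strictly ascending")
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def selected_threshold(self) -> float:
        if self.selected_index is None:
            raise ValueError("no threshold selected yet; call select_threshold")
        return float(self.thresholds[self.selected_index])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"threshold": self.thresholds, "count": self.counts})
        df["selected"] = False
        if self.selected_index is not None:
            df.loc[self.selected_index, "selected"] = True
        return df


@dataclass
class Spot:
    """One segmented dot: subvoxel centroid plus size/intensity features."""

    label: int
    centroid: Tuple[float, float, float]  # (z, y, x), fractional voxels
    volume: int
    total_intensity: float
    max_intensity: float


@dataclass
class SpotSet:
    """All dots detected in one channel of one (sub)volume."""

    channel_label: str
    spots: List[Spot] = field(default_factory=list)
    threshold_used: Optional[float] = None
    provenance: Dict = field(default_factory=dict)
    curve: Optional[ThresholdCurve] = None

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) centroids; empty -> shape (0, 3)."""
        if not self.spots:
            return np.empty((0, 3), dtype=float)
        return np.array([s.centroid for s in self.spots], dtype=float)

    @property
    def labels(self) -> List[int]:
        return [s.label for s in self.spots]

    @property
    def origin(self) -> Tuple[int, int, int]:
        return tuple(self.provenance.get("origin", (0, 0, 0)))  # type: ignore[return-value]

    def to_stack_frame(self) -> "SpotSet":
        """Map centroids from the local (ROI) frame to the parent stack frame."""
        oz, oy, ox = self.origin
        shifted = [
            Spot(
                label=s.label,
                centroid=(s.centroid[0] + oz, s.centroid[1] + oy, s.centroid[2] + ox),
                volume=s.volume,
                total_intensity=s.total_intensity,
                max_intensity=s.max_intensity,
            )
            for s in self.spots
        ]
        prov = dict(self.provenance)
        prov["origin"] = (0, 0, 0)
        return SpotSet(
            channel_label=self.channel_label,
            spots=shifted,
            threshold_used=self.threshold_used,
            provenance=prov,
            curve=self.curve,
        )

    def to_dataframe(self, sample_id: str = "", roi_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": sample_id,
                "roi": roi_id,
                "channel": self.channel_label,
                "label": [s.label for s in self.spots],
                "z": [s.centroid[0] for s in self.spots],
                "y": [s.centroid[1] for s in self.spots],
                "x": [s.centroid[2] for s in self.spots],
                "volume": [s.volume for s in self.spots],
                "total_intensity": [s.total_intensity for s in self.spots],
                "max_intensity": [s.max_intensity for s in self.spots],
            }
        )

    def to_csv(self, path, sample_id: str = "", roi_id: str = "") -> None:
        self.to_dataframe(sample_id, roi_id).to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpotSet":
        labels = df["channel"].unique().tolist() if len(df) else [""]
        if len(labels) > 1:
            raise FormatError(f"spot table mixes channels: {labels}")
        spots = [
            Spot(
                label=int(row.label),
                centroid=(float(row.z), float(row.y), float(row.x)),
                volume=int(row.volume),
                total_intensity=float(row.total_intensity),
                max_intensity=float(row.max_intensity),
            )
            for row in df.itertuples()
        ]
        return cls(channel_label=str(labels[0]), spots=spots)

    @classmethod
    def read_csv(cls, path) -> "SpotSet":
        return cls.from_dataframe(pd.read_csv(path))


# ---------------------------------------------------------------------------
# pipeline stages


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndi.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndi.generate_binary_structure(3, 1)
    raise FormatError("connectivity must be 6 or 26")


def binarize(stack: ImageStack, threshold: float) -> np.ndarray:
    """Boolean mask: foreground iff intensity strictly above the threshold."""
    return np.asarray(stack.voxels) > threshold


def label_components(mask: np.ndarray, connectivity: int = 26) -> Tuple[np.ndarray, int]:
    """Label maximal connected foreground sets; background stays 0."""
    labeled, n = ndi.label(mask, structure=_structure(connectivity))
    return labeled, int(n)


def _filtered_count(volumes: np.ndarray, config: DetectionConfig) -> int:
    return int(np.count_nonzero((volumes >= config.min_volume) & (volumes <= config.max_volume)))


def _prepared_voxels(stack: ImageStack, config: DetectionConfig) -> np.ndarray:
    vox = np.asarray(stack.voxels, dtype=float)
    if config.smooth_sigma > 0:
        vox = ndi.gaussian_filter(vox, sigma=config.smooth_sigma)
    return vox


def scan_thresholds(stack: ImageStack, config: Optional[DetectionConfig] = None) -> ThresholdCurve:
    """Count volume-filtered components on a grid of candidate thresholds.

    The grid is ``n_threshold_levels`` evenly spaced interior levels between
    the stack minimum and maximum, so every candidate threshold lies strictly
    inside the intensity range. Counts are not strictly monotone in the
    threshold: raising it can split a merged blob into several valid dots, or
    shrink a dot below the minimum volume.
    """
    config = config or DetectionConfig()
    vox = _prepared_voxels(stack, config)
    vmin, vmax = float(vox.min()), float(vox.max())
    if vmin == vmax:
        raise DegenerateInputError(
            f"constant stack (all voxels == {vmin}); cannot scan thresholds"
        )
    levels = np.linspace(vmin, vmax, config.n_threshold_levels + 2)[1:-1]
    structure = _structure(config.connectivity)
    counts = np.empty(len(levels), dtype=int)
    for i, t in enumerate(levels):
        labeled, n = ndi.label(vox > t, structure=structure)
        if n == 0:
            counts[i] = 0
            continue
        volumes = np.bincount(labeled.ravel())[1:]
        counts[i] = _filtered_count(volumes, config)
    return ThresholdCurve(
        thresholds=levels, counts=counts, smoothing_window=config.smoothing_window
    )


def select_threshold(curve: ThresholdCurve) -> float:
    """Pick the threshold at the flattest point of the smoothed count curve.

    The count curve is smoothed with a centered moving average
    (``smoothing_window`` levels) and its derivative with respect to the
    threshold is taken. The search is restricted to the falling branch — at
    or above the curve's maximum — because a volume-filtered count curve
    rises while the background breaks into countable specks, peaks, then
    falls steeply and flattens at the true molecule count; below the noise
    peak the counts are degenerate (one giant filtered blob). Within that
    branch, excluding the first and last 5% of levels, the level with the
    smallest absolute slope wins; ties go to the lower threshold. This is the
    plateau-center reading of the curve's inflection point: the binarization
    level where the detected count is least sensitive to the choice. If the
    searched region is entirely flat the lowest eligible level is returned
    and ``flat_warning`` is set.
    """
    n = len(curve.thresholds)
    if n < 10:
        raise DegenerateInputError(f"threshold curve has only {n} levels (need >= 10)")
    window = max(1, int(curve.smoothing_window))
    smoothed = ndi.uniform_filter1d(curve.counts.astype(float), size=window, mode="nearest")
    slope = np.gradient(smoothed, curve.thresholds)
    edge = max(1, int(np.ceil(0.05 * n)))
    peak = int(np.argmax(smoothed))
    start = max(edge, peak)
    stop = n - edge
    if start >= stop:  # peak sits at the top of the range; fall back to interior
        start = edge
    abs_slope = np.abs(slope[start:stop])
    # near-ties (within 1e-9 relative) count as ties and go to the lower
    # threshold; exact float comparison would let rounding noise in the
    # gradient pick an arbitrary member of a flat plateau
    m = float(abs_slope.min())
    tol = 1e-9 * max(1.0, m)
    best = int(np.argmax(abs_slope <= m + tol)) + start
    curve.selected_index = best
    curve.flat_warning = bool(np.allclose(abs_slope, abs_slope[0]))
    return float(curve.thresholds[best])


def filter_and_measure(
    labeled: np.ndarray,
    stack: ImageStack,
    config: Optional[DetectionConfig] = None,
) -> SpotSet:
    """Drop out-of-bounds-volume components and measure the survivors.

    Survivors get consecutive labels (ascending original label order) and are
    measured on the intensity stack: volume in voxels, total and peak
    intensity, and the centroid — intensity-weighted by default, plain
    binary-mask centroid when ``weighted_centroid`` is off.
    """
    config = config or DetectionConfig()
    vox = np.asarray(stack.voxels, dtype=float)
    if labeled.shape != vox.shape:
        raise FormatError(
            f"labeled volume shape {labeled.shape} != stack shape {vox.shape}"
        )
    n = int(labeled.max())
    spots: List[Spot] = []
    if n > 0:
        volumes = np.bincount(labeled.ravel())[1:]
        keep = np.flatnonzero(
            (volumes >= config.min_volume) & (volumes <= config.max_volume)
        ) + 1
        if keep.size:
            weight = vox if config.weighted_centroid else (labeled > 0).astype(float)
            centroids = ndi.center_of_mass(weight, labeled, keep)
            totals = ndi.sum_labels(vox, labeled, keep)
            maxima = ndi.maximum(vox, labeled, keep)
            for new_label, (old, com, tot, mx) in enumerate(
                zip(keep, centroids, totals, maxima), start=1
            ):
                spots.append(
                    Spot(
                        label=new_label,
                        centroid=tuple(float(c) for c in com),  # type: ignore[arg-type]
                        volume=int(volumes[old - 1]),
                        total_intensity=float(tot),
                        max_intensity=float(mx),
                    )
                )
    return SpotSet(
        channel_label=stack.channel_label,
        spots=spots,
        provenance={"origin": tuple(stack.origin), "shape": tuple(stack.shape)},
    )


def detect_spots(stack: ImageStack, config: Optional[DetectionConfig] = None) -> SpotSet:
    """Full deterministic pipeline: scan → select → binarize → label → filter.

    With ``manual_threshold`` set, the scan/selection is skipped and the
    override is used directly.
    """
    config = config or DetectionConfig()
    curve: Optional[ThresholdCurve] = None
    if config.manual_threshold is not None:
        threshold = float(config.manual_threshold)
    else:
        curve = scan_thresholds(stack, config)
        threshold = select_threshold(curve)
    prepared = ImageStack(
        voxels=_prepared_voxels(stack, config),
        channel_label=stack.channel_label,
        voxel_size=stack.voxel_size,
        origin=stack.origin,
    )
    labeled, _ = label_components(binarize(prepared, threshold), config.connectivity)
    spotset = filter_and_measure(labeled, prepared, config)
    spotset.threshold_used = threshold
    spotset.curve = curve
    return spotset
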