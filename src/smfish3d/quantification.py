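"""Derived per-ROI quantities and quality control.

All ratios are exact quotients of integer counts. A zero or missing
denominator always raises :class:`~smfish3d.errors.UndefinedRatioError`
rather than silently producing 0 or NaN; the batch runner records such
errors per ROI and continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from scipy.stats import pearsonr
from skimage.filters import threshold_otsu

from .detection import SpotSet, label_components
from .errors import DegenerateInputError, UndefinedRatioError
from .io_roi import ImageStack

QC_MIN_SPOTS = 10


@dataclass
class QuantRecord:
    """Per-(sample, ROI, channel) transcript quantification."""

    sample_id: str
    roi_id: str
    channel_label: str
    spot_count: int
    nucleus_count: Optional[int] = None
    mrna_per_cell: Optional[float] = None
    notes: str = ""


def mrna_per_cell(spot_count: int, nucleus_count: Optional[int]) -> float:
    """Transcripts per cell: spot count over nucleus count in the same ROI."""
    if nucleus_count is None or nucleus_count == 0:
        raise UndefinedRatioError(
            f"mRNA per cell undefined: nucleus_count={nucleus_count}"
        )
    if nucleus_count < 0 or spot_count < 0:
        raise UndefinedRatioError("counts must be non-negative")
    return spot_count / nucleus_count


def normalized_expression(
    target_count: int, reference_count: int, roi_id: str = ""
) -> float:
    """Target transcript count normalized to a reference transcript count."""
    if reference_count is None or reference_count == 0:
        where = f" (ROI {roi_id})" if roi_id else ""
        raise UndefinedRatioError(f"normalized expression undefined: zero reference{where}")
    return target_count / reference_count


def region_ratio(count_body: int, count_crypt: int) -> float:
    """Ratio of absolute transcript counts between two named regions."""
    if count_crypt is None or count_crypt == 0:
        raise UndefinedRatioError("region ratio undefined: zero crypt count")
    return count_body / count_crypt


# ---------------------------------------------------------------------------
# optional automatic nucleus counter (plumbing; manual counts take precedence)


@dataclass
class NucleusCountConfig:
    min_volume: int = 100
    max_volume: int = 20000
    connectivity: int = 26


def count_nuclei(hoechst: ImageStack, config: Optional[NucleusCountConfig] = None) -> int:
    """Count nuclei in a counterstain channel by Otsu threshold + 3D components.

    A convenience so synthetic scenes run end-to-end; results are flagged
    "automatic" in reports and never override manual counts from the ROI
    table. The volume band excludes specks and any background-sized blob an
    aggressive global threshold may produce.
    """
    config = config or NucleusCountConfig()
    vox = np.asarray(hoechst.voxels)
    if vox.min() == vox.max():
        raise DegenerateInputError("constant counterstain stack; cannot count nuclei")
    threshold = threshold_otsu(vox)
    labeled, n = label_components(vox > threshold, config.connectivity)
    if n == 0:
        return 0
    volumes = np.bincount(labeled.ravel())[1:]
    return int(
        np.count_nonzero((volumes >= config.min_volume) & (volumes <= config.max_volume))
    )


# ---------------------------------------------------------------------------
# QC (dot volume distribution and volume-intensity linearity)

#: moving-average window (bins) and relative prominence used when counting
#: modes of the volume histogram; see docs/methods.md
QC_MODE_SMOOTH_WINDOW = 5
QC_MODE_REL_PROMINENCE = 0.10


@dataclass
class QCRecord:
    """Sanity summary of one channel's detections."""

    n_spots: int
    insufficient: bool
    volume_hist: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (counts, bin edges)
    n_modes: Optional[int] = None
    volume_intensity_r: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "n_spots": self.n_spots,
            "insufficient": self.insufficient,
            "n_modes": self.n_modes,
            "volume_intensity_r": self.volume_intensity_r,
        }
        if self.volume_hist is not None:
            counts, edges = self.volume_hist
            d["volume_hist_counts"] = [int(c) for c in counts]
            d["volume_hist_edges"] = [float(e) for e in edges]
        return d


def _count_modes(hist: np.ndarray) -> int:
    """Modes of a histogram: prominent peaks of its moving-average smoothing.

    Raw width-1 histograms of a few hundred dots are ragged, so local maxima
    are counted on a smoothed curve and only peaks with prominence of at
    least 10% of the curve maximum qualify. Virtual zero bins are appended at
    both ends so a mode at the boundary still counts.
    """
    smoothed = ndi.uniform_filter1d(
        hist.astype(float), size=QC_MODE_SMOOTH_WINDOW, mode="constant"
    )
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, prominence=QC_MODE_REL_PROMINENCE * padded.max())
    return int(len(peaks))


def qc_summary(spots: SpotSet) -> QCRecord:
    """Volume histogram (bin width 1 voxel), mode count, and Pearson r
    between dot volume and total intensity.

    For well-behaved single-molecule detections the volume distribution is
    unimodal and volume scales linearly with integrated intensity; departures
    flag segmentation problems (merged dots, noise components).
    """
    n = len(spots)
    if n < QC_MIN_SPOTS:
        return QCRecord(n_spots=n, insufficient=True)
    volumes = np.array([s.volume for s in spots.spots], dtype=float)
    intensities = np.array([s.total_intensity for s in spots.spots], dtype=float)
    vmax = int(volumes.max())
    edges = np.arange(0.5, vmax + 1.5, 1.0)  # unit bins centered on integers
    hist, edges = np.histogram(volumes, bins=edges)
    if np.ptp(volumes) == 0 or np.ptp(intensities) == 0:
        r = 1.0 if np.ptp(volumes) == 0 and np.ptp(intensities) == 0 else 0.0
    else:
        r = float(pearsonr(volumes, intensities).statistic)
    return QCRecord(
        n_spots=n,
        insufficient=False,
        volume_hist=(hist, edges),
        n_modes=_count_modes(hist),
        volume_intensity_r=r,
    )


def save_qc_plots(spots: SpotSet, prefix) -> list:
    """Write the QC volume histogram and volume-intensity scatter as PNGs.

    Returns the list of written paths (empty for an insufficient spot set).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qc = qc_summary(spots)
    if qc.insufficient:
        return []
    volumes = np.array([s.volume for s in spots.spots], dtype=float)
    intensities = np.array([s.total_intensity for s in spots.spots], dtype=float)
    counts, edges = qc.volume_hist
    written = []

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(edges[:-1] + 0.5, counts, width=1.0, color="steelblue")
    ax.set_xlabel("dot volume (voxels)")
    ax.set_ylabel("dots")
    ax.set_title(f"{spots.channel_label}: {qc.n_modes} mode(s)")
    path = f"{prefix}_volume_hist.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(volumes, intensities, s=8, alpha=0.6, color="darkorange")
    ax.set_xlabel("dot volume (voxels)")
    ax.set_ylabel("total intensity")
    ax.set_title(f"{spots.channel_label}: r = {qc.volume_intensity_r:.2f}")
    path = f"{prefix}_volume_intensity.png"
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
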