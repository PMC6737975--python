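"""Ground-truth synthetic dual-channel smFISH scenes.

Emulates, at the level the detection and co-localization algorithms care
about, a deconvolved two-color smFISH acquisition of a ~18 µm z-stack:

* diffraction-limited dots rendered as anisotropic 3D Gaussians (axially
  elongated, sigma_z >= sigma_xy in physical terms once the coarser z step
  is accounted for) at subvoxel positions, truncated at 3 sigma;
* a stated fraction ``coloc_fraction`` of dots shared between the two
  channels, the shared copies jittered by a Gaussian of sd ``jitter_sd``
  voxels per axis (registration error + localization noise);
* a uniform background with Gaussian read/shot noise (a light-tailed
  stand-in for Poisson-Gaussian noise at the photon counts involved);
* ellipsoidal nuclei in a counterstain channel.

Every random draw flows from a single seed, so identical parameters give
bit-identical stacks and catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .colocalization import match_coordinates
from .detection import SpotSet
from .errors import PlacementError
from .io_roi import ImageStack


@dataclass
class SceneParams:
    """Scene geometry, optics and noise; defaults emulate the acquisition
    conditions the pipeline targets (12 planes ~ 18 µm at ~1.5 µm steps,
    300x300 lateral ROI, SNR ~ 20)."""

    shape: Tuple[int, int, int] = (12, 300, 300)
    n_spots: int = 200
    coloc_fraction: float = 0.5
    jitter_sd: float = 0.5
    spot_sigma: Tuple[float, float, float] = (1.0, 1.5, 1.5)
    amplitude_mean: float = 200.0
    amplitude_sd: float = 20.0
    background_level: float = 20.0
    noise_sd: float = 10.0
    n_nuclei: int = 25
    nucleus_radii: Tuple[float, float, float] = (2.0, 8.0, 8.0)
    nucleus_intensity: float = 150.0
    min_separation: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.jitter_sd < 0 or self.noise_sd < 0 or self.amplitude_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be positive on every axis")

    @property
    def n_shared(self) -> int:
        return int(round(self.coloc_fraction * self.n_spots))


@dataclass
class GroundTruth:
    """True catalogs behind a rendered scene.

    ``spots_a``/``spots_b`` have columns z, y, x (subvoxel), amplitude and
    shared (bool); the first ``n_shared`` rows of each are the shared dots,
    row i of A paired with row i of B. ``nuclei`` has columns z, y, x, rz,
    ry, rx.
    """

    spots_a: pd.DataFrame
    spots_b: pd.DataFrame
    nuclei: pd.DataFrame
    n_shared: int

    def positions(self, channel: str) -> np.ndarray:
        df = {"a": self.spots_a, "b": self.spots_b}[channel]
        if len(df) == 0:
            return np.empty((0, 3), dtype=float)
        return df[["z", "y", "x"]].to_numpy(dtype=float)


@dataclass
class SimulatedScene:
    stack_a: ImageStack
    stack_b: ImageStack
    hoechst: ImageStack
    truth: GroundTruth
    params: SceneParams


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: Tuple[int, int, int],
    margin: np.ndarray,
    min_separation: float,
    existing: Optional[np.ndarray] = None,
    max_tries_per_point: int = 500,
) -> np.ndarray:
    """Uniform rejection sampling with a minimum pairwise Euclidean distance."""
    lo = margin
    hi = np.asarray(shape, dtype=float) - 1.0 - margin
    if np.any(hi <= lo):
        raise PlacementError(f"shape {shape} too small for margin {margin}")
    placed: List[np.ndarray] = [] if existing is None else [p for p in existing]
    accepted: List[np.ndarray] = []
    for _ in range(n):
        for _try in range(max_tries_per_point):
            cand = rng.uniform(lo, hi)
            if not placed or np.min(
                np.linalg.norm(np.asarray(placed) - cand, axis=1)
            ) >= min_separation:
                placed.append(cand)
                accepted.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {n} points with separation {min_separation} "
                f"in shape {shape} (stuck after {len(accepted)})"
            )
    if not accepted:
        return np.empty((0, 3), dtype=float)
    return np.asarray(accepted)


def render_spots(
    shape: Tuple[int, int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma: Tuple[float, float, float],
) -> np.ndarray:
    """Additively render 3D Gaussian dots, each truncated at 3 sigma."""
    img = np.zeros(shape, dtype=float)
    sig = np.asarray(sigma, dtype=float)
    half = np.ceil(3.0 * sig).astype(int)
    for pos, amp in zip(np.atleast_2d(positions), np.atleast_1d(amplitudes)):
        lo = np.maximum(np.round(pos).astype(int) - half, 0)
        hi = np.minimum(np.round(pos).astype(int) + half + 1, shape)
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        d2 = (
            ((zz - pos[0]) / sig[0]) ** 2
            + ((yy - pos[1]) / sig[1]) ** 2
            + ((xx - pos[2]) / sig[2]) ** 2
        )
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(-0.5 * d2)
    return img


def _render_nuclei(
    shape: Tuple[int, int, int],
    centers: np.ndarray,
    radii: Tuple[float, float, float],
    intensity: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    rad = np.asarray(radii, dtype=float)
    half = np.ceil(rad).astype(int) + 1
    for c in np.atleast_2d(centers):
        lo = np.maximum(np.round(c).astype(int) - half, 0)
        hi = np.minimum(np.round(c).astype(int) + half + 1, shape)
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        inside = (
            ((zz - c[0]) / rad[0]) ** 2
            + ((yy - c[1]) / rad[1]) ** 2
            + ((xx - c[2]) / rad[2]) ** 2
        ) <= 1.0
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][inside] = intensity
    return img


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def simulate_scene(params: Optional[SceneParams] = None) -> SimulatedScene:
    """Render a dual-channel scene plus counterstain with full ground truth.

    The first ``round(coloc_fraction * n_spots)`` dots are shared: channel B
    carries them at the channel-A position plus per-axis Gaussian jitter.
    Remaining dots in each channel are channel-unique. Amplitudes are drawn
    independently per channel (different probe sets and fluorophores).
    """
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    sig = np.asarray(params.spot_sigma, dtype=float)
    # dots occupy the whole depth of a real stack; a 2-sigma border keeps
    # edge truncation below ~1% of a dot's mass without hollowing out the
    # few available z planes
    margin = np.maximum(np.ceil(2.0 * sig), 1.0)

    n, n_shared = params.n_spots, params.n_shared
    pos_a = _place_points(rng, n, params.shape, margin, params.min_separation)
    amp_a = np.abs(rng.normal(params.amplitude_mean, params.amplitude_sd, size=n))

    if n:
        shared_b = pos_a[:n_shared] + rng.normal(0.0, params.jitter_sd, size=(n_shared, 3))
        lo = margin
        hi = np.asarray(params.shape, dtype=float) - 1.0 - margin
        shared_b = np.clip(shared_b, lo, hi)
        unique_b = _place_points(
            rng,
            n - n_shared,
            params.shape,
            margin,
            params.min_separation,
            existing=shared_b if n_shared else None,
        )
        pos_b = (
            np.vstack([shared_b, unique_b])
            if n_shared and len(unique_b)
            else (shared_b if n_shared else unique_b)
        )
    else:
        shared_b = np.empty((0, 3))
        pos_b = np.empty((0, 3))
    amp_b = np.abs(rng.normal(params.amplitude_mean, params.amplitude_sd, size=n))

    nuc_margin = np.asarray(params.nucleus_radii, dtype=float) + 1.0
    nuc_sep = 2.0 * float(max(params.nucleus_radii)) + 2.0
    nuc_pos = (
        _place_points(rng, params.n_nuclei, params.shape, nuc_margin, nuc_sep)
        if params.n_nuclei
        else np.empty((0, 3))
    )

    def _catalog(pos: np.ndarray, amp: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(pos, columns=["z", "y", "x"])
        df["amplitude"] = amp[: len(df)]
        df["shared"] = np.arange(len(df)) < n_shared
        return df

    truth = GroundTruth(
        spots_a=_catalog(pos_a, amp_a),
        spots_b=_catalog(pos_b, amp_b),
        nuclei=pd.DataFrame(
            np.column_stack([nuc_pos, np.tile(params.nucleus_radii, (len(nuc_pos), 1))])
            if len(nuc_pos)
            else np.empty((0, 6)),
            columns=["z", "y", "x", "rz", "ry", "rx"],
        ),
        n_shared=n_shared,
    )

    def _channel(pos: np.ndarray, amp: np.ndarray, label: str) -> ImageStack:
        img = params.background_level + render_spots(params.shape, pos, amp, tuple(sig))
        img += rng.normal(0.0, params.noise_sd, size=params.shape)
        return ImageStack(voxels=_quantize(img), channel_label=label)

    stack_a = _channel(pos_a, amp_a, "A")
    stack_b = _channel(pos_b, amp_b, "B")
    hoechst_img = params.background_level + _render_nuclei(
        params.shape, nuc_pos, params.nucleus_radii, params.nucleus_intensity
    )
    hoechst_img += rng.normal(0.0, params.noise_sd, size=params.shape)
    hoechst = ImageStack(voxels=_quantize(hoechst_img), channel_label="hoechst")

    return SimulatedScene(
        stack_a=stack_a, stack_b=stack_b, hoechst=hoechst, truth=truth, params=params
    )


# ---------------------------------------------------------------------------
# scoring detections against the catalog


@dataclass
class DetectionScore:
    precision: Optional[float]  # None when nothing was detected
    recall: float
    rmse: float
    n_matched: int
    n_detected: int
    n_true: int


def evaluate_detection(
    detected: SpotSet,
    true_positions: np.ndarray,
    match_radius: float = 3.0,
) -> DetectionScore:
    """Score detections against true positions by greedy one-to-one matching.

    Precision = matched/detected (undefined when nothing was detected),
    recall = matched/true, RMSE over matched centroid-truth distances.
    """
    det = detected.centroids
    true_positions = np.atleast_2d(np.asarray(true_positions, dtype=float))
    if true_positions.size == 0:
        true_positions = np.empty((0, 3))
    pairs, _, _ = match_coordinates(
        det,
        true_positions,
        np.arange(len(det)),
        np.arange(len(true_positions)),
        match_radius,
    )
    n_matched = len(pairs)
    n_det, n_true = len(det), len(true_positions)
    rmse = float(np.sqrt(np.mean([d**2 for (_, _, d) in pairs]))) if pairs else 0.0
    return DetectionScore(
        precision=(n_matched / n_det) if n_det else None,
        recall=(n_matched / n_true) if n_true else 1.0,
        rmse=rmse,
        n_matched=n_matched,
        n_detected=n_det,
        n_true=n_true,
    )
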