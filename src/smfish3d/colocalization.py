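"""Object-based co-localization between two channels.

Dots from two channels co-localize when the Euclidean distance between
their centroids, in voxel units with the z index counted one unit per
plane, is strictly below a cutoff (default 3 voxels). To avoid
overestimating co-localization, every dot can be paired to at most one dot
in the other channel: candidate pairs are sorted by ascending distance and
accepted greedily, ties broken by (lower A label, then lower B label).
Both directional fractions — A dots paired among all A, and B dots paired
among all B — are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .detection import SpotSet
from .errors import FrameError, UndefinedRatioError

DEFAULT_D_MAX = 3.0


@dataclass
class MatchResult:
    """One-to-one pairings between two spot sets within a distance cutoff."""

    pairs: List[Tuple[int, int, float]]  # (label in A, label in B, distance)
    unmatched_a: List[int]
    unmatched_b: List[int]
    d_max: float = DEFAULT_D_MAX
    ratio_a_in_b: Optional[float] = None  # None when channel A is empty
    ratio_b_in_a: Optional[float] = None
    anisotropy: Optional[Tuple[float, float, float]] = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_unmatched_a": len(self.unmatched_a),
            "n_unmatched_b": len(self.unmatched_b),
            "d_max": self.d_max,
            "ratio_a_in_b": self.ratio_a_in_b,
            "ratio_b_in_a": self.ratio_b_in_a,
        }


def _check_frames(a: SpotSet, b: SpotSet) -> None:
    if a.origin != b.origin:
        raise FrameError(
            f"spot sets are in different frames: origins {a.origin} vs {b.origin}"
        )


def pairwise_distances(
    a: SpotSet,
    b: SpotSet,
    anisotropy: Optional[Tuple[float, float, float]] = None,
) -> np.ndarray:
    """(|A|, |B|) matrix of centroid distances in voxel units.

    By default one z plane counts as one unit, like y and x. ``anisotropy``
    optionally scales each axis (e.g. µm per voxel) before the distance is
    taken; it is off by default because the co-localization cutoff is stated
    in voxels.
    """
    _check_frames(a, b)
    ca, cb = a.centroids, b.centroids
    if anisotropy is not None:
        scale = np.asarray(anisotropy, dtype=float)
        ca = ca * scale
        cb = cb * scale
    if len(ca) == 0 or len(cb) == 0:
        return np.empty((len(ca), len(cb)), dtype=float)
    return cdist(ca, cb)


def match_coordinates(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    ids_a: np.ndarray,
    ids_b: np.ndarray,
    d_max: float,
) -> Tuple[List[Tuple[int, int, float]], List[int], List[int]]:
    """Greedy ascending-distance one-to-one matching on raw coordinates.

    Candidates with distance strictly below ``d_max`` are sorted by
    (distance, A id, B id) and accepted unless either member is already
    paired. Deterministic by construction.
    """
    coords_a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    coords_b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    ids_a = np.asarray(ids_a)
    ids_b = np.asarray(ids_b)
    if len(ids_a) == 0 or len(ids_b) == 0:
        return [], list(ids_a), list(ids_b)
    dist = cdist(coords_a, coords_b)
    ai, bi = np.nonzero(dist < d_max)
    dvals = dist[ai, bi]
    order = np.lexsort((ids_b[bi], ids_a[ai], dvals))
    taken_a: set = set()
    taken_b: set = set()
    pairs: List[Tuple[int, int, float]] = []
    for k in order:
        la, lb = ids_a[ai[k]], ids_b[bi[k]]
        if la in taken_a or lb in taken_b:
            continue
        taken_a.add(la)
        taken_b.add(lb)
        pairs.append((int(la), int(lb), float(dvals[k])))
    unmatched_a = [int(l) for l in ids_a if l not in taken_a]
    unmatched_b = [int(l) for l in ids_b if l not in taken_b]
    return pairs, unmatched_a, unmatched_b


def match_spots(
    a: SpotSet,
    b: SpotSet,
    d_max: float = DEFAULT_D_MAX,
    anisotropy: Optional[Tuple[float, float, float]] = None,
) -> MatchResult:
    """Pair spots across two channels one-to-one within ``d_max`` voxels.

    The pair set is symmetric under argument swap (direction labels
    exchange). Directional ratios are left undefined (None) for an empty
    reference channel rather than reported as zero.
    """
    _check_frames(a, b)
    ca, cb = a.centroids, b.centroids
    if anisotropy is not None:
        scale = np.asarray(anisotropy, dtype=float)
        ca, cb = ca * scale, cb * scale
    pairs, unmatched_a, unmatched_b = match_coordinates(
        ca, cb, np.asarray(a.labels), np.asarray(b.labels), d_max
    )
    n_pairs = len(pairs)
    return MatchResult(
        pairs=pairs,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        d_max=d_max,
        ratio_a_in_b=(n_pairs / len(a)) if len(a) else None,
        ratio_b_in_a=(n_pairs / len(b)) if len(b) else None,
        anisotropy=anisotropy,
    )


def coloc_ratio(result: MatchResult, direction: str = "a-in-b") -> float:
    """Fraction of the reference channel's dots that found a partner."""
    if direction == "a-in-b":
        ratio = result.ratio_a_in_b
    elif direction == "b-in-a":
        ratio = result.ratio_b_in_a
    else:
        raise ValueError(f"direction must be 'a-in-b' or 'b-in-a', got {direction!r}")
    if ratio is None:
        raise UndefinedRatioError(
            f"co-localization ratio {direction} undefined: reference channel empty"
        )
    return float(ratio)
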