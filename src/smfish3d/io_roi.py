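"""Image-stack and ROI input/output.

Conventions used throughout the package:

* Axis order is always ``(z, y, x)``.
* All voxel coordinates are 0-based; extents are half-open intervals, so an
  ROI with origin ``(0, 10, 20)`` and size ``(Z, 300, 300)`` covers planes
  ``0..Z-1``, rows ``10..309`` and columns ``20..319``.
* ROIs default to the lateral window size used for organoid quantification
  (300 × 300 pixels) through the full z range of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import BoundsError, FormatError

DEFAULT_ROI_LATERAL = 300

AXIS_NAMES = ("z", "y", "x")


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume.

    Parameters
    ----------
    voxels
        3D array indexed ``(z, y, x)`` of finite, non-negative intensities.
    channel_label
        Free-text channel name (probe or fluorophore, e.g. ``"APC-5p"``).
    voxel_size
        Optional physical voxel size per axis in µm, ``(z, y, x)``.
    origin
        Position of this volume's ``(0, 0, 0)`` corner in the frame of the
        stack it was extracted from. ``(0, 0, 0)`` for a full stack.
    """

    voxels: np.ndarray
    channel_label: str = ""
    voxel_size: Optional[Tuple[float, float, float]] = None
    origin: Tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise FormatError(
                f"ImageStack requires a 3D (z, y, x) array, got ndim={vox.ndim}"
            )
        if any(s < 1 for s in vox.shape):
            raise FormatError(f"ImageStack needs >= 1 plane per axis, got {vox.shape}")
        if np.issubdtype(vox.dtype, np.floating):
            if not np.all(np.isfinite(vox)):
                raise FormatError("ImageStack intensities must be finite")
        if vox.size and vox.min() < 0:
            raise FormatError("ImageStack intensities must be non-negative")
        self.voxels = vox

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned box: 0-based origin, half-open extents, (z, y, x) order."""

    origin: Tuple[int, int, int]
    size: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.size) != 3:
            raise FormatError("ROI origin and size must be (z, y, x) triples")
        if any(o < 0 for o in self.origin) or any(s < 1 for s in self.size):
            raise FormatError(
                f"ROI origin must be >= 0 and size >= 1, got {self.origin}, {self.size}"
            )

    @classmethod
    def full_z(
        cls,
        stack_shape: Sequence[int],
        y0: int,
        x0: int,
        dy: int = DEFAULT_ROI_LATERAL,
        dx: int = DEFAULT_ROI_LATERAL,
    ) -> "ROI":
        """Lateral window through the whole z range (the default ROI style)."""
        return cls(origin=(0, int(y0), int(x0)), size=(int(stack_shape[0]), dy, dx))

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(
            slice(o, o + s) for o, s in zip(self.origin, self.size)
        )  # type: ignore[return-value]


def extract_roi(stack: ImageStack, roi: ROI) -> ImageStack:
    """Copy the ROI sub-volume out of ``stack``.

    The returned stack records its origin in the parent frame so that spot
    centroids detected inside it can be mapped back (see
    ``SpotSet.to_stack_frame``).
    """
    for ax, name in enumerate(AXIS_NAMES):
        if roi.origin[ax] + roi.size[ax] > stack.shape[ax]:
            raise BoundsError(
                f"ROI exceeds stack bounds on axis {name}: "
                f"origin {roi.origin[ax]} + size {roi.size[ax]} > {stack.shape[ax]}"
            )
    sub = stack.voxels[roi.slices()].copy()
    new_origin = tuple(int(a + b) for a, b in zip(stack.origin, roi.origin))
    return replace(stack, voxels=sub, origin=new_origin)  # type: ignore[arg-type]


def read_stack(path, channel_label: str = "", channel: Optional[int] = None) -> ImageStack:
    """Read a grayscale TIFF z-stack as an ``(z, y, x)`` ImageStack.

    A 2D TIFF becomes a single-plane stack of shape ``(1, H, W)``. For a
    multi-channel TIFF the channel index must be given explicitly; channels
    are never picked by file order alone.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            axes = series.axes.upper()
            arr = series.asarray()
    except Exception as exc:  # tifffile raises various types for bad input
        raise FormatError(f"cannot read TIFF stack from {path}: {exc}") from exc

    if "S" in axes or axes.endswith(("RGB", "RGBA")):
        raise FormatError(f"{path}: RGB/multi-sample planes are not grayscale")
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    elif arr.ndim == 3:
        if "C" in axes and "Z" in axes:
            raise FormatError(
                f"{path}: single-plane multi-channel layout {axes!r} not supported"
            )
        if axes[0] == "C" or (channel is not None and "C" not in axes and "Z" not in axes):
            # explicit channel axis without z: pick one plane as a 2D image
            if channel is None:
                raise FormatError(
                    f"{path}: multi-channel TIFF ({axes}); pass an explicit channel index"
                )
            arr = arr[channel][np.newaxis, :, :]
    elif arr.ndim == 4:
        # one axis is channels; find it from the axes string
        caxis = axes.find("C")
        if caxis < 0:
            raise FormatError(f"{path}: cannot interpret 4D TIFF with axes {axes!r}")
        if channel is None:
            raise FormatError(
                f"{path}: multi-channel TIFF ({axes}); pass an explicit channel index"
            )
        arr = np.take(arr, channel, axis=caxis)
    else:
        raise FormatError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")

    if arr.ndim != 3:
        raise FormatError(f"{path}: could not coerce to a (z, y, x) stack")
    return ImageStack(voxels=arr, channel_label=channel_label)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page grayscale TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), stack.voxels)


# ---------------------------------------------------------------------------
# ROI tables

ROI_TABLE_COLUMNS = [
    "sample_id",
    "roi_id",
    "z0",
    "y0",
    "x0",
    "dz",
    "dy",
    "dx",
    "nucleus_count",
]


@dataclass
class RoiTable:
    """Rows of (sample_id, roi_id, ROI box, optional manual nucleus count)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ROI_TABLE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in ROI_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"ROI table is missing columns: {missing}")
        df = df[ROI_TABLE_COLUMNS].copy()
        keys = df[["sample_id", "roi_id"]].astype(str).agg("/".join, axis=1)
        dupes = keys[keys.duplicated()].unique().tolist()
        if dupes:
            raise FormatError(f"duplicate (sample_id, roi_id) keys: {dupes}")
        df["nucleus_count"] = pd.array(df["nucleus_count"], dtype="Int64")
        counts = df["nucleus_count"]
        if (counts.dropna() < 0).any():
            raise FormatError("nucleus_count must be non-negative")
        for col in ["z0", "y0", "x0", "dz", "dy", "dx"]:
            df[col] = df[col].astype(int)
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def iter_rois(self) -> Iterator[Tuple[str, str, ROI, Optional[int]]]:
        for _, row in self.frame.iterrows():
            roi = ROI(
                origin=(row.z0, row.y0, row.x0),
                size=(row.dz, row.dy, row.dx),
            )
            count = None if pd.isna(row.nucleus_count) else int(row.nucleus_count)
            yield str(row.sample_id), str(row.roi_id), roi, count


def read_roi_table(path) -> RoiTable:
    """Read a CSV ROI table; blank nucleus_count stays missing, never zero."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read ROI table {path}: {exc}") from exc
    return RoiTable(df)


def write_roi_table(table: RoiTable, path) -> None:
    table.frame.to_csv(path, index=False)


def write_report(records, path) -> None:
    """Write a list of dict records (or a DataFrame) as CSV."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, index=False)
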