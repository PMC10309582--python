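"""Shared domain types and readers/writers for the pipeline's file formats.

The pipeline touches three kinds of files: multi-page single-channel TIFF
stacks (frames = time), CSV trace tables (one row per cell), and label-image
TIFF + CSV pairs describing soma segmentations.  All CSVs are comma-separated
UTF-8 with '.' decimal and a mandatory header, so outputs stay
machine-comparable across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageStack:
    """A single-channel fluorescence movie.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative fluorescence intensities in arbitrary units.
    frame_interval_s : float
        Seconds per frame (acquisition default: 1 frame/s).
    stimulus_frame : int, optional
        Index of the first post-stimulus frame.  The recording is modelled
        as ONE concatenated stack (pre-stimulus segment followed by the
        post-stimulus segment) with this index marking the boundary.
    metadata : dict
        Free-form key/value annotations.
    """

    frames: np.ndarray
    frame_interval_s: float = 1.0
    stimulus_frame: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if self.stimulus_frame is not None:
            if not 0 < self.stimulus_frame < self.n_frames:
                raise ValueError(
                    f"stimulus_frame {self.stimulus_frame} outside (0, {self.n_frames})"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval_s)


@dataclass
class TraceMatrix:
    """Raw mean-fluorescence traces, one row per cell.

    ``values[i, t]`` is the mean gray value of cell ``cell_ids[i]`` at
    acquisition time ``time_s[t]``.  ``group`` carries a per-cell label such
    as the cell line of origin.
    """

    values: np.ndarray
    cell_ids: list
    group: list
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.group = [str(g) for g in self.group]
        self.time_s = np.asarray(self.time_s, dtype=float)
        n, t = self.values.shape
        if len(self.cell_ids) != n or len(self.group) != n:
            raise ValueError("cell_ids/group length does not match number of rows")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if self.time_s.shape != (t,):
            raise ValueError("time_s length does not match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values contain non-finite entries")
        if t > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedTraceMatrix:
    """ΔF/F₀ traces with the per-cell baseline that produced them.

    F₀ is the mean raw fluorescence over the ``n_baseline`` frames
    immediately preceding ``stimulus_frame``; values are (F − F₀)/F₀.
    """

    values: np.ndarray
    f0: np.ndarray
    stimulus_frame: int
    n_baseline: int
    cell_ids: list
    group: list
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.f0 = np.asarray(self.f0, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.group = [str(g) for g in self.group]
        if np.any(self.f0 <= 0):
            bad = [self.cell_ids[i] for i in np.flatnonzero(self.f0 <= 0)]
            raise ValueError(f"non-positive baseline F0 for cells {bad}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values contain non-finite entries")
        if self.n_baseline > self.stimulus_frame:
            raise ValueError("n_baseline exceeds stimulus_frame")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class RoiLabelMap:
    """Integer-labelled soma segmentation plus its per-ROI geometry table.

    ``labels`` uses 0 for background and contiguous 1..N for ROIs; ``table``
    has one row per ROI with columns label, area_px, centroid_y, centroid_x,
    touches_edge.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        present = np.unique(self.labels)
        present = present[present > 0]
        n = len(self.table)
        if not np.array_equal(present, np.arange(1, n + 1)):
            raise ValueError("label values must be contiguous 1..N matching the table")
        areas = np.bincount(self.labels.ravel(), minlength=n + 1)[1:]
        if n and not np.array_equal(areas, self.table["area_px"].to_numpy()):
            raise ValueError("table areas disagree with pixel counts")

    @property
    def n_rois(self) -> int:
        return len(self.table)


@dataclass
class SegParams:
    """Tunable knobs of the semi-automated soma segmentation."""

    projection_mode: str = "max"
    maxima_min_distance_px: float = 10.0
    maxima_rel_prominence: float = 0.1
    open_radius_px: int = 2
    min_area_px: int = 50
    max_area_px: int = 5000
    exclude_edge_rois: bool = True
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.projection_mode not in ("max", "mean"):
            raise ValueError(f"unknown projection_mode {self.projection_mode!r}")
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.maxima_min_distance_px <= 0 or self.open_radius_px < 0:
            raise ValueError("distances/radii must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_stack(
    path,
    frame_interval_s: float = 1.0,
    stimulus_frame: Optional[int] = None,
) -> ImageStack:
    """Read a multi-page single-channel TIFF as an :class:`ImageStack`.

    Pages are taken in stored order and intensities preserved exactly.
    Inconsistent page shapes or multi-channel pages are rejected with a
    message naming the offending page (1-based).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        frames = []
        ref_shape = None
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"page {i + 1} of {path.name} is not single-channel "
                    f"(shape {arr.shape})"
                )
            if ref_shape is None:
                ref_shape = arr.shape
            elif arr.shape != ref_shape:
                raise ValueError(
                    f"page {i + 1} of {path.name} has shape {arr.shape}, "
                    f"expected {ref_shape}"
                )
            frames.append(arr)
    if not frames:
        raise ValueError(f"{path.name} contains no pages")
    return ImageStack(
        frames=np.stack(frames),
        frame_interval_s=frame_interval_s,
        stimulus_frame=stimulus_frame,
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a multi-page TIFF, one page per frame."""
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")


def read_traces(path) -> TraceMatrix:
    """Read a trace CSV (columns cell_id, group, t0...t_{T-1})."""
    df = pd.read_csv(path, dtype={"cell_id": str, "group": str})
    if "cell_id" not in df.columns or "group" not in df.columns:
        raise ValueError("trace CSV must have 'cell_id' and 'group' columns")
    time_cols = [c for c in df.columns if c not in ("cell_id", "group")]
    try:
        time_s = np.array([float(c) for c in time_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric time column header: {exc}") from None
    values = df[time_cols].to_numpy()
    if values.dtype == object or np.isnan(values.astype(float)).any():
        raise ValueError("trace CSV contains non-numeric or missing values")
    if df["cell_id"].duplicated().any():
        dups = sorted(df.loc[df["cell_id"].duplicated(), "cell_id"].unique())
        raise ValueError(f"duplicate cell_ids: {dups}")
    return TraceMatrix(
        values=values.astype(float),
        cell_ids=df["cell_id"].tolist(),
        group=df["group"].tolist(),
        time_s=time_s,
    )


def write_traces(traces, path) -> None:
    """Write a (normalized or raw) trace matrix as CSV.

    Columns are cell_id, group, then one column per time point named by its
    acquisition time in seconds, formatted with repr-roundtrip precision.
    """
    df = pd.DataFrame(traces.values, columns=[format(t, "g") for t in traces.time_s])
    df.insert(0, "group", traces.group)
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False)


def write_rois(rois: RoiLabelMap, path_prefix) -> tuple:
    """Write a label map as <prefix>_labels.tif (16-bit) + <prefix>_rois.csv.

    Reading both back with :func:`read_rois` reconstructs the map exactly.
    """
    if rois.n_rois > 65535:
        raise ValueError("more than 65535 ROIs cannot be stored in a 16-bit label image")
    prefix = Path(path_prefix)
    tif_path = prefix.parent / (prefix.name + "_labels.tif")
    csv_path = prefix.parent / (prefix.name + "_rois.csv")
    tifffile.imwrite(str(tif_path), rois.labels.astype(np.uint16), photometric="minisblack")
    cols = ["label", "area_px", "centroid_x", "centroid_y", "touches_edge"]
    rois.table[cols].to_csv(csv_path, index=False)
    return tif_path, csv_path


def read_rois(path_prefix) -> RoiLabelMap:
    """Read back a label map written by :func:`write_rois`."""
    prefix = Path(path_prefix)
    labels = tifffile.imread(str(prefix.parent / (prefix.name + "_labels.tif")))
    df = pd.read_csv(prefix.parent / (prefix.name + "_rois.csv"))
    table = df.reindex(
        columns=["label", "area_px", "centroid_y", "centroid_x", "touches_edge"]
    )
    return RoiLabelMap(labels=labels.astype(int), table=table)
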