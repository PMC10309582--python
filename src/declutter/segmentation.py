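"""Semi-automated soma segmentation.

The strategy exploits the indicator's "leaky" baseline fluorescence: every
cell body is visible in a time-projection of the movie.  Somata are found by

1. projecting the stack over time (max by default),
2. detecting one intensity maximum per cell (mostly the nucleus),
3. tessellating the plane into one tile per maximum and keeping the tile
   borders,
4. thresholding the projection with Li's minimum-cross-entropy method to get
   the total cell area,
5. cutting the threshold mask along the tile borders so touching cells
   separate,
6. smoothing with a morphological opening and filling interior holes,
7. labelling connected components and filtering them by area and edge
   contact.

Manual curation steps of the interactive original (ROI inspection, brush
separation) are replaced by the area/edge filters and the tile-border cut.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_li
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, h_maxima, opening

from .core_io import ImageStack, RoiLabelMap, SegParams

__all__ = [
    "RoiLabelMap",
    "SegParams",
    "time_project",
    "detect_seeds",
    "seed_tiles",
    "li_threshold",
    "cut_foreground",
    "clean_binary",
    "label_particles",
    "segment_somata",
]


def time_project(stack: ImageStack, mode: str = "max") -> np.ndarray:
    """Project the movie over time, pixel-wise max (default) or mean."""
    if mode == "max":
        return np.max(stack.frames, axis=0)
    if mode == "mean":
        return np.mean(stack.frames, axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")


def detect_seeds(
    image: np.ndarray,
    min_distance_px: float = 10.0,
    rel_prominence: float = 0.1,
) -> np.ndarray:
    """Find one seed per cell: prominent local maxima of the projection.

    A maximum qualifies if it stands out from its surroundings by at least
    ``rel_prominence`` times the image dynamic range (h-maxima transform).
    Accepted seeds are mutually >= ``min_distance_px`` apart; candidates are
    ranked by intensity (ties: row-major order) and greedily accepted.

    Returns an (N, 2) array of (row, col) coordinates; empty for a constant
    image.
    """
    img = np.asarray(image, dtype=float)
    rng = float(img.max() - img.min())
    if rng == 0:
        return np.empty((0, 2), dtype=int)
    h = rel_prominence * rng
    peaks = h_maxima(img, h)
    lab = cc_label(peaks, connectivity=2)
    candidates = []
    for region in regionprops(lab):
        coords = region.coords
        vals = img[coords[:, 0], coords[:, 1]]
        best = coords[np.argmax(vals)]  # plateau: row-major first max
        candidates.append((img[best[0], best[1]], best[0], best[1]))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list = []
    min_d2 = float(min_distance_px) ** 2
    for _, y, x in candidates:
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_d2 for ay, ax in accepted):
            accepted.append((y, x))
    return np.array(accepted, dtype=int).reshape(-1, 2)


def seed_tiles(seeds: np.ndarray, shape: tuple) -> np.ndarray:
    """Boundary mask of the nearest-seed tessellation ("inverted tile mask").

    The plane is partitioned into Euclidean nearest-seed regions (equidistant
    pixels go to the seed with the smaller index); the returned binary mask
    marks the 1-pixel-wide border between adjacent tiles, realized by
    flagging each pixel whose right or down neighbour belongs to a different
    tile.  A single seed yields an empty mask.
    """
    seeds = np.asarray(seeds)
    if seeds.size == 0:
        raise ValueError("seed_tiles requires at least one seed")
    yy, xx = np.indices(shape)
    # (n_seeds, H, W) squared distances; argmin returns the first (smallest
    # index) seed on ties
    d2 = (yy[None] - seeds[:, 0, None, None]) ** 2 + (
        xx[None] - seeds[:, 1, None, None]
    ) ** 2
    region = np.argmin(d2, axis=0)
    border = np.zeros(shape, dtype=bool)
    border[:, :-1] |= region[:, :-1] != region[:, 1:]
    border[:-1, :] |= region[:-1, :] != region[1:, :]
    return border


def li_threshold(image: np.ndarray) -> np.ndarray:
    """Foreground mask from Li's minimum-cross-entropy threshold.

    The threshold minimizes the cross-entropy between the image and its
    binarized version (iterative fixed-point scheme); foreground is every
    pixel strictly above it.  A constant image has no threshold and is
    rejected.
    """
    img = np.asarray(image, dtype=float)
    if np.unique(img).size < 2:
        raise ValueError("cannot threshold a constant image")
    t = threshold_li(img)
    return img > t


def cut_foreground(foreground: np.ndarray, borders: np.ndarray) -> np.ndarray:
    """Remove tile-border pixels from the foreground mask.

    Equivalent, up to mask polarity, to XOR-ing the threshold mask with the
    inverted tile mask: touching cells become separate components.
    """
    foreground = np.asarray(foreground, dtype=bool)
    borders = np.asarray(borders, dtype=bool)
    if foreground.shape != borders.shape:
        raise ValueError(
            f"shape mismatch: foreground {foreground.shape} vs borders {borders.shape}"
        )
    return foreground & ~borders


def clean_binary(binary: np.ndarray, open_radius_px: int = 2) -> np.ndarray:
    """Morphological opening (disk) followed by hole filling.

    Opening removes isolated pixels and smooths ragged contours; every
    background component not connected to the image border is then filled.
    """
    binary = np.asarray(binary, dtype=bool)
    if open_radius_px > 0:
        binary = opening(binary, disk(open_radius_px))
    return ndimage.binary_fill_holes(binary)


def label_particles(binary: np.ndarray, params: SegParams) -> RoiLabelMap:
    """Connected-component labelling with area and edge filters.

    Components with area outside [min_area_px, max_area_px] are discarded;
    with ``exclude_edge_rois``, components touching the image border are
    discarded too.  Survivors are relabelled 1..N by decreasing area (ties:
    top-left-most centroid first).
    """
    binary = np.asarray(binary, dtype=bool)
    connectivity = 2 if params.connectivity == 8 else 1
    raw = cc_label(binary, connectivity=connectivity)
    h, w = binary.shape
    keep = []
    for region in regionprops(raw):
        if not params.min_area_px <= region.area <= params.max_area_px:
            continue
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        if params.exclude_edge_rois and touches:
            continue
        cy, cx = region.centroid
        keep.append((region, touches, cy, cx))
    keep.sort(key=lambda r: (-r[0].area, r[2], r[3]))
    labels = np.zeros(binary.shape, dtype=np.int32)
    rows = []
    for new_label, (region, touches, cy, cx) in enumerate(keep, start=1):
        labels[tuple(region.coords.T)] = new_label
        rows.append(
            {
                "label": new_label,
                "area_px": int(region.area),
                "centroid_y": cy,
                "centroid_x": cx,
                "touches_edge": bool(touches),
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "area_px", "centroid_y", "centroid_x", "touches_edge"]
    )
    return RoiLabelMap(labels=labels, table=table)


def segment_somata(stack: ImageStack, params: SegParams | None = None) -> RoiLabelMap:
    """Full soma segmentation of a (drift-corrected) movie.

    Composition of :func:`time_project` → :func:`detect_seeds` →
    :func:`seed_tiles` → :func:`li_threshold` → :func:`cut_foreground` →
    :func:`clean_binary` → :func:`label_particles`; the same projection is
    used for seeding and thresholding.  Zero ROIs is a valid result and
    raises only a warning.
    """
    if params is None:
        params = SegParams()
    proj = time_project(stack, params.projection_mode)
    seeds = detect_seeds(
        proj, params.maxima_min_distance_px, params.maxima_rel_prominence
    )
    empty = RoiLabelMap(
        labels=np.zeros(proj.shape, dtype=np.int32),
        table=pd.DataFrame(
            columns=["label", "area_px", "centroid_y", "centroid_x", "touches_edge"]
        ),
    )
    if len(seeds) == 0:
        warnings.warn("no seed maxima detected; returning empty segmentation")
        return empty
    foreground = li_threshold(proj)
    borders = seed_tiles(seeds, proj.shape)
    cut = cut_foreground(foreground, borders)
    cleaned = clean_binary(cut, params.open_radius_px)
    rois = label_particles(cleaned, params)
    if rois.n_rois == 0:
        warnings.warn("segmentation produced zero ROIs after filtering")
    return rois
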