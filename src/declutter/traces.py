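"""Per-ROI trace extraction, ΔF/F₀ normalization and summaries.

ΔF/F₀ is the signal-to-baseline ratio (F − F₀)/F₀, with F₀ the mean raw
fluorescence over the ``n_baseline`` frames immediately before the stimulus.
It is dimensionless and invariant to the acquisition gain.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import ImageStack, NormalizedTraceMatrix, RoiLabelMap, TraceMatrix

DEFAULT_N_BASELINE = 20


def extract_traces(stack: ImageStack, rois: RoiLabelMap) -> TraceMatrix:
    """Mean gray value of each ROI in each frame.

    ``values[i, t]`` is the arithmetic mean of frame t over ROI i's pixel
    set; cells are ordered by ROI label and named ``roi<label>``.
    """
    frames = stack.frames
    if frames.shape[1:] != rois.labels.shape:
        raise ValueError(
            f"stack frames {frames.shape[1:]} and label map {rois.labels.shape} differ"
        )
    n = rois.n_rois
    if n == 0:
        warnings.warn("empty ROI set; returning empty trace matrix")
        return TraceMatrix(
            values=np.empty((0, frames.shape[0])),
            cell_ids=[], group=[], time_s=stack.time_s,
        )
    index = np.arange(1, n + 1)
    values = np.stack(
        [ndimage.mean(frame, labels=rois.labels, index=index) for frame in frames],
        axis=1,
    )
    group = stack.metadata.get("group", "all")
    return TraceMatrix(
        values=values,
        cell_ids=[f"roi{lbl}" for lbl in index],
        group=[group] * n,
        time_s=stack.time_s,
    )


def normalize_dff(
    traces: TraceMatrix,
    stimulus_frame: int,
    n_baseline: int = DEFAULT_N_BASELINE,
) -> NormalizedTraceMatrix:
    """ΔF/F₀ normalization against the pre-stimulus baseline.

    F₀ᵢ is the mean of the ``n_baseline`` frames immediately preceding
    ``stimulus_frame`` (the window closest to the stimulus); the output is
    (F − F₀)/F₀ per cell.  A cell with F₀ ≤ 0 indicates a segmentation
    artifact and aborts with an error naming it.
    """
    if not 0 < n_baseline <= stimulus_frame:
        raise ValueError(
            f"n_baseline ({n_baseline}) must be in 1..stimulus_frame ({stimulus_frame})"
        )
    if stimulus_frame >= traces.n_frames:
        raise ValueError("stimulus_frame beyond end of recording")
    f0 = traces.values[:, stimulus_frame - n_baseline : stimulus_frame].mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        names = [traces.cell_ids[i] for i in bad]
        raise ValueError(f"non-positive baseline F0 for cells {names}")
    values = (traces.values - f0[:, None]) / f0[:, None]
    return NormalizedTraceMatrix(
        values=values,
        f0=f0,
        stimulus_frame=stimulus_frame,
        n_baseline=n_baseline,
        cell_ids=list(traces.cell_ids),
        group=list(traces.group),
        time_s=traces.time_s,
    )


def peak_amplitudes(norm: NormalizedTraceMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Per-cell post-stimulus peak ΔF/F₀ and per-group mean ± s.d.

    The peak is the maximum over all frames at or after the stimulus; the
    group summary uses the sample standard deviation (n − 1 denominator).
    """
    window = norm.values[:, norm.stimulus_frame :]
    if window.shape[1] == 0:
        raise ValueError("no post-stimulus frames to take peaks over")
    peaks = pd.Series(window.max(axis=1), index=norm.cell_ids, name="peak_dff")
    df = pd.DataFrame({"group": norm.group, "peak": peaks.to_numpy()})
    summary = (
        df.groupby("group", sort=False)["peak"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return peaks, summary


def sample_cells(
    norm: NormalizedTraceMatrix, n_per_group: int, seed: int
) -> NormalizedTraceMatrix:
    """Uniform random subsample of ``n_per_group`` cells from every group.

    Sampling is without replacement, reproducible under ``seed``; selected
    cells keep their original relative order.
    """
    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(norm.group))  # first-appearance order
    group_arr = np.asarray(norm.group)
    chosen: list[int] = []
    for g in groups:
        idx = np.flatnonzero(group_arr == g)
        if idx.size < n_per_group:
            raise ValueError(
                f"group {g!r} has {idx.size} cells, fewer than n_per_group={n_per_group}"
            )
        chosen.extend(sorted(rng.choice(idx, size=n_per_group, replace=False)))
    chosen_arr = np.array(chosen, dtype=int)
    return NormalizedTraceMatrix(
        values=norm.values[chosen_arr],
        f0=norm.f0[chosen_arr],
        stimulus_frame=norm.stimulus_frame,
        n_baseline=norm.n_baseline,
        cell_ids=[norm.cell_ids[i] for i in chosen_arr],
        group=[norm.group[i] for i in chosen_arr],
        time_s=norm.time_s,
    )


def heatmap_matrix(
    norm: NormalizedTraceMatrix, order_by: str = "peak"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Row-ordered ΔF/F₀ matrix for heatmap display.

    ``order_by='peak'`` sorts rows by group (first appearance) then by
    post-stimulus peak amplitude, descending; ``order_by='input'`` keeps the
    input order.  Values are ΔF/F₀, untransformed.  Returns the reordered
    matrix and a row-metadata frame (cell_id, group, peak).
    """
    peaks, _ = peak_amplitudes(norm)
    meta = pd.DataFrame(
        {"cell_id": norm.cell_ids, "group": norm.group, "peak": peaks.to_numpy()}
    )
    if order_by == "input":
        order = np.arange(norm.n_cells)
    elif order_by == "peak":
        groups = list(dict.fromkeys(norm.group))
        rank = meta["group"].map({g: i for i, g in enumerate(groups)})
        order = np.lexsort((-meta["peak"].to_numpy(), rank.to_numpy()))
    else:
        raise ValueError(f"unknown ordering key {order_by!r}")
    return norm.values[order], meta.iloc[order].reset_index(drop=True)
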