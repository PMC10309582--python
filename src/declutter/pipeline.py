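"""End-to-end orchestration of the analysis workflow.

The full chain is register → segment → extract → normalize → [sample] →
fPCA → truncate at the FVE threshold → k-means (elbow-suggested or
user-fixed k) → UMAP → cluster profiles.  A run starting from a trace CSV
skips the imaging stages and produces the same downstream files.

Every run writes a manifest recording all parameters, seeds, package
versions and per-stage warnings: any parameter not in the manifest is a
bug.  Two runs with identical config produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import _plots
from .cluster_embed import (
    DEFAULT_SEED,
    cluster_profiles,
    elbow_select,
    embed_umap,
    kmeans_cluster,
)
from .core_io import SegParams, read_stack, read_traces, write_rois, write_traces
from .fpca import fit_fpca, fraction_variance, select_k
from .registration import apply_drift, estimate_drift
from .segmentation import segment_somata
from .traces import extract_traces, heatmap_matrix, normalize_dff, peak_amplitudes, sample_cells

log = logging.getLogger("declutter")


@dataclass
class RunConfig:
    """Everything one analysis run depends on.

    Exactly one of ``stack_path`` (movie mode) and ``traces_path`` (trace
    CSV mode) must be set.
    """

    stack_path: Optional[str] = None
    traces_path: Optional[str] = None
    out_dir: str = "declutter_out"
    stimulus_frame: int = 60
    frame_interval_s: float = 1.0
    n_baseline: int = 20
    seg: SegParams = field(default_factory=SegParams)
    drift_correct: bool = True
    sample_n_per_group: Optional[int] = None
    fve_threshold: float = 0.95
    k: Optional[int] = None
    k_range: tuple = (1, 8)
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if (self.stack_path is None) == (self.traces_path is None):
            raise ValueError("exactly one of stack_path / traces_path must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = SegParams(**raw.pop("seg", {}))
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(seg=seg, **raw)


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run(config: RunConfig) -> Path:
    """Execute the configured workflow and write the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "seg"},
            "seg": asdict(config.seg),
        },
        "versions": _library_versions(),
        "warnings": {},
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append({"name": name, "start": time.time()})
        return warnings.catch_warnings(record=True)

    # --- input ------------------------------------------------------------
    if config.stack_path is not None:
        stack = read_stack(
            config.stack_path,
            frame_interval_s=config.frame_interval_s,
            stimulus_frame=config.stimulus_frame,
        )
        if config.drift_correct:
            with stage("register") as caught:
                drift = estimate_drift(stack)
                stack = apply_drift(stack, drift)
            manifest["warnings"]["register"] = [str(w.message) for w in caught]
            _csv(
                pd.DataFrame(drift.shifts, columns=["dy", "dx"]).assign(
                    frame=np.arange(drift.n_frames)
                )[["frame", "dy", "dx"]],
                out / "drift.csv",
            )
        with stage("segment") as caught:
            rois = segment_somata(stack, config.seg)
        manifest["warnings"]["segment"] = [str(w.message) for w in caught]
        write_rois(rois, out / "rois")
        with stage("extract") as caught:
            traces = extract_traces(stack, rois)
        manifest["warnings"]["extract"] = [str(w.message) for w in caught]
    else:
        traces = read_traces(config.traces_path)
    write_traces(traces, out / "traces.csv")

    # --- normalization ----------------------------------------------------
    with stage("normalize"):
        norm = normalize_dff(traces, config.stimulus_frame, config.n_baseline)
    if config.sample_n_per_group is not None:
        with stage("sample"):
            norm = sample_cells(norm, config.sample_n_per_group, config.seed)
    write_traces(norm, out / "dff.csv")
    _, group_peaks = peak_amplitudes(norm)
    _csv(group_peaks, out / "peak_amplitudes.csv")
    hm, hm_meta = heatmap_matrix(norm, order_by="peak")
    _csv(hm_meta, out / "heatmap_order.csv")
    _plots.save_heatmap(hm, hm_meta, norm.time_s, out / "heatmap.png")

    # --- fPCA -------------------------------------------------------------
    with stage("fpca") as caught:
        model = fit_fpca(norm)
        K = select_k(model, config.fve_threshold)
    manifest["warnings"]["fpca"] = [str(w.message) for w in caught]
    fve, cum = fraction_variance(model)
    _csv(
        pd.DataFrame(
            {"component": np.arange(1, len(fve) + 1), "eigenvalue": model.eigenvalues,
             "fve": fve, "cumulative_fve": cum}
        ),
        out / "fve.csv",
    )
    eig_df = pd.DataFrame(
        model.eigenfunctions[:K].T,
        columns=[f"phi{k + 1}" for k in range(K)],
    )
    eig_df.insert(0, "time_s", model.time_s)
    eig_df.insert(1, "mean_fn", model.mean_fn)
    _csv(eig_df, out / "fpca_eigenfunctions.csv")
    scores = model.scores[:, :K]
    score_df = pd.DataFrame(scores, columns=[f"xi{k + 1}" for k in range(K)])
    score_df.insert(0, "group", norm.group)
    score_df.insert(0, "cell_id", norm.cell_ids)
    _csv(score_df, out / "fpca_scores.csv")
    _plots.save_eigenfunctions(model, K, out / "eigenfunctions.png")
    manifest["fpca"] = {"n_components_95fve": K, "threshold": config.fve_threshold}

    # --- clustering -------------------------------------------------------
    with stage("cluster"):
        elbow = elbow_select(
            scores, range(config.k_range[0], config.k_range[1] + 1), config.seed
        )
        k = config.k if config.k is not None else elbow.suggested_k
        labels, wss = kmeans_cluster(scores, k, config.seed)
    _csv(elbow.curve, out / "wss.csv")
    _plots.save_elbow(elbow, out / "elbow.png")
    manifest["cluster"] = {
        "k": int(k),
        "k_suggested": int(elbow.suggested_k),
        "k_overridden": config.k is not None,
        "elbow_low_confidence": elbow.low_confidence,
        "wss_at_k": wss,
    }
    cl_df = pd.DataFrame({"cell_id": norm.cell_ids, "group": norm.group, "cluster": labels})
    _csv(cl_df, out / "clusters.csv")

    # --- embedding (display only) ----------------------------------------
    with stage("embed") as caught:
        emb = embed_umap(
            scores,
            n_neighbors=config.umap_n_neighbors,
            min_dist=config.umap_min_dist,
            seed=config.seed,
            cell_ids=norm.cell_ids,
            group=norm.group,
        )
    manifest["warnings"]["embed"] = [str(w.message) for w in caught]
    manifest["umap"] = {**emb.parameters, "seed": emb.seed}
    emb_df = pd.DataFrame(emb.coords, columns=["umap1", "umap2"])
    emb_df.insert(0, "group", norm.group)
    emb_df.insert(0, "cell_id", norm.cell_ids)
    emb_df["cluster"] = labels
    _csv(emb_df, out / "embedding.csv")
    _plots.save_umap(emb, labels, out / "umap.png")

    # --- cluster profiles -------------------------------------------------
    with stage("profiles"):
        profiles, composition = cluster_profiles(norm, labels)
    _csv(profiles, out / "profiles.csv")
    composition.to_csv(out / "composition.csv")
    _plots.save_profiles(norm, labels, profiles, out / "profiles.png")

    for s in manifest["stages"]:
        s["elapsed_s"] = round(time.time() - s.pop("start"), 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _library_versions() -> dict:
    import sklearn
    import skimage
    import umap

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-image": skimage.__version__,
        "umap-learn": umap.__version__,
    }
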