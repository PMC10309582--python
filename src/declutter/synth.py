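"""Ground-truthed synthetic calcium recordings.

Emulates the acquisition protocol the pipeline targets: a 1-min pre-stimulus
segment followed by a 10-min post-stimulus segment at 1 frame/s (660 frames,
stimulus at frame 60).  Each cell belongs to one of three response
archetypes — non-responder, low responder, high responder — and its raw
fluorescence follows

    F(t) = F0 · bleach(t) · (1 + a · g(t − t_stim)) + ε(t)

with ``g`` a stimulus-locked double-exponential transient (rise τ_r, decay
τ_d) normalized to peak 1 on the sampled frame grid, ``a`` the per-cell
response amplitude (0 for non-responders, truncated-normal otherwise),
``bleach`` a shared exponential photobleaching factor, and ε Gaussian noise
whose standard deviation is ``noise_sd × F0`` so ΔF/F₀ noise has sd
``noise_sd``.  The transient is phenomenological — the pipeline only needs
stimulus-locked shapes of controllable amplitude, not indicator biophysics.

Movies place Gaussian-profile somata on a flat background, modulate each by
its simulated trace, and optionally add a sinusoidal rigid drift plus read
noise; the truth label map, drift track and per-cell table come along so
every pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ImageStack, RoiLabelMap, TraceMatrix
from .registration import DriftTrack

#: archetype name -> (amplitude mean, amplitude sd); sd is ~15% of the mean,
#: a modest within-archetype cell-to-cell heterogeneity
DEFAULT_ARCHETYPES = {
    "non": (0.0, 0.0),
    "low": (0.3, 0.045),
    "high": (1.2, 0.18),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the target acquisition: 60 pre-stimulus frames + 600
    post-stimulus frames at 1 frame/s, baseline fluorescence ~100 a.u.,
    transient kinetics τ_r = 5 s / τ_d = 30 s, ΔF/F₀-scale noise 0.05.
    """

    n_cells: int = 300
    groups: dict = field(
        default_factory=lambda: {"line1": {"non": 1 / 3, "low": 1 / 3, "high": 1 / 3}}
    )
    n_frames: int = 660
    stimulus_frame: int = 60
    frame_interval_s: float = 1.0
    tau_rise_s: float = 5.0
    tau_decay_s: float = 30.0
    archetypes: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    f0_mean: float = 100.0
    f0_sd: float = 10.0
    noise_sd: float = 0.05
    bleach_rate_per_s: float = 0.0
    seed: int = 2023
    # movie extras
    height: int = 192
    width: int = 192
    soma_sigma_px: tuple = (3.0, 5.0)
    min_separation_px: float = 25.0
    drift_amplitude_px: float = 0.0
    background: float = 10.0
    movie_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for g, mix in self.groups.items():
            if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"archetype proportions for group {g!r} must sum to 1")
            unknown = set(mix) - set(self.archetypes)
            if unknown:
                raise ValueError(f"unknown archetypes {unknown} in group {g!r}")
        if not 0 < self.stimulus_frame < self.n_frames:
            raise ValueError("stimulus_frame must lie inside the recording")
        if min(self.tau_rise_s, self.tau_decay_s) <= 0 or self.noise_sd < 0:
            raise ValueError("kinetics must be positive and rates non-negative")
        if self.bleach_rate_per_s < 0:
            raise ValueError("bleach rate must be non-negative")


def largest_remainder(proportions: list, n: int) -> list:
    """Integer allocation of n items to proportions, largest remainder rule.

    Exact by construction: allocations sum to n and each is within 1 of
    n × proportion.  Remainder ties go to the earlier entry.
    """
    quotas = [p * n for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def transient_shape(config: SimConfig) -> np.ndarray:
    """Stimulus-locked transient g(t) on the full frame grid, peak 1.

    Zero before the stimulus; afterwards a double exponential
    (e^{−τ/τ_d} − e^{−τ/τ_r}) normalized by its maximum over the sampled
    post-stimulus frames, so a cell of amplitude a peaks at exactly a.
    """
    t = np.arange(config.n_frames) * config.frame_interval_s
    tau = t - config.stimulus_frame * config.frame_interval_s
    g = np.where(
        tau >= 0,
        np.exp(-np.maximum(tau, 0) / config.tau_decay_s)
        - np.exp(-np.maximum(tau, 0) / config.tau_rise_s),
        0.0,
    )
    peak = g.max()
    if peak > 0:
        g /= peak
    return g


def _truncated_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated at 0 by inverse-CDF sampling."""
    from scipy.stats import truncnorm

    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_traces(config: SimConfig | None = None) -> tuple[TraceMatrix, pd.DataFrame]:
    """Simulate raw fluorescence traces plus their ground-truth table.

    Cells are split over groups, and within each group over archetypes, by
    largest-remainder rounding (realized proportions exact, not just in
    expectation); the archetype sequence within each group is shuffled
    under the seed.  Returns (traces, truth) where truth has one row per
    cell: cell_id, group, archetype, amplitude, f0.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    group_names = list(config.groups)
    group_counts = largest_remainder([1 / len(group_names)] * len(group_names), config.n_cells)
    g = transient_shape(config)
    t = np.arange(config.n_frames) * config.frame_interval_s
    bleach = np.exp(-config.bleach_rate_per_s * t)

    cell_ids, cell_groups, archetypes, amplitudes, f0s = [], [], [], [], []
    for gname, count in zip(group_names, group_counts):
        mix = config.groups[gname]
        arch_names = list(mix)
        counts = largest_remainder([mix[a] for a in arch_names], count)
        seq = np.repeat(arch_names, counts)
        rng.shuffle(seq)
        for arch in seq:
            mean, sd = config.archetypes[arch]
            amp = 0.0 if mean == 0 and sd == 0 else float(_truncated_normal(rng, mean, sd, 1)[0])
            cell_ids.append(f"cell{len(cell_ids) + 1:04d}")
            cell_groups.append(gname)
            archetypes.append(arch)
            amplitudes.append(amp)
            f0s.append(float(_truncated_normal(rng, config.f0_mean, config.f0_sd, 1)[0]))

    amplitudes_arr = np.array(amplitudes)
    f0_arr = np.array(f0s)
    clean = f0_arr[:, None] * bleach[None, :] * (1 + amplitudes_arr[:, None] * g[None, :])
    noise = rng.standard_normal(clean.shape) * (config.noise_sd * f0_arr[:, None])
    traces = TraceMatrix(
        values=clean + noise, cell_ids=cell_ids, group=cell_groups, time_s=t
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "group": cell_groups,
            "archetype": archetypes,
            "amplitude": amplitudes_arr,
            "f0": f0_arr,
        }
    )
    return traces, truth


@dataclass
class SimulatedMovie:
    """A synthetic movie with every layer of ground truth attached."""

    stack: ImageStack
    rois: RoiLabelMap
    drift: DriftTrack
    traces: TraceMatrix  # noise-free generating trace of each soma
    truth: pd.DataFrame


def _place_somata(rng, config: SimConfig, n: int) -> np.ndarray:
    sig_lo, sig_hi = config.soma_sigma_px
    margin = math.ceil(2 * sig_hi + config.drift_amplitude_px + 2)
    if config.height - 2 * margin <= 0 or config.width - 2 * margin <= 0:
        raise ValueError("field too small for the requested soma size/drift")
    centers: list = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                "could not place all somata at the required separation; "
                "use fewer or smaller cells or a larger field"
            )
        cy = rng.uniform(margin, config.height - margin)
        cx = rng.uniform(margin, config.width - margin)
        if all(
            (cy - oy) ** 2 + (cx - ox) ** 2 >= config.min_separation_px**2
            for oy, ox in centers
        ):
            centers.append((cy, cx))
    return np.array(centers)


def simulate_movie(config: SimConfig | None = None) -> SimulatedMovie:
    """Render a full synthetic movie with truth ROIs and truth drift.

    Each soma is a 2-D Gaussian profile whose peak brightness follows the
    cell's noise-free simulated trace; the truth ROI is its r ≤ 2σ disk
    (soma extent).  Optional rigid drift moves all somata along a sinusoid
    of amplitude ``drift_amplitude_px`` (zero displacement at frame 0);
    Gaussian read noise of sd ``movie_noise_sd`` is added per pixel.
    """
    if config is None:
        config = SimConfig(n_cells=30, noise_sd=0.0)
    rng = np.random.default_rng(config.seed)
    noise_free = SimConfig(**{**config.__dict__, "noise_sd": 0.0})
    traces, truth = simulate_traces(noise_free)
    n = traces.n_cells
    centers = _place_somata(rng, config, n)
    sigmas = rng.uniform(*config.soma_sigma_px, size=n)

    T = config.n_frames
    tt = np.arange(T)
    if config.drift_amplitude_px > 0:
        phase = 2 * np.pi * tt / T
        shifts = np.column_stack(
            [
                config.drift_amplitude_px * np.sin(phase),
                config.drift_amplitude_px * (1 - np.cos(phase)) / 2,
            ]
        )
    else:
        shifts = np.zeros((T, 2))
    drift = DriftTrack(shifts=shifts, reference_frame=0)

    frames = np.full((T, config.height, config.width), config.background, dtype=float)
    half = np.ceil(3 * sigmas + config.drift_amplitude_px + 1).astype(int)
    for i in range(n):
        cy, cx = centers[i]
        h = half[i]
        y0 = max(0, int(cy) - h)
        y1 = min(config.height, int(cy) + h + 1)
        x0 = max(0, int(cx) - h)
        x1 = min(config.width, int(cx) + h + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        if config.drift_amplitude_px == 0:
            profile = np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigmas[i] ** 2)
            )
            frames[:, y0:y1, x0:x1] += traces.values[i][:, None, None] * profile
        else:
            for t in range(T):
                dy, dx = shifts[t]
                r2 = (yy - cy - dy) ** 2 + (xx - cx - dx) ** 2
                frames[t, y0:y1, x0:x1] += traces.values[i, t] * np.exp(
                    -r2 / (2 * sigmas[i] ** 2)
                )
    if config.movie_noise_sd > 0:
        frames += rng.standard_normal(frames.shape) * config.movie_noise_sd

    # truth ROIs: r <= 2 sigma disks at the undrifted positions
    labels = np.zeros((config.height, config.width), dtype=np.int32)
    rows = []
    yy, xx = np.indices(labels.shape)
    for i in range(n):
        cy, cx = centers[i]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (2 * sigmas[i]) ** 2
        labels[mask] = i + 1
        ys, xs = np.nonzero(mask)
        rows.append(
            {
                "label": i + 1,
                "area_px": int(mask.sum()),
                "centroid_y": float(ys.mean()),
                "centroid_x": float(xs.mean()),
                "touches_edge": bool(
                    ys.min() == 0 or xs.min() == 0
                    or ys.max() == config.height - 1 or xs.max() == config.width - 1
                ),
            }
        )
    rois = RoiLabelMap(labels=labels, table=pd.DataFrame(rows))

    stack = ImageStack(
        frames=frames,
        frame_interval_s=config.frame_interval_s,
        stimulus_frame=config.stimulus_frame,
        metadata={"synthetic": True, "seed": config.seed},
    )
    truth = truth.assign(
        sigma_px=sigmas, centroid_y=centers[:, 0], centroid_x=centers[:, 1]
    )
    return SimulatedMovie(stack=stack, rois=rois, drift=drift, traces=traces, truth=truth)
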