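# Methods

## Data model

A recording is a single-channel movie (T × H × W, frames = time) or a
cells × timepoints trace table.  The acquisition being emulated records a
1-minute pre-stimulus segment and a 10-minute post-stimulus segment at
1 frame/s; the package represents the two as **one** concatenated stack of
660 frames with `stimulus_frame = 60` marking the boundary, because every
downstream formula needs a single time axis.  The frame interval defaults
to 1 s and is configurable everywhere; no algorithm assumes it.

## Drift correction

Stage drift over an 11-minute same-field acquisition is dominated by
in-plane translation, so the model is rigid 2-D translation per frame —
no rotation or scale.  Shifts are estimated by phase correlation against
the first frame with local upsampled cross-correlation refinement
(upsampling factor 10, i.e. 0.1 px resolution; `scikit-image`'s
`phase_cross_correlation` stands behind the estimator).  Correction
translates each frame by the negated shift with cubic-spline
interpolation; border pixels exposed by the translation are filled with
the frame's median so background statistics are minimally perturbed.  A
zero-variance frame cannot be registered: it keeps shift (0, 0) and is
flagged.  On synthetic movies with injected sinusoidal drift of 5 px
amplitude, shifts are recovered well within 0.5 px.

## Soma segmentation

The indicator's leaky baseline fluorescence makes every cell body visible
in a time projection (max by default, so cells that only light up after
the stimulus are captured; mean is available for very noisy data).  The
stages, all on that projection:

- **Seeds** — one intensity maximum per cell, mostly the nucleus.  A
  maximum qualifies if it stands out by at least `rel_prominence` × the
  image dynamic range (h-maxima transform, default 0.1); accepted seeds
  are mutually ≥ `min_distance` apart (default 10 px), greedily chosen in
  decreasing-intensity order.  Relative prominence makes seeding invariant
  to the acquisition gain.
- **Tile borders** — the plane is partitioned into Euclidean nearest-seed
  tiles (equidistant pixels go to the smaller seed index); the border is
  the 1-px-wide set of pixels whose right or down neighbour lies in a
  different tile.
- **Threshold** — Li's minimum-cross-entropy method selects the total cell
  area.  The Li threshold scales with the image, which together with the
  relative prominence makes the whole label map invariant to multiplying
  the movie by any positive constant (tested at ×0.1, ×3, ×1000).
- **Cut** — border pixels are removed from the threshold mask
  (foreground AND NOT borders), separating touching cells.  This is the
  polarity-unambiguous form of XOR-ing the threshold mask with an
  inverted tile mask.
- **Clean-up** — morphological opening with a disk (default radius 2 px;
  opening is anti-extensive so it can never re-bridge a cut) followed by
  filling of background components not connected to the image border.
- **Particles** — connected components (8-connectivity by default),
  filtered by area (default 50–5000 px) and optionally by border contact,
  relabelled 1..N by decreasing area.

The interactive original of this strategy includes manual ROI inspection
and brush separation; here the area/edge filters and the tile-border cut
replace them, and the ROI table can be edited and re-loaded for manual
curation.  On simulated movies with 30 somata the segmentation reaches
recall and precision ≥ 0.9 at IoU ≥ 0.5 against the generating label map.

## ΔF/F₀

For each ROI, F(t) is the mean gray value per frame.  The baseline F₀ is
the mean of the `n_baseline` = 20 frames **immediately preceding** the
stimulus frame — the window closest to the stimulus, robust to early
settling — and ΔF/F₀ = (F − F₀)/F₀.  A cell with F₀ ≤ 0 aborts the run
with its name: that is a segmentation artifact that should be seen, not
silently dropped.  Peak amplitude is the per-cell maximum of ΔF/F₀ over
all post-stimulus frames; group summaries are mean ± sample s.d. (n − 1).

## Functional PCA

All cells share one dense regular grid, so the functional eigenproblem is
solved exactly on the raw T × T sample covariance — no smoothing, fully
deterministic, and checkable against a plain PCA oracle.  With quadrature
weights W = diag(w):

    eig( W^{1/2} C W^{1/2} ),  φ_k = W^{-1/2} u_k,  ξ_ik = Σ_t w_t (X_i − μ)(t) φ_k(t)

On a uniform grid the weights are the Riemann weights w_t = Δt, chosen
over the trapezoid rule deliberately: with w_t = Δt the estimator is
*exactly* standard PCA up to Δt scaling (λ = Δt·λ_PCA, ξ = √Δt·ξ_PCA),
which the test suite exploits as an independent oracle; trapezoid
endpoint half-weights would perturb that identity by O(1/T) for no
accuracy gain on a uniform grid.  Non-uniform grids fall back to
trapezoid weights with a warning.  A covariance pre-smoother is reserved
as a config flag (off by default).

Numerical conventions: eigenfunctions have unit L² norm; each is oriented
so its largest-magnitude value is positive (reproducible across
eigensolvers); eigenvalues below 1e-12 × max(λ₁, data scale) are clamped
to zero and excluded from the usable rank `k_max`; at most
min(n_cells − 1, T) components are kept.  Truncation selects the smallest
K whose cumulative fraction of variance explained reaches the threshold
(default 95 %).  Note that with white per-frame noise many small
components are needed to reach 95 %, so K grows with the noise floor —
this mirrors real recordings, where a few dozen components can be needed.

## Clustering and embedding

k-means (Lloyd, k-means++ initialization, best of 10 restarts, fixed
seed, default 2023) runs on the **truncated FPC scores**, never on the
UMAP coordinates — the stated workflow order is fPCA → k-means → UMAP,
and clustering in the embedding would inherit its distortions.  Scores
are used unstandardized: their scale already encodes the eigenvalues.
Labels are renumbered by decreasing cluster size so output is
deterministic.

**Elbow selection.**  The WSS curve over k = 1..8 is always reported; the
automated suggestion is the interior k of greatest curvature,
κ = |y″| / (1 + y′²)^{3/2}, evaluated with central differences on the
min–max-normalized curve.  The normalization matters: the raw second
difference of the WSS curve is dominated by the k = 1 → 2 drop whenever
one inter-cluster gap dwarfs the others (exactly the situation with
non-, low- and high-responders, whose low→high gap is ~3× the non→low
gap), and would then always suggest k = 2.  Curvature on the normalized
curve finds the visual elbow in both the balanced and unbalanced cases.
The suggestion is flagged low-confidence when the relative WSS drop at
the suggested k is below 5 %, and is never silently final — the CLI
prints the curve and accepts `--k`, mirroring selection by visual
evaluation.

UMAP (default `n_neighbors` 15, `min_dist` 0.1, fixed seed) is display
only; if fewer cells than neighbours are supplied the parameter is
reduced to n − 1 with a warning, recorded in the manifest.

## Synthetic generator

The generator defines the study conditions under which the pipeline is
validated: n = 300 cells, 660 frames at 1 frame/s, stimulus at frame 60,
and three archetypes in equal thirds.  Per cell,

    F(t) = F₀ · e^{−βt} · (1 + a · g(t − t_stim)) + ε(t)

- `g` is a double exponential (rise τ_r = 5 s, decay τ_d = 30 s) —
  phenomenological, not indicator biophysics; the kinetics were chosen to
  resemble typical ATP-evoked transients and are cosmetic.  `g` is
  normalized to peak 1 **on the sampled frame grid** (its continuous peak
  falls between frames), so a noise-free responder's ΔF/F₀ peak is
  exactly its amplitude `a`.
- amplitudes: non-responders a = 0; low responders a ~ N(0.3, 0.045);
  high responders a ~ N(1.2, 0.18), truncated at 0.  The ~15 % coefficient
  of variation is a modest within-archetype heterogeneity.
- F₀ ~ N(100, 10) a.u. truncated at 0; ε ~ N(0, (0.05·F₀)²) so ΔF/F₀
  noise has sd 0.05; photobleaching β defaults to 0 and is modelled as a
  shared exponential so gain effects are separable from response effects.
- archetype counts are allocated by largest-remainder rounding (realized
  proportions are exact, not just in expectation) and shuffled under the
  seed.

Movies add: Gaussian-profile somata (σ 3–5 px) placed by rejection
sampling at ≥ 25 px separation on a flat background (10 a.u.), peak
brightness following the cell's noise-free trace; optional sinusoidal
rigid drift (zero at frame 0); per-pixel Gaussian read noise (1 a.u.).
The truth ROI of a soma is its r ≤ 2σ disk — the visible soma extent,
containing 86 % of the 2-D Gaussian mass.  Everything is bit-reproducible
under the seed.

**What the generator does not emulate**: overlapping or moving cells,
non-rigid deformation, inhomogeneous illumination, spontaneous (non
stimulus-locked) transients, oscillatory responses, and focal drift.
Passing tests therefore demonstrate correctness of the algorithms under
clean, rigid, stimulus-locked conditions — not robustness to every
artifact of real recordings.

## Problem sizes used in the test suite

Desk-scale sizes keep the suite fast while preserving the study
conditions that matter: trace-level tests use the full default
n = 300 × 660 grid (the archetype-recovery check runs it over 5 seeds);
movie-level tests use 192 × 192 fields with 25–30 somata and 40–80
frames, since segmentation operates on the time projection and is
insensitive to T.

## Known limitations

- Registration handles translation only; rotating or deforming samples
  need external tools first.
- The segmentation assumes one intensity maximum per cell; cells with
  multiple bright foci can over-split (mitigated by `min_distance`), and
  deeply overlapping cells cannot be separated by a 2-D tile border.
- The fPCA estimator requires every cell observed at every frame; sparse
  or irregularly missing data are out of scope.
- The elbow suggestion is a heuristic; the WSS curve and UMAP plot are
  emitted precisely so a human can override it.
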