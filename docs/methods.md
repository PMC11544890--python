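# Methods

This note documents the models, parameter choices and numerical conventions
behind `holodcc`, and what the synthetic-data tests do and do not establish
about real recordings.

## Phase images and the preprocessing model

A recording is a stack of reconstructed quantitative-phase frames; each pixel
holds the optical phase shift in radians, proportional to the product of cell
height and refractive-index contrast against the medium. The flow cell is
static over a recording session, so the background (channel walls,
illumination non-uniformity) is estimated as the per-pixel **median over the
first `background_frames` frames** (default 1000, clipped to what is
available). At the nominal cell load (~5 cells per 384 × 512 frame) any one
pixel is covered by a cell in ~1% of frames, far below the 50% occupancy that
would bias a median.

Segmentation thresholds the background-subtracted frame at
`phase_threshold = 0.8` rad (strictly greater), labels connected components
(8-connectivity by default; 4 available), and drops components below
`min_area_px = 30`. The pixel count is the normative criterion; the
equivalent physical area (`min_area_px · pixel_area_um2`, 357 µm² at the
default 11.9 µm²/px) is reported as metadata only, because the implied pixel
pitch is unusually coarse for a 40× objective and the true pitch of a given
instrument should be configured, not assumed. Components are returned in
raster order of their bounding boxes so downstream row order is
deterministic.

Each surviving component is cut out as a `patch_size = 96` window, half-open
`[c − 48, c + 48)` on the rounded centroid. Cells whose window would leave
the frame are **discarded** by default (truncated morphology would bias
features); `edge_policy="zero-pad"` keeps them for throughput studies.
Touching cells are not split: in the sheath-flow geometry all cells sit in
one focal plane and occlusion is negligible, so no watershed stage is
included — a documented limitation for dense or clumped samples.

## The 24-feature catalog

Features are computed from the patch's phase values `P` and its segmentation
mask `M` — never from a re-threshold — so detection and description stay
consistent. Conventions that matter for reproducibility:

* Physical units derive from `pixel_area_um2` (pitch = its square root).
* **Perimeter** is the outer pixel-edge count × pitch: digitization-exact,
  trivially oracle-checkable, and stable under rotation by multiples of 90°.
  It overestimates smooth contours (a digital disc scores circularity ≈ 0.5),
  which is harmless for classification since all cells share the bias.
* **Ellipse features** come from the per-pixel central second moments with
  axis length `4·sqrt(eigenvalue)`; a collinear mask has a zero minor axis,
  which is floored at one pixel when forming the aspect ratio.
* **Solidity** divides the pixel count by the area of the convex hull of the
  pixel *corner* points, so convex digital shapes score ≈ 1 and none exceeds
  it.
* Phase statistics are over the masked values; SD uses the population
  convention; a constant patch has skewness/kurtosis 0 by definition;
  **entropy** uses a 32-bin histogram over the masked value range, natural
  log, empty bins contributing zero.
* **Optical volume** `Σ_M P · a_px` (rad·µm²) is the dry-mass proxy;
  **mass displacement** is the distance between binary and phase-weighted
  centroids; the **gradient** is a central difference in rad/px;
  **radial contrast** is the SD of mean phase over four equal-width
  concentric rings; the **local-maxima count** (lobation proxy) counts
  strict 8-neighbour maxima of the 1-px-Gaussian-smoothed patch inside the
  mask — an exact plateau (e.g. a flat-top disc) therefore counts zero.

Internally features are computed on the mask's bounding box plus a 4-px
margin, which is at least the smoothing-kernel radius plus one; features are
therefore exactly translation invariant, verified bit-for-bit in tests. The
ordered feature schema is fingerprinted (SHA-256 of names and units) and
stored with every trained model; prediction refuses tables whose fingerprint
differs, so a catalog change can never be silently combined with a stale
model.

## Synthetic recordings

Real sorted-cell and longitudinal recordings of this kind are not publicly
deposited, so the generator stands in for them with the statistical structure
the analysis relies on:

* **Phantom model** — a raised-cosine phase bump `0.5·(1 + cos πρ)` on an
  elliptical footprint (equal-area parameterisation, random orientation),
  plus optional Gaussian lobes at 0.45 of the radius (nuclear lobation
  proxy) and multiplicative speckle (Gaussian field, σ = 1.5 px). The
  speckle amplitude is tapered by the normalized profile so the thresholded
  footprint stays simply connected; the composite is renormalised so the
  mask maximum equals the sampled peak phase exactly. Morphology draws are
  clipped at ±2.5 SD.
* **Default class phenotypes** (radius px / peak rad): blood — granulocyte
  9.5/1.7 with 3 lobes, lymphocyte 7.0/2.4 smooth, monocyte 12.0/1.4
  eccentric; milk — granulocyte 9.5/1.6, lymphocyte 7.0/2.3, macrophage
  13.0/1.45 large and flat, optionally plus a sub-resolution "debris" class
  that segments above threshold but falls below the 30-px area filter. The
  values are stand-ins, not calibrated to bovine cells: chosen so classes
  are clearly separable yet overlapping (classifier comparisons stay
  non-trivial), and so that every default phantom exposes ≥ 30 px above
  0.8 rad even at worst-case ±2.5 SD draws — the preprocessing contract is
  always exercisable.
* **Frames** — static closed-form channel-artifact pattern (identical across
  a recording), i.i.d. Gaussian phase noise (default SD 0.05 rad), Poisson
  cell count (default mean 5), classes drawn from the mixture, placements
  rejection-sampled so masks stay > 2 px apart (thresholded blobs can never
  merge under 8-connectivity). `placement_margin` optionally keeps centres
  far enough from the border that every patch window fits — study scenes use
  margin = 50 because edge-discard probability is weakly size-dependent and
  would otherwise bias compositions by a few percent.
* **Datasets** — the sorted-cell (isolation) generator renders one
  single-class recording per subject × class with configurable class
  imbalance (default 5:3:1 expected yields) and systematic per-subject
  phenotype jitter (default ±4% multiplicative on radius and peak), which is
  what makes leave-one-subject-out genuinely harder than a same-subject
  hold-out. The longitudinal generator follows the study layout — 5 subjects
  sampled on 14 days over 26 days — with smooth per-subject composition
  trajectories (Dirichlet start, log-normal random walk); the
  reference-method series is the realized truth plus truncated additive
  Gaussian noise (default SD 0.02), renormalised.

Everything is driven by `numpy.random.Generator`; identical configuration
and seed give bit-identical output. What passing tests on this generator do
**not** show: robustness to focus drift, cell–cell occlusion, debris spectra
beyond the simple model, optical aberrations, or real bovine morphology —
absolute metric values on synthetic data are optimistic relative to real
recordings.

## Training protocol

SMOTE generates each synthetic row as `x_i + λ(x_nn − x_i)`, λ ~ U(0,1),
with `x_nn` one of the `k = 5` nearest same-class neighbours (Euclidean on
z-scored features; the interpolation itself is equivalent in original
space). Synthetic rows carry a flag and their parent indices; a λ override
exists purely as a verification hook. **Balancing the whole labeled table
before splitting leaks interpolated copies of test rows into training**, so
the default protocol is split-then-balance: the 70/30 hold-out and every
cross-validation fold are drawn from measured rows only, and SMOTE is
fitted inside each training fold. A `paper_protocol` switch restores
balance-before-split for faithful-reproduction comparisons.

Grid search is exhaustive over per-family grids (defaults: kNN
k ∈ {1,3,5,11,21}; RF trees ∈ {100,300} × depth ∈ {∞,10,20}; SVM
C ∈ {0.1,1,10} × γ ∈ {scale,0.01,0.1}) under stratified 5-fold CV; the best
point maximises mean accuracy with ties broken by mean macro sensitivity,
then grid order. kNN and SVM inputs are z-scored with training-fold
statistics; forests see raw features. kNN voting ties are broken by the
smaller mean neighbour distance, then sorted class order, making prediction
fully deterministic. After selection the model is refitted on the full
(balanced) training table.

## Evaluation conventions

Multi-class sensitivity and specificity are one-vs-rest per class and
macro-averaged without weights; a zero-support class has undefined
sensitivity and is excluded from the macro mean with a warning.
Leave-one-subject-out reports one fold per subject (training rows never
share a subject with test rows) and summarises each metric as mean and
sample SD across folds. Compositions live on the 0–1 proportion scale.
Series comparison pools all aligned (day, class) pairs: MAE and RMSE over
every pair (so MAE ≤ RMSE always), MRE over pairs with a non-zero reference
— zero-reference pairs are skipped and counted rather than dividing by
zero; whether to pool or average per class first is a genuine convention
choice, and pooling is used because it weights every observation equally.
The before/after vaccination check is deliberately descriptive (per-feature
mean/SD and Cohen's d), mirroring a visual density-overlay assessment; no
hypothesis test is bundled.

## Pipeline reproducibility and problem sizes

One global seed fans out to per-stage seeds via a stable hash of the stage
name, so stages are individually reproducible; reports contain no
timestamps, and two runs with the same configuration are byte-identical
(verified file-hash for file-hash, including the persisted model). Each run
writes a manifest with a SHA-256 per output, and unchanged stages are
skipped on re-run.

Default scales are chosen to keep a full run desk-sized: reduced 256 × 320
frames, ~6 cells/frame, tens of frames per recording. The end-to-end
recovery test uses the native 384 × 512 frame at a higher load
(20 cells/frame, 105 frames/sample → ~2100 cells per sample, 70 samples)
and recovers designed compositions with overall MAE ≈ 0.014 against a
0.05 acceptance bound. The native acquisition scale (~10,000 frames per
measurement) is reached by configuration only.

## Known limitations

* Feature catalog reconstructed from the four documented exemplars (optical
  volume, contrast, size, optical height) plus standard phase-imaging
  morphology descriptors; the fingerprint mechanism exists so an alternative
  catalog can be swapped in without silent mismatch.
* Threshold-monotonicity of the component *count* holds for unimodal
  phantoms only; a textured cell can split into two super-threshold parts at
  a higher threshold. The area-filter monotonicity is unconditional.
* No watershed, no focus correction, no tracking; debris modelling is
  minimal; phenotypes are not calibrated to real bovine leukocytes.
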