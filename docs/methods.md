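# Methods

`gastruquant` reimplements, as one tested pipeline, the quantitative
analyses used to characterize directed cell migration and cell/nuclear
morphology in gastrulating fish embryos, together with the
chromatin-peak-to-gene enrichment test used to connect a
transcription-factor binding landscape to differential expression.
Because the underlying live microscopy is not distributable at test
scale, every stage is validated against synthetic inputs with known
ground truth.

## Migration analysis

**Model.** Nuclei are detected per frame and linked into trajectories;
per track the pipeline reports displacement `D = ‖r_N − r_0‖`, path
length `L = Σ ‖r_{i+1} − r_i‖`, persistence `P = D/L`, and mean
velocity `v = ⟨‖Δr‖/Δt⟩`. `P = D/L` is the standard bounded
straightness surrogate for "how long a cell keeps its direction"; a
time-like alternative (mean run length of heading changes < 30°) is
available via `persistence_mode="run_length"`. Displacements are
color-binned as sub (<20), blue (20–50), green (50–80), yellow
(80–130, inclusive upper bound) and red (>130) µm, with lower-closed /
upper-open boundaries.

**Detection.** Frames (two confocal sections 10 µm apart) are
max-projected, unsharp-masked (`out = (in − w·G₁₅(in))/(1−w)`,
σ = 15 px, w = 0.60, clipped at 0) and median-filtered (radius 2 px).
Spots are maxima of the negated scale-normalized LoG response at scale
`diameter/(2√2)` px with diameter 7.9 px, refined sub-pixel by a
separable quadratic fit. Quality is the response normalized over its
nonnegative range per frame, thresholded at 0.23. Anchoring the
normalization at the frame *minimum* (which is ≈ −0.4× the maximum on
realistic frames) would place the zero-response floor near 0.3 and make
a 0.23 threshold pass thousands of noise maxima; normalizing over
[0, max] keeps the same threshold semantics and works at SNR 5.

**Linking.** Greedy mutual-nearest-neighbor frame-to-frame assignment,
Euclidean cost, links rejected above 15 µm, no gap closing. A cell that
disappears for one frame yields two tracks — deliberate, deterministic,
and scored as such. Tracks under 15 frames or starting within a
configurable half-width (default 50 µm, unreported in the source
workflow) of the midline are excluded before statistics.

**Group statistics.** Tests run on per-embryo means (n = 3 per group in
the emulated design): an F test for equal variances (α = 0.05) gates a
pooled versus Welch two-sided t test.

## 2D morphometry

* **Compactness** `C = 4πA/Per²`. The perimeter is the length of the
  0.5-level marching-squares contour simplified by Douglas–Peucker at
  0.9 px tolerance. The raw contour overestimates a digitized circle by
  ~5% (staircase); Crofton estimates (4 directions) underestimate an
  axis-aligned square by ~5%. The simplified contour keeps both within
  1% at radii/sides ≳ 100 px, at the cost of a constant ~0.6 px cut per
  right-angle corner (so very small polygons read slightly high).
* **Filopodia** are 8-connected components of
  `mask AND NOT opening(mask, disk(1.1 µm))` with area > 0.077 µm².
  Note the operator counts any opening residue, including the rounded
  corners of wide, sharp-cornered protrusions; only round-capped
  protrusions wider than the 2.2 µm disk vanish from the residue.
* **Focal-adhesion length** is the skeleton length (orthogonal steps
  1 px, diagonal √2 px) of the adhesion mask inside a 135 × 135 µm²
  window.
* **Intensity ROIs** are squares of the requested physical area
  (56 µm² → side ≈ 7.48 µm) centered on a point.
* **Nuclei counting** thresholds (Otsu by default), labels, and keeps
  components > 7.1 µm²; density is reported per 100 µm² of field.
  Positive-cell counting adds a distance-transform watershed split
  (h-maxima seeds, h = 2 px) and a 6–200 µm² gate applied after
  splitting, requiring overlap with a nucleus.
* **Embryo size** comes from an algebraic (Kåsa) least-squares circle
  fit to boundary points; area = πr².

## 3D nuclear morphometry

Stacks are calibrated at 0.132 × 0.132 × 0.24 µm (x, y, z). The
workflow is blur → threshold → watershed → per-label descriptors:

* `blur3d` is an isotropic-in-voxels Gaussian (σ = 2 voxels). Because
  voxels are anisotropic this blur is *anisotropic in physical space*
  (σ_z = 0.48 µm vs 0.26 µm laterally) and measurably flattens ~3 µm
  nuclei: thresholding a blurred noise-free ellipsoid biases flatness
  downward by ~13%. The blur therefore belongs to noise suppression on
  real data; descriptor-accuracy checks (and the demo stage, which
  renders noise-free fixtures) segment without it.
* Segmentation: global Otsu (or explicit) threshold, Euclidean distance
  transform in physical units, h-maxima seeds, watershed.
* Descriptors: semi-axes from the physical-coordinate covariance
  eigenvalues via the solid-ellipsoid identity `s_i = √(5λ_i)`, sorted
  `a ≥ b ≥ c`; flatness `F = b/c ≥ 1`; volume from the voxel count;
  surface area from a marching-cubes mesh of the 1-voxel-Gaussian-
  smoothed mask (meshing the raw binary grid overestimates a sphere's
  surface by ~11%, pushing sphericity to ~0.73; smoothing restores it
  to within 0.5%); sphericity `Ψ = 36πV²/S³`.
* Volume gating keeps 100–350 voxels inclusive ("volume unit"
  interpreted as voxels; a µm³ mode is available).

## Neighbor-density statistic

Nuclei centroids are deduplicated (every member of a pair closer than
8 px is removed — the source workflow does not say which duplicate was
kept, so neither is), border points are excluded (default margin 8 px,
unreported), and each point gets `d₅`, the mean distance to its five
nearest neighbors. Points are labeled active/inactive by the region
mask pixel beneath them; groups are compared on per-embryo means with a
two-sided t test. For a homogeneous Poisson process of rate λ the
expectation `E[d₅] = (1/√(πλ))·(1/5)·Σ_{k=1..5} Γ(k+½)/Γ(k)` serves as
the analytic oracle; 4:1 rate contrasts give the expected ≈2× distance
ratio (`d ∝ 1/√λ`).

## Peak-to-gene enrichment

Peak lists are concatenated (not merged — duplicates count twice, as in
the source workflow). Each peak is assigned the closest gene: distance
0 on interval overlap, otherwise the gap between nearest ends; ties go
to the smaller gene start; a TSS-distance mode exists. DEGs are genes
with padj < 0.05 and |log2FC| ≥ 1 (optionally downregulated only). The
DEG target fraction is compared against the target fraction of the
expressed-gene universe (the analog of a RowMeans-based expression
filter, supplied as input; a non-DEG control mode exists — the control
set of the original analysis is not precisely specified) using a pooled
two-proportion Z test, two-sided.

## qPCR quantification

`delta_delta_ct` implements the classical method with amplification
efficiency exactly 2 and the ef1a housekeeping reference: per replicate
`ΔCt = Ct_target − mean Ct_ref(group)`, `ΔΔCt = ΔCt − mean ΔCt_control`,
fold = `2^(−ΔΔCt)`, reported per replicate with mean ± SD.

## Synthetic data: what it emulates, and what it does not

* **Tracks** are correlated random walks: heading increments
  `Normal(0, σ)` with `σ = π(1 − p)`, one interpretable persistence
  knob `p ∈ [0, 1]`. Defaults emulate an 8 h movie at 4 min/frame,
  1 µm/min cells in a 400 µm arena. Boundaries reflect (implemented as
  exact coordinate folding of the unreflected path, valid because steps
  are position-independent). Optional jittered-grid starts model the
  volume exclusion of real nuclei; uniform starts occasionally place
  two walkers on top of each other, which no tracker can disambiguate.
  No speed heterogeneity, no cell division, no drift unless requested.
* **Movies** draw each nucleus as an isotropic Gaussian spot plus iid
  Gaussian noise — no PSF anisotropy, photobleaching, or background
  texture. SNR is amplitude/noise_sd.
* **Star cells** are disks with rectangular radial spikes of known
  count and area; **adhesion patterns** are smooth-edged bars of known
  total length; **nuclei** are voxelized solid ellipsoids with known
  axes; **point fields** are two-rate Poisson processes; the **genome
  fixture** puts genes on a 10 kb grid on one chromosome with one peak
  inside each target gene, and draws DEG labels so that
  `P(target | DEG) = factor × (background target fraction)`.

A green test on these fixtures establishes that the operators recover
known truth under the stated geometry and noise — not that they match
manual segmentations of real embryos, whose thresholds the source
workflow did not report.

## Numerical choices

* Track-level noise magnitudes are not published; generator defaults
  are plausible, documented free parameters, not claims about medaka.
* Displacement-bin units are taken as µm (the legend prints none).
* Detection sub-pixel refinement clamps offsets to ±0.5 px.
* The F-gate α for pooled-vs-Welch switching is 0.05, configurable;
  with both variances zero the pooled branch is the degenerate limit.
* Two-proportion Z returns z = 0, p = 1 with a degeneracy flag when the
  pooled proportion is 0 or 1.
* All generators are pure functions of (params, seed); the pipeline's
  CSV artifacts are byte-identical across reruns of one (config, seed).

## Known limitations

* The linker has no gap closing or motion model; crossing cells can
  swap identities, and merged detections (spots closer than ~½ blob
  diameter) are a documented single-detection outcome.
* Automated Otsu segmentation stands in for the manual segmentations of
  the original workflow; equivalence on real images is not claimed.
* The σ = 2 3D blur's anisotropic flattening bias (above) means real
  flatness values carry a systematic component the descriptors cannot
  remove.
* The Poisson k-NN oracle applies to interior points; border-affected
  points are excluded rather than edge-corrected.
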