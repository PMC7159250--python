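# Methods

`laminaseg` implements surface-based laminar segmentation of 3D
histological volumes: intensity profiles are sampled along approximately
columnar streamlines between paired pial and white surfaces, each of the
200 points per profile is classified into one of eight depth classes
(0 = supra-pial background/CSF, 1–6 = cortical layers I–VI, 7 = white
matter) by a 1D convolutional network, classifications are converted into
seven nested boundary surfaces, and total/laminar thickness is analyzed
against geodesic distance from primary areas. A synthetic laminar
generator provides ground truth at every stage.

## Volumes, blocks and smoothing

Volumes are isotropic scalar grids (NIfTI-1 on disk; MINC is read but not
written). Voxel centers sit at `origin + (i + 0.5)·spacing`, world units
are mm, and the y axis runs posterior→anterior. Large volumes are
partitioned into `n³` blocks whose non-overlapping cores tile the parent;
each block is expanded by `ceil(overlap/spacing)` voxels per side so any
cortical column shorter than the overlap lies wholly inside at least one
block (profiles near block faces are then unaffected by smoothing edge
effects). Downsampling is block-mean pooling — it preserves intensity
statistics, and composes exactly (pool by a then b = pool by a·b on
divisible grids); nearest-neighbour subsampling would alias the laminar
banding.

Edge-preserving volume smoothing is diffusion with Perona–Malik
conductance `g = 1/(1 + (|∇u|/K)²)` in flux form (total intensity is
conserved to <0.1%). The step count is calibrated analytically so that a
low-amplitude impulse in a flat region spreads to an effective FWHM of
0.163 mm (σ² = 2·dt·n in voxel units with dt = 1/6); across strong edges
the conductance suppresses flux, so laminar contrast survives. `K`
(default 1.0 intensity unit) sets the "strong edge" scale and should be
of the order of the interlaminar contrast.

## Profile geometry

The midsurface interpolates between corresponding pial/white vertices with
a logistic weight of the signed mean curvature, bounded in [0.25, 0.75]
and 0.5 at zero curvature: on gyral crowns (negative curvature by our
convention) it hugs the white surface, in sulcal fundi the pial surface,
reducing streamline crossings. The exact functional form of this weight is
a package choice; any bounded monotone sigmoid serves.

Meshes are upsampled by one edge-midpoint subdivision (V' = V + E,
F' = 4F; 163,842-vertex spheres become 655,362). Streamline directions —
unit white→pial vectors — are smoothed component-wise across the
midsurface graph with a Gaussian kernel (FWHM 3 mm by default; geodesic
edge distances truncated at 3σ) and re-normalized, then endpoints are
extended 0.5 mm beyond each surface. On folded sheets with noisy
pial–white correspondence this vector smoothing sharply reduces
surface self-intersections (counted exactly by a Möller triangle–triangle
test with an AABB sweep broad phase); the optimum is reached around
FWHM 2 mm, and both 2 and 3 mm are exposed in `SmoothingConfig`.

Profiles sample the raw and diffusion-smoothed volumes by trilinear
interpolation at 200 equidistant points per streamline (index 0 =
supra-pial end); a ~4 mm streamline gives 0.02 mm between points.
The rostrocaudal staining drift is removed by regressing mean profile
intensity on the anterior–posterior coordinate and subtracting the
centered fitted trend, which changes no profile's internal shape.

## The classifier

The network is a stack of identical blocks — batch normalization, ReLU,
same-length 1D convolution (reflect padding) — over the 2-channel
(raw + smoothed) input, closed by a width-1 convolution to 8 maps and a
per-point softmax. The loss is median class-frequency-weighted
cross-entropy, `w_c = median(f)/f_c`, so the thin layers II and IV
(≈5.6% and 5.5% of training points) weigh ≈2.5× more than average and
the network cannot profit from ignoring them; the log is clamped at
1e-12. Training is plain SGD with decoupled weight decay and early
stopping: the best-on-validation snapshot is kept and training stops when
validation accuracy has not improved for `patience_epochs`. Everything is
deterministic under a fixed seed.

Reference hyperparameters (the `NetworkConfig` defaults) are 6 blocks,
filter size 49, 64 feature maps, learning rate 5e-4, weight decay 1e-3,
patience 50. Desk-scale experiments use `desk_config()` — 3 blocks,
filter 25, 12 maps, learning rate 0.1, batch 64, ≤20 epochs — whose
~73-point receptive field spans enough laminar context to disambiguate
layers with similar staining darkness (III vs V need to "see" the dark
layer-IV band between them). The implementation is pure NumPy (im2col
convolutions through BLAS with hand-derived backprop), sized for a single
CPU; models serialize to a portable `.npz` of flat weight arrays plus the
architecture triple.

Cross-validation follows the k-fold scheme with a held-out validation
fold: per repetition the model trains on k−2 folds, early-stops on one,
and is scored on the final unseen fold; every profile is tested exactly
once. The resolution sweep degrades each profile to the number of
independent samples the coarse voxel grid supports (block-mean pooling,
then linear re-interpolation to 200 points — at 1,000 µm a ~3.5 mm
profile keeps ~4 values) and repeats train/test per resolution on rotated
splits, averaging the repeats; single-run SGD variance otherwise
dominates the small true differences between adjacent fine resolutions.

Confidence is the top-1 minus top-2 softmax margin per point, summarized
per class (mean over points assigned to the class) and per vertex (mean
over the 200 points).

## Surface reconstruction

Non-monotone label sequences are replaced by the monotone non-decreasing
relabeling that changes the fewest points, found by dynamic programming
over (position, class); ties backtrack to the smallest feasible class. A
vertex is flagged failed when the cleanup changed >30% of its points or
the profile contains a single class (both thresholds configurable — the
failure criterion is a package choice). Boundary b sits midway between
the last point of class ≤ b−1 and the first of class ≥ b (bias bound:
half a sample spacing); absent classes collapse to zero-thickness layers.
Failed vertices are filled by iterated unweighted neighbour means
(Jacobi) to convergence, then per-boundary indices are smoothed 0.5 mm
FWHM along the surface with nesting re-enforced by a cumulative maximum,
converted to coordinates by linear interpolation along each streamline,
and the resulting meshes get 20 iterations of Taubin smoothing
(λ = 0.5, µ = −0.53: volume change <1% on a fine sphere, high-frequency
vertex noise reduced well over 50%).

`max_gradient_depth` reports where a gradient-based white-surface rule
would sit: the steepest intensity step in the deep half of the profile
(ties to the smallest index). With an intermediate-intensity VIb band
this lands at the VIa/VIb transition, superficial to the
cytoarchitectonic VI/white boundary — the systematic offset between
gradient-placed and neuron-defined white surfaces.

## Morphometry and gradients

Thickness is the Euclidean distance between corresponding vertices of
bounding surfaces (the streamline construction keeps each column
collinear, so the six laminar thicknesses sum to the total exactly).
Fixation shrinkage is corrected by scaling coordinates, either
isotropically by the cube root of the volume factor (1.931^(1/3) = 1.245)
or per axis (1.15, 1.22, 1.43). Masks (medial wall, cuts, allocortex)
exclude vertices from all downstream statistics; separate masks for total
vs laminar analyses are supported.

Geodesic distance from a primary-area label is multi-source Dijkstra on
the mesh edge graph (a virtual zero-weight source node). Edge-graph
distances overestimate true polyhedral geodesics by at most the lattice
stretch factor (≈1.08 on a fine icosphere; antipodal distance on the unit
sphere is recovered within 5%), which is immaterial for rank/correlation
statistics. Gradients are Pearson correlations of (laminar) thickness
with distance over a system's region; p-values use the standard t
transform and are reported as computed (values below ~1e-15 print as 0 in
float display; we report the computed number). Sliding-window tables
average laminar thickness in [d, d + window) bins. Regional atlas
comparisons use area-weighted Pearson correlation (weighted means and
covariances); with uniform weights it reduces exactly to the ordinary
coefficient, and both modes are available since the weighting convention
for per-layer comparisons is not fixed.

## The synthetic generator

Default class fractions are 14.6 / 7.5 / 5.6 / 20.8 / 5.5 / 14.8 / 17.8 /
13.4 % (background, I–VI, white). Staining darkness per class is a
modeling choice — no per-layer intensity statistics exist to calibrate
against — fixed at 0.05 / 0.25 / 0.85 / 0.50 / 0.90 / 0.55 / 0.70 / 0.20
arbitrary units, a strictly contrastive assignment mimicking cell-density
contrast (granular layers II and IV dark, layer I and white matter pale).
Within-layer texture is iid Gaussian (default sd 0.05); boundary jitter
is Gaussian in depth, truncated to preserve ordering. The default
cortical thickness is 2.57 mm, chosen so that with the printed class
fractions the implied paddings beyond pial (≈0.52 mm) and white
(≈0.48 mm) fall inside the 0.25–0.75 mm extension interval; training
sets draw the paddings uniformly from that interval. The V1 variant
triples the layer-IV fraction, thins layer III by the same amount, and
adds two dark sub-bands inside layer IV (≥2 interior intensity extrema),
mimicking its sublaminated granular layer. A rostrocaudal staining slope
adds a linear mean-intensity trend in the y anchor coordinate. A
configurable fraction (<1% by default) of profiles is corrupted to
constant or saturated traces, emulating network/sampling failures.

The folded phantom is a sinusoidally folded laminar slab voxelized into a
volume (default 64³ at 100 µm) with paired open-sheet pial/white meshes in
1:1 vertex correspondence, optional curvature-coupled thinning (fundi
thinner than crowns) and an optional linear thickness gradient along x
emulating a processing-hierarchy gradient away from a "primary" edge.

What the generator does **not** emulate: spatially correlated
cell-clustering texture, section tears and shears, registration error
between sections, partial-volume effects of curved laminae, and closed
whole-hemisphere topology. Passing tests therefore demonstrate the
correctness and calibration of the pipeline machinery on profiles with
the right gross statistical structure, not performance on real
histology. One visible consequence: between 20 and 40 µm the synthetic
profiles carry nearly equal information (block-mean pooling even averages
the iid noise), so accuracy differences at the fine end of the resolution
sweep are small and only resolve after repeat averaging, whereas real
histology loses genuine fine-scale structure at every step.

## Problem sizes

Desk-scale defaults used by the test-suite and the acceptance script:
profile sets of 400–600, `desk_config()` networks, 10-fold CV at n=400,
resolution sweep at n=600 with 3 repeats per resolution, phantoms
of 64³ voxels at 100 µm with 256-vertex sheets. The reference
hyperparameters remain the library defaults for full-scale use.

## Known limitations

- Thickness uses corresponding-vertex distances; a nearest-point
  alternative would differ on strongly oblique columns.
- Geodesic distances are edge-graph, not exact polyhedral.
- The monotone-cleanup tie-break (smallest feasible class in the
  backtrace) is one of several minimal-edit optima.
- MINC files are read-only; writing targets NIfTI-1.
- The NumPy network trains on CPU only and is not sized for the
  full-resolution, whole-hemisphere problem.
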