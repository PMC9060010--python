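# Methods

`fibremorph` quantifies the 3D architecture of dermal elastic fibres in
confocal Z-stacks of cleared skin. This note records the model behind each
step, the parameters that matter, what the synthetic phantoms do and do not
emulate, and the numerical choices that were genuinely open.

## Pipeline

For each imaged field (a multichannel Z-stack with voxel spacing
(dz, dy, dx) µm):

1. **Depth crop.** Slices at depth > 100 µm (default, inclusive) are
   discarded; fluorescence in cleared skin degrades beyond that depth, so
   metrics are computed on the well-lit volume only. Depth is measured from
   the first acquired slice (`depth_origin`, default 0 = epidermal surface).
2. **Binarization.** Optional Gaussian smoothing and top-hat background
   subtraction in physical units, then a single per-volume Otsu threshold
   (256-bin histogram) on the fibre (tropoelastin) channel. Per-volume
   rather than per-slice thresholding avoids slice-to-slice flicker; a
   per-slice mode exists behind config for strongly attenuated stacks but
   is never the default. Components smaller than 10 µm³ (default) are
   removed at 26-connectivity.
3. **Skeletonization.** The mask is resampled by nearest neighbour to an
   isotropic grid at min(spacing) — 3D homotopic thinning assumes isotropy —
   and thinned to a one-voxel skeleton (Lee's algorithm via scikit-image).
   The implementation in scikit-image 0.26 deletes whole components whose
   cross-section is mirror-symmetric about a half-integer grid position;
   `skeletonize` therefore verifies that every mask component retains a
   skeleton voxel and re-thins failing components with a one-voxel
   parity-breaking smear (the resulting half-voxel bias is removed by the
   refinement below).
4. **Skeleton graph.** Skeleton voxels are classified by 26-neighbour
   count (1 = endpoint, ≥3 = junction candidate); 26-connected junction
   candidates merge into one junction node at their centroid, which
   prevents double counting where thick fibres cross. Edges are traced
   voxel to voxel; node-free loops receive an anchor node. Terminal edges
   shorter than 3 µm (default) emanating from junctions are pruned as
   thinning spurs, and degree-2 remnants are spliced; without this, branch
   counts on thick tubes are inflated.
5. **Centre-of-gravity refinement.** Each interior centreline point moves
   to the coverage-weighted centroid of its fibre cross-section: the plane
   normal to the local tangent is sampled at half-voxel pitch with
   trilinear mask coverage, the connected blob containing the point is
   kept (so a neighbouring fibre crossing the plane is ignored), and the
   move is restricted to the normal plane so points cannot migrate along
   the fibre. Tangents come from a lightly pre-smoothed copy of the
   polyline. Two iterations by default; on tube phantoms a third moves
   points by well under a tenth of a voxel. A final pass also re-centres
   degree-1 tip nodes (thinning leaves them off-axis); junction nodes stay
   anchored. On noise-free arc phantoms the refined centreline sits within
   ~0.1 µm RMS of the analytic axis at 1 µm voxels.
6. **Tip extension.** Homotopic thinning retreats from fibre tips by
   roughly the tube radius, which would bias length low by ~2r per fibre.
   Terminal polylines are prolonged along a least-squares local tangent in
   half-voxel steps until the trace leaves the mask, capped at the local
   radius plus two voxels. Extensions are straight guesses, not centred
   paths: they count toward length but are trimmed away (edge attribute
   `ext_um`) before curvature and diameter are estimated. For tightly
   curled thin fibres the straight extension cannot follow the bend, which
   leaves length up to ~4 % low in the worst tested case (R = 8 µm bend,
   r = 2 µm tube); typical cases recover within 2 %.
7. **Resampling and path fitting.** Each centreline is resampled at 1 µm
   arc length (linear interpolation; the final interval may be shorter).
   Before curvature/diameter estimation the path is fitted with a
   quadratic-preserving Savitzky–Golay filter whose window spans the whole
   path up to 21 points. A quadratic fit leaves the curvature of circular
   arcs essentially intact (worst observed bias −4.6 % on a half-circle at
   R = 8 µm) while suppressing voxel jitter, which enters the second
   difference at 1/Δs² and otherwise dominates gently curved fibres. The
   plain moving average (window 5, odd reflection so straight paths stay
   straight) is available via `path_smoothing="movavg"`.

## Metrics

- **Volume fraction** — foreground voxels / all voxels of the cropped
  field.
- **Surface area** — marching-cubes isosurface at level 0.5 of the
  anisotropy-scaled mask, pre-smoothed with σ = 0.8 voxel. Raw binary
  marching cubes carries a staircase overestimate (≈ +9 % on a digital
  sphere of r = 10 µm, ≈ +18 % on an r = 3 µm tube at 1 µm voxels); the
  smoothing brings both within ~4 % with errors that shrink as spacing
  halves. Voxel-face counting is not used (up to ~50 % overestimate on
  smooth surfaces). Phantom truth excludes end caps; measured areas
  include them, and tolerances account for that.
- **Length** — sum of consecutive point distances of the (extended)
  resampled path.
- **Curvature** — mean of ‖p_{i+1} − 2 p_i + p_{i−1}‖ / Δs² over interior
  points of the fitted 1 µm path. For arc-length-parametrized curves this
  is the geometric curvature: 1/R for a circle (with the closed-form chord
  error 2R(1 − cos(Δs/R))/Δs², ≈ 0.1 % at R = 10, Δs = 1), a/(a² + c²)
  for a helix. The vector-norm reading of "second derivative" is the key
  interpretive choice: per-component signed derivatives would not produce
  a single degree-of-curvature number. Points within 2 µm of a junction
  (cross-sections there merge fibres), within 2 µm of a fibre tip, and in
  the extension zone are excluded. Per-fibre means are averaged per field;
  a point-weighted pooled mode exists via config.
- **Diameter (thickness)** — equivalent-circle diameter 2√(A/π) of the
  cross-section in the plane normal to the local tangent, with A the
  coverage-integrated area of the connected blob (thresholding the
  trilinear field at 0.5 instead would bias the radius up by ~half a
  voxel). Reported as a diameter, never a radius. A fallback estimator,
  2 × the Euclidean distance transform at the point, agrees within one
  voxel on straight tubes and is selectable via config.
- **Branch count** — junction nodes of the pruned skeleton graph.
- **Intensity ratio** — mean fibrillin-1 intensity over the mask divided
  by mean tropoelastin intensity over the same mask.

## Group statistics

Both the exact Mann–Whitney U (headline) and the equal-variance Student's
t are always computed; methods sections and figure legends of aging
studies commonly disagree about which was used, and the package surfaces
the discrepancy rather than resolving it. The exact p enumerates all
C(n_A+n_B, n_A) group assignments of the observed midranks for pooled
sizes ≤ 12 (covers n = 3 vs 3) and falls back to the tie-corrected normal
approximation above that. Note the small-sample floor: at n = 3 per group
the exact two-sided p cannot fall below 2/20 = 0.1, so no n = 3 comparison
can be starred at 0.05 by an exact U test. Percent differences are
reported in both conventions (100·B/A and 100·(B/A − 1)) because "X %
thicker" is ambiguous between them. No multiple-testing correction is
applied.

## Synthetic phantoms

The human tissue stacks behind the original measurements are not public,
so validation rests on tubular phantoms with analytic truth: segments,
circular arcs, helices (curvature a/(a²+c²) under the standard
pitch-per-radian parametrization), branching trees, and candelabra figures
(an arched base fibre parallel to the epidermal surface with upward
prongs, emulating oxytalan cascades). Membership is
voxel-centre-within-radius of the centreline with end planes cut, so a
straight tube is an exact cylinder of volume π r² L; truth surface area is
the lateral 2π r L. The imaging model applies Gaussian PSF blur (defaults
σ = 1.0, 0.5, 0.5 µm — placeholders, not derived from any instrument),
depth attenuation exp(−z/ζ), constant background, and Poisson/Gaussian
noise, all driven by one explicit seed.

Cohort fields hold three candelabra fibres each — an imaged field of
papillary dermis contains many fibres, and per-field means average over
them. The "young" template uses a 40 µm bend radius, 1.5 µm tube radius
and ~5 prongs per fibre; the "aged" template scales curvature and
thickness by 2.65× and roughly halves the prong count, matching the
direction and magnitude of reported aging changes in abdominal skin.
Bend and tube radii are lognormal (CV 0.15 and 0.10); prong counts are
Poisson.

What phantoms do **not** emulate: fibre-type mixtures (oxytalan vs elaunin
vs elastic), nuclei and appendage autofluorescence, spatially varying
background, refractive-index distortion at depth, touching/merging fibre
bundles, or anisotropic PSF asymmetries. Passing the phantom suite shows
the measurement chain is unbiased on tubular geometry at realistic SNR; it
does not certify segmentation quality on real tissue, which depends on
staining and clearing quality outside the package's control.

## Problem sizes

Validation runs use 1 µm isotropic grids of roughly 20–60 voxels per side
(half-circle arc tubes with R ∈ {8, 15, 30} µm, r ∈ {2, 3, 4} µm; spheres
of r = 10 µm; candelabras with 2–5 prongs; cohorts of 10 three-fibre
fields per group), with 0.5 µm grids for the convergence checks. These
sizes keep the full suite and the acceptance script in the ~1 minute
range while leaving every recovery margin well clear of its tolerance.

## Known limitations

- Fibres shorter than ~8 µm after junction/tip trimming yield noisy
  curvature; the global quadratic fit stabilizes but cannot eliminate
  this.
- Tip extension is straight, so length is biased low (up to ~4 %) on
  tightly curled thin fibres.
- Diameter near junctions is undefined (excluded); fields dominated by
  junctions report diameter from few points.
- The candelabra base arc meets prongs at right angles; real oxytalan
  insertion geometry is more varied.
- Surface areas of structures thinner than ~2 voxels are unreliable at
  any setting; the σ = 0.8 pre-smoothing assumes features ≥ ~3 voxels
  across.
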