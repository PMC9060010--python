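# fibremorph

Quantitative 3D morphometry of dermal elastic fibres from confocal
Z-stacks of cleared skin.

Skin elasticity rests on a network of elastic fibres (an elastin core
wrapped in fibrillin-1 microfibrils) whose papillary-dermis portion —
candelabra-like oxytalan cascades rising to the dermal-epidermal junction
from arched elaunin fibres — remodels with age. Tissue clearing plus
confocal imaging yields multichannel stacks ~100 µm deep in which that
remodelling is visible but hard to judge by eye. `fibremorph` turns such
stacks into numbers: it binarizes the fibre channel, skeletonizes it,
refines each centreline to the fibre's cross-sectional centre of gravity,
and measures, per field,

- **volume fraction** (fibre voxels / field voxels) and **surface area**
  (marching-cubes isosurface, µm²),
- per fibre: **length** (µm), **thickness** as the equivalent-circle
  diameter 2√(A/π) of the perpendicular cross-section (µm), and
  **curvature** as the mean second-difference norm
  κ̄ = mean‖p₍ᵢ₊₁₎ − 2pᵢ + p₍ᵢ₋₁₎‖/Δs² of the centreline resampled at
  Δs = 1 µm (κ̄ → 1/R on a circular arc of radius R),
- **branch count** (junction nodes of the skeleton graph), and the
- **fibrillin-1 / tropoelastin intensity ratio** over the fibre mask.

Group comparisons (e.g. young vs aged donors) report mean ± SD, an exact
Mann-Whitney U test (enumeration for pooled n ≤ 12, where at n = 3 + 3
the two-sided p can never beat 0.1), Student's t, and percent differences
in both conventions (100·B/A and 100·(B/A − 1)).

Because real cleared-skin stacks are rarely shareable, the package ships a
phantom generator — tubes along segments, arcs and helices, branching
trees, and candelabra figures, rendered through a confocal-like model
(PSF blur, depth attenuation exp(−z/ζ), Poisson/Gaussian noise) — with
analytic ground truth for every metric. The whole measurement chain is
validated against those truths; see `docs/methods.md`.

## Worked example

Simulate a candelabra phantom (3 prongs, 2 µm tube radius, mild noise),
analyse it, and read the metrics:

```bash
$ cat candelabra.json
{
  "kind": "candelabra", "n_prongs": 3, "tube_radius_um": 2.0,
  "jitter_sd_um": 0.3, "base_depth_um": 30, "prong_length_um": 15,
  "seed": 7,
  "imaging": {"psf_sigma_um": [0.5, 0.5, 0.5], "gaussian_sd": 2.0, "peak": 100}
}

$ fibremorph simulate --spec candelabra.json --outdir sim
wrote candelabra.tif and candelabra_truth.json to sim

$ fibremorph analyze --input sim/candelabra.tif --group young --outdir young
analyzed 1 stack(s) -> young/field_metrics.csv
```

`young/field_metrics.csv` then contains (one row per stack):

```
sample_id,group,site,volume_fraction,surface_area_um2,n_branches,mean_length_um,mean_diameter_um,mean_curvature_per_um,intensity_ratio
candelabra,young,,0.00998434704830054,832.949035644531,3,13.8346381181145,3.83884799759815,0.0553678761069885,
```

Reading it: the pipeline recovered all **3** branch points of the phantom;
the mean fibre segment is **13.8 µm** long (the skeleton graph splits the
arched base at each prong insertion, giving 4 base arcs plus 3 prongs);
the mean equivalent diameter is **3.84 µm** against a true tube diameter
of 4 µm; fibres occupy **1.0 %** of the field. `intensity_ratio` is empty
because this phantom has a single channel — missing metrics stay missing,
never silently zero.

With two groups of stacks analysed into tables, compare them:

```bash
fibremorph compare --table young/field_metrics.csv --table aged/field_metrics.csv --outdir report
```

which writes `comparison.csv` / `comparison.json` with means, SDs, U and
t statistics, exact p-values, star annotations (p < 0.05 / 0.01 / 0.005)
and both percent conventions.

The same pipeline is available as a library:

```python
from fibremorph import read_stack, analyze_field
from fibremorph.morphometry import AnalysisConfig

stack = read_stack("field.tif", spacing_override=(0.8, 0.207, 0.207),
                   channel_roles=["nuclei", "tropoelastin", "fibrillin1"])
metrics = analyze_field(stack, AnalysisConfig(max_depth_um=100.0))
print(metrics.n_branches, metrics.mean_curvature_per_um)
```

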