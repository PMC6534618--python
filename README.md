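# crabcamo

Quantify camouflage of shore crabs (*Carcinus maenas*) the way their
predators see it. The package implements, as a reusable and fully tested
pipeline, the image-analysis chain used to compare **background matching**
and **disruptive coloration** between crabs from two intertidal habitats —
homogeneous mudflats and visually complex rock pools — and exercises the
whole chain end to end on synthetic multispectral scenes with known ground
truth.

## Who this is for

Visual-ecology and sensory-biology researchers who work with calibrated
(UV-capable) multispectral photography and need camouflage metrics through
receiver-specific vision models, plus the matching statistics; and anyone
who wants a self-contained, deterministic test bed for those metrics.

## What it computes

For each crab (region of interest) against each background image:

* **Cone catches.** Calibrated camera channels (UV/SW/MW/LW, linearised
  against 8.2% / 94.8% reflectance standards) are mapped to predator cone
  catches with the standard degree-2 polynomial mapping, for a violet-type
  tetrachromatic bird (peafowl-like, double-cone luminance channel) and a
  dichromatic fish (pollack-like, SW+LW).
* **Colour and luminance JNDs.** The log-linear receptor-noise-limited
  model: Δf_i = ln q_A,i − ln q_B,i, with chromatic distance

      ΔS² = Σ_{i<j} (Π_{k∉{i,j}} e_k)² (Δf_i − Δf_j)² / Σ_i (Π_{k≠i} e_k)²

  (reducing to the familiar di-/tri-/tetrachromat closed forms) and
  achromatic distance |Δf_L|/e_L. Values below ~1 JND are indistinguishable
  to the modelled viewer.
* **Pattern energy difference (PED).** Granularity spectra — the standard
  deviation of luminance band-passed at octave spatial scales — compared by
  the summed absolute difference across scales.
* **GabRat edge disruption.** Around the target outline, quadrature Gabor
  filters measure coherent (tangent-aligned) versus false (outline-crossing)
  edge energy; GabRat is the mean of E_perp/(E_par+E_perp). Targets are
  composited at 50 seeded, non-overlapping random positions per background.
* **Statistics.** A 2×2 split-plot repeated-measures ANOVA with type-III
  sums of squares (between factor: habitat of origin; within factor:
  background habitat) per metric, plus Levene (Brown–Forsythe) diagnostics.

The synthetic-data module generates the study conditions: 47 backgrounds
per habitat class with embedded reflectance standards, uniform
mudflat-matched and margin-blotched disruptive crab phenotypes, and a
four-channel camera with peaks at 380/460/540/625 nm.

## Worked example

```python
from crabcamo.pipeline import PipelineConfig, run_all

cfg = PipelineConfig(seed=1, n_backgrounds_per_habitat=6, n_crabs_per_origin=6,
                     scene_size=(384, 384), placements=10,
                     carapace_range_mm=(4.5, 6.5))
report = run_all(cfg)
print(report["cell_means"][["jnd_lum_avian", "ped", "gabrat"]].round(3))
at = report["anova"]["gabrat"].effects.loc["origin:background"]
print(f"gabrat interaction: F_1,{int(at.df_den)} = {at.F:.2f}, p = {at.p:.4f}")
```

prints

```
                   jnd_lum_avian    ped  gabrat
origin background
MF     MF                  0.538  0.008   0.117
       RP                 27.114  0.214   0.114
RP     MF                 33.092  0.155   0.197
       RP                  5.932  0.172   0.335
gabrat interaction: F_1,10 = 238.51, p = 0.0000
```

Read: mudflat-origin (uniform, mud-matched) crabs are nearly invisible on
mudflat (luminance 0.54 JND, PED 0.008) and conspicuous on rock pools,
while rock-pool-origin (disruptive) crabs carry higher edge disruption on
*both* habitats (0.197 / 0.335 vs 0.117 / 0.114) — background matching and
disruption as habitat-specific strategies. The interaction F tests whether
the background effect depends on the crabs' origin.

The same workflow is available from a shell:

```bash
crabcamo all --config config.yaml --seed 1 --out results/
```

which writes `measurements.csv` (one row per crab × background habitat),
`anova.csv`, `cell_means.csv`, the trained cone mappings and a JSON run log.

## Layout

| module | contents |
| --- | --- |
| `crabcamo.synthetic` | scene/crab/spectrum generators with ground truth |
| `crabcamo.calibration` | standard-based normalisation, rescaling |
| `crabcamo.vision` | visual systems, polynomial cone mapping |
| `crabcamo.discrimination` | receptor-noise-limited JNDs |
| `crabcamo.pattern` | granularity spectra and PED |
| `crabcamo.disruption` | GabRat, outline tracing, random placement |
| `crabcamo.stats` | Levene + split-plot type-III ANOVA |
| `crabcamo.pipeline` / `crabcamo.cli` / `crabcamo.io` | orchestration, files, CLI |

See `docs/methods.md` for the model details, defaults and limitations.
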