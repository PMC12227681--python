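# foveamap

Cone photoreceptor detection and foveolar topography analysis for confocal
adaptive-optics scanning light ophthalmoscopy (AOSLO) montages.

The foveola — the central ~1 degree of the human retina — packs cones in a
quasi-hexagonal mosaic with a steep density peak. Counting and mapping those
cones in vivo is the basis of much foveal vision research, but manual
annotation of a 2-degree montage (tens of thousands of cells) takes hours and
depends on the reader. `foveamap` provides a scriptable pipeline for this
task, aimed at vision scientists and image-analysis researchers working with
AOSLO-like data:

- **Detection.** A fully convolutional U-Net regresses the *distance
  transform* D(x) = distance to the nearest cone center from a 256×256 image
  patch (k = 2 conv+BN+ReLU sub-blocks per resolution, 3 poolings, dropout
  p = 0.2 at the bottleneck, 4×4/stride-2 transposed-conv decoder with skip
  connections, 1×1 regression head). Cone centers are the thresholded local
  minima of the stitched prediction, refined to sub-pixel precision. The
  network is implemented in pure numpy (im2col + BLAS), so training and
  inference run anywhere Python runs.
- **Refinement (optional).** A regularity-aware particle system (RAPS)
  minimizes `E = (1−α)·E_ext + (α/2)·E_int`, where `E_ext = Σ_p D(p)` is the
  image evidence and `E_int = Σ_p Σ_{n∈N(p)} (‖p−n‖ − d₀)²` imposes mosaic
  regularity over Delaunay neighbors. Off by default.
- **Evaluation.** One-to-one matching of predictions to ground truth within
  d = 0.35 × the minimal pairwise ground-truth distance, inside the convex
  hull of the ground-truth set; TPR = TP/(TP+FN), FDR = FP/(TP+FP),
  F1 = 2TP/(2TP+FP+FN); one-directional Chamfer distance; and an estimated
  manual correction time at 3 s per residual error.
- **Topography.** Three cone-density estimators — Voronoi (combined area of
  the 150 nearest cells), inter-cone distance (ICD; density = 2/(√3·ICD²)),
  and Yellott's ring (density = (√3/2)·f*² from the spectral ring frequency
  f*) — plus peak cone density (PCD), the cone density centroid (CDC,
  density-weighted centroid of the top-20% region), z-score maps against
  CDC-aligned group averages, and radial/meridional density profiles.
- **Simulation.** A seeded synthetic mosaic generator (dart throwing +
  Lloyd relaxation, lognormal reflectivity, Gaussian PSF, detector noise)
  with known ground truth, so the entire pipeline is testable end-to-end
  without any image downloads.

## Worked example

Simulate a 200×200 px foveal mosaic (600 px/deg, peak 15,000 cones/deg²,
base 6,000, exponential falloff 0.5 deg), detect cones on the exact distance
label (the no-model demo path), score them against the simulator's ground
truth and map the density topography:

```python
from foveamap.io import PipelineConfig, run_pipeline
from foveamap.synthetic_mosaic import MosaicSpec

spec = MosaicSpec(field_size_px=(200, 200), scale_px_per_deg=600.0,
                  peak_density_deg2=15_000.0, base_density_deg2=6_000.0,
                  falloff_scale_deg=0.5, seed=42)
session = run_pipeline(PipelineConfig(simulate=spec, seed=42))
print(session.evaluation)
print(session.landmarks)
```

prints, for this seed (rounded to 4 decimals here):

```
{'TP': 1431, 'FP': 0, 'FN': 14, 'TPR': 0.9903, 'FDR': 0.0, 'F1': 0.9951,
 'chamfer_px': 0.0717, 'd_px': 1.2913, 'correction_min': 0.7}
Landmarks(cdc_xy=(99.7, 99.8), cdc_value=14466.1,
          pcd_xy=(110.0, 100.0), pcd_value=14478.2)
```

1445 cones were simulated; 1431 are recovered within d = 1.29 px (0.35 × the
minimal ground-truth spacing), none are spurious, and fixing the 14 misses
would take an expert about 42 s. The peak cone density (~14,478 cones/deg²)
sits at the mosaic center and the CDC lands within half a pixel of the true
density peak at (99.5, 99.5).

The same stages are available from the shell:

```bash
foveamap simulate --out data/ --n 3 --seed 0
foveamap train    --images data/ --out model.npz --epochs 25
foveamap detect   --image data/mosaic_000.tif --model model.npz --out pred.csv
foveamap evaluate --pred pred.csv --gt data/mosaic_000.csv
foveamap topography --cones pred.csv --out topo/ --method voronoi
```

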