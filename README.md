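# panelpet

Simulation and correction of spatially-variant image deformations in
dual-panel PET.

Dual-panel scanners — such as dedicated breast-PET systems with two
flat detector heads 9–11 cm apart — acquire limited-angle data (132°
of the full 180° at 9 cm separation, i.e. 73% coverage).  Their
reconstructions show strong, spatially-variant deformations: lesions
blur anisotropically, elongate along the axis normal to the panels,
and shift toward the nearer panel.  `panelpet` is a toolkit for
studying and correcting these effects with a learned post-
reconstruction step, aimed at researchers in PET instrumentation and
image reconstruction:

* **Phantoms** — point sources, spheres, irregular triple-ellipsoid
  lesions in warm background, and breast-scanner cylinders (4–6 cm,
  1–10 spherical lesions of 2–10 mm at 6:1–10:1 contrast), all
  declarative and exactly reproducible from JSON specs.
* **PSF deformation** — a spatially-variant mixture of two 3D
  Gaussians per 15 mm anchor point (weights, widths, shifts),
  mirrored/interpolated across the FOV and applied as a
  count-conserving scatter blur; plus image-domain Poisson noise.
* **Limited-angle TOF reconstruction** — histo-image forward model
  (60 views x 3°, 15 tilts x 3.3°, 500 ps TOF, 0.8 mm LOR width) and
  relaxed row-action ML (RAMLA, lambda = 0.1, 10 iterations, one view
  per subset).
* **Corrector network** — a 3-level U-Net (3^d convolutions + ReLU,
  max-pool down, transposed-conv up, skip connections, 1 channel),
  trained with L1 loss and Adam at batch size 1 on synthetic
  (deformed/reconstructed, truth) pairs.  Implemented in pure numpy
  with explicit backprop — no GPU framework required — and
  bit-reproducible for a fixed seed.
* **Metrics** — per-lesion bias `Bias_i% = 100 (X̄_lesion - X̄_true)/
  X̄_true`, contrast recovery `CRC_i = ((X̄_lesion - X̄_bkg)/X̄_bkg) /
  contrast_true`, image roughness `IR% = 100 σ_bkg / X̄_bkg`, and the
  peak-to-valley separability measure `PVM% = 100 (P - V) / (P-V)_truth`.

See `docs/methods.md` for the models, parameter defaults and design
choices.

## Worked example

Deform a warm-background lesion phantom, add noise, and score it:

```python
import numpy as np
import panelpet as pp

grid = pp.VoxelGrid((64, 64))                      # 2D desk-scale grid, 1 mm voxels
rng = np.random.default_rng(1)
spec, label = pp.sample_lesion_field(rng, 2, grid, size_range=(6, 16))

kernels = pp.default_fig1_grid(grid)               # built-in dual-panel PSF table
deformed = pp.deform_image(label, kernels)
noisy = pp.add_poisson_noise(deformed, counts_scale=4.0, rng=rng)

rep = pp.report({"deformed": deformed, "noisy": noisy}, label, spec,
                background_margin_mm=8.0, wall_margin_mm=4.0)
print(rep.table.to_string(index=False))
```

```
  method  avg_abs_bias_percent  avg_crc  ir_percent
deformed              38.52500 0.544297   10.357096
   noisy               39.33104 0.545626   55.611930
```

The deformation biases the lesion means by ~39% and recovers only
~0.54 of the true contrast; Poisson noise at counts-scale 4 dominates
the background roughness (~50 percentage points, as expected from
IR ≈ 100/sqrt(4)).  The nonzero IR of the noiseless deformed image is
an artifact of the tight background margins a 64 mm FOV forces — edge
rolloff reaches into the mask.  On a larger grid with blur-reach
margins the deformed background is exactly flat; that measurement is
what `scripts/acceptance.py` reproduces (IR = 0.00%).

Training the corrector end to end (50 train / 5 test pairs, a few
CPU-minutes) and evaluating the held-out pairs:

```python
from panelpet.pipeline import ExperimentProfile, run_experiment
summary = run_experiment(ExperimentProfile(name="psf_deform", seed=11), "runs/")
```

A representative desk-scale run reports

```
            avg_abs_bias_percent   avg_crc  ir_percent
input                  39.058035  0.525893   51.680444
prediction             14.951986  0.788610    0.175872
```

i.e. the trained network more than halves the average absolute lesion
bias of the noisy deformed inputs, raises contrast recovery from 0.53
to 0.79 and suppresses background roughness from ~52% to ~0.2%.

The same pipeline is scriptable from the shell:

```bash
panelpet gen-phantoms --class complex --n 5 --seed 1 --shape 64,64 --out phantoms/
panelpet deform --in phantoms/phantom_0000.nii --out deformed.nii --noise-scale 4 --seed 1
panelpet evaluate --truth phantoms/phantom_0000.nii --images deformed.nii \
    --spec phantoms/phantom_0000_spec.json --out report.csv
panelpet run --family separability --out runs/
```

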