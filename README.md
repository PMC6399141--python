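# ecgitank

A synthetic torso-tank + optical-mapping platform for validating
electrocardiographic imaging (ECGI) reconstructions. Everything the analysis
needs is simulated: heart/tank geometry with sock and tank electrodes,
propagating activation with a perfusion-bed perturbation, transmembrane
action potentials, unipolar electrograms, a volume-conductor forward
solution, and a 100×100 fluorescence movie. On top of that sit the analysis
stages:

- **signal preprocessing** — spatial (2.1 mm) and temporal (1.5 ms)
  averaging, the 20%-amplitude data mask with component removal and
  dilation–erosion smoothing, multi-lead beat averaging, camera-sync
  alignment, bad-channel screening;
- **camera alignment** — perspective projection from a camera position and
  focal centre, stage-1 fit to 2D electrode references (mean reprojection
  distance, simplex with seeded multi-starts) and stage-2 refinement on the
  mean absolute activation-time difference;
- **ECGI** — method of fundamental solutions (deflated-heart ∪
  inflated-tank sources), Tikhonov regularization via the SVD, CRESO
  selection of λ per time sample;
- **markers** — activation from min dV/dt (electrograms) / max dF/dt
  (optical), repolarization from max dV/dt of the T-wave / min dF/dt, and a
  global activation field fitted to inter-electrogram delays for ECGI
  signals;
- **comparison** — nearest-pixel pairing, Pearson CC and RMSE, gradient
  profiles across the perfusion-bed border, paired t-tests, mean ± SD.

The forward model (factors 0.7/1.3, dense analytic collocation) is
deliberately configured differently from the inverse (0.8/1.2, electrode
collocation) so inverse tests never commit an inverse crime; an analytic
concentric-spheres solution serves as an independent oracle for both.

## CLI

One YAML config drives the whole study analogue. A packaged two-sequence
example lives in `configs/mini.yaml` (one plain paced sequence, one with a
slow-conducting, long-APD perfusion bed facing the camera):

```bash
ecgitank run-all --config configs/mini.yaml --out runs/demo --seed 1
```

Stages can also run individually (each consumes the previous stage's
artifacts from the run directory): `simulate`, `preprocess`, `align`,
`reconstruct`, `markers`, `compare`. Every command takes `--config`,
`--out`, optional `--seed` (overrides the config seed) and `--log-level`.

A run directory contains `geometry/` (PLY meshes, electrode CSVs, true
camera YAML), one `seq_XXX/` per sequence (HDF5 signal blocks, CSV
time maps, the data mask, λ trace, RT gradient profile) and `summary.csv`
with per-sequence CC/RMSE for the four comparisons
(sock-vs-optical and ECGI-vs-optical, AT and RT).

Config keys (see `configs/mini.yaml` for a complete example):
`geometry` (ellipsoid semi-axes, mesh edge targets, electrode counts),
`camera` (true camera pose, initial-guess perturbation, reference jitter),
`signals` (rates, noise levels, blur, sync offset), `scenario_defaults` +
`sequences` (pacing site, perfusion region, CV factor, APD delta), `mfs`
(source factors), `markers` (RT window, global-activation-field settings),
`metrics` (pairing cutoff). All randomness derives from the single `seed`.

## Layout

```
src/ecgitank/
  geometry.py   meshes, electrodes, farthest-point sampling, PLY/VTK I/O
  electro.py    activation, action potentials, electrograms, forward models,
                optical rendering, HDF5/CSV containers
  sigproc.py    filtering, data mask, beat averaging, sync, channel QC
  camera.py     pinhole model, projection, rasterization, 2-stage alignment
  ecgi.py       MFS system, Tikhonov/SVD, CRESO, reconstruction
  markers.py    AT/RT detection, global activation field
  metrics.py    pairing, CC/RMSE, gradient profiles, statistics
  pipeline.py   YAML-driven orchestration (stage functions)
  cli.py        click entry points
```
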