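# flatpaint

Quantitative analysis of DNA-PAINT super-resolution experiments under
Gaussian versus flat-top TIRF illumination, paired with a physics-based
simulator so that every stage of the pipeline can be validated by parameter
recovery — no experimental data required.

## The problem

In DNA-PAINT, dye-labeled "imager" oligonucleotides transiently hybridize to
"docking" strands on the target, producing the blinking that single-molecule
localization microscopy needs.  Several key observables depend directly on
the local excitation intensity `I`:

* **Spot detection.** Candidate spots are scored by the *net gradient* — the
  sum of image gradients pointing toward a pixel within a box.  A fixed
  global threshold under a Gaussian beam profile silently discards binding
  events at the field periphery, where the score drops with `I`.
* **Bright times.** A bound imager unbinds at rate `k_off` or photobleaches
  at rate `k_b·I`, so the expected bright time is `1/(k_off + k_b·I)`.
  Radially varying `I` broadens the pooled bright-time distribution and
  destroys kinetic species separation (e.g. 8-nt vs 9-nt docking strands).
* **Photons and precision.** The localization error scales as
  `sigma_loc ∝ psf_sigma / sqrt(N)` with `N ∝ I`, so precision degrades
  radially under Gaussian excitation.
* **Multi-emitter artifacts.** Two imagers bound simultaneously within a
  diffraction-limited region are fitted as one spurious localization with
  roughly the summed photons.  Under uniform excitation the photon histogram
  shows a clean second peak at twice the single-emitter peak, and a cut at
  the upper 1/e² abscissa of the first peak (`mu_1 + 2 sigma_1`) removes the
  doubles.

The package implements the full pipeline — parametric illumination fields,
equal-count concentric-ring segmentation (~800 structures per ring),
net-gradient detection plus Poisson-MLE Gaussian fitting, event linking and
temporal pick QC, photon-mixture filtering, NeNA precision estimation
(`p(d) = d/(2σ²)·exp(−d²/(4σ²))` for consecutive-frame nearest-neighbor
distances), and model-driven particle averaging (oversampling 40, 180°
symmetry) — together with a generator for origami grids (3×4 sites, 20 or
10 nm pitch) and microtubule-like rod phantoms under either profile.

## Worked example

```python
from flatpaint import RunConfig, run_scenario

cfg = RunConfig(seed=5, n_pixels=256, n_structures=80, n_frames=4000,
                profile_kind="flattop")
report = run_scenario(cfg)
print(round(report["averaging"]["spacing_nm"], 2),
      round(report["nena_nm"], 2),
      round(report["qc_pass_fraction"], 3))
```

prints

```
20.0 1.5 1.0
```

i.e. the double-Gaussian fit across the averaged origami grids recovers the
designed 20 nm docking-strand pitch, the NeNA estimate of the localization
precision is 1.5 nm (set here by ~15,000 photons per localization), and
every simulated pick passes the temporal QC filter.
The same scenario driven from the shell:

```bash
flatpaint simulate config.yaml --out locs.hdf5
flatpaint kinetics locs.hdf5 --out kinetics.csv --n-frames 4000
flatpaint filter locs.hdf5 --out filtered.hdf5
flatpaint average locs.hdf5 --out average.tif --report spacing.json
```

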