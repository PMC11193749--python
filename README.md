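# polfx

Analysis pipeline for correlative optical-tweezers / confocal-fluorescence
experiments on DNA polymerase exchange at the ssDNA/dsDNA junction.

From a synchronized force / end-to-end-distance trace and a line-scan
photon-count kymograph, the package:

- reconstructs the ssDNA fraction, junction position and base-pair count
  from DNA elasticity models (extensible FJC for ssDNA, extensible
  high-force WLC for dsDNA) — `polfx.polymer_models`;
- registers the kymograph against the reconstructed junction line
  (5-pixel box, exhaustive ±5 px offset search) and extracts the junction
  intensity — `polfx.kymo_registration`;
- smooths, noise-estimates (scaled MAD of differences), step-fits
  (penalized greedy change-point splitting) and binarizes traces —
  `polfx.step_detection`;
- extracts fluorescent burst segments, classifies exo/pol/pause activity
  with force-regime cutoffs, detects pauses, and computes the
  eight-configuration (pre→during→post) memory-effect statistic —
  `polfx.burst_analysis`;
- builds the binarized activity×fluorescence correlation classes, counts
  event clusters and derived fractions — `polfx.correlation_analysis`;
- fits bound lifetimes with photobleaching correction (competing
  exponentials) and diffusion constants from MSD of tracked particles —
  `polfx.kinetics`;
- ships a ground-truthed stochastic simulator of the whole experiment
  (binding kinetics, forward elasticity mixture, Poisson/PSF kymograph
  rendering) for validation — `polfx.exchange_simulator`.

## CLI

```sh
# generate a ground-truthed synthetic dataset
polfx simulate -c sim_config.json -o data/

# run the full pipeline (reconstruct → register → binarize → segment →
# correlate → kinetics); writes report.json + CSV tables
polfx analyze -d data/ -c analysis_config.json -o out/

# render summary text and figure panels
polfx report -r out/report.json -o figures/
```

Configs are JSON; every field of `SimulationConfig` / `AnalysisConfig` is
validated and unknown keys are rejected. Interchange formats: force trace
as CSV (`time_s,force_pN,eed_um`) or HDF5 (`/force_trace`), kymograph as
HDF5 (`/photons` with `line_time_s`, `pixel_size_um` attrs) plus 16-bit
TIFF export, simulation truth as JSON.

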