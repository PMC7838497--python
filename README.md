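# synaptoscope

Analysis of drug effects on spontaneous glutamate release and neuronal
population activity, for slice electrophysiologists and calcium imagers:

* **sEPSC arm** — detect spontaneous excitatory postsynaptic currents in
  voltage-clamp traces (−70 mV holding, inward events), build 10-s-bin
  frequency/amplitude histograms, normalize to the control baseline, read
  the drug effect off a 5-min maximal-effect window, find 50–150 ms bursts
  of synchronized release, and classify cells as responsive.
* **Calcium arm** — turn fluorescence movies (or per-ROI traces) into
  ΔF/F transients, a binary cells × frames onset raster, a coactivity
  histogram, and Monte Carlo–validated synchrony peaks, with per-cell
  activity compared across control/drug/wash conditions.
* **Synthetic recordings** — a first-class generator produces 5 kHz
  current traces and 4 frames/s fluorescence data (or rendered TIFF
  movies) with exported ground truth, so every stage is verifiable without
  proprietary raw data.

## The quantities at the core

ΔF/F is `(F_t − F0)/F0` with `F0` the resting fluorescence (10th
percentile). A transient is accepted when its amplitude exceeds
**2.5 × SD** of the trace noise; its onset frame sets a 1 in the binary
raster. Coactivity at frame *t* is `C(t) = Σ_i raster[i, t]`. Significance
of synchrony peaks comes from **1,000 surrogates**, each circularly
shifting every cell's row by an independent uniform offset; the threshold
is the smallest count *c* with
`#{surrogates whose max coactivity ≥ c} < α·N` (α = 0.05).

For currents, events are threshold crossings at `k × SD` of the baseline
noise (k = 3, robust MAD estimate), the drug effect is
`100 · mean(window)/mean(control) − 100` percent, and a burst is ≥ 3
events spanning 50–150 ms with within-burst frequency `(n−1)/span` above
1.5× baseline. Epoch comparisons use Mann–Whitney U (exact by enumeration
at small n), two-sample Kolmogorov–Smirnov, and Friedman tests.

## Worked example

```python
from synaptoscope import three_stage_protocol
from synaptoscope.synth import EpscSimParams, CalciumSimParams
from synaptoscope.workbench import (
    ExperimentConfig, run_epsc_pipeline, run_calcium_pipeline,
)

# 10 min control, 10 min drug (rate x2.72, amplitude x2.40), 10 min wash
protocol = three_stage_protocol(600, 600, 600,
                                drug_rate_ratio=2.72, drug_amp_ratio=2.40)
config = ExperimentConfig(
    protocol=protocol,
    epsc_sim=EpscSimParams(base_rate=3.5, seed=1), n_epsc_cells=5,
    calcium_sim=CalciumSimParams(n_cells=24, ensemble_rate=0.01, seed=1),
    seed=1,
)

r = run_epsc_pipeline(config).results
print(f"responsive cells:     {r['n_responsive']}/{r['n_cells']}")
print(f"baseline (cell 0):    {r['cells'][0]['baseline_freq_hz']:.2f} Hz")
print(f"frequency change:     +{r['group_frequency']['percent_change']:.0f}%")
print(f"amplitude change:     +{r['group_amplitude']['percent_change']:.0f}%")

r = run_calcium_pipeline(config).results
print(f"coactivity threshold: {r['coactivity_threshold']} cells")
print(f"synchrony peaks:      {len(r['significant_frames'])} significant frames")
```

prints

```
responsive cells:     5/5
baseline (cell 0):    3.50 Hz
frequency change:     +173%
amplitude change:     +137%
coactivity threshold: 6 cells
synchrony peaks:      31 significant frames
```

All five simulated cells show a significant frequency change within 10 min
of drug onset; the group estimate recovers the programmed +172%/+140%
effects from the detected events alone; and the population raster shows
synchrony peaks (frames where ≥ 6 of 24 cells start transients together)
that clear the surrogate threshold.

The same analyses are available from the shell:

```bash
synaptoscope run --config exp.yaml --out results/
synaptoscope synth epsc --config exp.yaml --seed 7 --out trace.h5
synaptoscope epsc detect --trace trace.h5 --out events.csv
synaptoscope caimg coactivity --raster raster.csv --out coactivity.json
```

`run` writes `epsc_report.json` / `calcium_report.json` (every number
traceable to a stage with recorded parameters and seeds) plus raster,
coactivity and time-frequency figures.

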