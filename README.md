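# organoflow

Simulation and quantification tools for morphogen delivery to a single
organoid in a perfused imaging chamber.

Guiding regional identity inside one organoid — rather than fusing
separately grown organoids — requires delivering a signalling molecule
(here SAG, a Sonic hedgehog agonist, traced by a fluorescent dye) to one
side of the tissue and then measuring both the gradient and its
biological readout. `organoflow` implements that computational chain for
a microfluidic chamber: a 5 mm deep, 5.6 mm wide liquid-filled well
holding a 1.8 mm organoid, perfused at 5×10⁻³ m/s with 50 nM tracer
pulses every 300 s. It is aimed at researchers modelling or analysing
organoid-on-chip gradient experiments.

Components:

* **chamber_flow / transport** — steady Stokes (creeping) flow on a
  staggered grid (Re ≈ ρuL/μ ≈ 4, so inertia is negligible), plus a
  conservative upwind finite-volume solver for pulsatile
  advection–diffusion, ∂c/∂t + ∇·(uc) = ∇·(D∇c), with diffusion-only
  penetration of the organoid (D_organoid = 6.5×10⁻¹⁴ m²/s) and a
  monotone scheme that guarantees the maximum principle (0 ≤ c ≤ 50 nM).
  Concentration time series are extracted over six readout regions
  (Top / Bottom / Left / Right / Middle / Center).
* **fluorescence_quant** — affine calibration I = m·c + b fitted by
  least squares (R² reported), per-pixel inversion with clamping, ROI
  time series and pairwise gradient offsets with stability estimates.
* **regionalization** — two-level segmentation of organoid
  cross-sections into the outer domain A1 and ventral-marker domain A2,
  the ventral fraction 100·A2/A1, nuclear spot detection at 4.5 μm
  diameter, marker/nucleus colocalization within 14 μm, and a
  domain-exclusivity index.
* **synthetic_data** — seeded generators (rendered stacks, calibration
  aliquots, two-domain phantoms, nuclei images) with ground truth, so
  the whole chain is testable without microscope data.
* **pipeline / CLI** — `organoflow run` orchestrates
  simulate → render → calibrate → quantify → regionalize from a YAML
  config, writing CSV/TIFF/JSON outputs and a run manifest;
  reruns with the same seed are byte-identical.

## Worked example

```python
from organoflow import (run_chamber_simulation, extract_roi_timeseries,
                        ventral_fraction, segment_domains,
                        make_two_domain_image, PhantomSpec)

run = run_chamber_simulation(resolution=56)   # default device, t_end = 4000 s
series = extract_roi_timeseries(run.history, run.rois)
print("peak / late-run mean concentration (nM):")
for name in ("Top", "Right", "Middle", "Left", "Bottom", "Center"):
    print(f"  {name:7s} peak={series.peak(name):6.2f}   "
          f"mean(3000-4000 s)={series.late_mean(name, 3000):6.2f}")

phantom = make_two_domain_image(PhantomSpec(seed=0), pixel_size=1.0)
masks = segment_domains(phantom["images"]["ventral"], pixel_size=1.0)
print(f"segmented A1={masks.a1:.1f} um^2, A2={masks.a2:.1f} um^2, "
      f"ventral fraction={ventral_fraction(masks.a2, masks.a1):.2f}%")
```

prints

```
peak / late-run mean concentration (nM):
  Top     peak= 49.99   mean(3000-4000 s)= 49.98
  Right   peak= 49.99   mean(3000-4000 s)= 49.93
  Middle  peak= 49.85   mean(3000-4000 s)= 49.22
  Left    peak= 49.20   mean(3000-4000 s)= 48.25
  Bottom  peak= 43.45   mean(3000-4000 s)= 40.30
  Center  peak=  0.00   mean(3000-4000 s)=  0.00
segmented A1=123250.0 um^2, A2=58828.0 um^2, ventral fraction=47.73%
```

Reading the numbers: the tracer loads stepwise with each injection and
never exceeds the 50 nM pulse concentration. The exposed surfaces (Top,
and the outlet-facing Right) equilibrate within a few pulses; the
sheltered lower/upstream surfaces (Left, Bottom) lag by thousands of
seconds — the asymmetric exposure that drives one-sided ventralization —
and the mid-chamber fluid sits between the two groups. Center is the
organoid interior, which the tracer penetrates only ~30 μm by diffusion
over the run. The phantom segmentation recovers a ventral domain of
47.7% of the organoid cross-section, within rasterization error of the
generated 47.49% ground truth.

The same pipeline from a shell:

```sh
organoflow run --seed 1 --out-dir out/        # full chain, default device
organoflow synth phantom --fraction 0.4749 --out-dir out/
organoflow simulate --resolution 56 --t-end 1200 --out-dir out/
```

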