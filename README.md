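# fiberprobe

Geometric modelling of illumination and collection efficiency for
fiber-optic probes in biomedical spectroscopy (fluorescence, Raman,
diffuse-reflectance), as a function of probe–sample distance.

Fiber probes deliver excitation light to tissue and collect the returning
signal. Whether the probe should touch the sample is a real design
question: a **single bare fiber** collects best in contact and loses
signal rapidly with stand-off, while a **multi-fiber probe** (separate
illumination and collection fibers) collects *nothing* in contact —
its illumination and collection spots do not overlap until the probe is
lifted — so it has an **optimal probe–sample distance**. This package
evaluates that geometry in closed form, finds the optimal distance,
validates every closed form against seeded Monte-Carlo geometric oracles,
and analyses (or synthesizes) fluorescence distance-series measurements.
It is intended for instrument builders designing fiber probes and for
anyone analysing distance-dependent spectra.

## Model

For a fiber of core radius *r*, numerical aperture NA in a medium of index
*n₀*, the acceptance half-angle is θ = arcsin(NA/n₀). At probe–sample
distance *d* and tilt β the model composes:

- effective distance
  d′ = d + (r + d·tanθ)·sinβ·tanβ·tanθ / (cos²β − sin²β·tan²θ),
  with d′ = d at normal incidence;
- illuminated-spot radius R = r + d′·tanθ and surface intensity ratio
  I₀/I_out = r²·cosβ/(r + d·tanθ)²;
- on-axis solid-angle fraction Ω = 1 − d′/√(d′² + r²) for light re-entering
  the core;
- for a multi-fiber probe with inter-fiber spacing r_c, the fraction of the
  illumination spot overlapped by the collection spot, zero until
  d = r_c/tanθ (the overlap onset).

Single-fiber efficiency ∝ (R/r)²·Ω; multi-fiber efficiency multiplies in
the overlap fraction. Two model **dialects** are first-class:
`as_printed` evaluates the published closed forms literally (including an
overlap coefficient that must be clamped to [0, 1]); `energy_conserving`
uses the exact equal-circle lens-area overlap and cancels the spreading
factor. All efficiencies are relative — unknown tissue/instrument
constants enter only as overall scale.

## Worked example

```python
from fiberprobe import FiberSpec, ProbeConfig, enhancement_ratio

fiber = FiberSpec(core_size=1000, numerical_aperture=0.22)
probe = ProbeConfig(mode="multi", fiber_spacing=10.0)
report = enhancement_ratio(probe, fiber, reference_distance=0.0)
print(report.optimal_distance, report.onset_distance, report.onset_ratio)
```

prints

```
670.9172784679627 45.34090326638981 16.538976382334397
```

meaning: for a 1000 μm multi-fiber probe (r_c = 10 μm, NA = 0.22) the
collection efficiency peaks at a stand-off of ≈ 671 μm; contact collects
nothing (the spots overlap only beyond ≈ 44 μm), and the optimum collects
≈ 16.5× more than a measurement just past the overlap onset. The
`examples/` scripts walk through the single-fiber falloff, the multi-fiber
optimum and a synthetic fluorescence distance series, each printing and
explaining its numbers.

The same is available from a shell:

```bash
fiberprobe optimize --mode multi --core-size 1000 --d-max 2000
fiberprobe figures --outdir figures      # the four efficiency-curve tables
fiberprobe oracle --kind solid-angle --core-size 50 --distance 100
```

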