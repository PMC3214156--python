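"""Simulate a fluorescence distance-series measurement and recover the
optimal probe distance from the data alone.

Generates skin-like emission spectra (broad 475-700 nm band under 450 nm
excitation) at a grid of probe distances with 5% multiplicative noise,
integrates the band per distance, and locates the maximum by parabolic
refinement -- then compares against the geometry model's own optimum.
"""

from fiberprobe import FiberSpec, ProbeConfig, generate_distance_series

fiber = FiberSpec(core_size=1000.0, numerical_aperture=0.22)
probe = ProbeConfig(mode="multi", fiber_spacing=10.0)

series = generate_distance_series(
    d_grid=range(100, 2001, 100), probe=probe, fiber=fiber, noise_sd=0.05, seed=7
)

print("distance_um  total_fluorescence")
for d, t in zip(series.distances, series.totals):
    print(f"{d:11.0f}  {t:18.1f}")

print(f"\nrecovered optimum: {series.optimum_distance:.0f} um "
      f"({series.optimum_method}, boundary={series.on_boundary})")
print(f"model optimum:     {series.model_optimum:.0f} um")
print(
    "\nThe recovered optimum is the parabolic-interpolated peak of the "
    "integrated 475-700 nm band; at 5% noise it lands close to the "
    "generating model's optimal probe distance."
)
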