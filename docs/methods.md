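# Methods

## The coupling model

The package models light coupling between a flat sample surface and a
fiber tip held above it, ignoring what happens *inside* the sample: photon
transport in tissue (scattering, absorption, re-emission depth profiles)
is explicitly out of scope, and all tissue physics is collapsed into two
relative constants — the fraction of incident light that escapes the
surface diffusely (R_diffuse) and the escaping/output intensity ratio.
Every reported efficiency is therefore *relative*: meaningful as a ratio
between configurations (distances, tilts, core sizes), never as an
absolute photon count.

Geometry, for a core radius r, acceptance half-angle θ = arcsin(NA/n₀),
distance d and tilt β:

1. **Effective distance.**
   d′ = d + (r + d·tanθ)·sinβ·tanβ·tanθ / (cos²β − sin²β·tan²θ).
   The grouping of this expression is fixed by requiring d′ = d at β = 0;
   as typeset elsewhere it is ambiguous. The construction is valid for
   β < 90° − θ, where the denominator is positive; beyond that the package
   raises a domain error rather than returning a sign-flipped distance.
2. **Spot spread.** The output power is spread over a spot of radius
   R = r + d′·tanθ, giving a surface intensity ratio
   I₀/I_out = r²·cosβ/(r + d·tanθ)².
3. **Collection solid angle.** From a surface point on the fiber axis the
   core subtends the hemisphere fraction Ω = 1 − d′/√(d′² + r²). This is a
   first-order (on-axis) approximation: off-axis points of the spot see a
   smaller disk solid angle, which the model — and therefore the oracle —
   does not resolve.
4. **Spot overlap (multi-fiber).** With inter-fiber spacing r_c the
   collection spot begins to intersect the illumination spot only beyond
   the onset distance r_c/tanθ; below it the multi-fiber efficiency is
   exactly zero.

## The two dialects

The efficiency closed forms are shipped in two deliberately distinct
dialects, selected per `ProbeConfig` and never conflated in outputs:

- **`as_printed`** (default). Single-fiber efficiency
  (R/r)²·Ω·(escape ratio), multi-fiber additionally ÷cosβ and ×overlap,
  with the overlap coefficient written with a leading 4:
  [4R²·arccos(c/R) − 2c·√(R²−c²)]/(πR²), c = r + r_c. Taken literally this
  coefficient tends to **2** at full overlap, so the value is clamped to
  [0, 1]; the unclamped value is accessible (`clamp=False`) and regression-
  tested. This dialect reproduces the published distance-falloff
  checkpoints (≈22% of contact at d = 100 μm for size 50 μm; ≈18% at
  d = 1200 μm for size 500 μm; both quoted as "20%") and the ≈700 μm
  optimum of the 1000 μm multi-fiber curve.
- **`energy_conserving`**. The surface-intensity ratio is substituted so
  the spread factor cancels (efficiency ∝ cosβ·Ω·R_diffuse) and the overlap
  uses the exact lens-area fraction for equal circles of radius R with
  centres 2c apart: [2R²·arccos(c/R) − 2c·√(R²−c²)]/(πR²), which lies in
  [0, 1] with no clamp. The Monte-Carlo disk oracle confirms this (and
  quantifies the as_printed inflation, which is everywhere ≥ the corrected
  value in the overlap regime).

Whether the leading 4 and the centre separation c = r + r_c (rather than
2r + r_c) are intended is undecidable from the source text; exposing both
dialects is the package's resolution. Likewise `size_convention`: the
published curve labels ("core-diameter of 50 … 500 μm") only reproduce
when fed directly as the r parameter, so `as_radius` (pass-through) is the
default and `as_diameter` (r = size/2) is offered for physically labelled
hardware. The published "≈20 μm optimum for a 100 μm fiber" is not
reproduced by any dialect/convention combination (the model gives
≈116 μm as_radius, ≈70 μm as_diameter) and is left as a documented
discrepancy rather than forced.

## Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| numerical_aperture | 0.22 (CLI) | – | the common silica fiber; θ = 12.7° |
| medium_index | 1.0 | – | air gap between probe and sample |
| fiber_spacing r_c | 10 | μm | cladding-gap scale used in the published curves |
| tilt β | 0 | deg | domain [0, 90° − θ) |
| dialect | as_printed | – | reproduction mode |
| scan ceiling d_max | 5 × core_size | μm | covers all modelled regimes |
| band | 475–700 | nm | strong skin emission under 450 nm excitation |
| long-pass cutoff | 470 | nm | excitation-blocking edge filter |

## Optimiser

The multi-fiber profile is zero up to the onset, unimodal past it, and
very flat around its peak (for the 1000 μm case the efficiency varies by
<1% over roughly 600–800 μm). The optimiser therefore evaluates a
deterministic coarse grid of 2000 intervals over [0, d_max] to bracket the
first maximum, then refines with a bounded scalar search
(`scipy.optimize.minimize_scalar(method="bounded")`, xatol = 10⁻⁶·d_max);
ties resolve to the smallest distance for reproducibility on plateaus.
Any maximiser within the flat peak region is treated as equivalent — the
1-μm-grid argmax for the 1000 μm case is 671 μm, within the plateau that
contains the published 700 μm. Single-fiber profiles are monotone
non-increasing, so contact (d = 0) is returned without searching. An
all-zero profile (no overlap within d_max) raises an error instead of
returning a meaningless argmax. The enhancement ratio against a contact
reference is reported as explicitly *unbounded* for multi-fiber probes
(contact efficiency is exactly zero under this model); a finite secondary
ratio is quoted against the first coarse-grid point past the onset.

## Monte-Carlo oracles

Two seeded estimators (`numpy.random.default_rng`, reproducible
bit-for-bit per (n, seed), default n = 10⁵) validate the closed forms by
direct geometric sampling rather than by re-deriving them:

- hemisphere rays, uniform in solid angle (cos φ ~ U(0,1); the model has
  no angular emission structure, so Lambertian weighting is deliberately
  not applied), intersected with the core disk → Ω;
- points uniform over the illumination disk, tested against the displaced
  collection disk → the lens-area overlap fraction.

Standard errors are binomial; agreement is asserted within 3 standard
errors across randomized parameter draws.

## Synthetic spectra

The generator emulates only what the distance-series analysis needs: a
broad skin-autofluorescence-like band (two fixed Gaussians at 510/35 and
600/55 nm, relative amplitudes 1.0/0.55, sampled at 1 nm over
450–750 nm — a keratin/collagen/elastin-like envelope chosen once as a
plausible stand-in, since the real spectral shape is not tabulated
anywhere usable), scaled by the configured efficiency model at each
distance, with multiplicative Gaussian noise (default relative SD 0, study
value 5%) and clipping at zero counts. Independent per-distance noise
streams are spawned from a single seed. What passing tests show is that
the *pipeline* (generate → band-integrate → locate optimum) closes the
loop on the geometry model; they say nothing about real tissue, where
multiple scattering shifts the experimental optimum (reported at 2 mm for
a 400 μm six-around-one probe) well above the geometric prediction. That
gap is a documented property of the model's scope — photon transport is
the stated future extension — not a target this package asserts. The
six-fiber collection ring is modelled as a single illumination–collection
pair; a fiber-count multiplier would scale only absolute, never
normalized, output.

Numerical choices: band integration is trapezoidal with linear
interpolation at the band edges; the series optimum takes the grid
maximum and, when interior, refines it by parabolic interpolation through
the three bracketing points (vertex clamped to the bracket; a flat triple
falls back to the grid point); a boundary maximum is returned with a
monotone-series warning flag instead of being extrapolated.

## Problem sizes

Default study sizes: optimiser coarse grid 2000 intervals; Monte-Carlo
oracles 10⁵ samples, 20 randomized draws; distance-series recovery 20
distances × 50 noise seeds at 5% noise. These sizes make every headline
quantity reproducible in seconds on one core while keeping Monte-Carlo
standard errors well below the tolerances being asserted.

## Known limitations

- No photon transport in tissue, no prediction of R_diffuse, no
  specular-path modelling (R_sp enters bookkeeping only), no
  core/cladding loss split (absorbed into the first-order Ω).
- Ω is the on-axis approximation for every point of the spot.
- The overlap geometry uses the published centre separation reading
  c = r + r_c; physically labelled probes may require `as_diameter` plus a
  reinterpretation of r_c.
- Spectra tooling assumes ideal instruments: no dark counts, wavelength
  calibration, or detector nonlinearity.
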