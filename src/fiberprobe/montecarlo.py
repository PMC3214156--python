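"""Seeded Monte-Carlo geometric oracles.

These estimators validate the two closed forms that carry the whole
distance dependence of the model — the on-axis disk solid-angle fraction
and the equal-circle overlap (lens-area) fraction — by direct geometric
sampling.  They ship in the package, not only in the test suite, so any
probe configuration can be audited from the command line.

Sampling is uniform in solid angle over the escape hemisphere (the model
assumes no angular emission structure) and uniform in area over the
illumination disk.  Both estimators are reproducible bit-for-bit for a
given (n, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OracleEstimate", "mc_solid_angle_fraction", "mc_overlap_fraction"]

DEFAULT_N = 100_000


@dataclass(frozen=True)
class OracleEstimate:
    """A binomial Monte-Carlo estimate with its standard error."""

    estimate: float
    standard_error: float
    n_samples: int
    seed: int

    def z_score(self, reference: float) -> float:
        """Standardised deviation from ``reference`` (inf if SE is zero
        and the values differ)."""
        diff = self.estimate - reference
        if self.standard_error == 0:
            return 0.0 if diff == 0 else float("inf")
        return diff / self.standard_error


def _binomial(hits: int, n: int, seed: int) -> OracleEstimate:
    p = hits / n
    se = float(np.sqrt(p * (1.0 - p) / n))
    return OracleEstimate(estimate=p, standard_error=se, n_samples=n, seed=seed)


def mc_solid_angle_fraction(
    d: float, r: float, n: int = DEFAULT_N, seed: int = 0
) -> OracleEstimate:
    """Estimate the solid-angle fraction of a disk seen from an on-axis point.

    Rays leave the surface point uniformly in solid angle over the upward
    hemisphere; a ray of polar angle phi hits the core disk (radius ``r``
    at height ``d``) iff d tan(phi) <= r.  By axial symmetry the azimuth
    is irrelevant to the hit test.  The expectation is exactly
    1 - d / sqrt(d^2 + r^2).
    """
    if d < 0 or r <= 0:
        raise ValueError("need d >= 0 and r > 0")
    if n < 1000:
        raise ValueError("n must be >= 1000 for a meaningful standard error")
    rng = np.random.default_rng(seed)
    cos_phi = rng.random(n)  # uniform in solid angle <=> cos(phi) ~ U(0,1)
    sin_phi = np.sqrt(1.0 - cos_phi**2)
    hits = int(np.count_nonzero(d * sin_phi <= r * cos_phi))
    return _binomial(hits, n, seed)


def mc_overlap_fraction(
    R: float, c: float, n: int = DEFAULT_N, seed: int = 0
) -> OracleEstimate:
    """Estimate the overlap fraction of two equal disks of radius ``R``
    whose centres are ``2c`` apart.

    Points are drawn uniformly over the first disk; the estimate is the
    fraction falling inside the second.  The expectation is the lens-area
    fraction (2/pi)(arccos(c/R) - (c/R) sqrt(1 - (c/R)^2)) for c < R and 0
    otherwise — the energy-conserving overlap dialect.
    """
    if R <= 0 or c < 0:
        raise ValueError("need R > 0 and c >= 0")
    if n < 1000:
        raise ValueError("n must be >= 1000 for a meaningful standard error")
    rng = np.random.default_rng(seed)
    rad = R * np.sqrt(rng.random(n))
    ang = 2.0 * np.pi * rng.random(n)
    x = rad * np.cos(ang)
    y = rad * np.sin(ang)
    hits = int(np.count_nonzero((x - 2.0 * c) ** 2 + y**2 <= R**2))
    return _binomial(hits, n, seed)
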