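"""Closed-form probe-sample coupling geometry.

The model treats the fiber tip as a disk of core radius r held a distance d
above a flat sample, with acceptance half-angle theta = arcsin(NA / n0).
Light leaving the fiber spreads into a spot of radius r + d' tan(theta)
(d' is the tilt-corrected effective distance); light escaping the sample
surface re-enters the core within the on-axis solid-angle fraction
Omega = 1 - d' / sqrt(d'^2 + r^2).  For a two-fiber probe the collected
signal is further gated by the fraction of the illumination spot overlapped
by the collection fiber's acceptance spot.

Two dialects of the efficiency model are exposed (see
:class:`~fiberprobe.params.Dialect`); all efficiencies are relative, with
the unknown tissue/instrument constants folded into an overall scale.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .errors import TiltDomainError, UndefinedFractionError
from .params import (
    Dialect,
    EfficiencyResult,
    FiberSpec,
    Mode,
    ProbeConfig,
    SizeConvention,
    TissueOptics,
)

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "acceptance_angle",
    "effective_distance",
    "spot_radius",
    "surface_intensity_ratio",
    "solid_angle_fraction",
    "overlap_fraction",
    "overlap_onset_distance",
    "single_fiber_efficiency",
    "multi_fiber_efficiency",
    "evaluate_efficiency",
    "efficiency_values",
    "collection_fraction",
]


def acceptance_angle(fiber: FiberSpec) -> float:
    """Acceptance half-angle arcsin(NA / n0), in degrees.

    For the common NA = 0.22 fiber in air this is 12.7 degrees.
    """
    return fiber.acceptance_angle_deg


def _resolved_radius(fiber: FiberSpec, convention: SizeConvention) -> float:
    if convention is SizeConvention.AS_DIAMETER:
        return fiber.core_size / 2.0
    return fiber.core_size


def _check_tilt(tilt_deg: float, theta_rad: float) -> float:
    """Validate beta against the geometric domain and return it in radians."""
    limit = 90.0 - math.degrees(theta_rad)
    if not 0 <= tilt_deg < limit:
        raise TiltDomainError(
            f"tilt {tilt_deg} deg outside [0, {limit:.3f}) deg: the effective-"
            "distance denominator cos^2(b) - sin^2(b) tan^2(theta) is not positive"
        )
    return math.radians(tilt_deg)


def _d_eff(d: ArrayLike, r: float, theta_rad: float, beta_rad: float) -> ArrayLike:
    if beta_rad == 0.0:
        return np.asarray(d, dtype=float) if np.ndim(d) else float(d)
    d = np.asarray(d, dtype=float)
    t = math.tan(theta_rad)
    num = (r + d * t) * math.sin(beta_rad) * math.tan(beta_rad) * t
    den = math.cos(beta_rad) ** 2 - math.sin(beta_rad) ** 2 * t**2
    out = d + num / den
    return out if out.ndim else float(out)


def effective_distance(d: ArrayLike, fiber: FiberSpec, tilt: float = 0.0) -> ArrayLike:
    """Tilt-corrected effective probe distance d', in um.

    d' = d + (r + d tan(theta)) sin(b) tan(b) tan(theta)
             / (cos^2(b) - sin^2(b) tan^2(theta))

    reduces to d at normal incidence and grows with tilt; the grouping is
    fixed by the b = 0 limit.  Raises :class:`TiltDomainError` once the
    denominator is no longer positive (tilt >= 90 deg - theta).
    """
    theta = fiber.acceptance_angle_rad
    beta = _check_tilt(tilt, theta)
    return _d_eff(d, fiber.core_size, theta, beta)


def spot_radius(d_eff: ArrayLike, fiber: FiberSpec) -> ArrayLike:
    """Illuminated-spot radius r + d' tan(theta), in um; equals r at contact."""
    r = fiber.core_size
    out = r + np.asarray(d_eff, dtype=float) * math.tan(fiber.acceptance_angle_rad)
    return out if out.ndim else float(out)


def surface_intensity_ratio(d: ArrayLike, fiber: FiberSpec, tilt: float = 0.0) -> ArrayLike:
    """Sample-surface to fiber-output intensity ratio I0/Iout.

    I0/Iout = r^2 cos(beta) / (r + d tan(theta))^2: the fiber output power
    is spread over the (tilted) illumination spot.  Maximal (= 1) at contact
    and normal incidence.
    """
    theta = fiber.acceptance_angle_rad
    beta = _check_tilt(tilt, theta)
    r = fiber.core_size
    spot = r + np.asarray(d, dtype=float) * math.tan(theta)
    out = r**2 * math.cos(beta) / spot**2
    return out if out.ndim else float(out)


def solid_angle_fraction(d_eff: ArrayLike, fiber: FiberSpec) -> ArrayLike:
    """On-axis solid-angle fraction Omega = 1 - d'/sqrt(d'^2 + r^2).

    First-order fraction of the escaping hemisphere, seen from a surface
    point on the fiber axis, that is subtended by the core disk.  Equals 1
    at contact and decreases monotonically to 0 with distance.
    """
    d_eff = np.asarray(d_eff, dtype=float)
    r = fiber.core_size
    out = 1.0 - d_eff / np.sqrt(d_eff**2 + r**2)
    return out if out.ndim else float(out)


def overlap_onset_distance(fiber: FiberSpec, spacing: float) -> float:
    """Smallest distance r_c/tan(theta) at which the spots start to overlap
    (normal incidence)."""
    return spacing / math.tan(fiber.acceptance_angle_rad)


def overlap_fraction(
    d_eff: ArrayLike,
    fiber: FiberSpec,
    spacing: float,
    dialect: Dialect = Dialect.AS_PRINTED,
    clamp: bool = True,
) -> ArrayLike:
    """Fraction of the illumination spot overlapped by the collection spot.

    With R = r + d' tan(theta) and c = r + r_c the published form is

        [4 R^2 arccos(c/R) - 2 c sqrt(R^2 - c^2)] / (pi R^2)

    which tends to 2 (not 1) at full overlap and is therefore clamped to
    [0, 1] in the AS_PRINTED dialect.  The ENERGY_CONSERVING dialect uses
    the exact lens-area fraction for two equal circles of radius R whose
    centres are 2c apart,

        [2 R^2 arccos(c/R) - 2 c sqrt(R^2 - c^2)] / (pi R^2),

    which lies in [0, 1] without clamping.  Both are 0 for R <= c.

    Pass ``clamp=False`` to inspect the raw AS_PRINTED value.
    """
    dialect = Dialect(dialect)
    d_eff = np.asarray(d_eff, dtype=float)
    r = fiber.core_size
    R = r + d_eff * math.tan(fiber.acceptance_angle_rad)
    c = r + spacing
    u = np.clip(c / R, None, 1.0)
    lead = 4.0 if dialect is Dialect.AS_PRINTED else 2.0
    with np.errstate(invalid="ignore"):
        frac = (lead * np.arccos(u) - 2.0 * u * np.sqrt(1.0 - u**2)) / math.pi
    frac = np.where(R <= c, 0.0, frac)
    if clamp:
        frac = np.clip(frac, 0.0, 1.0)
    return frac if frac.ndim else float(frac)


def efficiency_values(
    d: ArrayLike,
    probe: ProbeConfig,
    fiber: FiberSpec,
    tissue: TissueOptics | None = None,
) -> ArrayLike:
    """Vectorised relative collection efficiency over distances ``d`` (um).

    Dispatches on ``probe.mode`` and ``probe.dialect``; ``probe.distance``
    is ignored in favour of ``d``.  Used by the scan/optimisation layer and
    the synthetic spectra generator.
    """
    tissue = tissue or TissueOptics()
    r = _resolved_radius(fiber, probe.size_convention)
    rfib = FiberSpec(r, fiber.numerical_aperture, fiber.medium_index)
    theta = rfib.acceptance_angle_rad
    beta = _check_tilt(probe.tilt, theta)
    d_eff = _d_eff(d, r, theta, beta)
    omega = solid_angle_fraction(d_eff, rfib)
    spot = spot_radius(d_eff, rfib)

    if probe.dialect is Dialect.AS_PRINTED:
        kernel = (spot / r) ** 2 * omega * tissue.escape_ratio
        if probe.mode is Mode.MULTI:
            kernel = kernel / math.cos(beta)
    else:
        kernel = math.cos(beta) * omega * tissue.diffuse_reflectance

    if probe.mode is Mode.MULTI:
        ov = overlap_fraction(d_eff, rfib, probe.fiber_spacing, probe.dialect)
        kernel = kernel * ov
    return kernel


def evaluate_efficiency(
    probe: ProbeConfig,
    fiber: FiberSpec,
    tissue: TissueOptics | None = None,
) -> EfficiencyResult:
    """Evaluate the configured model at ``probe.distance`` with full
    factor decomposition."""
    tissue = tissue or TissueOptics()
    r = _resolved_radius(fiber, probe.size_convention)
    rfib = FiberSpec(r, fiber.numerical_aperture, fiber.medium_index)
    theta = rfib.acceptance_angle_rad
    beta = _check_tilt(probe.tilt, theta)
    d = probe.distance
    d_eff = float(_d_eff(d, r, theta, beta))
    omega = float(solid_angle_fraction(d_eff, rfib))
    spot = float(spot_radius(d_eff, rfib))
    intensity = float(surface_intensity_ratio(d, rfib, probe.tilt))
    if probe.mode is Mode.MULTI:
        ov = float(overlap_fraction(d_eff, rfib, probe.fiber_spacing, probe.dialect))
    else:
        ov = 1.0  # single fiber: collection spot is the illumination spot
    eff = float(efficiency_values(d, probe, fiber, tissue))
    return EfficiencyResult(
        efficiency=eff,
        effective_distance=d_eff,
        spot_radius=spot,
        solid_angle_fraction=omega,
        overlap_fraction=ov,
        intensity_ratio=intensity,
        dialect=probe.dialect,
    )


def single_fiber_efficiency(
    probe: ProbeConfig,
    fiber: FiberSpec,
    tissue: TissueOptics | None = None,
) -> EfficiencyResult:
    """Relative collection efficiency of a single bare fiber.

    AS_PRINTED: (spot/r)^2 * Omega * escape_ratio — the published closed
    form taken literally with the escape/output intensity ratio a constant.
    ENERGY_CONSERVING: cos(beta) * Omega * R_diffuse — the spreading factor
    cancels against the surface-intensity ratio.  Both equal their contact
    value at d = 0 and decrease with d, so contact is always optimal.
    """
    if probe.mode is not Mode.SINGLE:
        raise ValueError("single_fiber_efficiency requires probe.mode == 'single'")
    return evaluate_efficiency(probe, fiber, tissue)


def multi_fiber_efficiency(
    probe: ProbeConfig,
    fiber: FiberSpec,
    tissue: TissueOptics | None = None,
) -> EfficiencyResult:
    """Relative collection efficiency of an illumination/collection pair.

    The single-fiber kernel multiplied by the spot overlap fraction; zero
    below the overlap onset r_c/tan(theta) (normal incidence) and with a
    strictly interior maximum in distance.
    """
    if probe.mode is not Mode.MULTI:
        raise ValueError("multi_fiber_efficiency requires probe.mode == 'multi'")
    return evaluate_efficiency(probe, fiber, tissue)


def collection_fraction(result: EfficiencyResult, tissue: TissueOptics) -> float:
    """Collection fraction f = R_collect / R_diffuse.

    The specular component is excluded by convention (R_sp = 0 for
    multi-fiber probes and for fluorescence/Raman work).
    """
    if tissue.diffuse_reflectance == 0:
        raise UndefinedFractionError(
            "collection fraction undefined for diffuse_reflectance = 0"
        )
    return result.efficiency / tissue.diffuse_reflectance
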