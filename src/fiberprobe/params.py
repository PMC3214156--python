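"""Parameter containers for probe geometry.

All lengths are in micrometres and all angles in degrees at the public
interface; trigonometry is done in radians internally.  Efficiencies are
relative quantities: the unknown instrument constants (escape ratio, total
diffuse reflectance) enter only as overall scale factors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import InvalidFiberError


class Mode(str, enum.Enum):
    """Probe arrangement: one fiber for both roles, or separate fibers."""

    SINGLE = "single"
    MULTI = "multi"


class Dialect(str, enum.Enum):
    """Efficiency-model variant.

    AS_PRINTED evaluates the published closed forms literally, with the
    escape/output intensity ratio held as a distance-independent constant;
    this is the variant that reproduces the published distance-series
    checkpoints.  ENERGY_CONSERVING substitutes the surface-intensity
    spreading factor so that energy is conserved (the spread factor cancels)
    and uses the exact equal-circle lens-area coefficient for the overlap
    fraction.
    """

    AS_PRINTED = "as_printed"
    ENERGY_CONSERVING = "energy_conserving"


class SizeConvention(str, enum.Enum):
    """How ``core_size`` maps onto the core radius r in the formulas.

    AS_RADIUS feeds ``core_size`` straight in as r (the convention under
    which the published curve labels are reproduced); AS_DIAMETER uses
    r = core_size / 2 for physically labelled probes.
    """

    AS_RADIUS = "as_radius"
    AS_DIAMETER = "as_diameter"


@dataclass(frozen=True)
class FiberSpec:
    """One fiber's optical geometry.

    Parameters
    ----------
    core_size : float
        Core size in um; interpreted per :class:`SizeConvention`.
    numerical_aperture : float
        Fiber NA; must satisfy 0 < NA < medium_index so that the acceptance
        angle arcsin(NA / n0) is defined and lies in (0, 90) degrees.
    medium_index : float
        Refractive index n0 of the medium between probe and sample
        (1.0 for air).
    """

    core_size: float
    numerical_aperture: float
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if not self.core_size > 0:
            raise InvalidFiberError(f"core_size must be > 0, got {self.core_size}")
        if not self.numerical_aperture > 0:
            raise InvalidFiberError(
                f"numerical_aperture must be > 0, got {self.numerical_aperture}"
            )
        if self.numerical_aperture >= self.medium_index:
            raise InvalidFiberError(
                "numerical_aperture must be smaller than medium_index "
                f"(got NA={self.numerical_aperture}, n0={self.medium_index}): "
                "no guided acceptance cone exists"
            )

    @property
    def acceptance_angle_rad(self) -> float:
        """Half-angle of the acceptance cone, arcsin(NA / n0), in radians."""
        return math.asin(self.numerical_aperture / self.medium_index)

    @property
    def acceptance_angle_deg(self) -> float:
        return math.degrees(self.acceptance_angle_rad)


@dataclass(frozen=True)
class ProbeConfig:
    """Probe arrangement and model choices.

    ``fiber_spacing`` (r_c) is the gap between the illumination and the
    collection fiber and is only meaningful in multi mode.  The tilt upper
    bound (beta < 90 deg - acceptance angle) depends on the fiber and is
    enforced at evaluation time.
    """

    mode: Mode = Mode.SINGLE
    distance: float = 0.0
    tilt: float = 0.0
    fiber_spacing: float = 10.0
    dialect: Dialect = Dialect.AS_PRINTED
    size_convention: SizeConvention = SizeConvention.AS_RADIUS

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "dialect", Dialect(self.dialect))
        object.__setattr__(self, "size_convention", SizeConvention(self.size_convention))
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0, got {self.distance}")
        if not 0 <= self.tilt < 90:
            raise ValueError(f"tilt must lie in [0, 90) degrees, got {self.tilt}")
        if self.fiber_spacing < 0:
            raise ValueError(f"fiber_spacing must be >= 0, got {self.fiber_spacing}")


@dataclass(frozen=True)
class TissueOptics:
    """Surface bookkeeping constants of the sample.

    specular_reflectance (R_sp) defaults to 0: multi-fiber probes collect no
    specular component, and for fluorescence/Raman it carries no signal.
    diffuse_reflectance (R_diffuse) and escape_ratio (I_esc / I_out) are
    unknown overall constants and default to 1 so that efficiencies are
    relative.
    """

    specular_reflectance: float = 0.0
    diffuse_reflectance: float = 1.0
    escape_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.specular_reflectance <= 1:
            raise ValueError("specular_reflectance must lie in [0, 1]")
        if not 0 <= self.diffuse_reflectance <= 1:
            raise ValueError("diffuse_reflectance must lie in [0, 1]")
        if self.escape_ratio < 0:
            raise ValueError("escape_ratio must be >= 0")


@dataclass(frozen=True)
class EfficiencyResult:
    """A relative collection efficiency and its factor decomposition."""

    efficiency: float
    effective_distance: float
    spot_radius: float
    solid_angle_fraction: float
    overlap_fraction: float
    intensity_ratio: float
    dialect: Dialect = Dialect.AS_PRINTED
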