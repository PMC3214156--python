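"""Fluorescence spectra: I/O, band integration, distance-series analysis and
a synthetic skin-autofluorescence generator.

The distance-series workflow mirrors a bench measurement: acquire one
emission spectrum per probe-sample distance, integrate the fluorescence
band (475-700 nm by default, the strong skin emission under 450 nm
excitation), and locate the distance that maximises the total signal.

The synthetic generator emulates the broad skin band (keratin / collagen /
elastin-like envelope) with a fixed two-Gaussian shape whose amplitude is
driven by the configured probe-efficiency model, so noiseless synthetic
series recover the geometric optimum by construction.  The spectral shape
is a stand-in: only its band support (475-700 nm) and the amplitude-vs-
distance law are meaningful, never absolute counts.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import IO, Iterable, NamedTuple, Union

import numpy as np

from .errors import (
    InsufficientDataError,
    IntegrationError,
    SpectrumParseError,
)
from .geometry import efficiency_values
from .params import FiberSpec, Mode, ProbeConfig, TissueOptics
from .profiles import optimal_distance

__all__ = [
    "Spectrum",
    "DistanceSeries",
    "read_spectrum",
    "write_spectrum",
    "apply_longpass",
    "total_fluorescence",
    "OptimumResult",
    "distance_series_optimum",
    "generate_skin_spectrum",
    "generate_distance_series",
    "DEFAULT_BAND",
    "DEFAULT_LONGPASS_NM",
]

#: Default integration band (nm): the strong skin emission under 450 nm excitation.
DEFAULT_BAND = (475.0, 700.0)
#: Default long-pass cutoff (nm) blocking the excitation line.
DEFAULT_LONGPASS_NM = 470.0

# Synthetic skin envelope: (centre nm, sigma nm, relative amplitude).
_ENVELOPE_BANDS = ((510.0, 35.0, 1.0), (600.0, 55.0, 0.55))
_ENVELOPE_GRID = np.arange(450.0, 751.0, 1.0)
_PEAK_COUNTS = 10_000.0  # arbitrary counts scale at unit efficiency


@dataclass(frozen=True)
class Spectrum:
    """A wavelength/intensity series with acquisition metadata."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    probe_distance: float | None = None
    excitation: float = 450.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.shape != it.shape or wl.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1-D")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)


def read_spectrum(source: Union[str, os.PathLike, IO[str]]) -> Spectrum:
    """Parse a two-column (wavelength nm, intensity) delimited text file.

    Comment lines start with '#'; the header keys ``distance_um`` and
    ``excitation_nm`` (as ``# key: value``) populate the metadata.  Rows
    may be separated by whitespace or commas.  Wavelengths are sorted
    ascending; duplicate wavelengths and non-numeric rows are rejected
    with the offending line number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = getattr(source, "name", "<stream>")
    else:
        name = os.fspath(source)
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    meta: dict[str, float] = {}
    wl: list[float] = []
    it: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                if key in ("distance_um", "excitation_nm"):
                    try:
                        meta[key] = float(val)
                    except ValueError as exc:
                        raise SpectrumParseError(
                            f"{name}:{lineno}: bad value for {key}: {val.strip()!r}"
                        ) from exc
            continue
        fields = line.replace(",", " ").split()
        if len(fields) != 2:
            raise SpectrumParseError(
                f"{name}:{lineno}: expected two columns, got {len(fields)}"
            )
        try:
            wl.append(float(fields[0]))
            it.append(float(fields[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{name}:{lineno}: non-numeric row {line!r}") from exc

    if len(wl) < 2:
        raise SpectrumParseError(f"{name}: fewer than 2 data rows")
    order = np.argsort(wl, kind="stable")
    wl_arr = np.asarray(wl)[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = float(wl_arr[np.nonzero(np.diff(wl_arr) == 0)[0][0]])
        raise SpectrumParseError(f"{name}: duplicate wavelength {dup}")
    return Spectrum(
        wavelengths=wl_arr,
        intensities=np.asarray(it)[order],
        probe_distance=meta.get("distance_um"),
        excitation=meta.get("excitation_nm", 450.0),
    )


def write_spectrum(spectrum: Spectrum, path: Union[str, os.PathLike]) -> None:
    """Write a spectrum as two-column text with metadata header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        if spectrum.probe_distance is not None:
            fh.write(f"# distance_um: {float(spectrum.probe_distance)!r}\n")
        fh.write(f"# excitation_nm: {float(spectrum.excitation)!r}\n")
        for w, i in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{float(w)!r}\t{float(i)!r}\n")


def apply_longpass(spectrum: Spectrum, cutoff: float = DEFAULT_LONGPASS_NM) -> Spectrum:
    """Ideal long-pass edge filter: zero intensity below ``cutoff`` nm."""
    masked = np.where(spectrum.wavelengths < cutoff, 0.0, spectrum.intensities)
    return dataclasses.replace(spectrum, intensities=masked)


def total_fluorescence(
    spectrum: Spectrum,
    band_min: float = DEFAULT_BAND[0],
    band_max: float = DEFAULT_BAND[1],
) -> float:
    """Trapezoidal band integral of intensity over [band_min, band_max], in
    counts*nm, with linear interpolation at the band edges."""
    if band_min >= band_max:
        raise ValueError("band_min must be < band_max")
    wl, it = spectrum.wavelengths, spectrum.intensities
    lo = max(band_min, float(wl[0]))
    hi = min(band_max, float(wl[-1]))
    if lo >= hi:
        raise IntegrationError(
            f"band [{band_min}, {band_max}] nm does not intersect spectrum "
            f"range [{wl[0]}, {wl[-1]}] nm"
        )
    inside = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inside, [hi]))
    vals = np.interp(grid, wl, it)
    return float(np.trapezoid(vals, grid))


class OptimumResult(NamedTuple):
    """Located optimum of a distance series."""

    distance: float
    method: str  # 'grid_max' or 'parabolic'
    on_boundary: bool


def _locate_optimum(distances: np.ndarray, totals: np.ndarray) -> OptimumResult:
    if distances.size < 3:
        raise InsufficientDataError(
            f"need >= 3 distances to locate an optimum, got {distances.size}"
        )
    i = int(np.argmax(totals))
    if i == 0 or i == distances.size - 1:
        return OptimumResult(float(distances[i]), "grid_max", True)
    x0, x1, x2 = distances[i - 1 : i + 2]
    y0, y1, y2 = totals[i - 1 : i + 2]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0:  # flat triple: keep the grid maximum
        return OptimumResult(float(x1), "grid_max", False)
    vertex = x1 - 0.5 * (
        (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    ) / denom
    vertex = float(np.clip(vertex, x0, x2))
    return OptimumResult(vertex, "parabolic", False)


@dataclass(frozen=True)
class DistanceSeries:
    """Ordered (distance, total band fluorescence) pairs with their optimum.

    ``model_optimum`` carries the generating model's true argmax when the
    series is synthetic, for recovery studies; measured series leave it None.
    """

    distances: np.ndarray
    totals: np.ndarray
    optimum_distance: float
    optimum_method: str
    on_boundary: bool
    model_optimum: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        t = np.asarray(self.totals, dtype=float)
        if d.shape != t.shape or d.ndim != 1:
            raise ValueError("distances and totals must be equal-length 1-D")
        if not np.all(np.diff(d) > 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("total fluorescence must be >= 0")
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "totals", t)

    @classmethod
    def from_measurements(
        cls,
        distances: Iterable[float],
        totals: Iterable[float],
        model_optimum: float | None = None,
    ) -> "DistanceSeries":
        d = np.asarray(list(distances), dtype=float)
        t = np.asarray(list(totals), dtype=float)
        opt = _locate_optimum(d, t)
        return cls(d, t, opt.distance, opt.method, opt.on_boundary, model_optimum)


def distance_series_optimum(series: DistanceSeries) -> OptimumResult:
    """Locate the series maximum; interior maxima are refined by parabolic
    interpolation through the peak and its neighbours, boundary maxima are
    returned as-is with ``on_boundary`` set (monotone-series warning)."""
    return _locate_optimum(series.distances, series.totals)


def _envelope() -> np.ndarray:
    env = np.zeros_like(_ENVELOPE_GRID)
    for centre, sigma, amp in _ENVELOPE_BANDS:
        env += amp * np.exp(-0.5 * ((_ENVELOPE_GRID - centre) / sigma) ** 2)
    return env / env.max()


def generate_skin_spectrum(
    distance: float,
    probe: ProbeConfig,
    fiber: FiberSpec,
    noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    tissue: TissueOptics | None = None,
) -> Spectrum:
    """Synthesize a skin-like emission spectrum at one probe distance.

    A fixed two-Gaussian envelope spanning 475-700 nm, sampled at 1 nm, is
    scaled by the configured probe-efficiency model at ``distance`` and
    perturbed by multiplicative Gaussian noise of relative standard
    deviation ``noise_sd`` (clipped at zero counts).  Deterministic per
    seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    eff = float(efficiency_values(float(distance), probe, fiber, tissue))
    counts = _envelope() * _PEAK_COUNTS * eff
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        counts = counts * (1.0 + noise_sd * rng.standard_normal(counts.size))
        counts = np.clip(counts, 0.0, None)
    return Spectrum(
        wavelengths=_ENVELOPE_GRID.copy(),
        intensities=counts,
        probe_distance=float(distance),
        excitation=450.0,
    )


def generate_distance_series(
    d_grid: Iterable[float],
    probe: ProbeConfig,
    fiber: FiberSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    band: tuple[float, float] = DEFAULT_BAND,
    tissue: TissueOptics | None = None,
) -> DistanceSeries:
    """Simulate a full distance-series measurement.

    One synthetic spectrum per distance (independent noise streams spawned
    from ``seed``), band-integrated and assembled into a
    :class:`DistanceSeries`.  The generating model's own optimal distance
    is recorded in ``model_optimum`` for recovery studies (0 for
    single-fiber probes, whose optimum is contact).
    """
    d = np.asarray(list(d_grid), dtype=float)
    if d.size < 3:
        raise InsufficientDataError("need >= 3 distances")
    children = np.random.SeedSequence(seed).spawn(d.size)
    totals = []
    for dist, child in zip(d, children):
        spec = generate_skin_spectrum(dist, probe, fiber, noise_sd, child, tissue)
        totals.append(total_fluorescence(spec, *band))
    if probe.mode is Mode.MULTI:
        model_opt = optimal_distance(probe, fiber, d_max=float(d.max()), tissue=tissue)
    else:
        model_opt = 0.0
    return DistanceSeries.from_measurements(d, totals, model_optimum=model_opt)
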