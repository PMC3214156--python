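"""Closed-form geometry: acceptance cone, effective distance, spot spread,
solid angle, spot overlap and the two efficiency dialects."""

import dataclasses
import math

import numpy as np
import pytest

from fiberprobe import (
    Dialect,
    EfficiencyResult,
    FiberSpec,
    InvalidFiberError,
    ProbeConfig,
    TiltDomainError,
    TissueOptics,
    UndefinedFractionError,
    acceptance_angle,
    collection_fraction,
    effective_distance,
    multi_fiber_efficiency,
    overlap_fraction,
    overlap_onset_distance,
    single_fiber_efficiency,
    solid_angle_fraction,
    spot_radius,
    surface_intensity_ratio,
)


class TestAcceptanceAngle:
    @pytest.mark.parametrize(
        "na, n0, expected",
        [
            (0.22, 1.0, 12.709),  # the standard low-OH fiber in air
            (1e-9, 1.0, 0.0),
            (0.22, 1.33, 9.5213),  # probe immersed in water
        ],
    )
    def test_examples(self, na, n0, expected):
        theta = acceptance_angle(FiberSpec(100, na, n0))
        assert theta == pytest.approx(expected, abs=1e-3)
        # self-consistency: sin(theta) * n0 recovers the NA
        assert math.sin(math.radians(theta)) * n0 == pytest.approx(na, rel=1e-12)

    @pytest.mark.parametrize("na, n0", [(1.0, 1.0), (1.2, 1.0), (1.33, 1.33)])
    def test_na_at_or_above_medium_index_rejected(self, na, n0):
        with pytest.raises(InvalidFiberError):
            FiberSpec(100, na, n0)


class TestEffectiveDistance:
    @pytest.mark.parametrize("d", [0.0, 37.5, 500.0, 4000.0])
    @pytest.mark.parametrize("core", [50.0, 200.0, 1000.0])
    def test_identity_at_normal_incidence(self, na022, d, core):
        assert effective_distance(d, na022(core), tilt=0.0) == d

    def test_tilted_example(self, na022):
        # frozen from the closed form; cross-checked symbolically below
        assert effective_distance(100.0, na022(100), tilt=15.0) == pytest.approx(
            102.0619, abs=5e-3
        )

    def test_tilted_matches_independent_symbolic_evaluation(self, na022):
        sympy = pytest.importorskip("sympy")
        d, r = 100, 100
        theta = sympy.asin(sympy.Rational(22, 100))
        beta = sympy.rad(15)
        t = sympy.tan(theta)
        expr = d + (r + d * t) * sympy.sin(beta) * sympy.tan(beta) * t / (
            sympy.cos(beta) ** 2 - sympy.sin(beta) ** 2 * t**2
        )
        expected = float(sympy.N(expr, 20))
        assert effective_distance(100.0, na022(100), 15.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_tilt_increases_effective_distance(self, na022):
        fiber = na022(200)
        betas = [5, 15, 30, 50, 70]
        vals = [effective_distance(300.0, fiber, b) for b in betas]
        assert all(v > 300.0 for v in vals)
        assert vals == sorted(vals)

    def test_domain_error_at_geometric_limit(self, na022):
        fiber = na022(100)
        limit = 90.0 - acceptance_angle(fiber)
        with pytest.raises(TiltDomainError):
            effective_distance(100.0, fiber, limit)
        with pytest.raises(TiltDomainError):
            effective_distance(100.0, fiber, 89.0)


class TestSpotRadius:
    @pytest.mark.parametrize(
        "d, core, expected",
        [(0.0, 200.0, 200.0), (100.0, 50.0, 72.553), (1200.0, 500.0, 770.63)],
    )
    def test_examples(self, na022, d, core, expected):
        assert spot_radius(d, na022(core)) == pytest.approx(expected, abs=5e-3)


class TestSurfaceIntensityRatio:
    def test_contact_normal_is_unity(self, na022):
        assert surface_intensity_ratio(0.0, na022(100), 0.0) == pytest.approx(1.0)

    def test_contact_tilted_is_cosine(self, na022):
        assert surface_intensity_ratio(0.0, na022(100), 60.0) == pytest.approx(0.5)

    def test_spreading_example(self, na022):
        assert surface_intensity_ratio(200.0, na022(200), 0.0) == pytest.approx(
            0.6658, abs=5e-4
        )

    def test_maximized_at_normal_incidence(self, na022):
        fiber = na022(200)
        base = surface_intensity_ratio(300.0, fiber, 0.0)
        assert all(
            surface_intensity_ratio(300.0, fiber, b) < base for b in (5, 20, 45)
        )


class TestSolidAngleFraction:
    def test_contact_collects_full_hemisphere(self, na022):
        assert solid_angle_fraction(0.0, na022(200)) == pytest.approx(1.0)

    def test_distance_equal_radius(self, na022):
        assert solid_angle_fraction(123.0, na022(123)) == pytest.approx(
            1 - 1 / math.sqrt(2), rel=1e-12
        )

    def test_example(self, na022):
        assert solid_angle_fraction(100.0, na022(50)) == pytest.approx(0.10557, abs=1e-5)

    def test_bounded_and_strictly_decreasing(self, na022):
        grid = np.linspace(0, 5000, 1000)
        omega = solid_angle_fraction(grid, na022(200))
        assert np.all((omega >= 0) & (omega <= 1))
        assert np.all(np.diff(omega) < 0)


class TestOverlapFraction:
    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_zero_before_and_at_onset(self, na022, dialect):
        fiber = na022(100)
        onset = overlap_onset_distance(fiber, 10.0)
        for d in (0.0, onset / 2, onset):
            assert overlap_fraction(d, fiber, 10.0, dialect) == 0.0

    def test_corrected_reaches_full_overlap_in_far_field(self, na022):
        # c/R -> 0: the lens-area fraction tends to 1
        val = overlap_fraction(1e9, na022(100), 10.0, Dialect.ENERGY_CONSERVING)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_corrected_value_matches_lens_area_closed_form(self, na022):
        # r=1000, r_c=10, d=700: u = c/R = 0.87229, lens fraction 0.053723
        # (confirmed independently by the disk-sampling oracle)
        val = overlap_fraction(700.0, na022(1000), 10.0, Dialect.ENERGY_CONSERVING)
        u = 1010.0 / (1000.0 + 700.0 * math.tan(math.asin(0.22)))
        lens = (2 / math.pi) * (math.acos(u) - u * math.sqrt(1 - u**2))
        assert val == pytest.approx(lens, rel=1e-12)
        assert val == pytest.approx(0.053723, abs=1e-5)

    def test_as_printed_unclamped_tends_to_two(self, na022):
        raw = overlap_fraction(
            1e9, na022(100), 10.0, Dialect.AS_PRINTED, clamp=False
        )
        assert raw == pytest.approx(2.0, abs=1e-5)

    def test_clamp_engages_exactly_when_raw_exceeds_one(self, na022):
        fiber = na022(100)
        grid = np.linspace(0, 20000, 4000)
        raw = overlap_fraction(grid, fiber, 10.0, Dialect.AS_PRINTED, clamp=False)
        clamped = overlap_fraction(grid, fiber, 10.0, Dialect.AS_PRINTED, clamp=True)
        assert np.all(clamped[raw > 1] == 1.0)
        assert np.array_equal(clamped[raw <= 1], raw[raw <= 1])

    def test_as_printed_inflates_relative_to_corrected(self, na022):
        fiber = na022(200)
        onset = overlap_onset_distance(fiber, 10.0)
        grid = np.linspace(onset * 1.01, 5000, 200)
        printed = overlap_fraction(grid, fiber, 10.0, Dialect.AS_PRINTED)
        corrected = overlap_fraction(grid, fiber, 10.0, Dialect.ENERGY_CONSERVING)
        assert np.all(printed >= corrected)
        assert np.any(printed > corrected)


class TestSingleFiberEfficiency:
    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_contact_normalizes_to_one(self, na022, dialect):
        probe = ProbeConfig(mode="single", distance=0.0, dialect=dialect)
        assert single_fiber_efficiency(probe, na022(50)).efficiency == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "core, d, expected",
        [(50, 100.0, 0.22229), (500, 1200.0, 0.18273)],  # the "20%" checkpoints
    )
    def test_distance_falloff_checkpoints(self, na022, core, d, expected):
        fiber = na022(core)
        eff = single_fiber_efficiency(
            ProbeConfig(mode="single", distance=d), fiber
        ).efficiency
        contact = single_fiber_efficiency(
            ProbeConfig(mode="single", distance=0.0), fiber
        ).efficiency
        assert eff / contact == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_non_increasing_in_distance(self, na022, dialect):
        fiber = na022(200)
        vals = [
            single_fiber_efficiency(
                ProbeConfig(mode="single", distance=d, dialect=dialect), fiber
            ).efficiency
            for d in np.linspace(0, 2000, 100)
        ]
        assert np.all(np.diff(vals) <= 0)

    def test_mode_mismatch_rejected(self, na022, multi_probe):
        with pytest.raises(ValueError):
            single_fiber_efficiency(multi_probe, na022(200))

    def test_as_diameter_convention_halves_radius(self, na022):
        d = 150.0
        via_diameter = single_fiber_efficiency(
            ProbeConfig(mode="single", distance=d, size_convention="as_diameter"),
            na022(400),
        ).efficiency
        via_radius = single_fiber_efficiency(
            ProbeConfig(mode="single", distance=d), na022(200)
        ).efficiency
        assert via_diameter == pytest.approx(via_radius, rel=1e-12)


class TestMultiFiberEfficiency:
    def test_zero_below_onset(self, na022, multi_probe):
        fiber = na022(1000)
        onset = overlap_onset_distance(fiber, 10.0)
        assert onset == pytest.approx(44.341, abs=1e-3)
        for d in (0.0, 20.0, onset):
            probe = dataclasses.replace(multi_probe, distance=d)
            assert multi_fiber_efficiency(probe, fiber).efficiency == 0.0

    def test_interior_maximum_ordering(self, na022, multi_probe):
        fiber = na022(1000)

        def eff(d):
            return multi_fiber_efficiency(
                dataclasses.replace(multi_probe, distance=d), fiber
            ).efficiency

        assert eff(700.0) > eff(100.0)
        assert eff(700.0) > eff(2000.0)

    def test_decomposition_is_consistent(self, na022, multi_probe):
        fiber = na022(500)
        probe = dataclasses.replace(multi_probe, distance=400.0)
        res = multi_fiber_efficiency(probe, fiber)
        rebuilt = (
            (res.spot_radius / 500.0) ** 2
            * res.solid_angle_fraction
            * res.overlap_fraction
        )
        assert res.efficiency == pytest.approx(rebuilt, rel=1e-12)


class TestCollectionFraction:
    @pytest.mark.parametrize(
        "r_collect, r_diffuse, expected", [(0.5, 0.5, 1.0), (0.0, 0.5, 0.0), (0.25, 0.5, 0.5)]
    )
    def test_ratio(self, r_collect, r_diffuse, expected):
        res = EfficiencyResult(r_collect, 0, 0, 0, 0, 0)
        tissue = TissueOptics(diffuse_reflectance=r_diffuse)
        assert collection_fraction(res, tissue) == pytest.approx(expected)

    def test_zero_diffuse_reflectance_rejected(self):
        res = EfficiencyResult(0.5, 0, 0, 0, 0, 0)
        with pytest.raises(UndefinedFractionError):
            collection_fraction(res, TissueOptics(diffuse_reflectance=0.0))
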