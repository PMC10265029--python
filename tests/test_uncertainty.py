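"""Sensitivity analyses and Monte Carlo simulated error margins."""

import numpy as np
import pytest

from limbmech.moment_arms import group_summed_normalized, moment_arm_curve
from limbmech.synthetic import make_group_fixture
from limbmech.uncertainty import (PerturbationSpec, attachment_sensitivity,
                                  mass_sensitivity, monte_carlo_envelope,
                                  wrap_sensitivity)

GRID = np.arange(-30.0, 31.0, 2.0)


class TestAttachmentSensitivity:
    def test_axis_parallel_move_leaves_hinge_arm(self, wrapped_fixture):
        """Hinge-axis-parallel insertion move: lever unchanged to 1e-9 m.

        The insertion lies distal to a via point fixed at the joint level,
        so its span never crosses the joint and the axial move cannot alter
        the excursion.
        """
        from limbmech.path_engine import MusculotendonUnit, PathPoint
        model, _, wraps = wrapped_fixture
        mtu = MusculotendonUnit("via", [
            PathPoint([-0.1, 0.0, 0.0], "base"),
            PathPoint([0.1, 0.0, 0.0], "arm"),
            PathPoint([0.12, -0.05, 0.0], "arm")], wraps={"joint_cylinder": [0]})
        nominal, variants, summary = attachment_sensitivity(
            mtu, model, "hinge", "Z", GRID, wraps,
            directions=("mediolateral", "anteroposterior"))
        for label in ("mediolateral+", "mediolateral-"):
            dev = np.abs(variants[label].values_m - nominal.values_m)
            assert dev.max() < 1e-9

    def test_axial_move_of_spanning_point_second_order(self, wrapped_fixture):
        """Moving a joint-crossing endpoint along the axis tilts the line of
        action out of the hinge plane: the arm changes only by the obliquity
        factor, second order in the move (dz^2 / 2 L^2), never first order."""
        model, mtu, wraps = wrapped_fixture
        nominal, variants, _ = attachment_sensitivity(
            mtu, model, "hinge", "Z", GRID, wraps, magnitude=0.01)
        # minimum path length over the grid bounds the obliquity effect
        bound = 0.03 * (0.01 ** 2) / (2 * 0.19 ** 2)
        for label in ("mediolateral+", "mediolateral-"):
            dev = np.abs(variants[label].values_m - nominal.values_m).max()
            assert dev < 2 * bound
            assert dev < 1e-4

    def test_perpendicular_move_bounded_by_magnitude(self, wrapped_fixture):
        model, mtu, wraps = wrapped_fixture
        _, variants, _ = attachment_sensitivity(
            mtu, model, "hinge", "Z", GRID, wraps, magnitude=0.01)
        for label in ("anteroposterior+", "anteroposterior-"):
            curve = variants[label]
            assert curve is not None
            # geometric bound: a 1 cm move shifts the lever by at most 1 cm
            dev = np.abs(curve.values_m) - mtu.analytic_arm
            assert np.abs(dev).max() <= 0.01 + 1e-9

    def test_four_variants_produced(self, wrapped_fixture):
        model, mtu, wraps = wrapped_fixture
        _, variants, summary = attachment_sensitivity(
            mtu, model, "hinge", "Z", GRID, wraps)
        assert len(variants) == 4
        assert len(summary) == 4

    def test_zero_magnitude_identity(self, wrapped_fixture):
        model, mtu, wraps = wrapped_fixture
        nominal, variants, _ = attachment_sensitivity(
            mtu, model, "hinge", "Z", GRID, wraps, magnitude=0.0)
        for curve in variants.values():
            np.testing.assert_allclose(curve.values_m, nominal.values_m,
                                       atol=1e-15)

    def test_magnitude_continuity(self, wrapped_fixture):
        """Shrinking the move converges variants to the nominal curve."""
        model, mtu, wraps = wrapped_fixture
        nominal, v1, _ = attachment_sensitivity(
            mtu, model, "hinge", "Z", GRID, wraps, magnitude=1e-5)
        dev = max(np.abs(c.values_m - nominal.values_m).max()
                  for c in v1.values())
        assert dev < 1e-4

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="anatomical direction"):
            PerturbationSpec("attachment", 0.01, ("sideways",))


class TestWrapSensitivity:
    def test_enlarged_coaxial_radius_sets_arm(self, wrapped_fixture):
        model, mtu, wraps = wrapped_fixture
        wrap = wraps["joint_cylinder"]
        grid = np.arange(-10.0, 11.0, 1.0)
        nominal, variants, summary = wrap_sensitivity(
            wrap, model, [mtu], "hinge", "Z", grid, wraps, delta=0.02)
        enlarged = variants["radius+0.02"][mtu.name]
        np.testing.assert_allclose(np.abs(enlarged.values_m), 0.05, atol=1e-6)
        shrunk = variants["radius-0.02"][mtu.name]
        np.testing.assert_allclose(np.abs(shrunk.values_m), 0.01, atol=1e-6)

    def test_never_engaged_wrap_identity(self, wrapped_fixture):
        model, mtu, wraps = wrapped_fixture
        from limbmech.path_engine import MusculotendonUnit, PathPoint
        clear = MusculotendonUnit("clear", [
            PathPoint([-0.1, 0.2, 0.0], "base"),
            PathPoint([0.1, 0.2, 0.0], "arm")], wraps={"joint_cylinder": None})
        grid = np.arange(-10.0, 11.0, 1.0)
        nominal, variants, _ = wrap_sensitivity(
            wraps["joint_cylinder"], model, [clear], "hinge", "Z", grid,
            wraps, delta=0.02)
        for per_muscle in variants.values():
            np.testing.assert_allclose(per_muscle["clear"].values_m,
                                       nominal["clear"].values_m, atol=1e-12)

    def test_zero_delta_identity(self, wrapped_fixture):
        model, mtu, wraps = wrapped_fixture
        grid = np.arange(-10.0, 11.0, 1.0)
        nominal, variants, _ = wrap_sensitivity(
            wraps["joint_cylinder"], model, [mtu], "hinge", "Z", grid,
            wraps, delta=0.0)
        for per_muscle in variants.values():
            np.testing.assert_allclose(per_muscle[mtu.name].values_m,
                                       nominal[mtu.name].values_m, atol=1e-12)


class TestMassSensitivity:
    def test_factor_values(self):
        scaled = mass_sensitivity({"m": 0.2}, factors=(1.10, 1.15))
        assert scaled[1.15]["m"] == pytest.approx(0.23)
        assert scaled[1.10]["m"] == pytest.approx(0.22)

    def test_factor_one_identity(self):
        masses = {"a": 0.3, "b": 0.9}
        assert mass_sensitivity(masses, factors=(1.0,))[1.0] == masses

    def test_borderline_classification_flip(self):
        """A = 1.08 x B flips to 'B larger' once B is scaled by 1.10."""
        from limbmech.inertia import mass_comparison_table
        a = {"m": 1.08}
        b = {"m": 1.00}
        seg = {"s": 10.0}
        seg_of = {"m": "s"}
        base = mass_comparison_table(a, b, seg, seg, seg_of, labels=("A", "B"))
        assert base["larger_in"].iloc[0] == "A"
        for factor, expected in ((1.05, "A"), (1.10, "B"), (1.15, "B")):
            scaled_b = mass_sensitivity(b, factors=(factor,))[factor]
            df = mass_comparison_table(a, scaled_b, seg, seg, seg_of,
                                       labels=("A", "B"))
            assert df["larger_in"].iloc[0] == expected


class TestMonteCarloEnvelope:
    def test_zero_amplitude_zero_width(self):
        curves = make_group_fixture([0.0, 20.0], [0.02, 0.03])
        env = monte_carlo_envelope(curves, "hip_flexor", iterations=50,
                                   amplitude=0.0, seed=1)
        np.testing.assert_array_equal(env.lower, env.nominal)
        np.testing.assert_array_equal(env.upper, env.nominal)

    def test_fixed_seed_bit_identical(self):
        curves = make_group_fixture([0.0, 20.0], [0.02, 0.03])
        e1 = monte_carlo_envelope(curves, "hip_flexor", iterations=200, seed=7)
        e2 = monte_carlo_envelope(curves, "hip_flexor", iterations=200, seed=7)
        np.testing.assert_array_equal(e1.lower, e2.lower)
        np.testing.assert_array_equal(e1.upper, e2.upper)

    def test_single_muscle_extremes_at_peak(self):
        """1000 iterations: envelope at the nominal peak -> 1 +/- 0.2."""
        curves = make_group_fixture([0.0], [0.03])
        env = monte_carlo_envelope(curves, "hip_flexor", iterations=1000,
                                   amplitude=0.20, seed=3)
        k = int(np.argmax(env.nominal))
        assert env.nominal[k] == pytest.approx(1.0, abs=1e-12)
        assert env.upper[k] == pytest.approx(1.2, abs=0.01)
        assert env.lower[k] == pytest.approx(0.8, abs=0.01)

    def test_containment_every_seed(self):
        curves = make_group_fixture([-10.0, 15.0], [0.02, 0.05])
        for seed in range(5):
            env = monte_carlo_envelope(curves, "hip_flexor", iterations=100,
                                       seed=seed)
            assert np.all(env.lower <= env.nominal + 1e-12)
            assert np.all(env.upper >= env.nominal - 1e-12)

    def test_width_monotone_in_amplitude(self):
        curves = make_group_fixture([0.0, 20.0], [0.02, 0.03])
        widths = []
        for amp in (0.05, 0.10, 0.20):
            env = monte_carlo_envelope(curves, "hip_flexor", iterations=400,
                                       amplitude=amp, seed=5)
            widths.append((env.upper - env.lower).max())
        assert widths[0] < widths[1] < widths[2]

    def test_per_iteration_renormalization_degenerate_single(self):
        """Renormalizing inside each iteration cancels a single muscle's
        scale factor, collapsing the envelope to zero width."""
        curves = make_group_fixture([0.0], [0.03])
        env = monte_carlo_envelope(curves, "hip_flexor", iterations=200,
                                   seed=2, renormalize_per_iteration=True)
        assert (env.upper - env.lower).max() < 1e-12

    def test_percentile_inside_minmax(self):
        curves = make_group_fixture([0.0, 20.0], [0.02, 0.03])
        mm = monte_carlo_envelope(curves, "hip_flexor", iterations=500, seed=4)
        pc = monte_carlo_envelope(curves, "hip_flexor", iterations=500, seed=4,
                                  statistic="percentile")
        assert np.all(pc.lower >= mm.lower - 1e-12)
        assert np.all(pc.upper <= mm.upper + 1e-12)

    def test_amplitude_validation(self):
        curves = make_group_fixture([0.0], [0.03])
        with pytest.raises(ValueError):
            monte_carlo_envelope(curves, "hip_flexor", amplitude=1.0)
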