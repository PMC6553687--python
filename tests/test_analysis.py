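"""Series extraction, pattern classification, and the color legend."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyllosim.analysis import (
    CATEGORIES,
    ColorCode,
    PatternClass,
    classify,
    color_encode,
    divergence_series,
    group_nodes,
    ratio_stats,
)
from phyllosim.inhibition import DC1Params
from phyllosim.simulate import SimSettings, run_dc1

from conftest import trace_from_series


class TestDivergenceSeries:
    def test_opposite_pair_wraps_to_plus_180(self, make_trace):
        tr = make_trace([180.0])
        assert divergence_series(tr).angles[0] == pytest.approx(180.0)

    def test_signed_wrap(self, make_trace):
        tr = make_trace([-120.0, 200.0])
        np.testing.assert_allclose(
            divergence_series(tr).angles, [-120.0, -160.0]
        )

    def test_dc1_plastochrons_equal_G(self):
        tr = run_dc1(DC1Params(eta=2.0, G=0.3), SimSettings(max_primordia=12))
        np.testing.assert_allclose(
            divergence_series(tr).plastochrons, 0.3, rtol=1e-14
        )

    def test_too_short_rejected(self, make_trace):
        with pytest.raises(ValueError):
            divergence_series(make_trace([]))


class TestGroupNodes:
    def test_alternate_trace_all_singletons(self, make_trace):
        tr = make_trace([137.5] * 10)
        assert all(len(n) == 1 for n in group_nodes(tr))

    def test_simultaneous_insertions_share_node(self, make_trace):
        # pairs born together: plastochron 0 inside each pair
        divs = [90.0, 180.0] * 6
        plast = [1.0, 0.0] * 6
        nodes = group_nodes(make_trace(divs, plast))
        assert [len(n) for n in nodes[-2:]] == [2, 2]


def _whorled_trace(k, rotation, n_nodes=6):
    """Trace of k-member whorls, successive whorls rotated by `rotation`."""
    divs, plast = [], []
    for node in range(1, n_nodes):
        divs.append(rotation - (k - 1) * (360.0 / k))
        plast.append(1.0)
        for _ in range(k - 1):
            divs.append(360.0 / k)
            plast.append(0.0)
    # leading whorl completion
    lead = [360.0 / k] * (k - 1)
    return trace_from_series(lead + divs, [0.0] * (k - 1) + plast)


class TestClassify:
    def test_constant_golden_angle_is_regular(self, make_trace):
        pc = classify(make_trace([137.5] * 20))
        assert pc.category == "regular_alternate"
        assert pc.mean_divergence == pytest.approx(137.5)
        assert pc.angle_ratio == 1.0

    def test_two_cycle(self, make_trace):
        pc = classify(make_trace([170.0, 100.0] * 10, [0.3, 0.8] * 10))
        assert pc.category == "two_cycle_alternate"
        assert pc.cycle_length == 2
        assert pc.angle_ratio == pytest.approx(100.0 / 170.0)
        assert pc.plastochron_ratio == pytest.approx(0.3 / 0.8)

    def test_four_cycle_tetrastichous(self, make_trace):
        pc = classify(make_trace([165.0, -91.0, -165.0, 91.0] * 6))
        assert pc.category == "four_cycle_alternate"
        assert pc.cycle_length == 4
        assert pc.angle_ratio == pytest.approx(91.0 / 165.0, rel=1e-9)

    def test_four_cycle_orixate_with_plastochrons(self, make_trace):
        pc = classify(
            make_trace([180.0, 90.0, 180.0, -90.0] * 6, [0.1, 0.325] * 12)
        )
        assert pc.category == "four_cycle_alternate"
        assert pc.angle_ratio == pytest.approx(0.5)
        assert pc.plastochron_ratio == pytest.approx(0.1 / 0.325)

    def test_x_cycle_five(self, make_trace):
        pc = classify(make_trace([180.0, 0.0, 0.0, 0.0, 0.0] * 8))
        assert pc.category == "x_cycle_alternate"
        assert pc.cycle_length == 5

    def test_x_cycle_four_not_confused_with_tetrastichy(self, make_trace):
        # periodic with period 4 but lacking the (p, q, -p, -q) signature
        pc = classify(make_trace([180.0, 0.0, 0.0, 0.0] * 8))
        assert pc.category == "x_cycle_alternate"
        assert pc.cycle_length == 4

    @pytest.mark.parametrize("c", [1, 2, 4, 5, 6])
    def test_period_detection_exact_tiling(self, c, make_trace):
        """A tiled length-c motif is recovered with its exact cycle length."""
        motifs = {
            1: [150.0],
            2: [160.0, 110.0],
            4: [170.0, 80.0, -170.0, -80.0],
            5: [180.0, 2.0, -1.0, 1.5, 0.5],
            6: [179.0, 1.0, -2.0, 0.5, 1.0, -0.5],
        }
        pc = classify(make_trace(motifs[c] * 12))
        assert pc.cycle_length == c

    def test_decussate(self):
        pc = classify(_whorled_trace(2, 90.0))
        assert pc.category == "decussate"
        assert pc.primordia_per_node == 2

    def test_tricussate(self):
        pc = classify(_whorled_trace(3, 60.0))
        assert pc.category == "tricussate"
        assert pc.primordia_per_node == 3

    def test_whorl_without_proper_rotation_is_other_whorled(self):
        pc = classify(_whorled_trace(2, 40.0))
        assert pc.category == "other_whorled"

    def test_irregular_is_other(self, make_trace, rng):
        pc = classify(make_trace(rng.uniform(-170, 170, 40)))
        assert pc.category == "other"

    def test_short_trace_rejected(self, make_trace):
        with pytest.raises(ValueError):
            classify(make_trace([137.5] * 4))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(rot=st.floats(0, 360), flip=st.booleans())
    def test_rotation_and_mirror_invariance(self, rot, flip):
        motif = [165.0, -91.0, -165.0, 91.0]
        divs = np.array(motif * 6)
        if flip:
            divs = -divs
        pc = classify(trace_from_series(divs, theta0=rot))
        assert pc.category == "four_cycle_alternate"
        assert pc.angle_ratio == pytest.approx(91.0 / 165.0, rel=1e-9)


class TestColorEncode:
    def test_total_on_all_categories(self, make_trace):
        samples = {
            "regular_alternate": classify(make_trace([137.5] * 20)),
            "two_cycle_alternate": classify(make_trace([170.0, 100.0] * 10)),
            "four_cycle_alternate": classify(
                make_trace([165.0, -91.0, -165.0, 91.0] * 6)
            ),
            "x_cycle_alternate": classify(
                make_trace([180.0, 0.0, 0.0, 0.0, 0.0] * 8)
            ),
            "decussate": classify(_whorled_trace(2, 90.0)),
            "tricussate": classify(_whorled_trace(3, 60.0)),
            "other_whorled": classify(_whorled_trace(2, 40.0)),
            "other": PatternClass("other"),
        }
        assert set(samples) == set(CATEGORIES)
        for cat, pc in samples.items():
            assert pc.category == cat
            color = color_encode(pc)
            rgb = color.to_rgb()
            assert all(0.0 <= v <= 1.0 for v in rgb)

    def test_distichous_is_red_full_saturation(self, make_trace):
        pc = classify(make_trace([180.0] * 20))
        color = color_encode(pc)
        assert color.hue == pytest.approx(0.0)  # red
        assert color.saturation == 1.0

    def test_zero_divergence_is_cyan(self):
        pc = PatternClass(
            "regular_alternate", cycle_length=1, mean_divergence=0.0,
            angle_ratio=1.0, plastochron_ratio=1.0,
        )
        assert color_encode(pc).hue == pytest.approx(0.5)  # cyan

    def test_linear_midpoints(self):
        pc = PatternClass(
            "four_cycle_alternate", cycle_length=4, mean_divergence=90.0,
            angle_ratio=0.5, plastochron_ratio=0.5,
        )
        color = color_encode(pc)
        assert color.saturation == pytest.approx(0.5)
        assert color.lightness == pytest.approx(0.75)

    def test_component_range_validated(self):
        with pytest.raises(ValueError):
            ColorCode(1.2, 0.0, 0.0)


class TestRatioStats:
    def test_perfect_orixate(self, make_trace):
        pc = classify(
            make_trace([180.0, 90.0, 180.0, -90.0] * 6, [0.1, 0.325] * 12)
        )
        ar, pr = ratio_stats(pc)
        assert ar == pytest.approx(0.5)
        assert pr == pytest.approx(0.1 / 0.325)  # ~0.3077

    def test_equal_alternating_angles(self, make_trace):
        pc = classify(make_trace([120.0, -120.0] * 10))
        # sign flips but equal magnitude: |q|/|p| = 1
        assert ratio_stats(pc)[0] == pytest.approx(1.0)

    def test_undefined_for_regular(self, make_trace):
        pc = classify(make_trace([137.5] * 20))
        with pytest.raises(ValueError):
            ratio_stats(pc)
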