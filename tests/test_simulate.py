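"""Simulation engines: determinism, symmetries, and oracle cross-checks."""

import numpy as np
import pytest

from phyllosim.geometry import wrap_180
from phyllosim.inhibition import (
    DC1Params,
    DC2Params,
    EDC1Params,
    EDC2Params,
    field_dc1,
    field_dc2,
)
from phyllosim.simulate import (
    SimSettings,
    contour_matrix,
    equivalence_check_edc2_dc2,
    read_trace,
    run_dc1,
    run_dc2,
    write_trace,
)


def divergences(trace):
    return wrap_180(np.diff(trace.thetas))


SMALL = SimSettings(max_primordia=25)


class TestSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimSettings(angle_resolution=0.7)  # does not divide 360
        with pytest.raises(ValueError):
            SimSettings(dt=0.0)
        with pytest.raises(ValueError):
            SimSettings(initial_condition="ring")
        with pytest.raises(ValueError):
            SimSettings(max_primordia=1)

    def test_grid(self):
        s = SimSettings(angle_resolution=0.1)
        assert s.n_grid == 3600
        assert s.grid()[1] == pytest.approx(0.1)


class TestDC1Engine:
    def test_plastochron_identity(self):
        """ln(r_m / r_{m+1}) equals G exactly for every consecutive pair."""
        tr = run_dc1(DC1Params(eta=2.0, G=0.37), SMALL)
        np.testing.assert_allclose(np.diff(tr.birth_times), 0.37, rtol=1e-14)

    def test_determinism(self):
        a = run_dc1(DC1Params(eta=1.5, G=0.3), SMALL)
        b = run_dc1(DC1Params(eta=1.5, G=0.3), SMALL)
        np.testing.assert_array_equal(a.thetas, b.thetas)

    def test_mirror_symmetry(self):
        """The clockwise tie-break yields the mirror-image trace."""
        ccw = run_dc1(DC1Params(eta=1.5, G=0.3), SMALL)
        cw = run_dc1(
            DC1Params(eta=1.5, G=0.3),
            SimSettings(max_primordia=25, tie_break="cw"),
        )
        np.testing.assert_allclose(
            cw.thetas, (-ccw.thetas) % 360.0, atol=1e-12
        )

    def test_large_growth_gives_distichous(self):
        """With fast growth only the last primordium matters: 180 degrees."""
        tr = run_dc1(DC1Params(eta=2.0, G=2.0), SMALL)
        np.testing.assert_allclose(divergences(tr), 180.0, atol=1e-9)

    def test_edc1_zero_rate_identical_to_dc1(self):
        """A constant age factor scales the field but moves no argmin."""
        dc1 = run_dc1(DC1Params(eta=2.0, G=0.25), SMALL)
        edc1 = run_dc1(EDC1Params(G=0.25, a=0.0, b=3.0), SMALL)
        np.testing.assert_array_equal(dc1.thetas, edc1.thetas)
        np.testing.assert_array_equal(dc1.birth_times, edc1.birth_times)

    def test_insertion_matches_bruteforce_argmin(self):
        """Engine choices equal the argmin of the reference field function."""
        params = DC1Params(eta=1.8, G=0.4)
        tr = run_dc1(params, SimSettings(max_primordia=12))
        grid = tr.settings.grid()
        for n in range(5, 13):
            I = field_dc1(grid, tr.primordia[: n - 1], params, n=n)
            assert grid[np.argmin(I)] == pytest.approx(tr.primordia[n - 1].theta)


class TestDC2Engine:
    params = DC2Params(alpha=8.0, Gamma=2.6, N=1.0 / 3.0)

    def test_second_primordium_opposite(self):
        tr = run_dc2(self.params, SimSettings(max_primordia=5))
        assert tr.primordia[0].theta == 0.0
        assert tr.primordia[1].theta == pytest.approx(180.0)

    def test_determinism(self):
        a = run_dc2(self.params, SimSettings(max_primordia=15))
        b = run_dc2(self.params, SimSettings(max_primordia=15))
        np.testing.assert_array_equal(a.thetas, b.thetas)
        np.testing.assert_array_equal(a.birth_times, b.birth_times)

    def test_mirror_symmetry(self):
        ccw = run_dc2(self.params, SimSettings(max_primordia=15))
        cw = run_dc2(
            self.params, SimSettings(max_primordia=15, tie_break="cw")
        )
        np.testing.assert_allclose(cw.thetas, (-ccw.thetas) % 360.0, atol=1e-9)
        np.testing.assert_allclose(cw.birth_times, ccw.birth_times, atol=1e-12)

    def test_two_at_120_initial_condition(self):
        tr = run_dc2(
            DC2Params(alpha=2.0, Gamma=1.2, N=1.0 / 3.0),
            SimSettings(max_primordia=8, initial_condition="two_at_120"),
        )
        assert tr.primordia[0].theta == 0.0
        assert tr.primordia[1].theta == pytest.approx(120.0)
        assert tr.primordia[0].birth_time == tr.primordia[1].birth_time == 0.0

    def test_pruning_does_not_change_trace(self):
        """The far-primordium cutoff is a pure optimization."""
        pruned = run_dc2(self.params, SimSettings(max_primordia=20))
        exact = run_dc2(self.params, SimSettings(max_primordia=20, prune=False))
        np.testing.assert_array_equal(pruned.thetas, exact.thetas)
        np.testing.assert_array_equal(pruned.birth_times, exact.birth_times)

    def test_insertions_match_bruteforce_field(self):
        """At each insertion the event angle minimizes the reference field."""
        tr = run_dc2(self.params, SimSettings(max_primordia=10, prune=False))
        fine = np.arange(0, 360.0, 0.01)
        for k, ev in enumerate(tr.event_log):
            if np.isnan(ev.min_value):
                continue  # seeded initial primordium
            preceding = tr.primordia[:k]
            I = fine_I = field_dc2(fine, preceding, ev.time, tr.params)
            best = fine[np.argmin(fine_I)]
            gap = abs((best - ev.theta + 180.0) % 360.0 - 180.0)
            assert gap <= tr.settings.angle_resolution

    def test_stalled_run_raises(self):
        # enormous inhibition range: the field never drops below threshold
        stalled = DC2Params(alpha=1.0, Gamma=500.0, N=1.0 / 3.0)
        with pytest.raises(RuntimeError, match="max_time"):
            run_dc2(stalled, SimSettings(max_primordia=5, max_time=0.5))

    def test_gamma_ramp_delays_onset(self):
        """A large initial inhibition range suppresses insertion until the
        tanh schedule brings Gamma down to its final value."""
        from phyllosim.inhibition import GammaRamp

        p = EDC2Params(
            alpha=1.0, Gamma=2.8, N=1.0 / 3.0, A=5.0, B=0.74,
            ramp=GammaRamp(Gamma_i=50.0, Gamma_f=2.8, t_i=0.2, tau=0.3),
        )
        tr = run_dc2(p, SimSettings(max_primordia=15))
        assert len(tr.primordia) == 15
        # second primordium waits for the ramp to descend past t_i
        assert tr.primordia[1].birth_time > 0.2

    def test_counts_and_monotone_birth_times(self):
        tr = run_dc2(self.params, SimSettings(max_primordia=30))
        assert len(tr.primordia) == 30
        assert np.all(np.diff(tr.birth_times) >= 0)


class TestEquivalenceCheck:
    def test_trivially_true_at_two_primordia(self):
        p = DC2Params(alpha=2.0, Gamma=1.0, N=1.0 / 3.0)
        assert equivalence_check_edc2_dc2(p, SimSettings(max_primordia=2))

    def test_holds_in_stable_region(self):
        p = DC2Params(alpha=8.0, Gamma=2.6, N=1.0 / 3.0)
        assert equivalence_check_edc2_dc2(p, SimSettings(max_primordia=20))

    def test_fails_at_orixate_setting(self):
        """Moderate age-dependence genuinely changes the pattern."""
        base = DC2Params(alpha=1.0, Gamma=2.8, N=1.0 / 3.0)
        st = SimSettings(max_primordia=25)
        tr_dc2 = run_dc2(base, st)
        tr_edc2 = run_dc2(
            EDC2Params(alpha=1.0, Gamma=2.8, N=1.0 / 3.0, A=4.8, B=0.72), st
        )
        d = np.abs(tr_dc2.thetas - tr_edc2.thetas) % 360.0
        assert np.max(np.minimum(d, 360.0 - d)) > st.angle_resolution


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        tr = run_dc2(
            EDC2Params(alpha=1.0, Gamma=2.8, N=1.0 / 3.0, A=4.8, B=0.72),
            SimSettings(max_primordia=10),
        )
        path = tmp_path / "trace.csv"
        write_trace(tr, path)
        back = read_trace(path)
        np.testing.assert_allclose(back.thetas, tr.thetas)
        np.testing.assert_allclose(back.birth_times, tr.birth_times)
        assert back.model_tag == "edc2"
        assert back.params == tr.params
        assert back.settings == tr.settings

    def test_contour_matrix(self):
        tr = run_dc2(
            DC2Params(alpha=8.0, Gamma=2.6, N=1.0 / 3.0),
            SimSettings(max_primordia=8),
        )
        ln_I, r_axis, theta_axis = contour_matrix(tr, n_r=40, n_theta=90)
        assert ln_I.shape == (40, 90)
        # intensity decays with distance from the apex region
        assert np.nanmean(ln_I[-1]) < np.nanmean(ln_I[5])
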