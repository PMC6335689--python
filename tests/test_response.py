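import numpy as np
import pytest

import hepregen as h
from hepregen.simulate import Trajectory


def flat_trajectory(ref, level, horizon=912.5):
    """Synthetic do-nothing trajectory at constant mass fraction."""
    times = np.linspace(0.0, horizon, 50)
    states = np.tile(h.initial_state(1.0 - level), (50, 1))
    return Trajectory(times=times, states=states, resection_fraction=1.0 - level,
                      params=ref)


class TestClassifyResponse:
    def test_reference_patient_recovers_normally(self, ref):
        """Long-horizon reference run sits inside the 0.9-1.1 window."""
        tr = h.simulate_resection(ref, 2 / 3, horizon=3650.0)
        mode = h.classify_response(tr)
        assert mode.label == "normal"
        assert 0.9 <= mode.n_end <= 1.1

    def test_collapse_below_tenth_is_failure(self, ref):
        tr = h.simulate_resection(ref.replace(M=22.0), 0.30, horizon=912.5)
        mode = h.classify_response(tr)
        assert mode.label == "failure"
        assert mode.n_2y < 0.1

    def test_unchanged_mass_is_unresponsive(self, ref):
        mode = h.classify_response(flat_trajectory(ref, 0.6))
        assert mode.label == "unresponsive"
        assert mode.max_excursion == 0.0

    def test_partial_recovery_is_suppressed(self, ref):
        """At 2.5 years the reference run is still below the window."""
        tr = h.simulate_resection(ref, 2 / 3, horizon=912.5)
        mode = h.classify_response(tr)
        assert mode.label == "suppressed"
        assert 0.1 <= mode.n_end < 0.9

    def test_short_trajectory_rejected(self, ref):
        tr = h.simulate_resection(ref, 0.5, horizon=400.0)
        with pytest.raises(ValueError, match="spans"):
            h.classify_response(tr)

    def test_labels_are_exhaustive_and_exclusive(self, ref):
        rng = np.random.default_rng(5)
        for _ in range(6):
            p = ref.replace(
                M=float(rng.uniform(0.5, 25.0)),
                beta_ap=float(rng.uniform(0.005, 0.12)),
            )
            tr = h.simulate_resection(p, 2 / 3, horizon=3650.0, failure_exit=0.05)
            label = h.classify_response(tr).label
            assert label in {"normal", "suppressed", "failure", "unresponsive"}


class TestThresholdOfFailure:
    def test_bisect_agrees_with_full_scan(self, ref):
        grid = np.arange(0.05, 0.91, 0.05)
        p = ref.replace(M=12.0)
        fast = h.threshold_of_failure(p, grid=grid, scan="bisect")
        slow = h.threshold_of_failure(p, grid=grid, scan="full")
        assert fast == slow
        assert fast.status == "found"

    def test_reported_level_is_lowest_failing(self, ref):
        p = ref.replace(M=12.0)
        r = h.threshold_of_failure(p)
        level = r.percent / 100.0
        from hepregen.response import _fails
        from hepregen.simulate import SolverOptions

        assert _fails(p, level, 36500.0, SolverOptions())
        assert not _fails(p, level - 0.01, 36500.0, SolverOptions())

    def test_grid_refinement_moves_threshold_at_most_one_step(self, ref):
        p = ref.replace(M=12.0)
        coarse = h.threshold_of_failure(p)
        fine_grid = np.round(np.arange(0.05, 0.9001, 0.005), 10)
        fine = h.threshold_of_failure(p, grid=fine_grid)
        assert abs(coarse.percent - fine.percent) <= 1.0 + 1e-9

    def test_bistability_across_threshold(self, ref):
        """Trajectories bracketing the threshold reach distinct attractors."""
        p = ref.replace(M=12.0)
        r = h.threshold_of_failure(p)
        lo = h.simulate_resection(p, r.percent / 100 - 0.01, horizon=36500.0)
        hi = h.simulate_resection(p, r.percent / 100, horizon=36500.0, failure_exit=0.05)
        n_lo = lo.mass_fraction[-1]
        n_hi = hi.mass_fraction[-1]
        assert n_lo - n_hi > 0.5

    def test_none_found_on_truncated_grid(self, ref):
        """A grid capped below the tipping point reports no failure."""
        r = h.threshold_of_failure(ref.replace(M=4.0), grid=np.arange(0.05, 0.51, 0.05))
        assert r.status == "none-found"
        assert r.ordinal() > 90.0

    def test_ordinal_sorts_none_safe_below_grid(self):
        from hepregen.response import ThresholdResult

        ns = ThresholdResult("none-safe", 5.0)
        found = ThresholdResult("found", 60.0)
        nf = ThresholdResult("none-found", None)
        assert ns.ordinal() < found.ordinal() < nf.ordinal()


class TestPhasePortrait:
    def test_recovery_and_failure_attractors(self, ref):
        """Below-threshold curves end near (N_ss, 0); at/above threshold they
        end at the failure attractor near the origin."""
        p = ref.replace(M=12.0)
        portrait = h.phase_portrait(
            p, [0.30, 0.80], grid=np.arange(0.05, 0.91, 0.05)
        )
        recover, fail = portrait.curves
        assert np.all(recover >= 0) and np.all(fail >= 0)
        q_end, r_end = recover[-1]
        assert abs(q_end - p.N_ss) < 0.15 and r_end < 0.05
        q_end, r_end = fail[-1]
        assert q_end < 0.1 and r_end < 0.1
        assert portrait.threshold.status == "found"

    def test_zero_resection_degenerates_to_a_point(self, ref):
        portrait = h.phase_portrait(ref, [0.0], grid=np.arange(0.05, 0.91, 0.2))
        assert portrait.curves[0].shape == (1, 2)
        assert portrait.curves[0][0, 0] == ref.N_ss
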