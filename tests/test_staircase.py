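"""Staircase engine: continua, virtual observers, the up-down rule and its
convergence properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audlex import (
    ConfigurationError,
    ScriptedObserver,
    StaircaseConfig,
    StimulusContinuum,
    VirtualObserver,
    best_of_runs,
    build_fine_continuum,
    build_fm_continuum,
    build_id_continuum,
    build_rt_continuum,
    convergence_probability,
    respond,
    run_track,
)

# ---------------------------------------------------------------------------
# continua
# ---------------------------------------------------------------------------


class TestContinua:
    def test_fm_schedule(self):
        cont = build_fm_continuum()
        levels = np.array(cont.levels)
        assert levels[0] == 100.0
        # geometric region: constant 1.2 ratio down to the ~11 Hz boundary
        geo = levels[levels > 11.0]
        assert np.allclose(geo[:-1] / geo[1:], 1.2)
        assert geo[-1] / 1.2 <= 11.0
        # arithmetic region: 1 Hz steps, 11 down to the 1 Hz floor
        arith = levels[levels <= 11.0]
        assert np.array_equal(arith, np.arange(11.0, 0.0, -1.0))
        assert np.all(np.diff(levels) < 0)

    def test_rt_schedule(self):
        cont = build_rt_continuum()
        rise = np.array(cont.levels)[::-1] + 15.0  # back to absolute rise times
        assert len(rise) == 40  # 41 rise times minus the 15 ms reference
        assert cont.levels[0] == pytest.approx(485.0)
        full = np.concatenate([[15.0], rise])
        assert full[-1] == pytest.approx(500.0)
        # constant log spacing at (500/15)^(1/40)
        assert np.allclose(full[1:] / full[:-1], (500.0 / 15.0) ** (1.0 / 40.0))
        assert np.allclose(full, np.geomspace(15.0, 500.0, 41))

    def test_id_schedule(self):
        cont = build_id_continuum()
        levels = np.array(cont.levels)
        assert len(levels) == 40
        assert levels[0] == pytest.approx(10.0)
        assert levels[-1] == pytest.approx(0.25)
        assert np.allclose(np.diff(levels), -0.25)

    def test_continuum_validation(self):
        with pytest.raises(ConfigurationError):
            StimulusContinuum(task="X", levels=(1.0,))
        with pytest.raises(ConfigurationError):
            StimulusContinuum(task="X", levels=(1.0, 2.0))  # increasing


# ---------------------------------------------------------------------------
# observer / respond
# ---------------------------------------------------------------------------


class TestObserver:
    def test_guessing_floor_at_zero_difference(self):
        obs = VirtualObserver(threshold=10.0, slope=4.0, lapse=0.0)
        assert obs.p_correct(0.0) == pytest.approx(1.0 / 3.0)

    def test_asymptote_without_lapse(self):
        obs = VirtualObserver(threshold=10.0, slope=4.0, lapse=0.0)
        assert obs.p_correct(1e9) == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_probability_by_monte_carlo(self, rng):
        # at the threshold, P(correct) = guess + (1-guess-lapse)/2 exactly
        obs = VirtualObserver(threshold=10.0, slope=4.0, lapse=0.02)
        p_exact = obs.guess + (1.0 - obs.guess - obs.lapse) / 2.0
        assert obs.p_correct(10.0) == pytest.approx(p_exact)
        n = 100_000
        hits = sum(respond(obs, 10.0, rng) for _ in range(n))
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(hits / n - p_exact) < 3 * se

    def test_negative_level_rejected(self, rng):
        obs = VirtualObserver(threshold=10.0)
        with pytest.raises(ValueError):
            respond(obs, -1.0, rng)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            VirtualObserver(threshold=10.0, guess=0.0)
        with pytest.raises(ConfigurationError):
            VirtualObserver(threshold=10.0, lapse=0.5)
        with pytest.raises(ConfigurationError):
            VirtualObserver(threshold=-1.0)


# ---------------------------------------------------------------------------
# the up-down rule: independent brute-force oracle
# ---------------------------------------------------------------------------


def oracle_track(levels, script, n_down=2, stop_reversals=10, threshold_last=4):
    """Straightforward re-simulation of the transformed up-down rule used to
    validate run_track: independent bookkeeping, same definitions."""
    idx, streak, last_dir = 0, 0, 0
    reversal_levels, trace = [], []
    for correct in script:
        if len(reversal_levels) >= stop_reversals:
            break
        level = levels[idx]
        trace.append((level, correct))
        if correct:
            streak += 1
            move = 1 if streak == n_down else 0
        else:
            streak = 0
            move = -1
        if move:
            streak = 0
            if last_dir and move != last_dir:
                reversal_levels.append(level)
            last_dir = move
            idx = min(max(idx + move, 0), len(levels) - 1)
    tail = reversal_levels[-threshold_last:]
    thr = sum(tail) / len(tail) if tail else float("nan")
    return reversal_levels, thr


class TestRunTrack:
    def test_hand_enumerated_alternation(self):
        # C,C,W,C,C,W,... on a 5-level continuum: harder after each CC,
        # easier after each W; every move after the first flips direction.
        levels = (5.0, 4.0, 3.0, 2.0, 1.0)
        cont = StimulusContinuum(task="T", levels=levels)
        script = [True, True, False] * 12
        cfg = StaircaseConfig(stop_reversals=10, threshold_last=4)
        res = run_track(cont, cfg, ScriptedObserver(script))
        # trial 0,1: CC at 5 -> harder; trial 2: W at 4 -> easier (reversal);
        # trials 3,4: CC at 5 -> harder (reversal); ... oscillates 5 <-> 4
        assert res.reversal_levels == (4.0, 5.0, 4.0, 5.0, 4.0, 5.0, 4.0, 5.0, 4.0, 5.0)
        assert res.threshold == pytest.approx(4.5)
        assert res.terminated_normally

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        script=st.lists(st.booleans(), min_size=40, max_size=400),
        n_levels=st.integers(min_value=2, max_value=12),
    )
    def test_matches_brute_force_oracle_on_random_scripts(self, script, n_levels):
        levels = tuple(float(n_levels - i) for i in range(n_levels))
        cont = StimulusContinuum(task="T", levels=levels)
        cfg = StaircaseConfig(max_trials=len(script))
        res = run_track(cont, cfg, ScriptedObserver(script))
        rev, thr = oracle_track(levels, script)
        assert list(res.reversal_levels) == rev
        if rev:
            assert res.threshold == pytest.approx(thr)
        assert res.terminated_normally == (len(rev) >= cfg.stop_reversals)

    def test_omniscient_observer_walks_to_floor(self):
        cont = StimulusContinuum(task="T", levels=tuple(np.arange(20.0, 0.0, -1.0)))

        class Omniscient:
            def respond(self, level, rng=None):
                return True

        cfg = StaircaseConfig(max_trials=200)
        res = run_track(cont, cfg, Omniscient())
        # always-correct: monotone walk to the hardest level, no reversals
        assert not res.terminated_normally
        assert min(res.presented_levels) == 1.0
        assert res.presented_levels[-1] == 1.0

    def test_boundary_oscillation_counts_reversals(self):
        # near-omniscient observer that errs at the hardest level only
        cont = StimulusContinuum(task="T", levels=(3.0, 2.0, 1.0))

        class FloorErrer:
            def respond(self, level, rng=None):
                return level > 1.0

        res = run_track(cont, StaircaseConfig(), FloorErrer())
        assert res.terminated_normally
        assert len(res.reversal_indices) == 10
        # oscillates between the two hardest levels
        assert set(res.reversal_levels) <= {1.0, 2.0}
        assert 1.0 <= res.threshold <= 2.0

    def test_levels_never_leave_continuum(self, rng):
        cont = build_id_continuum()
        obs = VirtualObserver(threshold=1.0, slope=3.0)
        for _ in range(20):
            res = run_track(cont, StaircaseConfig(), obs, rng)
            assert set(res.presented_levels) <= set(cont.levels)

    def test_deterministic_under_fixed_seed(self):
        cont = build_fm_continuum()
        obs = VirtualObserver(threshold=4.0, slope=4.0)
        r1 = run_track(cont, StaircaseConfig(), obs, np.random.default_rng(42))
        r2 = run_track(cont, StaircaseConfig(), obs, np.random.default_rng(42))
        assert r1 == r2


class TestBestOfRuns:
    def test_picks_smaller_threshold(self):
        a = _mk_result("RT", 80.0)
        b = _mk_result("RT", 120.0)
        assert best_of_runs(a, b) == 80.0
        assert best_of_runs(_mk_result("ID", 1.46), _mk_result("ID", 1.04)) == 1.04

    def test_tie(self):
        assert best_of_runs(_mk_result("FM", 4.0), _mk_result("FM", 4.0)) == 4.0

    def test_task_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            best_of_runs(_mk_result("FM", 4.0), _mk_result("RT", 4.0))


def _mk_result(task, threshold):
    from audlex.staircase import TrackResult

    return TrackResult(
        task=task,
        presented_levels=(2.0, 1.0),
        responses=(True, False),
        reversal_indices=(1,),
        reversal_levels=(threshold,),
        threshold=threshold,
        terminated_normally=True,
    )


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------


class TestConvergence:
    def test_closed_form_target(self):
        assert StaircaseConfig(n_down=2).target_p == pytest.approx(0.70710678, abs=1e-6)
        assert StaircaseConfig(n_down=1).target_p == pytest.approx(0.5)

    def test_one_up_two_down_converges_to_70_7(self):
        cont = build_fine_continuum("FM", 1.0, 100.0, 100)
        obs = VirtualObserver(threshold=10.0, slope=4.0)
        res = convergence_probability(
            obs, StaircaseConfig(), cont, 200, np.random.default_rng(7)
        )
        assert abs(res.p_at_mean_level - 0.7071) < 0.02

    def test_one_up_one_down_converges_to_half(self):
        cont = build_fine_continuum("FM", 1.0, 100.0, 100)
        obs = VirtualObserver(threshold=10.0, slope=4.0)
        res = convergence_probability(
            obs, StaircaseConfig(n_down=1), cont, 200, np.random.default_rng(8)
        )
        assert abs(res.p_at_mean_level - 0.5) < 0.03

    def test_outside_continuum_flagged(self):
        cont = build_fine_continuum("FM", 1.0, 100.0, 50)
        obs = VirtualObserver(threshold=500.0, slope=4.0)
        res = convergence_probability(
            obs, StaircaseConfig(), cont, 5, np.random.default_rng(9)
        )
        assert res.threshold_outside_continuum

    def test_parameter_recovery_across_continuum(self):
        """Best-of-two 10-reversal tracks track true thresholds closely."""
        cont = build_fine_continuum("FM", 1.0, 200.0, 150)
        cfg = StaircaseConfig()
        rng = np.random.default_rng(10)
        true = np.geomspace(3.0, 80.0, 40)
        est = []
        for t in true:
            obs = VirtualObserver(threshold=float(t), slope=4.0)
            est.append(
                best_of_runs(run_track(cont, cfg, obs, rng), run_track(cont, cfg, obs, rng))
            )
        r = np.corrcoef(np.log(true), np.log(est))[0, 1]
        assert r > 0.9
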