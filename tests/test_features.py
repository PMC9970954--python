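"""Feature extraction: closed-form oracles and invariances."""

import numpy as np
import pytest

from digibrain import (compute_draw_shape, compute_esdmt, compute_pinching,
                       compute_sway_path, compute_turn_speed, compute_walk)
from digibrain.features import DIGITAL_MEASURES, _cv, extract_record
from digibrain.streams import DOWN, MOVE, UP, SensorStream, response_log
from digibrain.synthetic import (PERFECT, simulate_draw_shape_stream,
                                 simulate_inertial_stream, simulate_pinch_stream)


# ---------------------------------------------------------------- e-SDMT

class TestEsdmt:
    def test_uniform_responses_give_unit_fatigability(self):
        # 9 correct responses at t = 10, 20, ..., 90 s: a perfectly
        # sustained rate, so SFI30 = (3/30)/(6/60) = 1
        log = response_log(np.arange(10.0, 91.0, 10.0), [True] * 9)
        res = compute_esdmt(log)
        assert res.n_correct == 9
        assert res.max_gap == pytest.approx(10.0)
        assert res.sfi30 == pytest.approx(1.0)

    def test_single_response_has_zero_max_gap(self):
        res = compute_esdmt(response_log([5.0], [True]))
        assert res.n_correct == 1 and res.max_gap == 0.0

    def test_response_after_duration_rejected(self):
        with pytest.raises(ValueError):
            compute_esdmt(response_log([95.0], [True]))

    def test_incorrect_responses_do_not_count(self):
        log = response_log([10.0, 20.0, 30.0], [True, False, True])
        assert compute_esdmt(log).n_correct == 2

    def test_half_rate_thinning_halves_sfi(self, rng):
        # Poisson process at rate 0.4/s thinned to 0.2/s after 60 s;
        # analytic rate ratio oracle: E[SFI30] ~= 0.5
        vals = []
        for _ in range(500):
            t1 = np.sort(rng.uniform(0, 60, rng.poisson(0.4 * 60)))
            t2 = np.sort(rng.uniform(60, 90, rng.poisson(0.2 * 30)))
            t = np.concatenate([t1, t2])
            vals.append(compute_esdmt(response_log(t, [True] * len(t))).sfi30)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------- Draw a Shape

class TestDrawShape:
    def test_perfect_circle_has_full_accuracy(self):
        st = simulate_draw_shape_stream(PERFECT, "circle", 0, duration=2.0)
        res = compute_draw_shape(st, "circle")
        assert res.accuracy == pytest.approx(1.0)
        assert res.celerity == pytest.approx(0.5, rel=1e-6)

    def test_constant_speed_trace_has_zero_linear_cv(self):
        # straight-line trace at exactly constant speed
        n = 50
        t = np.linspace(0.0, 1.0, n)
        x = np.linspace(100.0, 500.0, n)
        st = SensorStream.touch(t, x, x, np.zeros(n, int),
                                [DOWN] + [MOVE] * (n - 2) + [UP])
        res = compute_draw_shape(st, "line1")
        assert res.cv_linear == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(res.cv_angular)  # not a round shape

    def test_known_segment_speeds_closed_form(self):
        # speeds {1, 2, 3} px/s with equal dt: CV = pop-SD/mean = 0.40825
        t = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.array([0.0, 1.0, 3.0, 6.0])
        st = SensorStream.touch(t, x, np.zeros(4), np.zeros(4, int),
                                [DOWN, MOVE, MOVE, UP])
        res = compute_draw_shape(st, "line1")
        expected = np.std([1, 2, 3]) / np.mean([1, 2, 3])
        assert res.cv_linear == pytest.approx(expected, rel=1e-12)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            simulate_draw_shape_stream(0.0, "triangle", 0)

    def test_degraded_skill_increases_velocity_cv(self):
        # paired comparison over 50 seeds: 3-SD-degraded skill must show
        # strictly larger speed variability than flawless drawing
        worse = 0
        for seed in range(50):
            lo = compute_draw_shape(
                simulate_draw_shape_stream(PERFECT, "circle", seed), "circle")
            hi = compute_draw_shape(
                simulate_draw_shape_stream(3.0, "circle", seed), "circle")
            worse += hi.cv_linear > lo.cv_linear
        assert worse == 50

    def test_timestamps_strictly_increasing(self):
        st = simulate_draw_shape_stream(2.0, "spiral", 3)
        assert np.all(np.diff(st.t) > 0)

    @pytest.mark.parametrize("scale", [0.25, 4.0])
    def test_cv_invariant_to_time_rescaling(self, scale):
        # rescaling time rescales every velocity by the same factor,
        # which cancels in SD/mean
        st = simulate_draw_shape_stream(1.0, "figure8", 5)
        res = compute_draw_shape(st, "figure8")
        st2 = SensorStream.touch(st.t * scale, st.x, st.y, st.pointer_id,
                                 st.phase, meta=st.meta)
        res2 = compute_draw_shape(st2, "figure8")
        for a, b in [(res.cv_linear, res2.cv_linear),
                     (res.cv_angular, res2.cv_angular),
                     (res.cv_radial, res2.cv_radial)]:
            assert a == pytest.approx(b, rel=1e-9)


# ---------------------------------------------------------------- Pinching

def _manual_pinch_stream(n_gestures=5, period=3.0, dur=1.0, asyn=0.0):
    ev = {"t": [], "x": [], "y": [], "pid": [], "ph": []}
    for k in range(n_gestures):
        t0 = k * period
        for pid, (x0, x1, td) in enumerate([(260.0, 290.0, t0),
                                            (340.0, 310.0, t0 + asyn)]):
            for t, x, ph in [(td, x0, DOWN), ((t0 + dur + td) / 2, (x0 + x1) / 2, MOVE),
                             (t0 + dur, x1, UP)]:
                ev["t"].append(t); ev["x"].append(x); ev["y"].append(300.0)
                ev["pid"].append(pid); ev["ph"].append(ph)
    order = np.argsort(ev["t"], kind="stable")
    return SensorStream.touch(np.array(ev["t"])[order], np.array(ev["x"])[order],
                              np.array(ev["y"])[order], np.array(ev["pid"])[order],
                              np.array(ev["ph"])[order])


class TestPinching:
    def test_simultaneous_contacts_give_zero_asynchrony(self):
        res = compute_pinching(_manual_pinch_stream(asyn=0.0))
        assert res.asynchrony == pytest.approx(0.0)

    def test_gap_time_from_constructed_intervals(self):
        # gestures start every 3 s and last 1 s -> median gap = 2 s
        res = compute_pinching(_manual_pinch_stream(period=3.0, dur=1.0))
        assert res.gap_time == pytest.approx(2.0)

    def test_empty_stream_yields_missing_not_zero(self):
        st = SensorStream.touch(np.zeros(0), np.zeros(0), np.zeros(0),
                                np.zeros(0, int), np.zeros(0, int))
        res = compute_pinching(st)
        assert res.n_success == 0
        assert np.isnan(res.gap_time) and np.isnan(res.asynchrony)

    def test_extraction_matches_generator_log(self):
        # the extracted asynchrony must equal the median of the planted
        # per-gesture values over successful pinches, recomputed from the
        # simulator's own log
        st = simulate_pinch_stream(0.5, 42)
        planted = st.meta["planted"]
        res = compute_pinching(st)
        expect = np.median([a for a, ok in zip(planted["asynchronies"],
                                               planted["success"]) if ok])
        assert res.asynchrony == pytest.approx(expect, abs=1e-9)
        assert res.n_success == sum(planted["success"])

    def test_fixed_asynchrony_recovered(self):
        st = simulate_pinch_stream(0.0, 7, fixed_asynchrony=0.1)
        assert compute_pinching(st).asynchrony == pytest.approx(0.1, abs=1e-9)


# ---------------------------------------------------------------- Static balance

class TestSwayPath:
    def test_constant_acceleration_gives_zero(self):
        t = np.linspace(0, 30, 1501)
        st = SensorStream.inertial(t, np.tile([[0.1, -0.2, 9.81]], (len(t), 1)))
        assert compute_sway_path(st) == 0.0

    def test_circular_trajectory_closed_form(self):
        # planar circular acceleration trajectory, k revolutions: path
        # length = 2*pi*r*k
        r, k = 0.4, 4
        t = np.linspace(0, 30, 6001)
        w = 2 * np.pi * k / 30
        a = np.column_stack([r * np.cos(w * t), r * np.sin(w * t),
                             9.81 * np.ones_like(t)])
        st = SensorStream.inertial(t, a)
        assert compute_sway_path(st) == pytest.approx(2 * np.pi * r * k, rel=0.01)

    def test_noise_amplitude_linearity(self):
        # doubling the balance-simulator noise amplitude doubles the
        # expected sway path (ratio over 50 seeds within 10%)
        lo, hi = [], []
        for seed in range(50):
            lo.append(compute_sway_path(
                simulate_inertial_stream("balance", seed, sway_amp=0.1)))
            hi.append(compute_sway_path(
                simulate_inertial_stream("balance", seed, sway_amp=0.2)))
        assert np.mean(hi) / np.mean(lo) == pytest.approx(2.0, rel=0.10)

    def test_zero_noise_stream_is_still(self):
        st = simulate_inertial_stream("balance", 0, sway_amp=0.0)
        assert compute_sway_path(st) == 0.0


# ---------------------------------------------------------------- Walking

class TestWalk:
    def test_pure_two_hertz_sinusoid(self):
        st = simulate_inertial_stream("walk", 0, f0=2.0, noise=0.0, duration=60)
        res = compute_walk(st)
        assert res.step_freq == pytest.approx(2.0, abs=0.02)
        assert res.step_freq_var <= 1e-3

    def test_flat_stream_has_no_steps(self):
        t = np.linspace(0, 120, 6001)
        st = SensorStream.inertial(t, np.tile([[0, 0, 9.81]], (len(t), 1)))
        res = compute_walk(st)
        assert np.isnan(res.step_freq)

    def test_alternating_cadence_raises_variance(self):
        # cadence alternating 1.8/2.2 Hz vs constant 2.0 Hz
        def alt(t):
            return 1.8 if int(t / 5) % 2 == 0 else 2.2
        st_alt = simulate_inertial_stream("walk", 1, noise=0.0, duration=60,
                                          freq_fn=alt)
        st_const = simulate_inertial_stream("walk", 1, f0=2.0, noise=0.0,
                                            duration=60)
        r_alt, r_const = compute_walk(st_alt), compute_walk(st_const)
        assert r_alt.step_freq == pytest.approx(2.0, abs=0.05)
        assert r_alt.step_freq_var > r_const.step_freq_var

    def test_short_stream_rejected(self):
        st = simulate_inertial_stream("walk", 0, duration=5.0)
        with pytest.raises(ValueError):
            compute_walk(st)

    def test_step_power_closed_form(self):
        # sinusoid amplitude a0 at f Hz: per-step integral of a^2 over one
        # period-per-step is a0^2/(2 f)
        a0, f = 1.5, 2.0
        st = simulate_inertial_stream("walk", 0, f0=f, a0=a0, noise=0.0,
                                      duration=60)
        res = compute_walk(st)
        assert res.step_power == pytest.approx(a0 ** 2 / (2 * f), rel=0.05)


# ---------------------------------------------------------------- U-turns

def _turn_stream(angles_durations, fs=50.0, gap=5.0):
    total = gap + sum(d + gap for _, d in angles_durations)
    n = int(total * fs) + 1
    t = np.arange(n) / fs
    yr = np.zeros(n)
    c = gap
    for angle, d in angles_durations:
        sel = (t >= c) & (t <= c + d)
        yr[sel] = angle / d
        c += d + gap
    return SensorStream.inertial(t, np.tile([[0, 0, 9.81]], (n, 1)), yaw_rate=yr)


class TestTurnSpeed:
    def test_five_pi_turns_in_two_seconds(self):
        st = _turn_stream([(np.pi, 2.0)] * 5)
        assert compute_turn_speed(st) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_zero_yaw_rate_is_missing(self):
        st = _turn_stream([])
        assert np.isnan(compute_turn_speed(st))

    def test_median_over_heterogeneous_turns(self):
        # pi rad over {1, 2, 4} s -> speeds {pi, pi/2, pi/4}, median pi/2
        st = _turn_stream([(np.pi, 1.0), (np.pi, 2.0), (np.pi, 4.0)])
        assert compute_turn_speed(st) == pytest.approx(np.pi / 2, rel=1e-3)

    def test_simulated_uturn_bursts_detected(self):
        # threshold detection trims the smooth burst's tails, so the
        # extracted speed slightly exceeds pi/duration but stays monotone
        fast = compute_turn_speed(
            simulate_inertial_stream("uturn", 3, turn_duration=1.5, noise=0.0))
        slow = compute_turn_speed(
            simulate_inertial_stream("uturn", 3, turn_duration=3.0, noise=0.0))
        assert np.pi / 1.5 <= fast <= 1.5 * np.pi / 1.5
        assert np.pi / 3.0 <= slow <= 1.5 * np.pi / 3.0
        assert fast > slow


# ---------------------------------------------------------------- invariants

class TestExtractorInvariants:
    def test_time_translation_invariance(self):
        """All stream extractors are unchanged by a uniform time shift."""
        shift = 37.5

        def close(a, b):
            return np.allclose(np.atleast_1d(a), np.atleast_1d(b),
                               rtol=1e-9, atol=1e-12, equal_nan=True)

        draw = simulate_draw_shape_stream(1.0, "circle", 9)
        assert close(compute_draw_shape(draw, "circle"),
                     compute_draw_shape(draw.time_shifted(shift), "circle"))
        pinch = simulate_pinch_stream(0.5, 9)
        assert close(compute_pinching(pinch),
                     compute_pinching(pinch.time_shifted(shift)))
        for kind, fn in [("balance", compute_sway_path),
                         ("walk", compute_walk)]:
            st = simulate_inertial_stream(kind, 9,
                                          duration=30 if kind == "balance" else 60)
            assert close(fn(st), fn(st.time_shifted(shift)))
        ut = simulate_inertial_stream("uturn", 9)
        assert close(compute_turn_speed(ut),
                     compute_turn_speed(ut.time_shifted(shift)))

    def test_registry_covers_all_sixteen_measures(self):
        assert len(DIGITAL_MEASURES) == 16
        # direction-of-better metadata: worse-is-higher for variability
        worse = {m.name for m in DIGITAL_MEASURES if not m.higher_is_better}
        assert {"draw_cv_linear", "sbt_sway_path", "esdmt_max_gap",
                "pinch_asynchrony", "walk_step_freq_var",
                "pinch_gap_time", "draw_cv_angular", "draw_cv_radial"} == worse

    def test_extract_record_per_test_type(self, small_cohort):
        by_type = {}
        for rec in small_cohort.records:
            by_type.setdefault(rec.test_type, rec)
        names = set()
        for rec in by_type.values():
            out = extract_record(rec)
            names |= set(out)
            assert all(np.isfinite(v) or np.isnan(v) for v in out.values())
        assert names == {m.name for m in DIGITAL_MEASURES}
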