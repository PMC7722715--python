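"""Schedule generation, the gaze simulator's generative laws, staircase."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oculorate.hypotheses import BLOCK_DISTRIBUTIONS
from oculorate.synthdata import (
    SimParams,
    build_schedule,
    run_staircase,
    session_block_sequence,
    simulate_gaze,
    weibull_observer,
)


class TestSchedules:
    @pytest.mark.parametrize("n", [5, 80, 400])
    @pytest.mark.parametrize("block_type", sorted(BLOCK_DISTRIBUTIONS))
    def test_exact_multinomial_counts(self, block_type, n):
        """Foreperiod counts are exact fractions of the block design."""
        sched = build_schedule(block_type, n, seed=3)
        counts = Counter(t.foreperiod_ms for t in sched)
        dist = BLOCK_DISTRIBUTIONS[block_type]
        for s, p in zip(dist.support, dist.probs):
            assert counts.get(s, 0) == round(n * p)
        assert len(sched) == n

    def test_table_examples(self):
        c = Counter(t.foreperiod_ms for t in build_schedule("high_certainty_1s", 80, 0))
        assert c == {1000: 64, 2000: 16}
        c = Counter(t.foreperiod_ms for t in build_schedule("full_certainty_2s", 80, 0))
        assert c == {2000: 80}
        c = Counter(t.foreperiod_ms for t in build_schedule("low_certainty", 80, 0))
        assert c == {fp: 16 for fp in (1000, 1500, 2000, 2500, 3000)}

    def test_indivisible_n_rejected_naming_divisor(self):
        with pytest.raises(ValueError, match="5"):
            build_schedule("high_certainty_1s", 7, seed=0)

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError, match="block_type"):
            build_schedule("medium_certainty", 10, seed=0)

    def test_timing_invariants(self):
        sched = build_schedule("low_certainty", 20, seed=9)
        for tr in sched:
            assert tr.target_onset_ms - tr.cue_onset_ms == tr.foreperiod_ms
            assert 700 <= tr.iti_ms <= 1200
        onsets = [t.cue_onset_ms for t in sched]
        assert onsets == sorted(onsets)

    def test_order_shuffled_by_seed(self):
        a = [t.foreperiod_ms for t in build_schedule("low_certainty", 20, seed=1)]
        b = [t.foreperiod_ms for t in build_schedule("low_certainty", 20, seed=1)]
        c = [t.foreperiod_ms for t in build_schedule("low_certainty", 20, seed=2)]
        assert a == b
        assert a != c  # 20!/(4!)^5 orderings; collision essentially impossible

    def test_session_structure(self):
        seq = session_block_sequence()
        assert len(seq) == 17
        assert Counter(seq) == {
            "full_certainty_1s": 1,
            "full_certainty_2s": 1,
            "high_certainty_1s": 5,
            "high_certainty_2s": 5,
            "low_certainty": 5,
        }


class TestSimulator:
    def test_zero_rates_produce_no_events(self):
        params = SimParams(base_saccade_rate=0.0, blink_rate=0.0)
        sched = build_schedule("full_certainty_1s", 5, seed=0)
        rec, truth = simulate_gaze(sched, params, np.random.default_rng(0))
        assert truth.n_saccades == 0
        assert truth.blink_intervals_ms == []
        assert np.isfinite(rec.xL).all()

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            simulate_gaze([], SimParams(), np.random.default_rng(0))

    def test_depth_zero_pretarget_rate_equals_base_rate(self):
        """Without inhibition the realized pre-target onset rate matches
        base_saccade_rate within sampling error (dead-time-corrected
        Bernoulli process)."""
        params = SimParams(inhibition_depth=0.0, blink_rate=0.0)
        sched = build_schedule("full_certainty_1s", 100, seed=1)
        rng = np.random.default_rng(5)
        count, trials = 0, 0
        for _ in range(20):  # 2000 trials
            _, truth = simulate_gaze(sched, params, rng)
            on = truth.saccade_onsets_ms
            for tr in sched:
                count += int(
                    ((on >= tr.target_onset_ms - 100) & (on <= tr.target_onset_ms)).sum()
                )
            trials += len(sched)
        rate = count / (trials * 0.101)
        se = math.sqrt(count) / (trials * 0.101)
        assert abs(rate - params.base_saccade_rate) < 4 * se

    def test_poisson_concentration_of_total_count(self):
        """Total event count over T seconds at constant rate r stays within
        4*sqrt(rT) of rT."""
        params = SimParams(inhibition_depth=0.0, blink_rate=0.0)
        sched = build_schedule("low_certainty", 40, seed=2)
        _, truth = simulate_gaze(sched, params, np.random.default_rng(3))
        T = (sched[-1].target_onset_ms + 600) / 1000.0
        expected = params.base_saccade_rate * T
        assert expected > 100
        assert abs(truth.n_saccades - expected) < 4 * math.sqrt(expected)

    def test_main_sequence_exact_without_noise(self):
        """Zero main-sequence noise -> log amplitude and log peak velocity
        correlate perfectly."""
        params = SimParams(main_sequence_noise_sd=0.0, blink_rate=0.0)
        sched = build_schedule("low_certainty", 20, seed=4)
        _, truth = simulate_gaze(sched, params, np.random.default_rng(4))
        assert truth.n_saccades > 30
        r = np.corrcoef(
            np.log(truth.saccade_amplitudes_deg),
            np.log(truth.saccade_peak_velocities_dps),
        )[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_ground_truth_pretarget_ordering_follows_orienting_law(self):
        """With inhibition on, ground-truth pre-target rates order as the
        temporal-orienting account predicts (parameter-recovery
        precondition). A 300 ms pre-target window is used: the anticipation
        driving the rate is constant over the final 300 ms of every 1 s and
        2 s foreperiod, and the wider window shrinks counting noise."""
        params = SimParams(blink_rate=0.0)
        rng = np.random.default_rng(11)
        specs = {
            "full@1s": ("full_certainty_1s", 1000),
            "freq@1s": ("high_certainty_1s", 1000),
            "rare@1s": ("high_certainty_2s", 1000),
            "low@1s": ("low_certainty", 1000),
            "full@2s": ("full_certainty_2s", 2000),
            "low@2s": ("low_certainty", 2000),
        }
        blocks = sorted({b for b, _ in specs.values()})
        counts = {k: [0, 0] for k in specs}
        window_s = 0.301
        for rep in range(4):
            for bi, block in enumerate(blocks):
                sched = build_schedule(block, 100, seed=100 * rep + bi)
                _, truth = simulate_gaze(sched, params, rng)
                on = truth.saccade_onsets_ms
                for key, (b, fp) in specs.items():
                    if b != block:
                        continue
                    for tr in sched:
                        if tr.foreperiod_ms != fp:
                            continue
                        counts[key][0] += int(
                            (
                                (on >= tr.target_onset_ms - 300)
                                & (on <= tr.target_onset_ms)
                            ).sum()
                        )
                        counts[key][1] += 1
        rates = {k: c / (ntr * window_s) for k, (c, ntr) in counts.items()}
        se = {
            k: math.sqrt(max(c, 1)) / (ntr * window_s)
            for k, (c, ntr) in counts.items()
        }
        # inequalities must clear their combined counting noise
        for lo, hi in [("full@1s", "freq@1s"), ("freq@1s", "rare@1s"),
                       ("full@2s", "low@2s")]:
            assert rates[hi] - rates[lo] > 2 * math.hypot(se[lo], se[hi])
        # predicted equality: rare@1s vs low@1s within 3 SE
        assert abs(rates["rare@1s"] - rates["low@1s"]) < 3 * math.hypot(
            se["rare@1s"], se["low@1s"]
        )

    def test_blink_signature(self):
        params = SimParams(blink_rate=0.5, base_saccade_rate=0.5)
        sched = build_schedule("full_certainty_2s", 10, seed=6)
        rec, truth = simulate_gaze(sched, params, np.random.default_rng(6))
        assert truth.blink_intervals_ms
        for on, off in truth.blink_intervals_ms:
            assert np.all(rec.pupilL[on : off + 1] == 0.0)
            assert np.all(np.isnan(rec.xL[on : off + 1]))
        # non-overlap
        ivals = truth.blink_intervals_ms
        assert all(b[0] > a[1] for a, b in zip(ivals, ivals[1:]))


class TestStaircase:
    def test_step_observer_converges_into_bracket(self):
        obs = lambda tilt: 1.0 if tilt >= 1.0 else 0.0  # noqa: E731
        th, state = run_staircase(obs, seed=0)
        assert 10**-0.15 <= th <= 10**0.15
        assert state.reversal_count == 4

    def test_always_correct_hits_trial_cap(self):
        th, state = run_staircase(lambda t: 1.0, seed=0)
        assert state.trial_count == 100
        assert state.reversal_count == 0
        assert th < 15.0

    @given(st.integers(0, 2**31 - 1), st.floats(0.3, 5.0), st.floats(1.0, 5.0))
    def test_always_terminates(self, seed, alpha, beta):
        obs = weibull_observer(threshold_deg=alpha, slope=beta)
        _, state = run_staircase(obs, seed=seed)
        assert state.trial_count <= 100
        assert state.reversal_count <= 4

    def test_nonpositive_start_rejected(self):
        with pytest.raises(ValueError):
            run_staircase(lambda t: 1.0, start_tilt=0.0, seed=0)

    def test_history_records_every_trial(self):
        obs = weibull_observer()
        _, state = run_staircase(obs, seed=3)
        assert len(state.history) == state.trial_count
        tilts = [h[0] for h in state.history]
        assert all(t > 0 for t in tilts)
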