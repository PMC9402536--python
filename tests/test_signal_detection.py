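"""ROC areas, preference assignment, neurometric functions and choice probability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plaidchoice as pc

from conftest import make_session_from_rows, make_unit, roc_area_bruteforce


class TestRocArea:
    def test_identical_distributions_give_half(self):
        assert pc.roc_area([3, 5, 7], [3, 5, 7]) == 0.5

    def test_pairwise_example(self):
        # brute force over all 9 pairs: 6 wins
        assert pc.roc_area([5, 7, 9], [4, 6, 8]) == pytest.approx(6 / 9)

    def test_tie_credited_half(self):
        # pairs: (2,2)x2 ties, (2,0)x2 wins -> (2 + 2*0.5)/4
        assert pc.roc_area([2, 2], [2, 0]) == pytest.approx(0.75)

    def test_empty_rejected(self):
        with pytest.raises(pc.InputError):
            pc.roc_area([], [1.0])

    @given(st.integers(0, 100_000))
    @settings(max_examples=80, deadline=None)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pref = rng.integers(0, 12, size=rng.integers(1, 30))
        null = rng.integers(0, 12, size=rng.integers(1, 30))
        assert pc.roc_area(pref, null) == pytest.approx(
            roc_area_bruteforce(pref, null), abs=1e-12
        )

    @given(st.integers(0, 100_000))
    @settings(max_examples=40, deadline=None)
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=rng.integers(1, 15))
        b = rng.integers(0, 10, size=rng.integers(1, 15))
        assert pc.roc_area(a, b) + pc.roc_area(b, a) == pytest.approx(1.0, abs=1e-12)


def _regression_session(slope, n_per=6, intercept=10.0):
    rows = []
    for c in (-40.0, -20.0, 20.0, 40.0):
        for _ in range(n_per):
            rate = intercept + slope * c
            rows.append(
                {
                    "contrast": c,
                    "choice": "coherent" if c > 0 else "transparent",  # correct
                    "rewarded": True,
                    "count:u0": int(round(rate * 1.5)),
                }
            )
    return make_session_from_rows(rows)


class TestAssignPreference:
    def test_positive_slope_prefers_coherent(self):
        a = pc.assign_preference(_regression_session(0.1), "u0", 90.0)
        assert a.preferred_cue == "coherent" and a.regression_slope > 0

    def test_negative_slope_prefers_transparent(self):
        a = pc.assign_preference(_regression_session(-0.1), "u0", 90.0)
        assert a.preferred_cue == "transparent"

    def test_constant_rates_indeterminate(self):
        a = pc.assign_preference(_regression_session(0.0), "u0", 90.0)
        assert a.preferred_cue == "indeterminate"

    def test_requires_two_nonzero_contrasts(self):
        rows = [
            {"contrast": 20.0, "choice": "coherent", "count:u0": 10}
            for _ in range(10)
        ]
        with pytest.raises(pc.InputError):
            pc.assign_preference(make_session_from_rows(rows), "u0", 90.0)


class TestNeurometric:
    def _simulated(self, slope_up, seed=0, gain=0.0, noise_sd=1.0):
        cfg = pc.SimConfig(n_units=1, trials_per_condition=40,
                           pattern_directions=(90.0,), decision_noise_sd=noise_sd,
                           seed=seed)
        unit = make_unit(slope_up=slope_up, gain_coupling=gain)
        session, _ = pc.simulate_session(cfg, [unit], seed + 1)
        return session

    def test_insensitive_unit_flagged_degenerate(self):
        session = self._simulated(slope_up=0.0)
        a = pc.PreferenceAssignment("u000", 90.0, "coherent", 1e-9, 100)
        res = pc.neurometric_function(session, a)
        aucs = [v[0] for v in res.roc_points.values()]
        assert max(abs(x - 0.5) for x in aucs) < 0.2
        assert res.degenerate

    def test_sensitive_unit_beats_behavior(self):
        """A steep low-noise unit yields a neurometric threshold below the
        session's psychometric threshold (N/P < 1)."""
        session = self._simulated(slope_up=1.2, seed=3)
        psych = pc.fit_psychometric(session)
        a = pc.assign_preference(session, "u000", 90.0)
        res = pc.neurometric_function(session, a, psychometric_threshold=psych.threshold)
        assert res.np_ratio is not None and res.np_ratio < 1.0

    def test_threshold_grows_with_count_noise(self):
        """Adding overdispersion to the counts raises the neurometric
        threshold (Monte-Carlo monotonicity over a small seed ensemble)."""
        lo, hi = [], []
        for seed in range(4):
            cfg = dict(n_units=1, trials_per_condition=40, pattern_directions=(90.0,),
                       seed=seed)
            unit = make_unit(slope_up=0.25)
            s_clean, _ = pc.simulate_session(pc.SimConfig(**cfg), [unit], 50 + seed)
            s_noisy, _ = pc.simulate_session(
                pc.SimConfig(**cfg, dispersion=0.4), [unit], 50 + seed
            )
            for s, acc in ((s_clean, lo), (s_noisy, hi)):
                a = pc.assign_preference(s, "u000", 90.0)
                acc.append(pc.neurometric_function(s, a).neuronal_threshold)
        assert np.mean(hi) > np.mean(lo)


def _cp_session(pref_counts, null_counts, contrast=0.0):
    rows = []
    for n in pref_counts:
        rows.append({"contrast": contrast, "choice": "coherent", "count:u0": n})
    for n in null_counts:
        rows.append({"contrast": contrast, "choice": "transparent", "count:u0": n})
    return make_session_from_rows(rows)


ASSIGN = pc.PreferenceAssignment("u0", 90.0, "coherent", 1.0, 100)


class TestChoiceProbability:
    def test_separated_counts_give_cp_one(self):
        s = _cp_session([20, 21, 22, 23, 24], [1, 2, 3, 4, 5])
        assert pc.choice_probability(s, ASSIGN, 0.0).cp == 1.0

    def test_four_choices_excluded_under_default_rule(self):
        s = _cp_session([10, 11, 12, 13], [1, 2, 3, 4, 5])
        res = pc.choice_probability(s, ASSIGN, 0.0)
        assert res.excluded and res.cp is None

    def test_relaxed_rule_allows_single_error(self):
        s = _cp_session([10, 11, 12, 13], [1])
        res = pc.choice_probability(s, ASSIGN, 0.0, min_choices=1)
        assert not res.excluded

    def test_preference_relabel_complements_cp(self):
        s = _cp_session([8, 12, 9, 14, 10, 3], [7, 5, 11, 2, 9, 6])
        flipped = pc.PreferenceAssignment("u0", 90.0, "transparent", -1.0, 100)
        cp = pc.choice_probability(s, ASSIGN, 0.0).cp
        cp_flip = pc.choice_probability(s, flipped, 0.0).cp
        assert cp + cp_flip == pytest.approx(1.0)


class TestGrandCP:
    def _session(self, seed=0):
        cfg = pc.SimConfig(n_units=1, trials_per_condition=30,
                           pattern_directions=(90.0,), seed=seed)
        unit = make_unit(gain_coupling=0.3)
        session, _ = pc.simulate_session(cfg, [unit], seed + 7)
        return session

    def test_condition_offsets_do_not_change_grand_cp(self):
        s = self._session()
        a = pc.assign_preference(s, "u000", 90.0)
        base = pc.grand_choice_probability(s, a).cp
        # add a large constant to every count of one condition
        mask = s.trials["contrast"] == 10.0
        s.trials.loc[mask, "count:u000"] += 1000
        assert pc.grand_choice_probability(s, a).cp == pytest.approx(base)

    def test_positive_scale_does_not_change_grand_cp(self):
        s = self._session(1)
        a = pc.assign_preference(s, "u000", 90.0)
        base = pc.grand_choice_probability(s, a).cp
        mask = s.trials["contrast"] == -5.0
        s.trials.loc[mask, "count:u000"] *= 7
        assert pc.grand_choice_probability(s, a).cp == pytest.approx(base)

    def test_contrast_cutoff_respected(self):
        s = self._session(2)
        a = pc.assign_preference(s, "u000", 90.0)
        res = pc.grand_choice_probability(s, a, max_contrast=20.0)
        assert all(abs(c) <= 20.0 for c in res.contrasts_used)

    def test_permutation_p_uniform_under_null(self):
        cfg = pc.SimConfig(n_units=1, contrast_set=(0.0,), trials_per_condition=60,
                           pattern_directions=(90.0,), pooling_weight=0.0)
        unit = make_unit(gain_coupling=0.0)
        session, _ = pc.simulate_session(cfg, [unit], 9)
        a = pc.PreferenceAssignment("u000", 90.0, "coherent", 1.0, 60)
        res = pc.grand_choice_probability(session, a, n_permutations=200, rng_seed=3)
        assert res.permutation_p > 0.01


@pytest.fixture(scope="module")
def timed_session():
    cfg = pc.SimConfig(
        n_units=2, contrast_set=(-10.0, 0.0, 10.0), trials_per_condition=25,
        pattern_directions=(90.0,), emit_spike_times=True, seed=31,
        coupling_window=(0.5, 1.5), gain_range=(0.4, 0.5),
        pooling_weight=1.5, decision_noise_sd=0.3,
    )
    units = pc.sample_units(cfg, 31)
    session, _ = pc.simulate_session(cfg, units, 32)
    return session


class TestTimecourse:
    def test_requires_spike_times(self, small_session):
        session, _ = small_session
        a = pc.PreferenceAssignment("u000", 90.0, "coherent", 1.0, 10)
        with pytest.raises(pc.InputError):
            pc.cp_timecourse(session, a)

    def test_full_epoch_window_equals_count_grand_cp(self, timed_session):
        s = timed_session
        a = pc.assign_preference(s, "u000", 90.0)
        dur_ms = s.stimulus_duration * 1000.0
        series = pc.cp_timecourse(
            s, a, window_ms=dur_ms, step_ms=2 * dur_ms,
            t_start_ms=0.0, t_end_ms=dur_ms,
        )
        assert len(series) == 1
        grand = pc.grand_choice_probability(s, a)
        assert series[0].cp == pytest.approx(grand.cp, abs=1e-12)

    def test_choice_signal_confined_to_coupling_window(self, timed_session):
        """Gain coupling gated to t > 500 ms: pre-stimulus and early windows
        hover at chance while late windows carry the choice signal."""
        s = timed_session
        cps = {}
        for u in s.units:
            a = pc.assign_preference(s, u, 90.0)
            if a.preferred_cue == "indeterminate":
                continue
            for pt in pc.cp_timecourse(s, a, window_ms=200.0, step_ms=100.0):
                if pt.cp is not None:
                    cps.setdefault(pt.time_ms, []).append(pt.cp)
        early = [np.mean(v) for t, v in cps.items() if t < 400.0]
        late = [np.mean(v) for t, v in cps.items() if 700.0 <= t <= 1400.0]
        assert abs(np.mean(early) - 0.5) < 0.08
        assert np.mean(late) - 0.5 > 0.1


class TestCpVsChoiceRatio:
    def test_few_points_omit_moving_average(self, small_session):
        session, _ = small_session
        assignments = []
        for d in (90.0, 270.0):
            try:
                assignments.append(pc.assign_preference(session, "u000", d))
            except pc.InputError:
                pass
        res = pc.cp_vs_choice_ratio(session, assignments, window=20)
        assert res.moving_average is None or len(res.pairs) >= 20
        assert {"choice_ratio", "cp"} <= set(res.pairs.columns)
        assert ((res.pairs["choice_ratio"] > 0) & (res.pairs["choice_ratio"] < 1)).all()

    def test_null_simulator_moving_average_near_half(self):
        cfg = pc.SimConfig(n_units=1, trials_per_condition=30, pooling_weight=0.0,
                           seed=13)
        unit = make_unit(gain_coupling=0.0)
        session, _ = pc.simulate_session(cfg, [unit], 14)
        assignments = [pc.assign_preference(session, "u000", d) for d in (90.0, 270.0)]
        res = pc.cp_vs_choice_ratio(session, assignments, window=10)
        if res.moving_average is not None:
            assert abs(res.moving_average["cp_mean"].mean() - 0.5) < 0.1
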