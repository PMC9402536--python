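"""Cumulative-Gaussian psychometric fitting and behavioral summaries."""

import numpy as np
import pytest
from scipy import stats

import plaidchoice as pc
from plaidchoice.psychometrics import CumulativeGaussianPsychometric, PsychometricFit

from conftest import make_session_from_rows

CONTRASTS = np.array([-80.0, -40.0, -20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0, 40.0, 80.0])


def _proportion_fit(mu, sigma, n_per=10_000):
    """Fit the exact generating proportions with large per-level counts."""
    p = stats.norm.cdf((CONTRASTS - mu) / sigma)
    est = CumulativeGaussianPsychometric()
    est.fit(CONTRASTS, p, sample_weight=np.full_like(CONTRASTS, n_per))
    return est


def test_parameter_recovery_from_exact_proportions():
    est = _proportion_fit(mu=5.0, sigma=20.0)
    assert est.mu_ == pytest.approx(5.0, abs=0.05)
    assert est.sigma_ == pytest.approx(20.0, abs=0.05)


def test_threshold_is_the_84_percent_point():
    est = _proportion_fit(mu=5.0, sigma=20.0)
    assert est.threshold_ == pytest.approx(est.mu_ + est.sigma_)
    assert est.predict(est.threshold_) == pytest.approx(stats.norm.cdf(1.0))
    assert stats.norm.cdf(1.0) == pytest.approx(0.8413, abs=5e-5)


def test_recovery_from_binary_draws_within_3se():
    rng = np.random.default_rng(42)
    mu, sigma, n_per = -3.0, 18.0, 300
    x = np.repeat(CONTRASTS, n_per)
    y = (rng.random(x.size) < stats.norm.cdf((x - mu) / sigma)).astype(float)
    est = CumulativeGaussianPsychometric().fit(x, y)
    assert abs(est.mu_ - mu) < 3 * est.se_mu_
    assert abs(est.sigma_ - sigma) < 3 * est.se_sigma_


def test_shift_equivariance():
    rng = np.random.default_rng(1)
    x = np.repeat(CONTRASTS, 50)
    y = (rng.random(x.size) < stats.norm.cdf(x / 15.0)).astype(float)
    a = CumulativeGaussianPsychometric().fit(x, y)
    b = CumulativeGaussianPsychometric().fit(x + 12.5, y)
    assert b.mu_ == pytest.approx(a.mu_ + 12.5, abs=1e-3)
    assert b.sigma_ == pytest.approx(a.sigma_, abs=1e-3)


def test_optimum_beats_moment_initializer():
    rng = np.random.default_rng(2)
    x = np.repeat(CONTRASTS, 30)
    y = (rng.random(x.size) < stats.norm.cdf((x - 4) / 25.0)).astype(float)
    est = CumulativeGaussianPsychometric().fit(x, y)
    assert est.log_likelihood_ >= est.init_log_likelihood_ - 1e-9


def test_all_one_choice_raises_degenerate_with_fit():
    x = np.repeat(CONTRASTS, 5)
    y = np.ones_like(x)
    with pytest.raises(pc.DegenerateFitError) as exc:
        CumulativeGaussianPsychometric().fit(x, y)
    assert exc.value.fit is not None


def test_flat_choice_data_flags_sigma_bound():
    """P = 0.5 at every contrast: no contrast dependence, sigma runs to the
    upper bound and the fit is flagged degenerate."""
    est = CumulativeGaussianPsychometric()
    est.fit(CONTRASTS, np.full_like(CONTRASTS, 0.5), sample_weight=np.full_like(CONTRASTS, 100))
    assert est.degenerate_
    assert est.sigma_ == pytest.approx(est.sigma_bounds[1], rel=1e-6)


def test_fewer_than_two_contrasts_rejected():
    with pytest.raises(pc.InputError):
        CumulativeGaussianPsychometric().fit([5.0, 5.0], [0.0, 1.0])


def test_fit_psychometric_recovers_generator_sigma(default_session):
    cfg, units, session, truth = default_session
    fit = pc.fit_psychometric(session)
    assert fit.pattern_direction == "pooled"
    assert abs(fit.mu - truth.psychometric_mu) < 4 * fit.se_mu
    assert abs(fit.sigma - truth.psychometric_sigma) < 4 * fit.se_sigma
    assert 0.0 <= fit.r_squared <= 1.0


def test_session_qc_thresholding():
    fit = PsychometricFit(0, 1, 1, 1, r_squared=1.0, n_trials=10,
                          log_likelihood=0.0, pattern_direction="pooled")
    assert pc.session_qc(fit)
    fit.r_squared = 0.0
    assert not pc.session_qc(fit)


class TestAngleEffect:
    def _fits(self, pses, slopes):
        return [
            PsychometricFit(mu, 1.0 / sl, mu + 1.0 / sl, sl, 0.9, 100, 0.0, "pooled")
            for mu, sl in zip(pses, slopes)
        ]

    def test_linear_pse_gives_unit_correlation(self):
        angles = [95.0, 105.0, 120.0, 130.0]
        fits = self._fits([2 * a - 100 for a in angles], [0.05] * 4)
        out = pc.angle_effect(fits, angles)
        assert out["pse"][0] == pytest.approx(1.0)

    def test_angle_independent_slope_uncorrelated(self):
        angles = [95.0, 105.0, 120.0, 130.0, 100.0, 125.0]
        rng = np.random.default_rng(3)
        slopes = 0.05 + 0.0001 * rng.standard_normal(6)
        fits = self._fits(rng.normal(0, 5, 6), slopes)
        out = pc.angle_effect(fits, angles)
        assert abs(out["slope"][0]) < 0.9  # no systematic relation

    def test_single_angle_rejected(self):
        fits = self._fits([0.0, 1.0, 2.0], [0.05] * 3)
        with pytest.raises(pc.InputError):
            pc.angle_effect(fits, [115.0, 115.0, 115.0])

    def test_simulator_angle_offset_recovered(self):
        """Sessions whose generative PSE shifts with the inter-grating angle
        show a positive PSE~angle correlation."""
        angles = [95.0, 100.0, 105.0, 120.0, 125.0, 130.0]
        fits = []
        for i, a in enumerate(angles):
            cfg = pc.SimConfig(n_units=1, inter_grating_angle=a,
                               trials_per_condition=30, seed=i)
            units = pc.sample_units(cfg, 100 + i)
            session, _ = pc.simulate_session(cfg, units, 200 + i)
            # angle-dependent cue offset: shift contrasts by 0.4 %/deg
            session.trials["contrast"] += 0.4 * (a - 95.0)
            fits.append(pc.fit_psychometric(session))
        out = pc.angle_effect(fits, angles)
        assert out["pse"][0] > 0.8


class TestChoiceHistoryBias:
    def _rows(self, choices, contrasts, rewarded):
        return [
            {"contrast": c, "choice": ch, "rewarded": rw, "count:u0": 5}
            for ch, c, rw in zip(choices, contrasts, rewarded)
        ]

    def test_all_repeats_give_one(self):
        rows = self._rows(
            ["coherent", "coherent", "coherent", "coherent"],
            [40.0, 0.0, 40.0, 0.0],
            [True, True, True, True],
        )
        out = pc.choice_history_bias(make_session_from_rows(rows))
        assert out["proportion_repeat"] == 1.0

    def test_alternation_gives_zero(self):
        rows = self._rows(
            ["coherent", "transparent", "coherent", "transparent"],
            [40.0, 0.0, 40.0, 0.0],
            [True, True, True, True],
        )
        out = pc.choice_history_bias(make_session_from_rows(rows))
        assert out["proportion_repeat"] == 0.0

    def test_no_qualifying_pairs_rejected(self):
        rows = self._rows(["coherent", "coherent"], [40.0, 40.0], [True, True])
        with pytest.raises(pc.InputError):
            pc.choice_history_bias(make_session_from_rows(rows))

    def test_simulator_has_no_history_term(self, default_session):
        _, _, session, _ = default_session
        out = pc.choice_history_bias(session)
        assert abs(out["proportion_repeat"] - 0.5) < 1.96 * 0.5 / np.sqrt(out["n"]) + 0.05
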