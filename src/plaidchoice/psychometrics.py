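"""Psychometric analysis: cumulative-Gaussian fits of coherent/transparent
choices against signed texture contrast, session QC, inter-grating-angle
effects and choice-history bias.

The model is a plain cumulative Gaussian, P(coherent | c) = Phi((c - mu)/sigma)
with no lapse or guess parameters, fit by Bernoulli maximum likelihood. The
point of subjective equality (PSE) is mu; the threshold is mu + sigma, the
contrast supporting ~84% (Phi(1) = 0.8413) coherent-preferred choices. "Slope"
is reported as 1/sigma: the function's maximal derivative up to the constant
phi(0), so that angle effects on bias (mu shifts) and sensitivity (sigma
changes) separate cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .data_io import Session
from .errors import DegenerateFitError, InputError


def _nll(params, x, y, w):
    mu, sigma = params
    p = stats.norm.cdf((x - mu) / sigma)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(w * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class CumulativeGaussianPsychometric(BaseEstimator):
    """Maximum-likelihood cumulative-Gaussian psychometric function.

    Accepts per-trial binary choices or per-level proportions with counts as
    ``sample_weight``. Deterministic: multi-start L-BFGS-B from a
    method-of-moments initializer plus a fixed spread grid.

    Parameters
    ----------
    sigma_bounds : (float, float)
        Box constraint on the spread. A fit on the upper bound is flagged
        degenerate (the data show no contrast dependence).
    n_sigma_starts : int
        Number of log-spaced multi-start values for sigma.

    Attributes
    ----------
    mu_ : float
        PSE (% contrast).
    sigma_ : float
        Spread (% contrast), > 0.
    threshold_ : float
        ``mu_ + sigma_``, the ~84% point.
    slope_ : float
        ``1 / sigma_``.
    r_squared_ : float
        R^2 between observed and fitted per-level proportions.
    log_likelihood_ : float
    se_mu_, se_sigma_ : float
        Asymptotic standard errors from the inverse observed information.
    degenerate_ : bool
        True when sigma_ sits on a bound.
    """

    def __init__(self, sigma_bounds=(1e-2, 1e4), n_sigma_starts=5):
        self.sigma_bounds = sigma_bounds
        self.n_sigma_starts = n_sigma_starts

    # -- initialization ----------------------------------------------------
    def _moments_init(self, x, y, w):
        """Probit-regression method of moments on per-level proportions."""
        levels, inv = np.unique(x, return_inverse=True)
        num = np.bincount(inv, weights=w * y)
        den = np.bincount(inv, weights=w)
        p = num / den
        z = stats.norm.ppf(np.clip(p, 0.05, 0.95))
        if np.ptp(levels) > 0 and np.ptp(z) > 1e-9:
            slope, icept = np.polyfit(levels, z, 1, w=np.sqrt(den))
            if slope > 1e-9:
                return float(-icept / slope), float(1.0 / slope)
        scale = max(np.ptp(levels), 1.0)
        return float(np.average(levels, weights=den)), float(scale)

    def fit(self, X, y, sample_weight=None):
        """Fit to contrasts ``X`` and choices/proportions ``y`` in [0, 1]."""
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise InputError("X and y must have equal length")
        w = (
            np.ones_like(x)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).ravel()
        )
        if np.unique(x).size < 2:
            raise InputError("need at least 2 distinct contrast levels")
        lo, hi = self.sigma_bounds

        mu0, sigma0 = self._moments_init(x, y, w)
        sigma0 = float(np.clip(sigma0, lo, hi))
        starts = [(mu0, sigma0)]
        for s in np.geomspace(max(sigma0 / 10, lo), min(sigma0 * 10, hi),
                              self.n_sigma_starts):
            starts.append((mu0, float(s)))

        best = None
        for start in starts:
            res = optimize.minimize(
                _nll, start, args=(x, y, w), method="L-BFGS-B",
                bounds=[(None, None), (lo, hi)],
            )
            if best is None or res.fun < best.fun:
                best = res
        self.mu_, self.sigma_ = map(float, best.x)
        self.log_likelihood_ = -float(best.fun)
        self.init_log_likelihood_ = -float(_nll((mu0, sigma0), x, y, w))
        self.degenerate_ = bool(
            np.isclose(self.sigma_, hi) or np.isclose(self.sigma_, lo)
        )
        self.threshold_ = self.mu_ + self.sigma_
        self.slope_ = 1.0 / self.sigma_
        self.n_trials_ = float(w.sum())

        # R^2 on per-level observed vs fitted proportions (unweighted)
        levels, inv = np.unique(x, return_inverse=True)
        p_obs = np.bincount(inv, weights=w * y) / np.bincount(inv, weights=w)
        p_fit = self.predict(levels)
        ss_res = np.sum((p_obs - p_fit) ** 2)
        ss_tot = np.sum((p_obs - p_obs.mean()) ** 2)
        self.r_squared_ = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0

        self._standard_errors(x, y, w)

        if np.all(y == 1.0) or np.all(y == 0.0):
            raise DegenerateFitError(
                "all choices identical; psychometric parameters unidentified",
                fit=self,
            )
        return self

    def _standard_errors(self, x, y, w):
        """Numerical observed information at the optimum."""
        theta = np.array([self.mu_, self.sigma_])
        h = np.maximum(np.abs(theta) * 1e-4, 1e-6)
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H[i, j] = (
                    _nll(tpp, x, y, w) - _nll(tpm, x, y, w)
                    - _nll(tmp, x, y, w) + _nll(tmm, x, y, w)
                ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            self.se_mu_, self.se_sigma_ = float(se[0]), float(se[1])
        except np.linalg.LinAlgError:
            self.se_mu_ = self.se_sigma_ = float("nan")

    def predict(self, X):
        """P(coherent) at contrasts ``X`` under the fitted function."""
        x = np.asarray(X, dtype=float)
        return stats.norm.cdf((x - self.mu_) / self.sigma_)

    @staticmethod
    def model(x, mu, sigma):
        """The model function Phi((x - mu)/sigma) itself."""
        return stats.norm.cdf((np.asarray(x, dtype=float) - mu) / sigma)


@dataclass
class PsychometricFit:
    """Summary of one session x direction cumulative-Gaussian fit."""

    mu: float  # PSE, % contrast
    sigma: float  # % contrast, > 0
    threshold: float  # mu + sigma
    slope: float  # 1 / sigma
    r_squared: float
    n_trials: float
    log_likelihood: float
    pattern_direction: object  # a direction in degrees, or "pooled"
    se_mu: float = float("nan")
    se_sigma: float = float("nan")
    degenerate: bool = False

    @classmethod
    def from_estimator(cls, est: CumulativeGaussianPsychometric, pattern_direction):
        return cls(
            mu=est.mu_, sigma=est.sigma_, threshold=est.threshold_,
            slope=est.slope_, r_squared=est.r_squared_, n_trials=est.n_trials_,
            log_likelihood=est.log_likelihood_, pattern_direction=pattern_direction,
            se_mu=est.se_mu_, se_sigma=est.se_sigma_, degenerate=est.degenerate_,
        )


def fit_psychometric(
    session: Session,
    pattern_direction=None,
    estimator: Optional[CumulativeGaussianPsychometric] = None,
) -> PsychometricFit:
    """Fit P(coherent | signed contrast) for one direction (or pooled).

    Zero-contrast trials are included: correctness is undefined there but the
    choice is not, and they inform the PSE.
    """
    df = session.select(pattern_direction=pattern_direction)
    if len(df) == 0:
        raise InputError(f"no trials for pattern_direction={pattern_direction}")
    est = estimator if estimator is not None else CumulativeGaussianPsychometric()
    x = df["contrast"].to_numpy(float)
    y = (df["choice"].to_numpy() == "coherent").astype(float)
    label = "pooled" if pattern_direction is None else pattern_direction
    est.fit(x, y)
    return PsychometricFit.from_estimator(est, label)


def session_qc(fit: PsychometricFit, r2_min: float = 0.6) -> bool:
    """Accept a session fit iff its R^2 meets the configurable cutoff."""
    return bool(fit.r_squared >= r2_min)


def normalized_angles(angles, angle_set=None) -> np.ndarray:
    """Min-max normalization of inter-grating angles over the configured set."""
    angles = np.asarray(angles, dtype=float)
    ref = angles if angle_set is None else np.asarray(angle_set, dtype=float)
    span = ref.max() - ref.min()
    if span == 0:
        raise InputError("cannot normalize: a single inter-grating angle")
    return (angles - ref.min()) / span


def angle_effect(fits: Sequence[PsychometricFit], angles, angle_set=None) -> dict:
    """Correlate PSE and slope with normalized inter-grating angle.

    Returns ``{"pse": (r, p), "slope": (r, p)}`` (Pearson, two-sided). A
    shifting-without-steepening pattern appears as a significant PSE
    correlation with a flat slope correlation.
    """
    if len(fits) < 3:
        raise InputError("need >= 3 session fits")
    norm = normalized_angles(angles, angle_set)
    out = {}
    for name, vals in (
        ("pse", np.array([f.mu for f in fits])),
        ("slope", np.array([f.slope for f in fits])),
    ):
        if np.std(vals) == 0:  # constant outcome: correlation undefined
            out[name] = (float("nan"), float("nan"))
        else:
            r, p = stats.pearsonr(norm, vals)
            out[name] = (float(r), float(p))
    return out


def choice_history_bias(session: Session) -> dict:
    """Tendency of zero-contrast choices to repeat the previously rewarded choice.

    Considers zero-contrast trials whose immediately preceding trial was
    rewarded; reports the fraction whose choice repeats that previous choice,
    with a two-sided binomial test against 0.5.
    """
    df = session.trials.reset_index(drop=True)
    prev_rewarded = df["rewarded"].shift(1).to_numpy()
    prev_rewarded = np.array([bool(v) and v == v for v in prev_rewarded])
    prev_choice = df["choice"].shift(1)
    qualifying = (df["contrast"] == 0) & prev_rewarded & prev_choice.notna()
    if qualifying.sum() == 0:
        raise InputError("no zero-contrast trials following a rewarded trial")
    repeats = (df.loc[qualifying, "choice"] == prev_choice[qualifying]).to_numpy()
    n, k = int(repeats.size), int(repeats.sum())
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return {"proportion_repeat": k / n, "n": n, "p_value": float(p)}
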