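"""Direction-tuning characterization and pattern/component classification.

A unit's grating tuning curve yields two predictions for its plaid tuning
(plaids built from two gratings 135 deg apart, indexed by pattern direction):

* **pattern prediction** — plaid tuning identical to grating tuning (the unit
  signals the global 2-D pattern motion);
* **component prediction** — the sum of the responses to each component
  grating, i.e. the grating curve evaluated at +/-67.5 deg from each pattern
  direction (baseline subtracted before summing and added back once).

Partial correlations of the measured plaid curve with the two predictions
(each controlling for the other), Fisher-transformed to z-scores, classify the
unit: pattern iff Zp exceeds max(Zc, 0) by 1.28 (the one-tailed p = 0.1
criterion), component symmetrically, otherwise unclassified. The pattern index
PI = Zp - Zc is the continuous version of the same axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from ._utils import von_mises_shape, wrap_degrees
from .data_io import TuningBlock, TUNING_PLAID_ANGLE
from .errors import InputError, UndefinedCorrelationError

#: z-difference criterion for classification, the one-tailed p = 0.1 point
CLASSIFICATION_CRITERION = 1.28

#: |r| clamp applied before Fisher transformation and partials (logged)
R_CLAMP = 0.9999


class VonMisesTuning(BaseEstimator):
    """Least-squares Von Mises fit b + a*exp(kappa*(cos(theta - mu) - 1)).

    Deterministic: multi-start over the sampled direction grid. Flat curves
    (variance ~ 0) are flagged untuned with the preferred direction undefined.

    Attributes
    ----------
    preferred_direction_ : float (deg); nan when untuned
    kappa_ : float, >= 0
    amplitude_ : float (spikes/s)
    baseline_ : float (spikes/s)
    fwhm_ : float (deg); 2*acos(1 - ln2/kappa) when kappa >= ln2/2, else 360
    rss_ : float
    untuned_ : bool
    """

    def __init__(self, flat_tol: float = 1e-9):
        self.flat_tol = flat_tol

    def fit(self, X, y):
        """Fit to directions ``X`` (deg) and mean rates ``y`` (spikes/s)."""
        theta = np.asarray(X, dtype=float).ravel()
        rates = np.asarray(y, dtype=float).ravel()
        if theta.size != rates.size or theta.size < 4:
            raise InputError("need matching direction/rate arrays of length >= 4")
        if np.var(rates) <= self.flat_tol:
            self.untuned_ = True
            self.preferred_direction_ = float("nan")
            self.kappa_ = 0.0
            self.amplitude_ = 0.0
            self.baseline_ = float(rates.mean())
            self.fwhm_ = 360.0
            self.rss_ = float(np.sum((rates - rates.mean()) ** 2))
            return self

        def residuals(params):
            b, a, kappa, mu = params
            return b + a * von_mises_shape(theta, mu, kappa) - rates

        best = None
        b0, a0 = float(rates.min()), float(np.ptp(rates))
        for mu0 in theta:
            res = optimize.least_squares(
                residuals,
                x0=[b0, a0, 2.0, mu0],
                bounds=([-np.inf, 0.0, 0.0, -np.inf], [np.inf, np.inf, 500.0, np.inf]),
            )
            if best is None or res.cost < best.cost:
                best = res
        b, a, kappa, mu = best.x
        self.untuned_ = False
        self.baseline_ = float(b)
        self.amplitude_ = float(a)
        self.kappa_ = float(kappa)
        self.preferred_direction_ = float(wrap_degrees(mu))
        self.fwhm_ = float(
            2.0 * np.degrees(np.arccos(1.0 - np.log(2.0) / kappa))
            if kappa >= np.log(2.0) / 2.0
            else 360.0
        )
        self.rss_ = float(2.0 * best.cost)
        return self

    def predict(self, X):
        theta = np.asarray(X, dtype=float)
        if self.untuned_:
            return np.full_like(theta, self.baseline_, dtype=float)
        return self.baseline_ + self.amplitude_ * von_mises_shape(
            theta, self.preferred_direction_, self.kappa_
        )


@dataclass
class VonMisesFit:
    """Summary of one unit's grating direction tuning."""

    preferred_direction: float  # deg
    kappa: float
    amplitude: float  # spikes/s
    baseline_param: float  # spikes/s
    fwhm: float  # deg
    rss: float
    untuned: bool = False


def fit_von_mises(block: TuningBlock, estimator: Optional[VonMisesTuning] = None) -> VonMisesFit:
    """Fit a Von Mises function to the mean rates of a grating tuning block."""
    if block.stimulus_class != "grating":
        raise InputError("Von Mises fits are defined on grating blocks")
    est = estimator if estimator is not None else VonMisesTuning()
    est.fit(block.directions, block.mean_rates)
    return VonMisesFit(
        preferred_direction=est.preferred_direction_,
        kappa=est.kappa_,
        amplitude=est.amplitude_,
        baseline_param=est.baseline_,
        fwhm=est.fwhm_,
        rss=est.rss_,
        untuned=est.untuned_,
    )


def _circular_interp(query_deg, grid_deg, values) -> np.ndarray:
    """Linear interpolation on the circle; exact at grid points."""
    grid = np.asarray(grid_deg, dtype=float)
    vals = np.asarray(values, dtype=float)
    period = 360.0
    q = np.asarray(query_deg, dtype=float) % period
    ext_grid = np.concatenate([grid, [grid[0] + period]])
    ext_vals = np.concatenate([vals, [vals[0]]])
    return np.interp(q, ext_grid, ext_vals)


def pattern_prediction(grating: TuningBlock) -> np.ndarray:
    """Pattern prediction: the grating curve itself, indexed by pattern direction."""
    return grating.mean_rates.copy()


def component_prediction(
    grating: TuningBlock, inter_grating_angle: float = TUNING_PLAID_ANGLE
) -> np.ndarray:
    """Component prediction: sum of baseline-subtracted grating responses at the
    two component directions (pattern direction +/- half the inter-grating
    angle), baseline added back once. Offsets are multiples of the 22.5 deg
    sampling at the default 135 deg angle, so interpolation is exact there."""
    half = inter_grating_angle / 2.0
    b = grating.baseline_rate
    r_minus = _circular_interp(grating.directions - half, grating.directions, grating.mean_rates)
    r_plus = _circular_interp(grating.directions + half, grating.directions, grating.mean_rates)
    return (r_minus - b) + (r_plus - b) + b


def _corr(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a zero-variance curve")
    return float(np.corrcoef(a, b)[0, 1])


def partial_correlations(plaid_means, pattern_pred, component_pred):
    """Partial correlations (Rp, Rc) of a plaid curve with the two predictions.

    Rp = (rp - rc*rpc) / sqrt((1 - rc^2)(1 - rpc^2)) and symmetrically for Rc,
    where rp, rc correlate the data with each prediction and rpc the
    predictions with each other. Raw correlations are clamped to +/-0.9999
    so perfect matches stay finite.
    """
    plaid = np.asarray(plaid_means, dtype=float)
    pat = np.asarray(pattern_pred, dtype=float)
    comp = np.asarray(component_pred, dtype=float)
    if not (plaid.size == pat.size == comp.size):
        raise InputError("curves must have equal length")
    rp = np.clip(_corr(plaid, pat), -R_CLAMP, R_CLAMP)
    rc = np.clip(_corr(plaid, comp), -R_CLAMP, R_CLAMP)
    rpc = np.clip(_corr(pat, comp), -R_CLAMP, R_CLAMP)
    r_pattern = (rp - rc * rpc) / np.sqrt((1.0 - rc**2) * (1.0 - rpc**2))
    r_component = (rc - rp * rpc) / np.sqrt((1.0 - rp**2) * (1.0 - rpc**2))
    return float(r_pattern), float(r_component)


def fisher_z(r: float, n: int = 16) -> float:
    """Fisher R-to-z transformation scaled by the sample size: atanh(r)*sqrt(n-3)."""
    if n <= 3:
        raise InputError("fisher_z requires n > 3")
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(np.arctanh(r) * np.sqrt(n - 3))


def classify_pattern_component(
    z_pattern: float, z_component: float, criterion: float = CLASSIFICATION_CRITERION
):
    """Apply the 1.28 z-difference rule; returns (label, pattern_index).

    pattern iff Zp - max(Zc, 0) >= criterion; component iff
    Zc - max(Zp, 0) >= criterion; else unclassified. PI = Zp - Zc always.
    """
    if not (np.isfinite(z_pattern) and np.isfinite(z_component)):
        raise InputError("z-scores must be finite")
    pi = float(z_pattern - z_component)
    if z_pattern - max(z_component, 0.0) >= criterion:
        return "pattern", pi
    if z_component - max(z_pattern, 0.0) >= criterion:
        return "component", pi
    return "unclassified", pi


@dataclass
class PatternComponentResult:
    """Per-unit pattern/component analysis outputs (the Zp-Zc scatter's data)."""

    unit_id: str
    r_pattern: float
    r_component: float
    z_pattern: float
    z_component: float
    pattern_index: float  # Zp - Zc
    label: str  # pattern | component | unclassified


class PatternComponentClassifier(BaseEstimator):
    """Classify a unit as pattern/component/unclassified from its tuning blocks.

    ``fit`` consumes a grating block and a plaid block measured on the same
    unit; fitted attributes mirror :class:`PatternComponentResult`.
    """

    def __init__(self, criterion: float = CLASSIFICATION_CRITERION,
                 inter_grating_angle: float = TUNING_PLAID_ANGLE):
        self.criterion = criterion
        self.inter_grating_angle = inter_grating_angle

    def fit(self, grating: TuningBlock, plaid: TuningBlock):
        if grating.stimulus_class != "grating" or plaid.stimulus_class != "plaid":
            raise InputError("expected one grating block and one plaid block")
        pat = pattern_prediction(grating)
        comp = component_prediction(grating, self.inter_grating_angle)
        rp, rc = partial_correlations(plaid.mean_rates, pat, comp)
        n = plaid.directions.size
        self.r_pattern_, self.r_component_ = rp, rc
        self.z_pattern_ = fisher_z(rp, n)
        self.z_component_ = fisher_z(rc, n)
        self.label_, self.pattern_index_ = classify_pattern_component(
            self.z_pattern_, self.z_component_, self.criterion
        )
        return self


def classify_unit(
    grating: TuningBlock,
    plaid: TuningBlock,
    criterion: float = CLASSIFICATION_CRITERION,
) -> PatternComponentResult:
    """Full pattern/component analysis for one unit's pair of tuning blocks."""
    clf = PatternComponentClassifier(criterion=criterion).fit(grating, plaid)
    return PatternComponentResult(
        unit_id=plaid.unit_id,
        r_pattern=clf.r_pattern_,
        r_component=clf.r_component_,
        z_pattern=clf.z_pattern_,
        z_component=clf.z_component_,
        pattern_index=clf.pattern_index_,
        label=clf.label_,
    )
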