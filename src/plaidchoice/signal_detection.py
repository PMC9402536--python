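"""ROC machinery: cue-preference assignment, neurometric functions and
thresholds, N/P ratios, and choice probability (per-condition, grand, and
time-resolved).

The ROC area here is the tie-aware pairwise probability
``(#{pref > null} + 0.5 * #{pref = null}) / (n_pref * n_null)`` — the
probability that an ideal observer given one draw from each response
distribution ranks them correctly, with ties credited half. It equals the
trapezoidal area under the criterion-sweep ROC curve and is computed with
midranks.

Choice probability (CP) applies the same statistic to responses sorted by the
animal's *choice* at fixed stimulus: CP = 0.5 means no choice-related
modulation. The grand CP z-scores rates within each (signed contrast x
pattern direction) condition and pools across the low-contrast conditions
(|contrast| <= 20% by default) before a single ROC computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Session
from .errors import InputError
from .psychometrics import CumulativeGaussianPsychometric

#: minimum choices of each type for a per-condition CP
MIN_CHOICES_PER_TYPE = 5

#: |contrast| cutoff for conditions entering the grand CP (% Michelson)
GRAND_CP_MAX_CONTRAST = 20.0


def roc_area(pref_values, null_values) -> float:
    """Tie-aware ROC area between two response distributions.

    Computed from midranks: equals brute-force pair counting with ties
    credited 0.5, and the trapezoidal area under the ROC curve.
    """
    pref = np.asarray(pref_values, dtype=float).ravel()
    null = np.asarray(null_values, dtype=float).ravel()
    if pref.size == 0 or null.size == 0:
        raise InputError("both response lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pref, null]))
    r_pref = ranks[: pref.size].sum()
    u = r_pref - pref.size * (pref.size + 1) / 2.0
    return float(u / (pref.size * null.size))


@dataclass
class PreferenceAssignment:
    """A unit's coherent/transparent preference for one pattern direction,
    from the sign of the rate-on-contrast regression over correct cued trials."""

    unit_id: str
    pattern_direction: float
    preferred_cue: str  # "coherent" | "transparent" | "indeterminate"
    regression_slope: float  # spikes/s per % contrast
    n_trials: int

    @property
    def null_cue(self) -> str:
        return {"coherent": "transparent", "transparent": "coherent"}.get(
            self.preferred_cue, "indeterminate"
        )


def assign_preference(session: Session, unit: str, pattern_direction: float) -> PreferenceAssignment:
    """OLS of firing rate on signed contrast over correct, cued trials.

    Positive slope -> the unit prefers coherent cues; negative -> transparent;
    an exactly zero slope is marked indeterminate (excluded downstream).
    Zero-contrast and error trials never enter this regression, so the
    preference tag cannot be biased by the choice effects measured later.
    """
    df = session.select(pattern_direction=pattern_direction)
    df = df[(df["contrast"] != 0) & (df["correct"] == 1.0)]
    if df["contrast"].nunique() < 2:
        raise InputError(
            "need correct trials at >= 2 distinct non-zero contrasts"
        )
    x = df["contrast"].to_numpy(float)
    rates = df[f"count:{unit}"].to_numpy(float) / session.stimulus_duration
    slope = float(np.polyfit(x, rates, 1)[0])
    if abs(slope) < 1e-12:  # numerically flat regression
        slope = 0.0
    if slope > 0:
        cue = "coherent"
    elif slope < 0:
        cue = "transparent"
    else:
        cue = "indeterminate"
    return PreferenceAssignment(
        unit_id=unit,
        pattern_direction=float(pattern_direction),
        preferred_cue=cue,
        regression_slope=slope,
        n_trials=len(df),
    )


@dataclass
class NeurometricResult:
    """Ideal-observer performance of one unit for one pattern direction."""

    roc_points: dict  # |contrast| -> (roc_area, n_pref, n_null)
    mu: float  # on the preferred-cue-positive reordered contrast axis
    sigma: float
    neuronal_threshold: float  # mu + sigma, % contrast
    np_ratio: Optional[float]  # neuronal / psychometric threshold
    degenerate: bool
    skipped_magnitudes: list = field(default_factory=list)


def neurometric_function(
    session: Session,
    assignment: PreferenceAssignment,
    psychometric_threshold: Optional[float] = None,
    estimator: Optional[CumulativeGaussianPsychometric] = None,
) -> NeurometricResult:
    """Per-|contrast| ROC between preferred- and null-cue correct-trial rates,
    with a cumulative Gaussian fitted to the resulting neurometric points.

    Contrast is reordered so preferred cues are positive; each magnitude m
    contributes the symmetric points (+m, ROC) and (-m, 1 - ROC), weighted by
    the number of trials involved. The neuronal threshold is the fitted
    mean + 1 SD on this axis — the same ~84% convention as the psychometric
    threshold, making the N/P ratio like-for-like.
    """
    if assignment.preferred_cue == "indeterminate":
        raise InputError("cannot compute a neurometric function for an indeterminate unit")
    df = session.select(pattern_direction=assignment.pattern_direction)
    df = df[(df["contrast"] != 0) & (df["correct"] == 1.0)]
    rates = df[f"count:{assignment.unit_id}"].to_numpy(float) / session.stimulus_duration
    contrast = df["contrast"].to_numpy(float)
    pref_sign = 1.0 if assignment.preferred_cue == "coherent" else -1.0

    roc_points, skipped = {}, []
    for m in sorted(set(np.abs(contrast))):
        pref_side = rates[contrast == pref_sign * m]
        null_side = rates[contrast == -pref_sign * m]
        if pref_side.size == 0 or null_side.size == 0:
            skipped.append(float(m))
            continue
        roc_points[float(m)] = (
            roc_area(pref_side, null_side), pref_side.size, null_side.size,
        )
    if len(roc_points) < 2:
        raise InputError("fewer than 2 usable contrast magnitudes")

    mags = np.array(sorted(roc_points))
    aucs = np.array([roc_points[m][0] for m in mags])
    weights = np.array([roc_points[m][1] + roc_points[m][2] for m in mags], dtype=float)
    x = np.concatenate([mags, -mags])
    y = np.concatenate([aucs, 1.0 - aucs])
    w = np.concatenate([weights, weights])

    est = estimator if estimator is not None else CumulativeGaussianPsychometric()
    est.fit(x, y, sample_weight=w)
    threshold = est.threshold_
    # a threshold far beyond the tested contrast range is an extrapolation
    # from a near-flat neurometric function, not a measurement
    degenerate = bool(est.degenerate_ or threshold > 5.0 * mags.max())
    np_ratio = None
    if psychometric_threshold is not None and psychometric_threshold != 0:
        np_ratio = float(threshold / psychometric_threshold)
    return NeurometricResult(
        roc_points=roc_points,
        mu=est.mu_,
        sigma=est.sigma_,
        neuronal_threshold=float(threshold),
        np_ratio=np_ratio,
        degenerate=degenerate,
        skipped_magnitudes=skipped,
    )


@dataclass
class ConditionCP:
    """Choice probability for one stimulus condition (or its exclusion)."""

    contrast: float
    pattern_direction: float
    cp: Optional[float]
    n_pref: int
    n_null: int
    excluded: bool = False
    reason: str = ""


def _choice_split(df: pd.DataFrame, session: Session, assignment: PreferenceAssignment):
    rates = df[f"count:{assignment.unit_id}"].to_numpy(float) / session.stimulus_duration
    is_pref = df["choice"].to_numpy() == assignment.preferred_cue
    return rates[is_pref], rates[~is_pref]


def choice_probability(
    session: Session,
    assignment: PreferenceAssignment,
    contrast: float,
    min_choices: int = MIN_CHOICES_PER_TYPE,
) -> ConditionCP:
    """CP for one (signed contrast, direction) condition: ROC between rates on
    preferred-cue-choice trials and null-choice trials, all trials regardless
    of correctness. Below ``min_choices`` of either type the condition is
    excluded (a marker, not an exception)."""
    df = session.select(pattern_direction=assignment.pattern_direction, contrast=contrast)
    pref, null = _choice_split(df, session, assignment)
    if pref.size < min_choices or null.size < min_choices:
        return ConditionCP(
            contrast=float(contrast),
            pattern_direction=assignment.pattern_direction,
            cp=None, n_pref=int(pref.size), n_null=int(null.size),
            excluded=True,
            reason=f"fewer than {min_choices} choices of one type",
        )
    return ConditionCP(
        contrast=float(contrast),
        pattern_direction=assignment.pattern_direction,
        cp=roc_area(pref, null), n_pref=int(pref.size), n_null=int(null.size),
    )


@dataclass
class GrandCP:
    """Grand choice probability for one unit x pattern direction."""

    cp: float
    n_pref: int
    n_null: int
    contrasts_used: list
    dropped_conditions: list  # zero-variance conditions
    permutation_p: Optional[float] = None


def _grand_cp_pool(
    values: np.ndarray,
    contrast: np.ndarray,
    is_pref: np.ndarray,
):
    """Z-score within signed-contrast condition and pool; returns pooled
    (z, is_pref) arrays and the list of dropped zero-variance conditions."""
    z_all, keep_pref, dropped, used = [], [], [], []
    for c in sorted(set(contrast)):
        mask = contrast == c
        vals = values[mask]
        sd = vals.std()
        if sd == 0:
            dropped.append(float(c))
            continue
        z_all.append((vals - vals.mean()) / sd)
        keep_pref.append(is_pref[mask])
        used.append(float(c))
    if not z_all:
        raise InputError("all conditions have zero rate variance")
    return np.concatenate(z_all), np.concatenate(keep_pref), dropped, used


def grand_choice_probability(
    session: Session,
    assignment: PreferenceAssignment,
    max_contrast: float = GRAND_CP_MAX_CONTRAST,
    n_permutations: int = 0,
    rng_seed: int = 0,
) -> GrandCP:
    """Grand CP: z-score rates within each signed-contrast condition of this
    direction, pool conditions with |contrast| <= ``max_contrast``, and compute
    one ROC between pooled preferred-choice and null-choice z-scores.

    With ``n_permutations`` > 0, a two-sided permutation p-value is computed by
    shuffling choice labels within condition.
    """
    df = session.select(pattern_direction=assignment.pattern_direction)
    df = df[np.abs(df["contrast"]) <= max_contrast]
    if len(df) == 0:
        raise InputError("no trials at or below the grand-CP contrast cutoff")
    values = df[f"count:{assignment.unit_id}"].to_numpy(float)
    contrast = df["contrast"].to_numpy(float)
    is_pref = df["choice"].to_numpy() == assignment.preferred_cue

    z, zp, dropped, used = _grand_cp_pool(values, contrast, is_pref)
    if zp.sum() == 0 or (~zp).sum() == 0:
        raise InputError("need both choice types present after pooling")
    cp = roc_area(z[zp], z[~zp])

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(rng_seed)
        obs = abs(cp - 0.5)
        hits = 0
        for _ in range(n_permutations):
            perm_pref = np.empty_like(is_pref)
            for c in used:
                mask = contrast == c
                perm_pref[mask] = rng.permutation(is_pref[mask])
            zi, zpi, _, _ = _grand_cp_pool(values, contrast, perm_pref)
            if zpi.sum() == 0 or (~zpi).sum() == 0:
                continue
            if abs(roc_area(zi[zpi], zi[~zpi]) - 0.5) >= obs - 1e-12:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)
    return GrandCP(
        cp=cp, n_pref=int(zp.sum()), n_null=int((~zp).sum()),
        contrasts_used=used, dropped_conditions=dropped, permutation_p=perm_p,
    )


@dataclass
class CPTimepoint:
    time_ms: float  # window center, ms from stimulus onset
    cp: Optional[float]
    n_pref: int
    n_null: int


def cp_timecourse(
    session: Session,
    assignment: PreferenceAssignment,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
    max_contrast: float = GRAND_CP_MAX_CONTRAST,
    t_start_ms: Optional[float] = None,
    t_end_ms: Optional[float] = None,
) -> list:
    """Grand CP in a sliding window over spike times (default 100 ms window,
    10 ms steps), from just before stimulus onset to just after offset.

    Windows where every condition has zero count variance (e.g. before onset
    at low baseline) yield ``cp=None``.
    """
    if not session.has_spike_times:
        raise InputError("session has no spike times")
    dur_ms = session.stimulus_duration * 1000.0
    if t_start_ms is None:
        t_start_ms = -200.0
    if t_end_ms is None:
        t_end_ms = dur_ms + 200.0
    df = session.select(pattern_direction=assignment.pattern_direction)
    df = df[np.abs(df["contrast"]) <= max_contrast]
    idx = df.index.to_numpy()
    contrast = df["contrast"].to_numpy(float)
    is_pref = df["choice"].to_numpy() == assignment.preferred_cue
    all_times = [
        session.spike_times(assignment.unit_id, session.trials.index.get_loc(i))
        for i in idx
    ]

    centers = np.arange(t_start_ms + window_ms / 2.0, t_end_ms - window_ms / 2.0 + 1e-9, step_ms)
    series = []
    for c in centers:
        a, b = c - window_ms / 2.0, c + window_ms / 2.0
        counts = np.array([np.sum((t >= a) & (t < b)) for t in all_times], dtype=float)
        try:
            z, zp, _, _ = _grand_cp_pool(counts, contrast, is_pref)
            if zp.sum() == 0 or (~zp).sum() == 0:
                raise InputError("one-sided")
            cp = roc_area(z[zp], z[~zp])
            series.append(CPTimepoint(float(c), cp, int(zp.sum()), int((~zp).sum())))
        except InputError:
            series.append(CPTimepoint(float(c), None, 0, 0))
    return series


@dataclass
class CPChoiceRatioResult:
    """CP vs choice-ratio pairs across stimuli, with a 20-point moving average."""

    pairs: pd.DataFrame  # columns: pattern_direction, contrast, choice_ratio, cp, n_pref, n_null
    moving_average: Optional[pd.DataFrame]  # choice_ratio, cp_mean, cp_sem


def cp_vs_choice_ratio(
    session: Session,
    assignments: Sequence[PreferenceAssignment],
    window: int = 20,
) -> CPChoiceRatioResult:
    """CP against choice ratio (pref/(pref+null)) for every stimulus with at
    least one choice of each type (i.e. at least a single error on cued
    stimuli), plus a centered ``window``-point moving mean +/- SEM over pairs
    sorted by ratio (omitted when there are fewer pairs than the window)."""
    rows = []
    for assignment in assignments:
        if assignment.preferred_cue == "indeterminate":
            continue
        df_dir = session.select(pattern_direction=assignment.pattern_direction)
        for c in sorted(df_dir["contrast"].unique()):
            res = choice_probability(session, assignment, c, min_choices=1)
            if res.excluded:
                continue
            rows.append(
                {
                    "pattern_direction": assignment.pattern_direction,
                    "contrast": float(c),
                    "choice_ratio": res.n_pref / (res.n_pref + res.n_null),
                    "cp": res.cp,
                    "n_pref": res.n_pref,
                    "n_null": res.n_null,
                }
            )
    pairs = pd.DataFrame(rows).sort_values("choice_ratio", kind="stable").reset_index(drop=True)
    moving = None
    if len(pairs) >= window:
        roll = pairs["cp"].rolling(window, center=True, min_periods=window)
        moving = pd.DataFrame(
            {
                "choice_ratio": pairs["choice_ratio"],
                "cp_mean": roll.mean(),
                "cp_sem": roll.std(ddof=1) / np.sqrt(window),
            }
        ).dropna().reset_index(drop=True)
    return CPChoiceRatioResult(pairs=pairs, moving_average=moving)


@dataclass
class ChoiceProbabilityResult:
    """All CP outputs for one unit x pattern direction."""

    unit_id: str
    pattern_direction: float
    per_condition: list  # ConditionCP
    grand: Optional[GrandCP]
    timecourse: Optional[list] = None


def analyze_choice_probability(
    session: Session,
    assignment: PreferenceAssignment,
    max_contrast: float = GRAND_CP_MAX_CONTRAST,
    min_choices: int = MIN_CHOICES_PER_TYPE,
    n_permutations: int = 0,
    rng_seed: int = 0,
    timecourse: bool = False,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
) -> ChoiceProbabilityResult:
    """Per-condition CPs, grand CP and (optionally) the CP time course."""
    df = session.select(pattern_direction=assignment.pattern_direction)
    per_condition = [
        choice_probability(session, assignment, c, min_choices=min_choices)
        for c in sorted(df["contrast"].unique())
    ]
    try:
        grand = grand_choice_probability(
            session, assignment, max_contrast=max_contrast,
            n_permutations=n_permutations, rng_seed=rng_seed,
        )
    except InputError:
        grand = None
    tc = None
    if timecourse and session.has_spike_times:
        tc = cp_timecourse(
            session, assignment, window_ms=window_ms, step_ms=step_ms,
            max_contrast=max_contrast,
        )
    return ChoiceProbabilityResult(
        unit_id=assignment.unit_id,
        pattern_direction=assignment.pattern_direction,
        per_condition=per_condition,
        grand=grand,
        timecourse=tc,
    )
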