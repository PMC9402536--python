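"""Across-unit population relationships: sensitivity vs preferred direction,
CP vs sensitivity and pattern index, geometric mean regression, circular
statistics.

Angle conventions: the "best" plaid direction for a unit is the pattern
direction closest (circularly) to its preferred direction; the normalized
preferred direction is the magnitude of that circular difference, folded to
[0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import circular_difference
from .errors import InputError


@dataclass
class UnitSummary:
    """Per-unit quantities entering the population analyses."""

    unit_id: str
    preferred_direction: float
    best_direction: float
    normalized_preferred_direction: float  # deg in [0, 180]
    thresholds: dict  # pattern direction -> neuronal threshold (% contrast)
    threshold_ratio: Optional[float]  # worst/best, >= 1
    grand_cp: dict  # pattern direction -> grand CP
    pattern_index: Optional[float]
    label: Optional[str]

    @property
    def best_grand_cp(self) -> Optional[float]:
        return self.grand_cp.get(self.best_direction)

    @property
    def best_threshold(self) -> Optional[float]:
        return self.thresholds.get(self.best_direction)


def best_direction(
    preferred_direction: float,
    pattern_directions: Sequence[float],
    thresholds: Optional[dict] = None,
):
    """Candidate pattern direction with the smallest circular distance to the
    unit's preferred direction; an exact tie is broken by the lower neuronal
    threshold when thresholds are given. Returns (direction, tie_broken)."""
    cands = np.asarray(list(pattern_directions), dtype=float)
    if cands.size == 0:
        raise InputError("need at least one candidate direction")
    dist = np.abs(circular_difference(preferred_direction, cands))
    winners = cands[np.isclose(dist, dist.min())]
    tie = winners.size > 1
    if tie and thresholds is not None:
        winners = sorted(winners, key=lambda d: thresholds.get(float(d), np.inf))
    return float(winners[0]), bool(tie)


def summarize_unit(
    unit_id: str,
    preferred_direction: float,
    pattern_directions: Sequence[float],
    thresholds: dict,
    grand_cp: dict,
    pattern_index: Optional[float] = None,
    label: Optional[str] = None,
) -> UnitSummary:
    """Assemble a :class:`UnitSummary` (best direction, folded angle, ratio)."""
    best, _ = best_direction(preferred_direction, pattern_directions, thresholds)
    norm = float(abs(circular_difference(preferred_direction, best)))
    ratio = None
    vals = [thresholds[d] for d in pattern_directions if d in thresholds]
    if len(vals) == len(list(pattern_directions)) and min(vals) > 0:
        ratio = float(max(vals) / min(vals))
    return UnitSummary(
        unit_id=unit_id,
        preferred_direction=float(preferred_direction),
        best_direction=best,
        normalized_preferred_direction=norm,
        thresholds=dict(thresholds),
        threshold_ratio=ratio,
        grand_cp=dict(grand_cp),
        pattern_index=pattern_index,
        label=label,
    )


def threshold_ratio_profile(
    summaries: Sequence[UnitSummary], bin_width: float = 10.0
) -> pd.DataFrame:
    """Mean normalized threshold ratio by normalized preferred direction.

    Units are binned by normalized preferred direction (default 10 deg bins
    over [0, 180]); ratios are divided by the sample maximum and averaged
    within bins. Empty bins are absent from the output, not zero."""
    rows = [
        (s.normalized_preferred_direction, s.threshold_ratio)
        for s in summaries
        if s.threshold_ratio is not None
    ]
    if not rows:
        raise InputError("no units with thresholds for both directions")
    angle = np.array([r[0] for r in rows])
    ratio = np.array([r[1] for r in rows])
    ratio = ratio / ratio.max()
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(angle, edges) - 1, 0, len(edges) - 2)
    out = []
    for b in sorted(set(idx)):
        mask = idx == b
        vals = ratio[mask]
        out.append(
            {
                "bin_center": (edges[b] + edges[b + 1]) / 2.0,
                "mean_ratio": vals.mean(),
                "sem_ratio": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(out)


@dataclass
class GMRResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def geometric_mean_regression(x, y) -> GMRResult:
    """Geometric mean (SD-line) regression: slope = sign(r) * SD(y)/SD(x),
    line through the means; r and p from the Pearson correlation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise InputError("need matched samples with n >= 3")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise InputError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = y.mean() - slope * x.mean()
    return GMRResult(slope=float(slope), intercept=float(intercept),
                     r=float(r), p=float(p), n=int(x.size))


def _first_order_partial(rxy: float, rxz: float, rzy: float) -> float:
    """Closed-form first-order partial correlation r_xy.z."""
    denom = np.sqrt((1.0 - rxz**2) * (1.0 - rzy**2))
    if denom == 0:
        raise InputError("a predictor is perfectly correlated with the covariate")
    return float(np.clip((rxy - rxz * rzy) / denom, -1.0, 1.0))


def cp_threshold_pi_partials(grand_cp, threshold, pattern_index) -> dict:
    """Partial correlations from the multiple regression of grand CP on
    neuronal threshold and pattern index: CP~threshold controlling PI, and
    CP~PI controlling threshold. Two-sided p-values from the t-distribution
    with n - 3 degrees of freedom."""
    cp = np.asarray(grand_cp, dtype=float).ravel()
    thr = np.asarray(threshold, dtype=float).ravel()
    pi = np.asarray(pattern_index, dtype=float).ravel()
    n = cp.size
    if not (thr.size == n == pi.size) or n < 4:
        raise InputError("need matched samples with n >= 4 units")
    for name, col in (("cp", cp), ("threshold", thr), ("pi", pi)):
        if np.std(col) == 0:
            raise InputError(f"column {name} is constant")
    r_ct = float(np.corrcoef(cp, thr)[0, 1])
    r_cp = float(np.corrcoef(cp, pi)[0, 1])
    r_tp = float(np.corrcoef(thr, pi)[0, 1])
    if abs(r_tp) > 0.999999:
        raise InputError("threshold and pattern index are collinear")
    out = {}
    for var, rxy, rzy in (("threshold", r_ct, r_cp), ("pi", r_cp, r_ct)):
        # r_xy.z with x = cp, y = var, z = the other predictor
        r = _first_order_partial(rxy, r_tp, rzy)
        df_t = n - 3
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df_t / (1.0 - r**2))
            p = float(2.0 * stats.t.sf(abs(t), df_t))
        out[var] = (r, p)
    return out


def rayleigh_test(angles_deg) -> tuple:
    """Rayleigh test of circular uniformity: z = n * rbar^2 with rbar the mean
    resultant length; p by the standard (Zar) approximation."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float).ravel())
    n = a.size
    if n < 2:
        raise InputError("need n >= 2 angles")
    rbar = np.abs(np.mean(np.exp(1j * a)))
    z = n * rbar**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - (n * rbar) ** 2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))


def circular_mean(angles_deg) -> tuple:
    """Circular mean direction (deg in [0, 360)) and its standard error (deg).

    SEM is the angular deviation sqrt(2*(1 - rbar)) / sqrt(n), in degrees."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float).ravel())
    if a.size == 0:
        raise InputError("need at least one angle")
    vec = np.mean(np.exp(1j * a))
    mean = np.rad2deg(np.angle(vec)) % 360.0
    rbar = np.abs(vec)
    sem = np.rad2deg(np.sqrt(max(2.0 * (1.0 - rbar), 0.0)) / np.sqrt(a.size))
    return float(mean), float(sem)


# Routine comparisons are delegated to standard statistical routines; these
# thin aliases exist so reports can call one namespace.
wilcoxon_ranksum = stats.ranksums
kruskal_wallis = stats.kruskal
one_way_anova = stats.f_oneway
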