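"""Synthetic sessions and tuning blocks with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage has a recovery test against known parameters:

* Von-Mises-tuned units spanning the pattern<->component continuum via a
  mixing weight ``w`` (1 = responds to plaid pattern direction like a grating,
  0 = responds to the two component directions independently);
* linear modulation of firing rate by signed texture contrast, with a slope
  per pattern direction;
* Poisson (optionally negative-binomial) spike counts whose gain is modulated
  by a shared per-trial fluctuation ``eta``;
* choices driven by a decision variable pooling the texture cue and the same
  shared fluctuation, which makes choice probability tunable through
  ``pooling_weight`` x per-unit ``gain_coupling``;
* the task's reward rule: cue-congruent choices rewarded, 50/50 random reward
  on zero-contrast trials.

All stochastic operations take an explicit seed; nothing uses global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import von_mises_shape, wrap_degrees
from .data_io import Session, StimulusCondition, TuningBlock, TUNING_DIRECTIONS, TUNING_PLAID_ANGLE
from .errors import ConfigError

#: texture-contrast set used in the majority of sessions (% Michelson)
DEFAULT_CONTRAST_SET = (-80.0, -40.0, -20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0, 40.0, 80.0)


@dataclass
class SimUnit:
    """Ground-truth parameters of one simulated direction-selective unit."""

    preferred_direction: float  # deg
    kappa: float  # Von Mises concentration
    amplitude: float  # spikes/s at preferred direction above baseline
    baseline: float  # spikes/s
    pattern_weight: float  # w in [0,1]: 1 pattern-like, 0 component-like
    texture_slope: dict  # pattern direction -> spikes/s per % signed contrast
    gain_coupling: float  # >= 0, sensitivity to the shared fluctuation

    def __post_init__(self):
        if not (0.0 <= self.pattern_weight <= 1.0):
            raise ConfigError(f"pattern_weight {self.pattern_weight} outside [0, 1]")
        if self.gain_coupling < 0:
            raise ConfigError("gain_coupling must be >= 0")


@dataclass
class SimConfig:
    """Study conditions for one simulated session.

    Defaults reproduce the task structure: the 11-level signed contrast set,
    two pattern directions (90 up / 270 down), >= 20 trials per condition, a
    1.5 s stimulus. ``cue_weight``/``pooling_weight``/``decision_noise_sd``
    imply a psychometric spread sigma = sqrt(pooling^2 + noise^2)/cue of about
    20% contrast at the defaults, in the range of the reported thresholds.
    """

    n_units: int = 40
    contrast_set: Sequence[float] = DEFAULT_CONTRAST_SET
    pattern_directions: Sequence[float] = (90.0, 270.0)
    inter_grating_angle: float = 115.0
    trials_per_condition: int = 20
    cue_weight: float = 0.056  # choice evidence per % contrast
    pooling_weight: float = 0.5  # coupling of eta into the decision variable
    decision_noise_sd: float = 1.0
    stimulus_duration: float = 1.5  # s
    seed: int = 0
    # unit-population parameters
    w_mixture: Sequence[float] = (0.25, 0.25, 0.5)  # P(pattern-end, component-end, middle)
    texture_slope_sd: float = 0.08  # spikes/s per % contrast
    gain_range: Sequence[float] = (0.05, 0.35)
    # count-noise knob: None -> Poisson; else negative binomial with this
    # dispersion (variance = m + m^2/dispersion)
    dispersion: Optional[float] = None
    # optional spike-time emission for the CP time course
    emit_spike_times: bool = False
    pre_window: float = 0.3  # s of pre-stimulus baseline recorded
    post_window: float = 0.3  # s of post-stimulus baseline recorded
    # interval (s from onset) in which eta modulates the gain; None -> whole epoch
    coupling_window: Optional[Sequence[float]] = None

    def validate(self) -> None:
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        if self.trials_per_condition < 20:
            raise ConfigError("trials_per_condition must be >= 20")
        if len(self.contrast_set) < 1 or len(self.pattern_directions) < 1:
            raise ConfigError("contrast_set and pattern_directions must be non-empty")
        if not np.isclose(sum(self.w_mixture), 1.0):
            raise ConfigError("w_mixture must sum to 1")
        if min(self.w_mixture) < 0:
            raise ConfigError("w_mixture probabilities must be >= 0")
        if self.decision_noise_sd < 0:
            raise ConfigError("decision_noise_sd must be >= 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        lo, hi = self.gain_range
        if lo < 0 or hi < lo:
            raise ConfigError("gain_range must satisfy 0 <= lo <= hi")
        if self.coupling_window is not None:
            a, b = self.coupling_window
            if not (0 <= a < b <= self.stimulus_duration):
                raise ConfigError("coupling_window must lie within the stimulus epoch")

    @property
    def implied_psychometric_sigma(self) -> float:
        """Spread of the generative psychometric function (% contrast)."""
        return float(
            np.hypot(self.pooling_weight, self.decision_noise_sd) / self.cue_weight
        )


@dataclass
class GroundTruth:
    """Per-trial latents and unit parameters recorded by the generator."""

    units: list
    eta: np.ndarray  # shared fluctuation per trial
    config: SimConfig
    n_gain_clipped: int = 0  # trials x units whose gain factor clipped at 0

    @property
    def psychometric_mu(self) -> float:
        return 0.0

    @property
    def psychometric_sigma(self) -> float:
        return self.config.implied_psychometric_sigma


def sample_units(config: SimConfig, rng_seed: int) -> list:
    """Draw a unit population spanning the pattern<->component continuum.

    Preferred directions are uniform on the circle by default; the pattern
    weight ``w`` comes from a three-part mixture (high / low / intermediate)
    so pattern, component and unclassified cells all occur.
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)
    units = []
    for _ in range(config.n_units):
        comp = rng.choice(3, p=list(config.w_mixture))
        if comp == 0:
            w = rng.uniform(0.85, 1.0)
        elif comp == 1:
            w = rng.uniform(0.0, 0.15)
        else:
            w = rng.uniform(0.15, 0.85)
        units.append(
            SimUnit(
                preferred_direction=float(wrap_degrees(rng.uniform(0.0, 360.0))),
                kappa=float(rng.lognormal(mean=np.log(2.0), sigma=0.4)),
                amplitude=float(rng.lognormal(mean=np.log(30.0), sigma=0.4)),
                baseline=float(rng.gamma(shape=4.0, scale=2.0)),
                pattern_weight=float(w),
                texture_slope={
                    float(d): float(rng.normal(0.0, config.texture_slope_sd))
                    for d in config.pattern_directions
                },
                gain_coupling=float(rng.uniform(*config.gain_range)),
            )
        )
    return units


def _tuning_rate(unit: SimUnit, theta, inter_grating_angle: float) -> np.ndarray:
    """Stimulus-driven rate component for a plaid at pattern direction theta."""
    half = inter_grating_angle / 2.0
    pattern = von_mises_shape(theta, unit.preferred_direction, unit.kappa)
    component = von_mises_shape(np.asarray(theta) - half, unit.preferred_direction, unit.kappa) + \
        von_mises_shape(np.asarray(theta) + half, unit.preferred_direction, unit.kappa)
    w = unit.pattern_weight
    return unit.amplitude * (w * pattern + (1.0 - w) * component)


def expected_rate(unit: SimUnit, condition: StimulusCondition) -> float:
    """Noise-free firing rate (spikes/s) of a unit for one stimulus condition.

    baseline + w-mixture of pattern/component Von Mises tuning evaluated at the
    plaid's directions + texture_slope x signed contrast, clipped at 0.
    """
    rate = unit.baseline + float(
        _tuning_rate(unit, condition.pattern_direction, condition.inter_grating_angle)
    )
    slope = unit.texture_slope.get(float(condition.pattern_direction), 0.0)
    rate += slope * condition.contrast
    return max(rate, 0.0)


def tuning_means(unit: SimUnit, stimulus_class: str,
                 directions: np.ndarray = TUNING_DIRECTIONS) -> np.ndarray:
    """Noise-free mean rates for a tuning block (grating or 135-deg plaid)."""
    directions = np.asarray(directions, dtype=float)
    if stimulus_class == "grating":
        drive = unit.amplitude * von_mises_shape(directions, unit.preferred_direction, unit.kappa)
    elif stimulus_class == "plaid":
        drive = _tuning_rate(unit, directions, TUNING_PLAID_ANGLE)
    else:
        raise ConfigError(f"unknown stimulus_class {stimulus_class!r}")
    return np.maximum(unit.baseline + drive, 0.0)


def _draw_counts(rng, mean_counts: np.ndarray, dispersion: Optional[float]) -> np.ndarray:
    mean_counts = np.maximum(mean_counts, 0.0)
    if dispersion is None:
        return rng.poisson(mean_counts)
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean_counts, 1e-12) / dispersion)
    return rng.poisson(lam)


def simulate_session(config: SimConfig, units: Sequence[SimUnit], rng_seed: int):
    """Simulate one session; returns ``(Session, GroundTruth)``.

    Per trial: a shared fluctuation ``eta ~ N(0,1)`` multiplies each unit's
    rate by ``max(1 + g*eta, 0)``; spike counts are Poisson (or negative
    binomial) around rate x duration; the decision variable
    ``DV = cue_weight*contrast + pooling_weight*eta + noise`` sets the choice
    (coherent iff DV > 0); reward follows the cue, or a fair coin at zero
    contrast. The RNG stream is laid out so that runs differing only in
    ``pooling_weight`` share identical counts and latents (common random
    numbers for coupling sweeps).
    """
    config.validate()
    rng = np.random.default_rng(rng_seed)

    conditions = [
        (float(c), float(d))
        for d in config.pattern_directions
        for c in config.contrast_set
    ]
    per_trial = np.repeat(np.arange(len(conditions)), config.trials_per_condition)
    order = rng.permutation(per_trial.size)
    cond_idx = per_trial[order]
    n_trials = cond_idx.size
    contrast = np.array([conditions[i][0] for i in cond_idx])
    direction = np.array([conditions[i][1] for i in cond_idx])

    eta = rng.standard_normal(n_trials)
    decision_noise = rng.standard_normal(n_trials) * config.decision_noise_sd
    coin = rng.random(n_trials)  # zero-contrast reward draws

    # expected stimulus-epoch rates per unit x trial
    dur = config.stimulus_duration
    if config.coupling_window is None:
        win_a, win_b = 0.0, dur
    else:
        win_a, win_b = map(float, config.coupling_window)
    mod_len = win_b - win_a

    base_rates = np.empty((len(units), n_trials))
    for k, u in enumerate(units):
        for (c, d) in set(zip(contrast, direction)):
            mask = (contrast == c) & (direction == d)
            base_rates[k, mask] = expected_rate(
                u, StimulusCondition(d, c, config.inter_grating_angle)
            )
    g = np.array([u.gain_coupling for u in units])[:, None]
    gain = 1.0 + g * eta[None, :]
    n_clipped = int(np.sum(gain < 0))
    gain = np.maximum(gain, 0.0)

    # counts over the stimulus epoch: unmodulated outside the coupling window
    mean_counts = base_rates * ((dur - mod_len) + mod_len * gain)

    times_cols = {}
    if config.emit_spike_times:
        counts = np.zeros((len(units), n_trials), dtype=int)
        for k, u in enumerate(units):
            col = []
            for t in range(n_trials):
                segs = [
                    (-config.pre_window, 0.0, u.baseline, False),
                    (0.0, win_a, base_rates[k, t], True),
                    (win_a, win_b, base_rates[k, t] * gain[k, t], True),
                    (win_b, dur, base_rates[k, t], True),
                    (dur, dur + config.post_window, u.baseline, False),
                ]
                times = []
                for a, b, r, in_epoch in segs:
                    if b <= a:
                        continue
                    n = int(_draw_counts(rng, np.array([r * (b - a)]), config.dispersion)[0])
                    if in_epoch:
                        counts[k, t] += n
                    if n:
                        times.append(rng.uniform(a, b, size=n) * 1000.0)
                ts = np.sort(np.concatenate(times)) if times else np.empty(0)
                col.append(";".join(f"{x:.8g}" for x in ts))
            times_cols[f"times:u{k:03d}"] = col
    else:
        counts = _draw_counts(rng, mean_counts, config.dispersion)

    dv = config.cue_weight * contrast + config.pooling_weight * eta + decision_noise
    choice = np.where(dv > 0, "coherent", "transparent")
    correct = np.where(
        contrast == 0, np.nan, ((choice == "coherent") == (contrast > 0)).astype(float)
    )
    rewarded = np.where(contrast == 0, coin < 0.5, correct == 1.0).astype(bool)

    unit_ids = [f"u{k:03d}" for k in range(len(units))]
    data = {
        "pattern_direction": direction,
        "contrast": contrast,
        "inter_grating_angle": np.full(n_trials, config.inter_grating_angle),
        "choice": choice,
        "rewarded": rewarded,
        "correct": correct,
    }
    for k, uid in enumerate(unit_ids):
        data[f"count:{uid}"] = counts[k]
    data.update(times_cols)
    session = Session(
        trials=pd.DataFrame(data),
        units=unit_ids,
        stimulus_duration=dur,
        monkey_id="sim",
    )
    truth = GroundTruth(units=list(units), eta=eta, config=config, n_gain_clipped=n_clipped)
    return session, truth


def simulate_tuning_block(
    unit: SimUnit,
    stimulus_class: str,
    reps: int,
    rng_seed: int,
    duration: float = 1.0,
    noise: str = "poisson",
) -> TuningBlock:
    """Simulate one 16-direction tuning block for a unit.

    ``noise="poisson"`` draws Poisson counts over ``duration``; ``"none"``
    returns the exact expected rates (for noise-free recovery tests).
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    means = tuning_means(unit, stimulus_class)
    if noise == "none":
        rates = np.tile(means, (reps, 1))
        baseline = unit.baseline
    elif noise == "poisson":
        rng = np.random.default_rng(rng_seed)
        rates = rng.poisson(np.tile(means * duration, (reps, 1))) / duration
        baseline = rng.poisson(unit.baseline * duration * reps) / (duration * reps)
    else:
        raise ConfigError(f"unknown noise model {noise!r}")
    return TuningBlock(
        unit_id="sim",
        stimulus_class=stimulus_class,
        directions=TUNING_DIRECTIONS.copy(),
        rates=rates,
        baseline_rate=float(baseline),
    )


def simulate_tuning_blocks(units: Sequence[SimUnit], reps: int, rng_seed: int):
    """Grating + plaid tuning blocks for every unit, with per-unit sub-seeds."""
    blocks = []
    for k, u in enumerate(units):
        for j, cls in enumerate(("grating", "plaid")):
            blk = simulate_tuning_block(u, cls, reps, rng_seed + 2 * k + j)
            blk.unit_id = f"u{k:03d}"
            blocks.append(blk)
    return blocks
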