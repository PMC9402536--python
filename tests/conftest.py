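"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import plaidchoice as pc


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately brute-force / formula-free of the
# implementation paths they check)

def roc_area_bruteforce(pref, null) -> float:
    """Pair-count ROC: (#{p > n} + 0.5 #{p == n}) / (n_p * n_n)."""
    pref = np.asarray(pref, float)
    null = np.asarray(null, float)
    wins = ties = 0
    for p in pref:
        for n in null:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (pref.size * null.size)


def partial_corr_residualization(y, x, control) -> float:
    """Partial correlation of y and x controlling for `control`, by
    regressing `control` out of both and correlating the residuals."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    c = np.asarray(control, float)
    design = np.column_stack([np.ones_like(c), c])
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    return float(np.corrcoef(ry, rx)[0, 1])


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_config():
    return pc.SimConfig(
        n_units=6,
        contrast_set=(-40.0, -20.0, -10.0, 0.0, 10.0, 20.0, 40.0),
        trials_per_condition=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    units = pc.sample_units(small_config, 11)
    session, truth = pc.simulate_session(small_config, units, 12)
    return session, truth


@pytest.fixture(scope="session")
def default_session():
    """Full default study conditions; shared across read-only tests."""
    cfg = pc.SimConfig(n_units=10, seed=21)
    units = pc.sample_units(cfg, 21)
    session, truth = pc.simulate_session(cfg, units, 22)
    return cfg, units, session, truth


def make_unit(
    preferred_direction=90.0,
    kappa=2.0,
    amplitude=30.0,
    baseline=8.0,
    pattern_weight=1.0,
    slope_up=0.1,
    slope_down=-0.05,
    gain_coupling=0.2,
):
    return pc.SimUnit(
        preferred_direction=preferred_direction,
        kappa=kappa,
        amplitude=amplitude,
        baseline=baseline,
        pattern_weight=pattern_weight,
        texture_slope={90.0: slope_up, 270.0: slope_down},
        gain_coupling=gain_coupling,
    )


def make_session_from_rows(rows, units=("u0",), stimulus_duration=1.5):
    """Hand-built session: rows are dicts with trial columns + counts."""
    df = pd.DataFrame(rows)
    for col, default in (
        ("pattern_direction", 90.0),
        ("inter_grating_angle", 115.0),
        ("rewarded", True),
    ):
        if col not in df.columns:
            df[col] = default
    if "correct" not in df.columns:
        df["correct"] = np.where(
            df["contrast"] == 0,
            np.nan,
            ((df["choice"] == "coherent") == (df["contrast"] > 0)).astype(float),
        )
    return pc.Session(
        trials=df,
        units=list(units),
        stimulus_duration=stimulus_duration,
        monkey_id="fixture",
    )
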