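"""Domain types and delimited-text readers/writers for trial and tuning tables.

A *session* is one behavioral recording: an ordered table of trials, each with a
stimulus condition (signed texture contrast, pattern direction, inter-grating
angle), the animal's coherent/transparent choice, the reward outcome and, per
recorded unit, a spike count over the stimulus epoch (optionally with spike
times in ms from stimulus onset).

File dialects (UTF-8, comma-delimited, "." decimal, versioned header line):

``sessions.csv``::

    # plaidchoice-session v1; stimulus_duration=1.5; monkey_id=sim
    pattern_direction,contrast,inter_grating_angle,choice,rewarded,correct,count:u000,...[,times:u000,...]
    90,-40,115,transparent,1,1,12,...

``tuning.csv`` (long format, one row per repetition x direction)::

    # plaidchoice-tuning v1
    unit_id,stimulus_class,direction,rep,rate,baseline_rate
    u000,grating,0,0,31.2,7.9

Spike times are serialized as semicolon-joined ms values. ``correct`` is empty
on zero-contrast trials, where correctness is undefined.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

SESSION_MAGIC = "# plaidchoice-session v1"
TUNING_MAGIC = "# plaidchoice-tuning v1"

#: canonical non-unit trial columns, in serialization order
TRIAL_COLUMNS = [
    "pattern_direction",
    "contrast",
    "inter_grating_angle",
    "choice",
    "rewarded",
    "correct",
]

CHOICES = ("coherent", "transparent")

#: 16 equally spaced tuning directions, 22.5 deg apart
TUNING_DIRECTIONS = np.arange(16) * 22.5

#: relative angle between the two sinusoidal gratings in tuning plaids
TUNING_PLAID_ANGLE = 135.0


@dataclass(frozen=True)
class StimulusCondition:
    """One plaid stimulus: signed texture contrast (% Michelson,
    (Lmax-Lmin)/(Lmax+Lmin); transparent cues negative, coherent positive),
    pattern drift direction (deg, 90 = up, 270 = down) and the angle separating
    the two component gratings."""

    pattern_direction: float
    contrast: float
    inter_grating_angle: float

    def __post_init__(self):
        if not (0.0 <= self.pattern_direction < 360.0):
            raise ValidationError(
                f"pattern_direction {self.pattern_direction} outside [0, 360)"
            )
        if not (-100.0 <= self.contrast <= 100.0):
            raise ValidationError(f"contrast {self.contrast} outside [-100, 100]")


@dataclass
class TrialRecord:
    """One behavioral trial."""

    condition: StimulusCondition
    spike_counts: dict  # unit id -> nonnegative int over the stimulus epoch
    choice: str  # "coherent" | "transparent"
    rewarded: bool
    correct: Optional[bool]  # None when contrast == 0
    spike_times: Optional[dict] = None  # unit id -> ms from stimulus onset


@dataclass
class Session:
    """An ordered trial table plus session-level metadata.

    ``trials`` holds one row per trial with columns ``TRIAL_COLUMNS`` followed
    by ``count:<unit>`` (int spike counts) and optional ``times:<unit>``
    (semicolon-joined ms strings). Trial order is meaningful (choice-history
    analysis) and preserved by I/O.
    """

    trials: pd.DataFrame
    units: list = field(default_factory=list)
    stimulus_duration: float = 1.5  # seconds
    monkey_id: str = "unknown"

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def inter_grating_angle(self) -> float:
        angles = self.trials["inter_grating_angle"].unique()
        return float(angles[0])

    def count_column(self, unit: str) -> str:
        return f"count:{unit}"

    def rates(self, unit: str) -> np.ndarray:
        """Firing rates (spikes/s) over the stimulus epoch for one unit."""
        return self.trials[self.count_column(unit)].to_numpy(float) / self.stimulus_duration

    def spike_times(self, unit: str, trial_index: int) -> np.ndarray:
        """Spike times (ms from onset) for one unit on one trial."""
        col = f"times:{unit}"
        if col not in self.trials.columns:
            raise SchemaError(f"session has no spike times for unit {unit!r}")
        raw = self.trials[col].iloc[trial_index]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
            return np.empty(0)
        return np.array([float(t) for t in str(raw).split(";")])

    @property
    def has_spike_times(self) -> bool:
        return any(c.startswith("times:") for c in self.trials.columns)

    def iter_trials(self) -> Iterator[TrialRecord]:
        for _, row in self.trials.iterrows():
            cond = StimulusCondition(
                pattern_direction=float(row["pattern_direction"]),
                contrast=float(row["contrast"]),
                inter_grating_angle=float(row["inter_grating_angle"]),
            )
            correct = row["correct"]
            yield TrialRecord(
                condition=cond,
                spike_counts={u: int(row[f"count:{u}"]) for u in self.units},
                choice=str(row["choice"]),
                rewarded=bool(row["rewarded"]),
                correct=None if pd.isna(correct) else bool(correct),
            )

    def select(self, pattern_direction=None, contrast=None) -> pd.DataFrame:
        """Trials matching a direction and/or signed contrast (no copy of order)."""
        mask = np.ones(len(self.trials), dtype=bool)
        if pattern_direction is not None:
            mask &= self.trials["pattern_direction"].to_numpy() == pattern_direction
        if contrast is not None:
            mask &= self.trials["contrast"].to_numpy() == contrast
        return self.trials[mask]


@dataclass
class TuningBlock:
    """Direction-tuning measurements for one unit and one stimulus class.

    ``rates`` is repetitions x directions in spikes/s; ``baseline_rate`` comes
    from no-stimulus epochs flanking the trials. Plaid blocks use a 135 deg
    inter-grating angle; directions index *pattern* motion.
    """

    unit_id: str
    stimulus_class: str  # "grating" | "plaid"
    directions: np.ndarray
    rates: np.ndarray
    baseline_rate: float

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.stimulus_class not in ("grating", "plaid"):
            raise ValidationError(f"unknown stimulus_class {self.stimulus_class!r}")
        if np.any(np.diff(self.directions) <= 0):
            raise ValidationError("directions must be strictly increasing")
        if self.rates.shape[1] != self.directions.size:
            raise ValidationError("rates and directions have mismatched length")

    @property
    def mean_rates(self) -> np.ndarray:
        return self.rates.mean(axis=0)


@dataclass(frozen=True)
class Finding:
    """One validation finding: which trial, which rule, what happened."""

    trial_index: Optional[int]
    rule: str
    message: str

    def __str__(self):
        where = "session" if self.trial_index is None else f"trial {self.trial_index}"
        return f"[{self.rule}] {where}: {self.message}"


def _fmt(x: float) -> str:
    """Bit-stable float formatting (shortest round-trippable form)."""
    return repr(float(x)) if not float(x).is_integer() else str(int(x))


def _parse_header(line: str, magic: str, path) -> dict:
    if not line.startswith(magic):
        raise SchemaError(
            f"{path}: expected header {magic!r}, got {line[:60]!r}"
        )
    meta = {}
    for part in line[len(magic):].split(";"):
        part = part.strip()
        if "=" in part:
            key, val = part.split("=", 1)
            meta[key.strip()] = val.strip()
    return meta


def read_session(path) -> Session:
    """Parse a ``sessions.csv`` file into a :class:`Session`.

    Raises :class:`SchemaError` for a missing header or column and
    :class:`ValidationError` (with line numbers) for out-of-range values.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first, _, rest = text.partition("\n")
    meta = _parse_header(first, SESSION_MAGIC, path)
    df = pd.read_csv(
        _io.StringIO(rest),
        dtype={"choice": str},
        keep_default_na=True,
    )
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    units = [c.split(":", 1)[1] for c in df.columns if c.startswith("count:")]
    if not units:
        raise SchemaError(f"{path}: no unit count columns (count:<unit>)")

    # line number of data row i: magic line + csv header precede it
    bad = df.index[(df["contrast"] < -100) | (df["contrast"] > 100)].tolist()
    if bad:
        lines = ", ".join(str(i + 3) for i in bad)
        raise ValidationError(f"{path}: contrast outside [-100, 100] at line(s) {lines}")
    bad = df.index[~df["choice"].isin(CHOICES)].tolist()
    if bad:
        lines = ", ".join(str(i + 3) for i in bad)
        raise ValidationError(f"{path}: invalid choice at line(s) {lines}")

    df["rewarded"] = df["rewarded"].astype(bool)
    for col in ("pattern_direction", "contrast", "inter_grating_angle", "correct"):
        df[col] = df[col].astype(float)
    for col in df.columns:
        if col.startswith("count:"):
            df[col] = df[col].astype(np.int64)
        elif col.startswith("times:"):
            df[col] = df[col].astype("string").fillna("")
    return Session(
        trials=df,
        units=units,
        stimulus_duration=float(meta.get("stimulus_duration", 1.5)),
        monkey_id=meta.get("monkey_id", "unknown"),
    )


def write_session(session: Session, path) -> None:
    """Write a session with fixed column order and stable float formatting."""
    path = Path(path)
    cols = list(TRIAL_COLUMNS)
    cols += [f"count:{u}" for u in session.units]
    time_cols = [f"times:{u}" for u in session.units if f"times:{u}" in session.trials.columns]
    cols += time_cols
    lines = [
        f"{SESSION_MAGIC}; stimulus_duration={_fmt(session.stimulus_duration)}; "
        f"monkey_id={session.monkey_id}",
        ",".join(cols),
    ]
    df = session.trials
    for _, row in df.iterrows():
        fields = [
            _fmt(row["pattern_direction"]),
            _fmt(row["contrast"]),
            _fmt(row["inter_grating_angle"]),
            str(row["choice"]),
            str(int(bool(row["rewarded"]))),
            "" if pd.isna(row["correct"]) else str(int(row["correct"])),
        ]
        fields += [str(int(row[f"count:{u}"])) for u in session.units]
        fields += [str(row[c]) if not pd.isna(row[c]) else "" for c in time_cols]
        lines.append(",".join(fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_session(session: Session) -> list:
    """Check session invariants; return findings rather than raising.

    Empty list iff all invariants hold. Checked rules: choice vocabulary,
    contrast range, a single inter-grating angle per session within [95, 130],
    correctness undefined at zero contrast and cue-consistent elsewhere,
    nonnegative integer counts.
    """
    findings: list = []
    df = session.trials
    angles = df["inter_grating_angle"].unique()
    if len(angles) != 1:
        findings.append(Finding(None, "single-angle",
                                f"{len(angles)} distinct inter_grating_angles in session"))
    for a in angles:
        if not (95.0 <= a <= 130.0):
            findings.append(Finding(None, "angle-range",
                                    f"inter_grating_angle {a} outside [95, 130]"))
    for i, row in df.reset_index(drop=True).iterrows():
        c = row["contrast"]
        if not (-100.0 <= c <= 100.0):
            findings.append(Finding(i, "contrast-range", f"contrast {c} outside [-100, 100]"))
        if row["choice"] not in CHOICES:
            findings.append(Finding(i, "choice-vocab", f"choice {row['choice']!r}"))
            continue
        correct = row["correct"]
        if c == 0:
            if not pd.isna(correct):
                findings.append(Finding(i, "correct-undefined",
                                        "correct undefined at zero contrast"))
        else:
            expected = (row["choice"] == "coherent") == (c > 0)
            if pd.isna(correct) or bool(correct) != expected:
                findings.append(Finding(i, "correct-consistency",
                                        "correct does not match choice sign vs cue sign"))
        for u in session.units:
            n = row[f"count:{u}"]
            if n < 0 or n != int(n):
                findings.append(Finding(i, "count-domain",
                                        f"count for {u} is {n}, not a nonnegative integer"))
    return findings


def write_tuning(blocks: Sequence[TuningBlock], path) -> None:
    """Write tuning blocks in the long csv dialect (stable formatting)."""
    path = Path(path)
    lines = [TUNING_MAGIC, "unit_id,stimulus_class,direction,rep,rate,baseline_rate"]
    for b in blocks:
        base = _fmt(b.baseline_rate)
        for rep in range(b.rates.shape[0]):
            for j, d in enumerate(b.directions):
                lines.append(
                    f"{b.unit_id},{b.stimulus_class},{_fmt(d)},{rep},"
                    f"{_fmt(b.rates[rep, j])},{base}"
                )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tuning(path) -> list:
    """Parse a ``tuning.csv`` file into a list of :class:`TuningBlock`."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    first, _, rest = text.partition("\n")
    _parse_header(first, TUNING_MAGIC, path)
    df = pd.read_csv(_io.StringIO(rest))
    required = {"unit_id", "stimulus_class", "direction", "rep", "rate", "baseline_rate"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    blocks = []
    for (uid, cls), grp in df.groupby(["unit_id", "stimulus_class"], sort=False):
        piv = grp.pivot(index="rep", columns="direction", values="rate").sort_index(axis=1)
        blocks.append(
            TuningBlock(
                unit_id=str(uid),
                stimulus_class=str(cls),
                directions=piv.columns.to_numpy(float),
                rates=piv.to_numpy(float),
                baseline_rate=float(grp["baseline_rate"].iloc[0]),
            )
        )
    return blocks
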