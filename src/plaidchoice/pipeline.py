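"""End-to-end orchestration: simulate -> fit-psych -> classify -> detect ->
population, with JSON configs and outputs, derived per-stage seeds, and a run
manifest (versions, sub-seeds, input hashes, stage status).

Each stage consumes only files and writes only files, so stages can be rerun
in isolation; a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import __version__
from ._utils import derive_seed
from .data_io import read_session, read_tuning, write_session, write_tuning
from .errors import InputError, PlaidChoiceError
from .psychometrics import fit_psychometric, choice_history_bias, session_qc
from .signal_detection import (
    analyze_choice_probability,
    assign_preference,
    neurometric_function,
)
from .synthetic import SimConfig, sample_units, simulate_session, simulate_tuning_blocks
from .tuning import classify_unit, fit_von_mises
from .population import (
    circular_mean,
    cp_threshold_pi_partials,
    geometric_mean_regression,
    rayleigh_test,
    summarize_unit,
    threshold_ratio_profile,
)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    tuning_reps: int = 10
    grand_cp_max_contrast: float = 20.0
    cp_min_choices: int = 5
    n_permutations: int = 0
    timecourse_window_ms: float = 100.0
    timecourse_step_ms: float = 10.0
    r2_min: float = 0.6

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    sim_seed = derive_seed(config.seed, "simulate")
    units = sample_units(config.sim, derive_seed(sim_seed, "units"))
    session, truth = simulate_session(config.sim, units, derive_seed(sim_seed, "session"))
    blocks = simulate_tuning_blocks(units, config.tuning_reps, derive_seed(sim_seed, "tuning"))
    write_session(session, outdir / "sessions.csv")
    write_tuning(blocks, outdir / "tuning.csv")
    _dump(
        {
            "units": truth.units,
            "eta": truth.eta,
            "config": truth.config,
            "n_gain_clipped": truth.n_gain_clipped,
            "psychometric_sigma": truth.psychometric_sigma,
        },
        outdir / "truth.json",
    )
    return {"outputs": ["sessions.csv", "tuning.csv", "truth.json"], "seed": sim_seed}


def stage_fit_psych(config: PipelineConfig, outdir: Path) -> dict:
    session = read_session(outdir / "sessions.csv")
    fits = {}
    for d in sorted(session.trials["pattern_direction"].unique()):
        fit = fit_psychometric(session, pattern_direction=d)
        fits[str(d)] = {**dataclasses.asdict(fit), "qc_accept": session_qc(fit, config.r2_min)}
    pooled = fit_psychometric(session, pattern_direction=None)
    fits["pooled"] = {**dataclasses.asdict(pooled), "qc_accept": session_qc(pooled, config.r2_min)}
    try:
        history = choice_history_bias(session)
    except InputError:
        history = None
    _dump({"fits": fits, "choice_history_bias": history}, outdir / "psych.json")
    return {"outputs": ["psych.json"]}


def stage_classify(config: PipelineConfig, outdir: Path) -> dict:
    blocks = read_tuning(outdir / "tuning.csv")
    by_unit = {}
    for b in blocks:
        by_unit.setdefault(b.unit_id, {})[b.stimulus_class] = b
    results = {}
    for uid, pair in sorted(by_unit.items()):
        if "grating" not in pair or "plaid" not in pair:
            continue
        vm = fit_von_mises(pair["grating"])
        pc = classify_unit(pair["grating"], pair["plaid"])
        results[uid] = {"von_mises": dataclasses.asdict(vm), **dataclasses.asdict(pc)}
    _dump(results, outdir / "pc.json")
    return {"outputs": ["pc.json"]}


def stage_detect(config: PipelineConfig, outdir: Path) -> dict:
    session = read_session(outdir / "sessions.csv")
    psych = json.loads((outdir / "psych.json").read_text())["fits"]
    cp_seed = derive_seed(config.seed, "detect")
    results = {}
    for unit in session.units:
        per_dir = {}
        for d in sorted(session.trials["pattern_direction"].unique()):
            entry = {}
            try:
                assignment = assign_preference(session, unit, d)
            except InputError as exc:
                per_dir[str(d)] = {"error": str(exc)}
                continue
            entry["preference"] = dataclasses.asdict(assignment)
            if assignment.preferred_cue != "indeterminate":
                psy_thr = psych[str(d)]["threshold"]
                try:
                    neuro = neurometric_function(
                        session, assignment, psychometric_threshold=psy_thr
                    )
                    entry["neurometric"] = dataclasses.asdict(neuro)
                except (InputError, PlaidChoiceError) as exc:
                    entry["neurometric"] = {"error": str(exc)}
                cp = analyze_choice_probability(
                    session, assignment,
                    max_contrast=config.grand_cp_max_contrast,
                    min_choices=config.cp_min_choices,
                    n_permutations=config.n_permutations,
                    rng_seed=derive_seed(cp_seed, f"{unit}:{d}"),
                    timecourse=session.has_spike_times,
                    window_ms=config.timecourse_window_ms,
                    step_ms=config.timecourse_step_ms,
                )
                entry["choice_probability"] = dataclasses.asdict(cp)
            per_dir[str(d)] = entry
        results[unit] = per_dir
    _dump(results, outdir / "sd.json")
    return {"outputs": ["sd.json"]}


def stage_population(config: PipelineConfig, outdir: Path) -> dict:
    sd = json.loads((outdir / "sd.json").read_text())
    pc = json.loads((outdir / "pc.json").read_text())
    directions = list(config.sim.pattern_directions)

    summaries = []
    for uid, per_dir in sd.items():
        if uid not in pc or pc[uid]["von_mises"]["untuned"]:
            continue
        thresholds, grand = {}, {}
        for d in directions:
            entry = per_dir.get(str(float(d)), per_dir.get(str(d), {}))
            neuro = entry.get("neurometric") or {}
            if "neuronal_threshold" in neuro and not neuro.get("degenerate"):
                thresholds[float(d)] = neuro["neuronal_threshold"]
            cp = (entry.get("choice_probability") or {}).get("grand")
            if cp:
                grand[float(d)] = cp["cp"]
        summaries.append(
            summarize_unit(
                uid,
                pc[uid]["von_mises"]["preferred_direction"],
                directions,
                thresholds,
                grand,
                pattern_index=pc[uid]["pattern_index"],
                label=pc[uid]["label"],
            )
        )

    out = {"n_units": len(summaries)}
    try:
        out["threshold_ratio_profile"] = threshold_ratio_profile(summaries).to_dict("records")
    except InputError as exc:
        out["threshold_ratio_profile"] = {"error": str(exc)}

    rows = [
        (s.best_grand_cp, s.best_threshold, s.pattern_index)
        for s in summaries
        if s.best_grand_cp is not None and s.best_threshold is not None
        and s.pattern_index is not None
    ]
    if len(rows) >= 4:
        cp_v, thr_v, pi_v = map(np.array, zip(*rows))
        try:
            out["gmr_cp_vs_threshold"] = dataclasses.asdict(
                geometric_mean_regression(thr_v, cp_v)
            )
            out["gmr_cp_vs_pattern_index"] = dataclasses.asdict(
                geometric_mean_regression(pi_v, cp_v)
            )
            out["cp_partials"] = cp_threshold_pi_partials(cp_v, thr_v, pi_v)
        except InputError as exc:
            out["population_regressions"] = {"error": str(exc)}
    prefs = [s.preferred_direction for s in summaries]
    if len(prefs) >= 2:
        z, p = rayleigh_test(prefs)
        mean, sem = circular_mean(prefs)
        out["preferred_direction_rayleigh"] = {"z": z, "p": p}
        out["preferred_direction_circular_mean"] = {"mean": mean, "sem": sem}
    out["mean_grand_cp"] = float(np.mean([v for s in summaries for v in s.grand_cp.values()])) \
        if any(s.grand_cp for s in summaries) else None
    _dump(out, outdir / "pop.json")
    return {"outputs": ["pop.json"]}


STAGES = [
    ("simulate", stage_simulate),
    ("fit-psych", stage_fit_psych),
    ("classify", stage_classify),
    ("detect", stage_detect),
    ("population", stage_population),
]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages in dependency order; returns (and writes) the manifest.

    On a stage failure, outputs of earlier stages are retained and the
    manifest records the failure point.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": {},
    }
    for name, fn in STAGES:
        try:
            info = fn(config, outdir)
            info["status"] = "ok"
            info["output_hashes"] = {
                f: _sha256(outdir / f) for f in info.get("outputs", [])
            }
        except Exception as exc:  # stage isolation: record and stop
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            break
        manifest["stages"][name] = info
    _dump(manifest, outdir / "manifest.json")
    return manifest
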