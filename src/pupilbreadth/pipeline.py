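"""End-to-end orchestration: config parsing, staged execution, run report.

The configuration is a single TOML file with one section per stage
(``[design]``, ``[observer]``, ``[pupil]``, ``[preprocess]``,
``[analysis]``, ``[output]``).  Unknown keys are rejected so parameter-name
typos cannot silently fall back to defaults.  Every random draw descends
from the single ``design.seed`` via named substreams, so identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .behavior import accuracy_validity_model, bf01_staircase_efficacy, rt_model
from .preprocess import PreprocParams, run_preprocessing
from .synthdata import ObserverParams, PupilGenParams, generate_dataset
from .windowstats import (WindowSpec, crossval_select_window,
                          fit_interaction_lme, per_participant_effect)

__all__ = ["DesignConfig", "AnalysisConfig", "PipelineConfig",
           "load_config", "run_pipeline"]

log = logging.getLogger("pupilbreadth")


@dataclass
class DesignConfig:
    variant: str = "exp1"
    n_participants: int = 12
    seed: int = 0
    include_practice: bool = True
    max_experimental_trials: int | None = None
    trace_duration_ms: float | None = None


@dataclass
class AnalysisConfig:
    search_start_ms: float = 750.0
    search_end_ms: float = 3000.0
    n_folds: int = 4
    bin_ms: float = 10.0
    window_ms: float = 100.0


@dataclass
class OutputConfig:
    out_dir: str = "pupilbreadth-out"


@dataclass
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    observer: ObserverParams = field(default_factory=ObserverParams)
    pupil: PupilGenParams = field(default_factory=PupilGenParams)
    preprocess: PreprocParams = field(default_factory=PreprocParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output: OutputConfig = field(default_factory=OutputConfig)


_SECTIONS = {
    "design": DesignConfig,
    "observer": ObserverParams,
    "pupil": PupilGenParams,
    "preprocess": PreprocParams,
    "analysis": AnalysisConfig,
    "output": OutputConfig,
}


def _build_section(cls, values: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}; "
                         f"valid keys: {sorted(known)}")
    return cls(**values)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline TOML configuration file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}; "
                         f"valid sections: {sorted(_SECTIONS)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, raw.get(name, {}), name)
    return PipelineConfig(**kwargs)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> preprocess -> pupil analysis -> behavioral analysis.

    Writes the raw and processed tables plus ``results.json`` and
    ``report.json`` to the configured output directory and returns the run
    report.  A stage failure is recorded with its cause and downstream
    stages are skipped.
    """
    from . import __version__

    out_dir = Path(config.output.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.design.seed,
                    "stages": {}, "results": {}}
    state: dict = {}

    def _stage(name, fn, deps=()):
        if any(report["stages"].get(d, {}).get("status") != "ok" for d in deps):
            report["stages"][name] = {"status": "skipped"}
            return False
        try:
            fn()
            report["stages"][name] = {"status": "ok"}
            return True
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "error", "error": str(exc)}
            return False

    def _simulate():
        d = config.design
        samples, trials = generate_dataset(
            d.n_participants, d.variant, config.observer, config.pupil,
            seed=d.seed, include_practice=d.include_practice,
            max_experimental_trials=d.max_experimental_trials,
            trace_duration_ms=d.trace_duration_ms)
        log.info("simulated %d trials, %d samples", len(trials), len(samples))
        pio.write_samples(samples, out_dir / "samples_raw.csv")
        pio.write_trials(trials, out_dir / "trials_raw.csv")
        state["samples"], state["trials"] = samples, trials

    def _preprocess():
        s, t, rep = run_preprocessing(state["samples"], state["trials"],
                                      config.preprocess)
        log.info("preprocessing: %s", rep)
        pio.write_samples(s, out_dir / "samples_proc.csv")
        pio.write_trials(t, out_dir / "trials_proc.csv")
        state["samples"], state["trials"] = s, t
        report["results"]["preprocessing"] = rep

    def _analyze_pupil():
        a = config.analysis
        cv = crossval_select_window(
            state["samples"], state["trials"],
            search=WindowSpec(a.search_start_ms, a.search_end_ms),
            n_folds=a.n_folds, bin_ms=a.bin_ms, window_ms=a.window_ms,
            seed=config.design.seed)
        res = {"crossval": cv,
               "per_participant_effects": per_participant_effect(
                   state["samples"], state["trials"], cv.selected_window)}
        if set(state["trials"].get("breadth_type", ()).unique()
               if "breadth_type" in state["trials"] else ()) == {"size", "location"}:
            res["interaction"] = fit_interaction_lme(
                state["samples"], state["trials"], cv.selected_window)
        log.info("selected window: %s", cv.selected_window)
        report["results"]["pupil"] = res

    def _analyze_behavior():
        res = {"validity": accuracy_validity_model(state["trials"]),
               "rt": rt_model(state["trials"]),
               "staircase_efficacy": bf01_staircase_efficacy(state["trials"])}
        report["results"]["behavior"] = res

    _stage("simulate", _simulate)
    _stage("preprocess", _preprocess, deps=("simulate",))
    _stage("analyze-pupil", _analyze_pupil, deps=("preprocess",))
    _stage("analyze-behavior", _analyze_behavior, deps=("preprocess",))

    jsonable = _to_jsonable(report)
    with open(out_dir / "results.json", "w") as fh:
        json.dump(jsonable.get("results", {}), fh, indent=2, sort_keys=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(jsonable, fh, indent=2, sort_keys=True)
    return jsonable
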