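"""Synthetic multi-participant datasets: behavior plus pupil traces.

Stands in for a real eye-tracking deposit.  The generator couples the
session designs (:mod:`.design`), the adaptive staircases
(:mod:`.staircase`) and a stochastic observer into trial-level behavioral
outcomes, and renders one cue-locked pupil trace per trial with:

* a per-participant tonic baseline (between-participant normal),
* a slight dilation during the 1-s cue period,
* a pupillary light response (constriction) once the noise display appears,
* an attentional-breadth effect — pupil size increasing with the ordinal
  code of the cued eccentricity — ramping in from 1750 ms after cue onset
  and plateauing at 2500 ms, with a per-participant random slope,
* white measurement noise, blinks (runs of zero samples), and an affine
  map from millimeters to tracker arbitrary units.

Defaults emulate the study conditions: ~5 mm baselines, a breadth slope of
0.008 mm per ordinal eccentricity unit with substantial between-participant
variability, 1000-Hz sampling, and staircase-held ~70% valid-trial accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream
from . import design as design_mod
from .design import Eccentricity, SessionDesign, TrialSpec, build_session
from .staircase import StaircaseState, update as staircase_update

__all__ = [
    "ObserverParams",
    "PupilGenParams",
    "simulate_response",
    "generate_trace",
    "generate_dataset",
]

SAMPLES_COLUMNS = ["participant_id", "trial_index", "t_ms", "pupil",
                   "gaze_x_deg", "gaze_y_deg", "blink_flag"]


@dataclass
class ObserverParams:
    """Generative parameters of the simulated observer.

    The two-alternative (increment/decrement) discrimination gives chance
    performance 0.5 at zero opacity.  Probability correct rises with target
    opacity along a logistic psychometric function; on validly cued trials
    the effective sensitivity is multiplied by ``validity_sensitivity_gain``
    (>= 1), producing the behavioral cueing effect.  Reaction times are
    log-normal and independent of eccentricity.
    """

    threshold_opacity_pct: float | Mapping[str, float] = 20.0
    psychometric_slope: float = 0.15  # 1/percent
    lapse_rate: float = 0.02
    validity_sensitivity_gain: float = 1.4
    rt_location_ms: float = 600.0
    rt_scale: float = 0.25

    def __post_init__(self):
        if not (0 <= self.lapse_rate <= 0.05):
            raise ValueError("lapse_rate must lie in [0, 0.05]")
        if self.validity_sensitivity_gain < 1:
            raise ValueError("validity_sensitivity_gain must be >= 1")

    def threshold_for(self, ecc: Eccentricity | str | None) -> float:
        if isinstance(self.threshold_opacity_pct, Mapping):
            key = ecc.label if isinstance(ecc, Eccentricity) else ecc
            return float(self.threshold_opacity_pct[key])
        return float(self.threshold_opacity_pct)

    def percent_correct(self, opacity_pct: float, valid: bool = True,
                        ecc: Eccentricity | str | None = None) -> float:
        """P(correct) at a given opacity; exactly 0.5 at zero opacity.

        Covert attention acts as a contrast gain: on valid trials the
        effective target strength is ``gain * opacity``, so accuracy is
        higher on valid than invalid trials at any positive opacity.
        """
        theta = self.threshold_for(ecc)
        s = self.psychometric_slope
        gain = self.validity_sensitivity_gain if valid else 1.0
        lam0 = expit(-s * theta)
        f = (expit(s * (gain * opacity_pct - theta)) - lam0) / (1.0 - lam0)
        f = min(1.0, max(0.0, f))
        return 0.5 + (0.5 - self.lapse_rate) * f


@dataclass
class PupilGenParams:
    """Generative parameters of the synthetic pupil traces.

    All amplitudes are in millimeters of pupil diameter;
    ``light_response_amplitude_mm`` is negative (a constriction).  The
    breadth effect ramps linearly from zero at ``breadth_onset_ms`` to its
    full per-participant value at ``breadth_plateau_ms`` and is held
    thereafter.  Raw output is in tracker arbitrary units via
    ``au = au_gain * mm + au_offset``; blinks are recorded as runs of zero.
    """

    baseline_mm_mean: float = 5.0
    baseline_mm_sd_between: float = 0.5
    cue_dilation_mm: float = 0.05
    light_response_amplitude_mm: float = -1.0
    light_amplitude_sd_between: float = 0.1
    light_response_latency_ms: float = 230.0
    light_response_tau_ms: float = 400.0
    breadth_slope_mm: float = 0.008
    breadth_onset_ms: float = 1750.0
    breadth_plateau_ms: float = 2500.0
    slope_sd_between: float = 0.015
    trial_jitter_mm: float = 0.1
    sample_noise_sd_mm: float = 0.15
    blink_rate_hz: float = 0.1
    blink_duration_ms: float = 120.0
    gaze_jitter_deg: float = 0.3
    au_gain: float = 500.0
    au_offset: float = 1000.0
    sampling_rate_hz: float = 1000.0

    def __post_init__(self):
        if not self.breadth_onset_ms < self.breadth_plateau_ms:
            raise ValueError("breadth_onset_ms must be < breadth_plateau_ms")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


def simulate_response(trial: TrialSpec, observer: ObserverParams,
                      rng: np.random.Generator, opacity_pct: float | None = None):
    """Simulate (accuracy, rt_ms) for one trial.

    ``opacity_pct`` may be passed explicitly or carried on the trial as a
    ``target_opacity_pct`` attribute.
    """
    if opacity_pct is None:
        opacity_pct = getattr(trial, "target_opacity_pct", None)
    if opacity_pct is None:
        raise ValueError("target opacity not set on trial; pass opacity_pct")
    p = observer.percent_correct(opacity_pct, valid=trial.validity == "valid",
                                 ecc=trial.target_ecc)
    accuracy = int(rng.random() < p)
    rt_ms = float(rng.lognormal(np.log(observer.rt_location_ms), observer.rt_scale))
    return accuracy, rt_ms


# ---------------------------------------------------------------------------
# trace generation


def _mean_trace(t_ms: np.ndarray, ecc_codes: np.ndarray, params: PupilGenParams,
                intercept_mm: float, slope_mm: float,
                jitter_mm: np.ndarray, light_amp_mm: float | None = None) -> np.ndarray:
    """Noise-free trace matrix (n_trials, n_samples) in mm."""
    if light_amp_mm is None:
        light_amp_mm = params.light_response_amplitude_mm
    t = t_ms[None, :]
    cue = params.cue_dilation_mm * np.clip(t / design_mod.CUE_DURATION_MS, 0.0, 1.0)
    t_on = design_mod.CUE_DURATION_MS + params.light_response_latency_ms
    light = light_amp_mm * (
        1.0 - np.exp(-np.clip(t - t_on, 0.0, None) / params.light_response_tau_ms)
    ) * (t >= t_on)
    ramp = np.clip((t - params.breadth_onset_ms)
                   / (params.breadth_plateau_ms - params.breadth_onset_ms), 0.0, 1.0)
    breadth = ecc_codes[:, None] * slope_mm * ramp
    return intercept_mm + jitter_mm[:, None] + cue + light + breadth


def _insert_blinks(au: np.ndarray, blink: np.ndarray, params: PupilGenParams,
                   rng: np.random.Generator, dt_ms: float) -> None:
    n_trials, n_t = au.shape
    dur_ms = n_t * dt_ms
    counts = rng.poisson(params.blink_rate_hz * dur_ms / 1000.0, size=n_trials)
    n_blink = max(1, int(round(params.blink_duration_ms / dt_ms)))
    for tr in np.nonzero(counts)[0]:
        for _ in range(counts[tr]):
            i0 = int(rng.integers(0, n_t))
            i1 = min(n_t, i0 + n_blink)
            au[tr, i0:i1] = 0.0
            blink[tr, i0:i1] = True


def generate_trace(trial: TrialSpec, params: PupilGenParams,
                   participant_effects: tuple[float, float],
                   rng: np.random.Generator,
                   duration_ms: float | None = None) -> pd.DataFrame:
    """Render the raw samples rows (arbitrary units) for a single trial."""
    intercept_mm, slope_mm = participant_effects
    if duration_ms is None:
        duration_ms = (trial.target_onset_ms + trial.target_duration_ms
                       + trial.post_target_noise_ms)
    dt = 1000.0 / params.sampling_rate_hz
    t = np.arange(0.0, duration_ms, dt)
    code = np.array([trial.cued_ecc.ordinal_code], dtype=float)
    jitter = rng.normal(0.0, params.trial_jitter_mm, size=1)
    mm = _mean_trace(t, code, params, intercept_mm, slope_mm, jitter)
    mm += rng.normal(0.0, params.sample_noise_sd_mm, size=mm.shape)
    au = params.au_gain * mm + params.au_offset
    blink = np.zeros_like(au, dtype=bool)
    if params.blink_rate_hz > 0:
        _insert_blinks(au, blink, params, rng, dt)
    return pd.DataFrame({
        "trial_index": np.full(t.size, trial.trial_index, dtype=np.int32),
        "t_ms": t.astype(np.float32),
        "pupil": au[0].astype(np.float32),
        "gaze_x_deg": rng.normal(0, params.gaze_jitter_deg, t.size).astype(np.float32),
        "gaze_y_deg": rng.normal(0, params.gaze_jitter_deg, t.size).astype(np.float32),
        "blink_flag": blink[0],
    })


# ---------------------------------------------------------------------------
# full dataset


def _staircase_n_up(variant: str) -> int:
    return 2 if variant == "exp1" else 3


def _simulate_behavior(session: SessionDesign, observer: ObserverParams,
                       n_up: int, rng: np.random.Generator,
                       start_opacity_pct: float = 25.0) -> pd.DataFrame:
    """Play the session against the observer with staircase-coupled opacity.

    One staircase per eccentricity; the presented opacity comes from the
    target eccentricity's staircase, and only validly cued trials update it
    (the accuracy criterion is defined on validly cued trials).
    """
    stairs = {e: StaircaseState(n_up=n_up, opacity_pct=start_opacity_pct,
                                eccentricity=e)
              for e in design_mod.ECCENTRICITIES}
    recs = []
    for trial in session.trials:
        st = stairs[trial.target_ecc]
        opacity = st.opacity_pct
        acc, rt = simulate_response(trial, observer, rng, opacity_pct=opacity)
        if trial.validity == "valid":
            stairs[trial.target_ecc] = staircase_update(st, bool(acc))
        recs.append(dict(
            trial_index=trial.trial_index, block=trial.block, phase=trial.phase,
            breadth_type=trial.breadth_type, cued_ecc=trial.cued_ecc.label,
            cued_loc=trial.cued_loc, validity=trial.validity,
            target_ecc=trial.target_ecc.label, target_loc=trial.target_loc,
            target_polarity=trial.target_polarity,
            target_onset_ms=trial.target_onset_ms,
            target_opacity_pct=opacity, accuracy=acc, rt_ms=rt,
        ))
    return pd.DataFrame.from_records(recs)


def generate_dataset(n_participants: int, variant: str = "exp1",
                     observer: ObserverParams | None = None,
                     pupil: PupilGenParams | None = None,
                     seed: int = 0,
                     include_practice: bool = True,
                     max_experimental_trials: int | None = None,
                     trace_duration_ms: float | None = None,
                     staircase_start_opacity_pct: float = 25.0):
    """Generate (samples, trials) tables for a synthetic cohort.

    Per participant: a fresh session design, staircase-coupled behavioral
    responses, and one raw 1000-Hz (by default) pupil trace per trial.
    Per-participant intercepts and breadth slopes are drawn from the
    between-participant normal distributions in ``pupil``.  Fully
    reproducible from ``seed``.

    ``include_practice=False`` and ``max_experimental_trials`` scale the
    dataset down for simulation studies; ``trace_duration_ms`` fixes a
    common trace length (default: long enough to cover the latest possible
    target offset).
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    observer = observer if observer is not None else ObserverParams()
    pupil = pupil if pupil is not None else PupilGenParams()
    if trace_duration_ms is None:
        trace_duration_ms = (design_mod.TARGET_ONSET_MAX_MS
                             + design_mod.TARGET_DURATION_MS
                             + design_mod.POST_TARGET_NOISE_MS)
    dt = 1000.0 / pupil.sampling_rate_hz
    t = np.arange(0.0, trace_duration_ms, dt)
    n_t = t.size
    n_up = _staircase_n_up(variant)

    all_trials, all_samples = [], []
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        session = build_session(variant, pid, seed)
        if not include_practice or max_experimental_trials is not None:
            kept = [tr for tr in session.trials
                    if include_practice or tr.phase == "experimental"]
            if max_experimental_trials is not None:
                exp_kept, out = 0, []
                for tr in kept:
                    if tr.phase == "experimental":
                        if exp_kept >= max_experimental_trials:
                            continue
                        exp_kept += 1
                    out.append(tr)
                kept = out
            session = SessionDesign(session.participant_id, session.variant,
                                    session.symbol_mapping, kept, session.seed)

        beh_rng = substream(seed, "observer", pid)
        trials = _simulate_behavior(session, observer, n_up, beh_rng,
                                    start_opacity_pct=staircase_start_opacity_pct)
        trials.insert(0, "participant_id", pid)
        trials["baseline_pupil"] = np.nan
        trials["excluded"] = False
        trials["exclusion_reason"] = "none"
        all_trials.append(trials)

        eff_rng = substream(seed, "effects", pid)
        intercept = eff_rng.normal(pupil.baseline_mm_mean, pupil.baseline_mm_sd_between)
        slope = eff_rng.normal(pupil.breadth_slope_mm, pupil.slope_sd_between)
        light_amp = eff_rng.normal(pupil.light_response_amplitude_mm,
                                   pupil.light_amplitude_sd_between)

        tr_rng = substream(seed, "trace", pid)
        codes = np.array([tr.cued_ecc.ordinal_code for tr in session.trials], dtype=float)
        n_tr = codes.size
        jitter = tr_rng.normal(0.0, pupil.trial_jitter_mm, size=n_tr)
        mm = _mean_trace(t, codes, pupil, intercept, slope, jitter, light_amp)
        mm += tr_rng.normal(0.0, pupil.sample_noise_sd_mm, size=mm.shape)
        au = (pupil.au_gain * mm + pupil.au_offset).astype(np.float32)
        blink = np.zeros(au.shape, dtype=bool)
        if pupil.blink_rate_hz > 0:
            _insert_blinks(au, blink, pupil, tr_rng, dt)
        idx = np.repeat(np.array([tr.trial_index for tr in session.trials],
                                 dtype=np.int32), n_t)
        gaze = tr_rng.normal(0.0, pupil.gaze_jitter_deg,
                             size=(2, n_tr * n_t)).astype(np.float32)
        all_samples.append(pd.DataFrame({
            "participant_id": pd.Categorical([pid] * (n_tr * n_t)),
            "trial_index": idx,
            "t_ms": np.tile(t.astype(np.float32), n_tr),
            "pupil": au.ravel(),
            "gaze_x_deg": gaze[0],
            "gaze_y_deg": gaze[1],
            "blink_flag": blink.ravel(),
        }))

    trials_df = pd.concat(all_trials, ignore_index=True)
    samples_df = pd.concat(all_samples, ignore_index=True)
    samples_df["participant_id"] = samples_df["participant_id"].astype("category")
    samples_df.attrs["preprocessing_state"] = "raw"
    return samples_df, trials_df
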