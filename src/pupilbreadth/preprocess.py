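"""Pupil preprocessing chain.

Fixed order: blink interpolation -> downsampling -> arbitrary-units-to-mm
conversion -> per-trial baseline correction -> baseline-outlier flagging.
A processing-state marker travels with the samples table (``DataFrame.attrs``)
and each step refuses input that is not at the preceding stage, so the chain
cannot be reordered or re-run on already-processed data.

Conventions: time is in ms relative to cue onset (t = 0); the baseline is
the mean pupil size over the half-open window [0, 50) ms; baseline z-scores
are computed within participant and trials beyond +/-2 z are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PreprocParams",
    "interpolate_blinks",
    "downsample",
    "au_to_mm",
    "baseline_correct",
    "flag_baseline_outliers",
    "run_preprocessing",
]

_STATE_KEY = "preprocessing_state"
_CHAIN = ["raw", "blinks_interpolated", "downsampled", "mm", "baseline_corrected"]


@dataclass
class PreprocParams:
    """Parameters of the preprocessing chain.

    ``mm_coeff_a``/``mm_coeff_b`` define the lab-specific affine map from
    tracker arbitrary units to millimeters of diameter
    (``mm = a * au + b``); they must be supplied in the configuration.
    """

    downsample_factor: int = 10
    baseline_window_ms: tuple = (0.0, 50.0)
    z_threshold: float = 2.0
    mm_coeff_a: float | None = None
    mm_coeff_b: float | None = None
    blink_margin_ms: float = 50.0
    blink_min_duration_ms: float = 20.0

    def __post_init__(self):
        if self.downsample_factor < 1 or int(self.downsample_factor) != self.downsample_factor:
            raise ValueError("downsample_factor must be a positive integer")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


def _require_state(samples: pd.DataFrame, expected: str, step: str) -> None:
    state = samples.attrs.get(_STATE_KEY, "raw")
    if state != expected:
        raise ValueError(
            f"{step} expects samples at stage {expected!r} but got {state!r}; "
            f"the pipeline order is fixed: {' -> '.join(_CHAIN)}"
        )


def _group_bounds(samples: pd.DataFrame) -> np.ndarray:
    """Start indices of each (participant, trial) run, plus the end sentinel.

    Samples must be sorted with each trial's rows contiguous and time
    increasing within trial (the generator and readers guarantee this).
    """
    pid = samples["participant_id"]
    codes = pid.cat.codes.to_numpy() if hasattr(pid, "cat") else pd.factorize(pid)[0]
    key = codes.astype(np.int64) * 10_000_000 + samples["trial_index"].to_numpy(np.int64)
    change = np.flatnonzero(np.diff(key)) + 1
    return np.concatenate(([0], change, [len(samples)]))


def _sample_dt_ms(samples: pd.DataFrame, bounds: np.ndarray) -> float:
    t = samples["t_ms"].to_numpy()
    if bounds[1] - bounds[0] < 2:
        raise ValueError("trials must contain at least two samples")
    return float(t[1] - t[0])


def interpolate_blinks(samples: pd.DataFrame, params: PreprocParams) -> pd.DataFrame:
    """Linearly interpolate blink episodes in the raw pupil signal.

    Blinks are runs of invalid samples (flagged, non-finite, or <= 0 pupil).
    Runs of at least ``blink_min_duration_ms`` are extended by
    ``blink_margin_ms`` on both sides before interpolation between the
    flanking valid samples; leading/trailing blinks take the nearest valid
    value.  Trials with no valid samples are marked missing (all-NaN).
    """
    _require_state(samples, "raw", "interpolate_blinks")
    bounds = _group_bounds(samples)
    dt = _sample_dt_ms(samples, bounds)
    margin = int(round(params.blink_margin_ms / dt))
    min_len = max(1, int(round(params.blink_min_duration_ms / dt)))

    pupil = samples["pupil"].to_numpy(np.float64, copy=True)
    invalid = (~np.isfinite(pupil)) | (pupil <= 0)
    if "blink_flag" in samples:
        invalid |= samples["blink_flag"].to_numpy(bool)

    n_runs = 0
    n_missing_trials = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = invalid[s:e]
        if not m.any():
            continue
        if m.all():
            pupil[s:e] = np.nan
            n_missing_trials += 1
            continue
        seg = pupil[s:e]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        mask = m.copy()
        for r0, r1 in zip(starts, ends):
            n_runs += 1
            if r1 - r0 >= min_len:
                mask[max(0, r0 - margin):min(len(mask), r1 + margin)] = True
        if mask.all():
            pupil[s:e] = np.nan
            n_missing_trials += 1
            continue
        pos = np.arange(len(mask))
        seg[mask] = np.interp(pos[mask], pos[~mask], seg[~mask])
        pupil[s:e] = seg

    out = samples.copy(deep=False)
    out["pupil"] = pupil.astype(np.float32)
    out.attrs[_STATE_KEY] = "blinks_interpolated"
    out.attrs["n_blink_runs_interpolated"] = int(n_runs)
    out.attrs["n_trials_fully_missing"] = int(n_missing_trials)
    return out


def downsample(samples: pd.DataFrame, factor: int) -> pd.DataFrame:
    """Downsample by block means of ``factor`` consecutive samples.

    Each output sample is the mean of ``factor`` input samples; the output
    timestamp is the first timestamp of each block; a trailing partial
    block is dropped.  ``factor=1`` is the identity (state still advances).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    _require_state(samples, "blinks_interpolated", "downsample")
    factor = int(factor)
    if factor == 1:
        out = samples.copy(deep=False)
        out.attrs[_STATE_KEY] = "downsampled"
        return out
    bounds = _group_bounds(samples)
    counts = np.diff(bounds)
    pos = np.arange(len(samples)) - np.repeat(bounds[:-1], counts)
    nbins = counts // factor
    keep = pos < np.repeat(nbins, counts) * factor
    gid = np.repeat(np.arange(len(counts)), counts)
    key = gid.astype(np.int64) * 100_000 + pos // factor

    df = samples.loc[keep]
    key = key[keep]
    g = df.groupby(key, sort=False, observed=True)
    out = g.agg(
        participant_id=("participant_id", "first"),
        trial_index=("trial_index", "first"),
        t_ms=("t_ms", "first"),
        pupil=("pupil", "mean"),
        gaze_x_deg=("gaze_x_deg", "mean"),
        gaze_y_deg=("gaze_y_deg", "mean"),
        blink_flag=("blink_flag", "any"),
    ).reset_index(drop=True)
    out["participant_id"] = out["participant_id"].astype("category")
    out["pupil"] = out["pupil"].astype(np.float32)
    out.attrs[_STATE_KEY] = "downsampled"
    return out


def au_to_mm(samples: pd.DataFrame, params: PreprocParams) -> pd.DataFrame:
    """Convert pupil size from tracker arbitrary units to millimeters.

    Applies the affine lab calibration ``mm = mm_coeff_a * au + mm_coeff_b``
    samplewise.
    """
    _require_state(samples, "downsampled", "au_to_mm")
    if params.mm_coeff_a is None or params.mm_coeff_b is None:
        raise ValueError(
            "millimeter conversion coefficients are not set; provide "
            "'preprocess.mm_coeff_a' and 'preprocess.mm_coeff_b' in the configuration"
        )
    out = samples.copy(deep=False)
    out["pupil"] = (params.mm_coeff_a * samples["pupil"].to_numpy(np.float64)
                    + params.mm_coeff_b).astype(np.float32)
    out.attrs[_STATE_KEY] = "mm"
    return out


def baseline_correct(samples: pd.DataFrame, trials: pd.DataFrame,
                     params: PreprocParams):
    """Subtract each trial's baseline (mean pupil over [0, 50) ms post cue).

    The per-trial baseline is stored in ``trials['baseline_pupil']``; trials
    with no usable samples in the baseline window are marked missing.
    Returns the corrected ``(samples, trials)``.
    """
    _require_state(samples, "mm", "baseline_correct")
    lo, hi = params.baseline_window_ms
    t = samples["t_ms"].to_numpy()
    in_win = (t >= lo) & (t < hi)
    bounds = _group_bounds(samples)
    counts = np.diff(bounds)
    gid = np.repeat(np.arange(len(counts)), counts)
    pupil = samples["pupil"].to_numpy(np.float64)

    with np.errstate(invalid="ignore"):
        win = in_win & np.isfinite(pupil)
        num = np.bincount(gid[win], weights=pupil[win], minlength=len(counts))
        den = np.bincount(gid[win], minlength=len(counts))
        baseline = np.where(den > 0, num / np.maximum(den, 1), np.nan)

    starts = bounds[:-1]
    key_df = pd.DataFrame({
        "participant_id": samples["participant_id"].to_numpy()[starts],
        "trial_index": samples["trial_index"].to_numpy()[starts],
        "baseline_pupil": baseline,
    })
    out_trials = trials.drop(columns=["baseline_pupil"], errors="ignore").merge(
        key_df, on=["participant_id", "trial_index"], how="left")
    missing = ~np.isfinite(out_trials["baseline_pupil"].to_numpy(np.float64))
    if "excluded" not in out_trials:
        out_trials["excluded"] = False
        out_trials["exclusion_reason"] = "none"
    out_trials.loc[missing, "excluded"] = True
    out_trials.loc[missing, "exclusion_reason"] = "missing"

    out = samples.copy(deep=False)
    out["pupil"] = (pupil - baseline[gid]).astype(np.float32)
    out.attrs[_STATE_KEY] = "baseline_corrected"
    return out, out_trials


def flag_baseline_outliers(trials: pd.DataFrame, params: PreprocParams) -> pd.DataFrame:
    """Flag trials whose baseline pupil is beyond +/- ``z_threshold`` z-scores.

    z-scores are computed within participant over that participant's
    non-missing trials.  Participants with fewer than 3 usable trials are
    left unflagged with a warning.
    """
    if "baseline_pupil" not in trials:
        raise ValueError("trials must carry 'baseline_pupil'; run baseline_correct first")
    out = trials.copy()
    if "excluded" not in out:
        out["excluded"] = False
        out["exclusion_reason"] = "none"
    usable = np.isfinite(out["baseline_pupil"].to_numpy(np.float64)) & (
        out["exclusion_reason"].to_numpy() != "missing")
    for pid, idx in out.groupby("participant_id", observed=True).groups.items():
        idx = np.asarray(idx)
        sel = idx[usable[idx]]
        if len(sel) < 3:
            warnings.warn(f"participant {pid!r} has fewer than 3 usable trials; "
                          "baseline z-flagging skipped")
            continue
        b = out.loc[sel, "baseline_pupil"].to_numpy(np.float64)
        sd = b.std(ddof=1)
        if sd == 0:
            continue
        z = (b - b.mean()) / sd
        bad = sel[np.abs(z) > params.z_threshold]
        out.loc[bad, "excluded"] = True
        out.loc[bad, "exclusion_reason"] = "baseline_outlier"
    return out


def run_preprocessing(samples: pd.DataFrame, trials: pd.DataFrame,
                      params: PreprocParams):
    """Run the full chain and return ``(samples, trials, report)``.

    The report gives per-step counts: blink runs interpolated, missing
    trials, baseline outliers, and the total excluded fraction.
    """
    s = interpolate_blinks(samples, params)
    n_runs = s.attrs.get("n_blink_runs_interpolated", 0)
    s = downsample(s, params.downsample_factor)
    s = au_to_mm(s, params)
    s, t = baseline_correct(s, trials, params)
    t = flag_baseline_outliers(t, params)
    n_total = len(t)
    n_missing = int((t["exclusion_reason"] == "missing").sum())
    n_outlier = int((t["exclusion_reason"] == "baseline_outlier").sum())
    report = {
        "n_blink_runs_interpolated": int(n_runs),
        "n_trials": n_total,
        "n_trials_missing": n_missing,
        "n_trials_baseline_outlier": n_outlier,
        "fraction_excluded": float((n_missing + n_outlier) / max(n_total, 1)),
    }
    return s, t, report
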