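"""Reading and writing the delimited table schemas.

Both tables are plain UTF-8 CSV with a header row: the samples table is
long-format (one row per eye-tracker sample) and the trials table has one
row per trial.  The preprocessing-state marker does not survive a round
trip; freshly read samples are treated as raw unless a state is passed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_samples", "write_samples", "read_trials", "write_trials"]

_SAMPLE_DTYPES = {
    "trial_index": np.int32,
    "t_ms": np.float32,
    "pupil": np.float32,
    "gaze_x_deg": np.float32,
    "gaze_y_deg": np.float32,
}


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False)


def read_samples(path: str | Path, state: str = "raw") -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": "category"})
    for col, dt in _SAMPLE_DTYPES.items():
        if col in df:
            df[col] = df[col].astype(dt)
    if "blink_flag" in df:
        df["blink_flag"] = df["blink_flag"].astype(bool)
    df = df.sort_values(["participant_id", "trial_index", "t_ms"],
                        kind="stable", ignore_index=True)
    df.attrs["preprocessing_state"] = state
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "excluded" in df:
        df["excluded"] = df["excluded"].astype(bool)
    return df
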