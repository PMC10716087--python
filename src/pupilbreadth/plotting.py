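"""Condition-mean trace plot with the selected analysis window shaded."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .windowstats import WindowSpec

__all__ = ["plot_condition_traces"]


def plot_condition_traces(samples: pd.DataFrame, trials: pd.DataFrame,
                          window: WindowSpec | None = None, ax=None):
    """Plot per-eccentricity mean baseline-corrected pupil traces.

    Optionally shades the selected analysis window.  Returns the axes.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    if ax is None:
        matplotlib.use("Agg", force=False)
        _, ax = plt.subplots(figsize=(7, 4))
    keep = trials
    if "excluded" in keep:
        keep = keep[~keep["excluded"].astype(bool)]
    merged = samples.merge(
        keep[["participant_id", "trial_index", "cued_ecc"]],
        on=["participant_id", "trial_index"], how="inner")
    for ecc in ("near", "medium", "far"):
        d = merged[merged["cued_ecc"] == ecc]
        m = d.groupby("t_ms", observed=True)["pupil"].mean()
        ax.plot(m.index.to_numpy(np.float64), m.to_numpy(np.float64), label=ecc)
    if window is not None:
        ax.axvspan(window.start_ms, window.end_ms, color="pink", alpha=0.4)
    ax.set_xlabel("time since cue onset (ms)")
    ax.set_ylabel("baseline-corrected pupil (mm)")
    ax.legend(title="cued eccentricity")
    return ax
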