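"""n-up-1-down adaptive opacity staircases.

The discrimination target's opacity is lowered by one step after ``n_up``
consecutive correct responses and raised by one step after any error.  Such
a staircase converges to the opacity where the probability of ``n_up``
consecutive correct responses is 1/2, i.e. to percent-correct
``0.5 ** (1 / n_up)`` — about 70.7% for the 2-up-1-down rule and 79.4% for
3-up-1-down.  One independent staircase is run per eccentricity so task
difficulty is equated across annuli.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from ._rng import substream

__all__ = ["StaircaseState", "update", "equilibrium_accuracy", "simulate_convergence"]

DEFAULT_START_OPACITY = 50.0
DEFAULT_OPACITY_MIN = 1.0


@dataclass(frozen=True)
class StaircaseState:
    """Immutable state of one staircase."""

    n_up: int
    opacity_pct: float = DEFAULT_START_OPACITY
    consecutive_correct: int = 0
    step_pct: float = 1.0
    opacity_min: float = DEFAULT_OPACITY_MIN
    eccentricity: object = None

    def __post_init__(self):
        if self.n_up < 1:
            raise ValueError("n_up must be >= 1")
        if not (0 < self.opacity_min <= self.opacity_pct <= 100):
            raise ValueError("opacity must lie in [opacity_min, 100] with opacity_min > 0")
        if not (0 <= self.consecutive_correct < self.n_up):
            raise ValueError("consecutive_correct must lie in [0, n_up)")


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one response.

    ``n_up`` correct responses in a row lower the opacity by one step
    (clamped at ``opacity_min``); a single error raises it by one step
    (clamped at 100).  Either event resets the run counter.
    """
    if correct:
        cc = state.consecutive_correct + 1
        if cc == state.n_up:
            new_op = max(state.opacity_min, state.opacity_pct - state.step_pct)
            return replace(state, opacity_pct=new_op, consecutive_correct=0)
        return replace(state, consecutive_correct=cc)
    new_op = min(100.0, state.opacity_pct + state.step_pct)
    return replace(state, opacity_pct=new_op, consecutive_correct=0)


def equilibrium_accuracy(n_up: int) -> float:
    """Closed-form asymptotic percent correct of an n-up-1-down staircase."""
    return 0.5 ** (1.0 / n_up)


def _check_monotone(observer: Callable[[float], float]) -> None:
    grid = np.arange(0.0, 101.0, 1.0)
    p = np.array([observer(o) for o in grid])
    if np.any(np.diff(p) < -1e-9):
        raise ValueError("observer must have a non-decreasing psychometric function of opacity")


def simulate_convergence(
    n_up: int,
    observer: Callable[[float], float],
    n_trials: int,
    seed: int,
    burn_in: int = 500,
    start_opacity: float = DEFAULT_START_OPACITY,
    opacity_min: float = DEFAULT_OPACITY_MIN,
):
    """Run the staircase against a simulated observer.

    ``observer`` maps opacity (percent) to probability correct and must be
    monotone non-decreasing.  Returns ``(accuracy, opacity_trace)`` where
    accuracy is the mean proportion correct after the first ``burn_in``
    trials and ``opacity_trace`` is the opacity presented on each trial.
    """
    if n_trials < 200:
        raise ValueError("n_trials must be >= 200")
    if burn_in >= n_trials:
        raise ValueError("burn_in must be smaller than n_trials")
    _check_monotone(observer)
    rng = substream(seed, "staircase")
    state = StaircaseState(n_up=n_up, opacity_pct=start_opacity, opacity_min=opacity_min)
    trace = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    for i in range(n_trials):
        trace[i] = state.opacity_pct
        c = bool(rng.random() < observer(state.opacity_pct))
        correct[i] = c
        state = update(state, c)
    return float(correct[burn_in:].mean()), trace
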