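"""Session designs for the covert-attention cueing experiments.

Builds complete trial-by-trial schedules for the three experiment variants:

* ``exp1`` — symbolic cues (one of three shapes) indicate which of three
  concentric annuli (near 1.16 deg, medium 3.47 deg, far 10.40 deg) the
  target is most likely to appear on (size cueing only).
* ``exp2`` — alphanumeric cues (e.g. ``U2``) indicate both the annulus and
  a location on it (location cueing only).
* ``exp3`` — both cue types, blocked: one half of the session uses location
  cues, the other half size cues.

Each session has 330 trials in 10 equal blocks.  Cues are valid on exactly
80% of trials within every cued-eccentricity cell.  Designs are fully
deterministic given (variant, participant id, seed).
"""

from __future__ import annotations

import enum
import itertools
import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "Eccentricity",
    "ECCENTRICITIES",
    "TrialSpec",
    "SessionDesign",
    "VARIANTS",
    "build_session",
    "counterbalance_symbol_mapping",
    "sample_target_onset",
    "session_to_frame",
]

VARIANTS = ("exp1", "exp2", "exp3")

#: Symbolic cues used in experiment 1 (assignment counterbalanced).
EXP1_SYMBOLS = ("□", "○", "◁")  # square, circle, triangle

#: Fixed numeric eccentricity codes used in experiments 2 and 3.
ECC_CODES = ("1", "2", "3")

#: Fixed location codes used in experiments 2 and 3.
LOC_CODES = {"U": "up", "D": "down", "R": "right", "L": "left"}

LOCATIONS = ("up", "down", "left", "right")

CUE_DURATION_MS = 1000
TARGET_DURATION_MS = 30
POST_TARGET_NOISE_MS = 300

#: Earliest possible target onset relative to cue onset (ms); targets appear
#: at a random moment within the following second.
TARGET_ONSET_MIN_MS = 3000
TARGET_ONSET_MAX_MS = 4000

N_TRIALS = 330
N_BLOCKS = 10
VALID_FRACTION = 0.8


class Eccentricity(enum.Enum):
    """Annulus eccentricity: radius in degrees of visual angle and the
    ordinal code (-1/0/+1) used throughout the statistical models."""

    NEAR = ("near", 1.16, -1)
    MEDIUM = ("medium", 3.47, 0)
    FAR = ("far", 10.40, 1)

    def __init__(self, label: str, radius_deg: float, ordinal_code: int):
        self.label = label
        self.radius_deg = radius_deg
        self.ordinal_code = ordinal_code

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Eccentricity.{self.name}"


ECCENTRICITIES = (Eccentricity.NEAR, Eccentricity.MEDIUM, Eccentricity.FAR)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial."""

    trial_index: int
    block: int
    phase: str  # practice | experimental
    breadth_type: str  # size | location
    cued_ecc: Eccentricity
    cued_loc: str  # up | down | left | right | none
    validity: str  # valid | invalid
    target_ecc: Eccentricity
    target_loc: str
    target_polarity: str  # increment | decrement
    target_onset_ms: float
    cue_duration_ms: int = CUE_DURATION_MS
    target_duration_ms: int = TARGET_DURATION_MS
    post_target_noise_ms: int = POST_TARGET_NOISE_MS


@dataclass
class SessionDesign:
    """A complete, ordered session schedule for one participant."""

    participant_id: str
    variant: str
    symbol_mapping: dict
    trials: list = field(default_factory=list)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return session_to_frame(self)


def participant_index(participant_id: str) -> int:
    """Stable integer index for a participant id.

    Trailing digits are used when present (``"p07"`` -> 7) so consecutive
    participant numbers cycle through counterbalancing schemes; otherwise a
    CRC32 hash of the id is used.
    """
    if not participant_id:
        raise ValueError("participant_id must be non-empty")
    m = re.search(r"(\d+)$", participant_id)
    if m:
        return int(m.group(1))
    return zlib.crc32(participant_id.encode("utf-8"))


def counterbalance_symbol_mapping(participant_id: str, variant: str = "exp1") -> dict:
    """Mapping from cue symbol to :class:`Eccentricity` for one participant.

    For ``exp1`` the three shape symbols are assigned to the three
    eccentricities using one of the 6 permutations, chosen from the
    participant index so that consecutive participants cycle through all
    permutations equally often.  Experiments 2 and 3 use the fixed numeric
    code scheme (1/2/3 = near/medium/far); location codes are in
    :data:`LOC_CODES`.
    """
    if not participant_id:
        raise ValueError("participant_id must be non-empty")
    if variant == "exp1":
        perms = list(itertools.permutations(ECCENTRICITIES))
        perm = perms[(participant_index(participant_id) - 1) % 6]
        return dict(zip(EXP1_SYMBOLS, perm))
    if variant in ("exp2", "exp3"):
        return dict(zip(ECC_CODES, ECCENTRICITIES))
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def sample_target_onset(rng: np.random.Generator) -> float:
    """Draw a target onset uniformly from [3000, 4000) ms post cue onset.

    The noise display runs for 3000 ms before the one-second window in which
    the target can appear, so 3000 ms is the earliest possible onset.
    """
    return float(rng.uniform(TARGET_ONSET_MIN_MS, TARGET_ONSET_MAX_MS))


# ---------------------------------------------------------------------------
# cell construction


def _other_eccs(ecc: Eccentricity):
    return [e for e in ECCENTRICITIES if e is not ecc]


def _polarity_cycle(n: int):
    return [("increment", "decrement")[i % 2] for i in range(n)]


def _size_cell(ecc: Eccentricity, n: int, phase: str, rng: np.random.Generator):
    """Trials for one cued-eccentricity cell under size cueing.

    Exactly 80% valid; invalid targets split evenly over the two non-cued
    annuli; polarity balanced within valid and invalid subsets.
    """
    n_valid = round(n * VALID_FRACTION)
    n_invalid = n - n_valid
    rows = []
    for pol, loc in zip(_polarity_cycle(n_valid), itertools.cycle(LOCATIONS)):
        rows.append(dict(phase=phase, breadth_type="size", cued_ecc=ecc, cued_loc="none",
                         validity="valid", target_ecc=ecc,
                         target_loc=loc, target_polarity=pol))
    others = _other_eccs(ecc)
    for i, pol in enumerate(_polarity_cycle(n_invalid)):
        rows.append(dict(phase=phase, breadth_type="size", cued_ecc=ecc, cued_loc="none",
                         validity="invalid", target_ecc=others[i % 2],
                         target_loc=LOCATIONS[i % 4], target_polarity=pol))
    return rows


def _location_cell(ecc: Eccentricity, n: int, phase: str, rng: np.random.Generator):
    """Trials for one cued-eccentricity cell under location cueing.

    Cued locations cycle over the four positions as evenly as ``n`` allows;
    invalid targets are drawn uniformly from the 11 non-cued
    (eccentricity, location) combinations.
    """
    n_valid = round(n * VALID_FRACTION)
    validity = ["valid"] * n_valid + ["invalid"] * (n - n_valid)
    cells = [(e, l) for e in ECCENTRICITIES for l in LOCATIONS]
    rows = []
    for i, (val, loc, pol) in enumerate(
        zip(validity, itertools.cycle(LOCATIONS), _polarity_cycle(n))
    ):
        if val == "valid":
            t_ecc, t_loc = ecc, loc
        else:
            others = [c for c in cells if c != (ecc, loc)]
            t_ecc, t_loc = others[rng.integers(len(others))]
        rows.append(dict(phase=phase, breadth_type="location", cued_ecc=ecc,
                         cued_loc=loc, validity=val, target_ecc=t_ecc,
                         target_loc=t_loc, target_polarity=pol))
    return rows


def _segment(breadth_type: str, n_per_ecc: int, phase: str, rng: np.random.Generator):
    make = _size_cell if breadth_type == "size" else _location_cell
    rows = []
    for ecc in ECCENTRICITIES:
        rows.extend(make(ecc, n_per_ecc, phase, rng))
    rng.shuffle(rows)
    return rows


def build_session(variant: str, participant_id: str, seed: int) -> SessionDesign:
    """Build the full, shuffled session schedule for one participant.

    330 trials in 10 equal blocks.  ``exp1``/``exp2``: 90 practice then 240
    experimental trials.  ``exp3``: 30 practice and 300 experimental trials,
    the experimental trials split 150/150 between location- and size-cueing
    halves (five contiguous blocks each, order counterbalanced across
    participants); each half is preceded by half of the practice trials.
    Identical arguments always produce an identical design.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if seed < 0 or int(seed) != seed:
        raise ValueError("seed must be a non-negative integer")
    rng = substream(int(seed), "design", variant, participant_id)

    if variant in ("exp1", "exp2"):
        btype = "size" if variant == "exp1" else "location"
        rows = _segment(btype, 30, "practice", rng) + _segment(btype, 80, "experimental", rng)
    else:
        first_size = participant_index(participant_id) % 2 == 0
        halves = ("size", "location") if first_size else ("location", "size")
        rows = []
        for btype in halves:
            rows.extend(_segment(btype, 5, "practice", rng))
            rows.extend(_segment(btype, 50, "experimental", rng))

    assert len(rows) == N_TRIALS
    per_block = N_TRIALS // N_BLOCKS
    trials = []
    for i, row in enumerate(rows):
        trials.append(TrialSpec(trial_index=i + 1, block=i // per_block + 1,
                                target_onset_ms=sample_target_onset(rng), **row))
    mapping = counterbalance_symbol_mapping(participant_id, variant)
    return SessionDesign(participant_id=participant_id, variant=variant,
                         symbol_mapping=mapping, trials=trials, seed=int(seed))


def session_to_frame(design: SessionDesign) -> pd.DataFrame:
    """Serialize a design to a tidy table, one row per trial."""
    recs = []
    for t in design.trials:
        recs.append(dict(
            trial_index=t.trial_index, block=t.block, phase=t.phase,
            breadth_type=t.breadth_type, cued_ecc=t.cued_ecc.label,
            cued_loc=t.cued_loc, validity=t.validity,
            target_ecc=t.target_ecc.label, target_loc=t.target_loc,
            target_polarity=t.target_polarity,
            target_onset_ms=t.target_onset_ms,
            cue_duration_ms=t.cue_duration_ms,
            target_duration_ms=t.target_duration_ms,
            post_target_noise_ms=t.post_target_noise_ms,
        ))
    return pd.DataFrame.from_records(recs)
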