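"""Named, reproducible random substreams.

Every stochastic stage of the pipeline draws from a substream derived from
the single top-level seed plus a stable string label, so stages can be
re-run in isolation without replaying the whole pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``.

    The same (seed, labels) pair always yields an identical stream;
    distinct labels yield statistically independent streams.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    key = tuple(_label_key(lab) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
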