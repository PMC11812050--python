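"""Deterministic per-stage random substreams derived from one master seed."""
from __future__ import annotations

import numpy as np

# Fixed stream indices: adding a stage appends, never reorders.
_STREAMS = {
    "climate": 0,
    "covariates": 1,
    "catalog": 2,
    "esm": 3,
    "observations": 4,
    "mcmc": 5,
    "rof": 6,
    "misc": 7,
}


def substream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Generator for a named stage, optionally replicated (``index``)."""
    key = (_STREAMS[stage], index)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def substream_seed(seed: int, stage: str, index: int = 0) -> int:
    """A plain integer seed (< 2^31) for libraries that need one."""
    key = (_STREAMS[stage], index)
    state = np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0]
    return int(state % (2**31 - 1))
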