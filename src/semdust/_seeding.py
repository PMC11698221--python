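"""Derivation of per-stage random streams from one master seed.

Every stage of the pipeline draws from its own :class:`numpy.random.Generator`
spawned from ``SeedSequence(master_seed, spawn_key=(stage_id,))`` with the
fixed stage ids below, so a stage can be rerun independently of the others
and a run manifest (master seed + config) reproduces any output exactly.
"""

from __future__ import annotations

import numpy as np

STAGE_IDS = {
    "generate": 0,
    "measure": 1,
    "survey": 2,
    "mc_electron": 3,
    "blank": 4,
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for one named pipeline stage derived from the master seed."""
    try:
        stage_id = STAGE_IDS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(STAGE_IDS)}")
    seq = np.random.SeedSequence(entropy=master_seed, spawn_key=(stage_id,))
    return np.random.default_rng(seq)
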