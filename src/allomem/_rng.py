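"""Hierarchical random-number streams.

A single master seed fans out into named, order-independent substreams
(per stage, per subject, per environment) so that any component can be
re-simulated in isolation and the whole cohort is reproducible without any
global state.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0x7FFFFFFF
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Generator for the substream identified by ``keys`` under ``master_seed``."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
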