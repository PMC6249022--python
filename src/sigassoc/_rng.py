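"""Deterministic, key-addressed random streams.

Every stochastic step in the pipeline (one-sample-per-patient draws, cohort
simulation, permutation shuffles) gets its own generator derived from a master
seed plus a tuple of string/int keys. Streams are therefore independent of
iteration order and of unrelated entities: adding a patient, a cancer type or
a driver never perturbs another entity's draws.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stable_key", "child_rng", "child_seed"]

_MOD = 2**31  # derived seeds stay within a signed 32-bit range


def stable_key(part: object) -> int:
    """Map an arbitrary key component to a stable non-negative integer.

    Uses SHA-256 of the string form, so the mapping is identical across
    processes and Python versions (unlike ``hash``).
    """
    if isinstance(part, (int, np.integer)):
        return int(part) % _MOD
    digest = hashlib.sha256(str(part).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % _MOD


def child_seed(master_seed: int, *keys: object) -> int:
    """A sub-seed (< 2**31) for the stream addressed by ``keys``."""
    ss = np.random.SeedSequence(
        int(master_seed) % _MOD, spawn_key=tuple(stable_key(k) for k in keys)
    )
    return int(ss.generate_state(1, np.uint32)[0]) % _MOD


def child_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Generator for the independent stream addressed by ``keys``."""
    ss = np.random.SeedSequence(
        int(master_seed) % _MOD, spawn_key=tuple(stable_key(k) for k in keys)
    )
    return np.random.Generator(np.random.PCG64(ss))
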