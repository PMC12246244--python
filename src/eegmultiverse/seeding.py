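"""Deterministic seed derivation.

A single master seed reproduces an entire multiverse run.  Child seeds are
derived from the master seed plus a stable textual context (e.g. a forking-path
id, participant id and processing stage), so that adding or removing paths
never perturbs the random streams of the remaining ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master_seed: int, *context: object) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and context.

    Context tokens are converted to strings and hashed with CRC32 (stable
    across processes and Python versions, unlike ``hash``).
    """
    tokens = [int(master_seed) & 0xFFFFFFFF]
    tokens += [zlib.crc32(str(t).encode("utf-8")) for t in context]
    ss = np.random.SeedSequence(tokens)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(master_seed: int, *context: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded via :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *context))
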