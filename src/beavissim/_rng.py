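"""Named, hierarchical random streams.

Every stochastic operation in the package draws from a generator obtained
through :func:`rng_for`, keyed by a root seed plus a tuple of names (module,
operation, replicate index, ...).  Two calls with the same root and key yield
bit-identical streams; different keys yield statistically independent streams.
The scheme is counter-based: string keys are hashed with CRC-32 into the
``spawn_key`` of a :class:`numpy.random.SeedSequence`, so any cell of a large
experiment can be regenerated in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_sequence", "rng_for"]


def _key_ints(keys: tuple) -> tuple[int, ...]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            if k < 0:
                raise ValueError("seed keys must be non-negative")
            out.append(int(k))
        elif isinstance(k, str):
            out.append(zlib.crc32(k.encode("utf-8")))
        else:
            raise TypeError(f"unsupported seed key type: {type(k)!r}")
    return tuple(out)


def child_sequence(root, *keys) -> np.random.SeedSequence:
    """Derive a child ``SeedSequence`` from ``root`` and a tuple of names.

    ``root`` may be an integer seed or an existing ``SeedSequence``; in the
    latter case the child extends the parent's spawn key.
    """
    ints = _key_ints(keys)
    if isinstance(root, np.random.SeedSequence):
        return np.random.SeedSequence(
            entropy=root.entropy, spawn_key=tuple(root.spawn_key) + ints
        )
    if root is None:
        raise ValueError("a seed is required; got None")
    return np.random.SeedSequence(entropy=int(root), spawn_key=ints)


def rng_for(root, *keys) -> np.random.Generator:
    """A ``numpy`` Generator for the named stream under ``root``."""
    return np.random.Generator(np.random.PCG64(child_sequence(root, *keys)))
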