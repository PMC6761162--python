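"""Deterministic random-stream management.

Every stochastic operation in the package draws from a numpy ``Generator``
created by :func:`substream`, which derives an independent child stream from
a single root seed and a named path.  The same ``(seed, *path)`` pair always
yields the same stream, distinct paths yield statistically independent
streams, and adding a new consumer never perturbs existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _path_key(path: tuple[str, ...]) -> tuple[int, ...]:
    return tuple(
        int.from_bytes(hashlib.blake2s(p.encode("utf8"), digest_size=4).digest(), "little")
        for p in path
    )


def substream(seed: int, *path: str) -> np.random.Generator:
    """Return a named, reproducible child generator of ``seed``.

    Parameters
    ----------
    seed:
        Root integer seed.
    *path:
        One or more string labels naming the consumer, e.g.
        ``substream(seed, "simulate", "depths")``.
    """
    if not path:
        raise ValueError("substream requires at least one path component")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_path_key(path))
    return np.random.default_rng(ss)
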