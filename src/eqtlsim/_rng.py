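"""Seed management.

All randomness in the package flows from a single integer master seed.
Independent streams for sub-tasks are derived with
:class:`numpy.random.SeedSequence` keyed by the master seed plus a tuple of
small integer/str labels, so that adding a new consumer of randomness never
perturbs existing streams.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "rng_for"]

_MOD = 2**31


def _key_ints(key: tuple) -> list[int]:
    out: list[int] = []
    for k in key:
        if isinstance(k, str):
            # stable string -> int folding (no builtin hash: not reproducible)
            acc = 0
            for ch in k.encode():
                acc = (acc * 257 + ch) % _MOD
            out.append(acc)
        else:
            out.append(int(k) % _MOD)
    return out


def child_seed(master: int, *key) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence([int(master) % _MOD, *_key_ints(key)])
    return int(ss.generate_state(1)[0] % _MOD)


def rng_for(master: int, *key) -> np.random.Generator:
    """A :class:`numpy.random.Generator` on the stream named by ``key``."""
    ss = np.random.SeedSequence([int(master) % _MOD, *_key_ints(key)])
    return np.random.default_rng(ss)
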