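"""Deterministic random-stream management.

Every stochastic stage of the pipeline draws from a named substream derived
from a single master seed.  Substreams are independent (distinct SeedSequence
spawn keys), so adding or reordering one stage never perturbs the randomness
seen by another, and any artifact can be regenerated from the master seed and
the stage name alone.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(names: tuple) -> int:
    digest = hashlib.sha256("/".join(str(n) for n in names).encode()).digest()
    return int.from_bytes(digest[:4], "big")


def substream(master_seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same (master_seed, names) pair always yields an identically seeded
    generator; different names yield statistically independent streams.
    """
    ss = np.random.SeedSequence([int(master_seed), _name_key(names)])
    return np.random.default_rng(ss)


def substream_seed(master_seed: int, *names) -> int:
    """A plain integer seed (< 2**31) derived from a named substream."""
    ss = np.random.SeedSequence([int(master_seed), _name_key(names)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
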