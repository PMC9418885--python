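"""Deterministic seed splitting.

All randomness in the generators flows from one explicit integer seed through
``numpy.random.SeedSequence`` with a counter-style spawn key, so that every
curve / image / correlogram in a batch has an independent, reproducible
stream and regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

# Domain tags keep streams for different artifact kinds disjoint even when
# the same user seed and counter are used.
TAG_FORCE = 1
TAG_RETRACT = 2
TAG_IMAGE = 3
TAG_DLS = 4


def child_rng(seed: int, tag: int, counter: int = 0) -> np.random.Generator:
    """Generator for item ``counter`` of domain ``tag`` under ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(tag), int(counter)))
    return np.random.default_rng(ss)
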