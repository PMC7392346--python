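"""Named random substreams derived from one master seed.

Every source of randomness (split, folds, SMOTE, classifier init, simulation)
draws from its own substream so that changing one stage's consumption never
perturbs another stage, while the whole run stays reproducible from a single
integer.
"""

from __future__ import annotations

import zlib

import numpy as np


def seed_sequence(master_seed: int, name: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])


def substream(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(master_seed, name))


def substream_int(master_seed: int, name: str) -> int:
    """A derived integer seed (< 2^31) for APIs that take ``random_state``."""
    return int(seed_sequence(master_seed, name).generate_state(1)[0] % (2**31))
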