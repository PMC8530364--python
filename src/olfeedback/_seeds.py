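"""Named seed substreams.

Every random operation in the package derives its generator from a master
seed plus a stable string label, so that a single integer reproduces a full
pipeline run while components stay statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(master_seed: int, label: str) -> np.random.SeedSequence:
    """Return a SeedSequence for the substream named ``label``.

    The label is hashed with CRC-32, which is stable across platforms and
    Python versions (unlike ``hash``).
    """
    return np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode("utf-8"))])


def substream(master_seed: int, label: str) -> np.random.Generator:
    """A PCG64 generator for the substream named ``label``."""
    return np.random.Generator(np.random.PCG64(child_seed(master_seed, label)))
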