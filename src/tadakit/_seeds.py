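"""Named random substreams derived from a single root seed.

Every stochastic stage draws from a stream derived as
``derive_seed(root, "stage.name")`` so that one root seed pins the whole
run while stages remain independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(root: int, name: str) -> int:
    """Return a 31-bit child seed for substream `name` under `root`."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(root) & 0x7FFFFFFF, spawn_key=(tag,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(root: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root, name))
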