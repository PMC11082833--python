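"""Named random substreams derived from a single root seed.

Every stage of the pipeline (simulation, HMM initialisation, k-means) draws
its seed from the root seed plus a stage name, so stages are individually
reproducible and independent of execution order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(root_seed: int, name: str) -> int:
    """Deterministically derive a 31-bit seed for the substream ``name``."""
    digest = hashlib.sha256(f"{int(root_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_for(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, name))
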