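"""Seed derivation shared by every stochastic stage.

Each stage derives its seed deterministically from (global seed, stage
name, replicate index) via SHA-256, so re-running any configuration
reproduces all numeric output exactly and stages never share a stream.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(base_seed: int, stage: str, index: int = 0) -> int:
    """A 31-bit seed, a deterministic function of (base_seed, stage, index)."""
    digest = hashlib.sha256(f"{base_seed}/{stage}/{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
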