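"""Deterministic seed derivation.

Every stochastic step derives its seed from the single global run seed and a
stable string tag, so runs are reproducible regardless of execution order or
parallelism.
"""

from __future__ import annotations

import hashlib


def derive_seed(global_seed: int, *tags) -> int:
    """Stable sub-seed below 2^31 from a global seed and string tags."""
    key = "|".join([str(int(global_seed))] + [str(t) for t in tags])
    h = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
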