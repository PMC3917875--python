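"""Deterministic seed derivation.

Every stochastic stage derives its seed from the single top-level seed plus
string tokens (stage name, dataset id, gene id ...), so results never depend
on execution order and reruns are bit-identical.
"""

from __future__ import annotations

import hashlib


def derive_seed(base: int, *tokens: object) -> int:
    """Derive a child seed (< 2**31) from a base seed and hashable tokens."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(base)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest(), "big") % (2**31)
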