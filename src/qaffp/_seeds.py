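"""Deterministic seed fan-out.

A single master seed is hashed together with string/int context parts into
independent 31-bit child seeds, so no two pipeline stages (or benchmark jobs)
share an RNG stream and the schedule is stable across platforms and runs.
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts: object) -> int:
    """Derive a 31-bit seed from arbitrary hashable context parts.

    The derivation is a SHA-256 of the repr-joined parts, so it is stable
    across processes and platforms (unlike the builtin ``hash``).
    """
    token = "\x1f".join(repr(p) for p in parts)
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
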