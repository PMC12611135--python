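"""Reproducibility plumbing shared across modules."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(global_seed: int, component: str) -> int:
    """Stable per-component seed derived from a single global seed.

    Hashes ``"<seed>:<component>"`` with blake2b and folds the digest into
    [0, 2^31), so components can be re-run independently yet reproducibly
    from one run-level seed.
    """
    digest = hashlib.blake2b(
        f"{int(global_seed)}:{component}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)
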