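"""Deterministic sub-seed derivation.

Every stage of the pipeline (split, tuning, refit, importance, per-permutation
draws) derives its own seed from the run seed plus a stage tag, so results are
reproducible across machines and independent of execution order or
parallelism.  No global random state is ever used.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *tags: object) -> int:
    """Derive a 31-bit sub-seed from ``seed`` and a sequence of stage tags.

    The derivation hashes ``"{seed}|tag1|tag2|..."`` with SHA-256 and keeps
    the low 31 bits, so any (seed, tags) pair maps to a stable integer in
    ``[0, 2**31)`` on every platform.
    """
    key = "|".join([str(int(seed)), *map(str, tags)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
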