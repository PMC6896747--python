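"""Deterministic seed derivation.

Every stochastic step in the pipeline (fold assignment, resampling,
hyperparameter draws, learner initialisation) draws its seed from a master
seed plus a string path, via CRC-32 of the joined representation.  This keeps
each grid cell independently reproducible: re-running one (review, learner,
balancing) cell in isolation uses the same randomness as the full grid run.
"""

from __future__ import annotations

import zlib

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def derive_seed(*parts: object) -> int:
    """Derive a 31-bit seed from a master seed and a path of string parts.

    Stable across processes and platforms (unlike ``hash()``).
    """
    key = "|".join(str(p) for p in parts)
    return zlib.crc32(key.encode("utf-8")) & _SEED_MASK
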