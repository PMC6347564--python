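"""Small shared helpers: seed derivation and allele encoding."""

from __future__ import annotations

import hashlib

import numpy as np

#: canonical allele order; code -1 means "absent / not ACGT"
ALLELES = "ACGT"
_CODE = {b: i for i, b in enumerate(ALLELES)}


def encode_allele(base: str) -> int:
    """Map a base letter to its 0..3 code, or -1 if not an unambiguous ACGT."""
    return _CODE.get(base.upper(), -1)


def decode_allele(code: int) -> str:
    return ALLELES[code] if 0 <= code < 4 else "N"


def derive_seed(base_seed: int, *keys) -> int:
    """Derive a stream-independent 31-bit seed from a base seed and string keys.

    Keyed derivation means adding a pipeline stage never shifts another
    stage's random stream.
    """
    tag = "/".join([str(int(base_seed))] + [str(k) for k in keys])
    digest = hashlib.blake2b(tag.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") & 0x7FFFFFFF


def rng_for(base_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base_seed, *keys))
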