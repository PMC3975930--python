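"""DNA alphabet encoding.

Sequences are handled internally as int8 arrays with A,C,G,T -> 0..3.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string (case-insensitive) as an int8 array."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            raise InputError(f"non-DNA symbol {ch!r} at position {i}")
        out[i] = code
    return out


def decode(codes) -> str:
    return "".join(ALPHABET[c] for c in codes)
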