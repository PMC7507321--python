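"""Small nucleotide-code helpers shared across modules.

Bases are encoded A=0, C=1, G=2, T=3 so that complement(code) == 3 - code.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

# byte-level translation tables
_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP = str.maketrans("ACGTacgtUu", "TGCAtgcaAa")


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return 3 - codes
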