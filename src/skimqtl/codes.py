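"""Integer genotype codes shared across the package.

Calls are stored as ``int8``. ``A`` is the allele of the recurrent/reference
parent, ``B`` the allele of the donor parent. ``UNDET`` marks a window or bin
call that could not be assigned to either parent; ``MISSING`` marks absent
raw calls.
"""

import numpy as np

A = np.int8(0)
B = np.int8(1)
HET = np.int8(2)
UNDET = np.int8(3)
MISSING = np.int8(-1)

#: letters used on TSV I/O
CODE_TO_CHAR = {int(A): "A", int(B): "B", int(HET): "H", int(UNDET): "U", int(MISSING): "-"}
CHAR_TO_CODE = {v: np.int8(k) for k, v in CODE_TO_CHAR.items()}


def score(calls: np.ndarray) -> np.ndarray:
    """Map calls to additive scores: A -> -1, B -> +1, anything else -> 0."""
    out = np.zeros(calls.shape, dtype=float)
    out[calls == A] = -1.0
    out[calls == B] = 1.0
    return out
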