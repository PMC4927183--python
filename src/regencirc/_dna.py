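"""Small DNA-string helpers shared across modules.

The package works internally in DNA space (T, not U); RNA is converted at
file boundaries only.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and map U->T so catalog matching never sees RNA letters."""
    return seq.upper().replace("U", "T")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))
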