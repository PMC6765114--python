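"""Small sequence utilities shared across modules."""
from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
RNA_BASES = "ACGU"

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


class SequenceError(ValueError):
    """Raised for sequences outside the expected alphabet."""


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    """Normalize a DNA or RNA string to uppercase RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def check_rna(seq: str) -> str:
    s = to_rna(seq)
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise SequenceError(f"invalid letters {sorted(bad)} in sequence")
    return s


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform-composition random DNA of length n."""
    codes = rng.integers(0, 4, size=n)
    return "".join(DNA_BASES[c] for c in codes)


def encode_dna(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3; anything else (incl. N) -> -1."""
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(DNA_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
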