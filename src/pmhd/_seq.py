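"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_nt(rng: np.random.Generator, length: int) -> str:
    """Uniform random nucleotide string of the given length."""
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


def find_sites(seq: str, motif: str) -> list[int]:
    """All start offsets (0-based) of exact occurrences of ``motif`` in ``seq``.

    Overlapping occurrences are reported.
    """
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def mutate_uniform(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply independent uniform substitutions at ``error_rate`` per base."""
    if error_rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        base = arr[i].decode()
        choices = [b for b in ALPHABET if b != base]
        arr[i] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()
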