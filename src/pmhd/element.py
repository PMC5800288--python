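"""The P-element consensus model and its internally deleted variants.

The full-length (FP) P element is a 2907-bp DNA transposon bounded by 31-bp
terminal inverted repeats (TIRs).  Natural populations additionally carry
internally deleted, non-autonomous derivatives; the most common is the KP
element, which lacks the interval 808–2560 (1-based, inclusive) of the
consensus and encodes a truncated repressor polypeptide instead of the
transposase.

:class:`ElementModel` bundles a consensus sequence, a registry of named
variants (each a list of deletion intervals in consensus coordinates) and a
registry of primer pairs expressed as consensus coordinates.  For simulation
work the consensus is a seeded-random sequence with proper TIR structure; the
deletion coordinates and lengths are the biologically meaningful part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import random_nt, revcomp

CONSENSUS_LENGTH = 2907
TIR_LENGTH = 31
KP_DELETION = (808, 2560)  # 1-based inclusive consensus coordinates

# Element-interior context (bp) used to tell the two termini apart when a
# read shows only one junction; within the TIR the ends are identical, so
# disambiguation relies on subterminal sequence inside this window.
TERMINUS_CONTEXT = 60


@dataclass(frozen=True)
class ElementModel:
    """P-element consensus plus named deletion variants and primer pairs.

    Deletion intervals and primer coordinates are 1-based inclusive on the
    consensus.  ``variants`` maps a variant name to a tuple of disjoint
    deletion intervals; the full-length element ("FP") has none.
    """

    consensus: str
    variants: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    primer_pairs: dict[str, tuple[int, int]] = field(default_factory=dict)
    tir_length: int = TIR_LENGTH

    def __post_init__(self) -> None:
        if len(self.consensus) != CONSENSUS_LENGTH:
            raise ValueError(
                f"consensus must be {CONSENSUS_LENGTH} nt, got {len(self.consensus)}"
            )
        for name, intervals in self.variants.items():
            last_end = 0
            for start, end in sorted(intervals):
                if not (1 <= start <= end <= CONSENSUS_LENGTH):
                    raise ValueError(f"variant {name}: interval ({start}, {end}) out of range")
                if start <= last_end:
                    raise ValueError(f"variant {name}: overlapping deletion intervals")
                last_end = end

    @property
    def five_prime_terminus(self) -> str:
        return self.consensus[: self.tir_length]

    @property
    def three_prime_terminus(self) -> str:
        return self.consensus[-self.tir_length :]

    def variant_sequence(self, name: str) -> str:
        """Sequence of a named variant: the consensus minus its deletions."""
        if name not in self.variants:
            raise KeyError(f"unknown variant {name!r}")
        return apply_deletions(self.consensus, self.variants[name])

    def deleted_positions(self, name: str) -> set[int]:
        """1-based consensus positions removed in the named variant."""
        out: set[int] = set()
        for start, end in self.variants[name]:
            out.update(range(start, end + 1))
        return out


def apply_deletions(seq: str, intervals: tuple[tuple[int, int], ...]) -> str:
    """Remove 1-based inclusive intervals from ``seq``."""
    keep = []
    pos = 0  # 0-based cursor
    for start, end in sorted(intervals):
        keep.append(seq[pos : start - 1])
        pos = end
    keep.append(seq[pos:])
    return "".join(keep)


def make_element_model(seed: int) -> ElementModel:
    """Build a seeded-random 2907-nt consensus with 31-bp TIRs.

    The final 31 nt are the reverse complement of the first 31 nt, mimicking
    the terminal inverted repeats of the real element.  Registered variants:
    ``FP`` (no deletion) and ``KP`` (single deletion 808–2560).  Default
    primer pairs span the whole element (``total_p``) and anchor the forward
    primer inside the KP deletion (``non_kp``), so that KP templates yield no
    product with the latter; both are configuration, not biology.
    """
    rng = np.random.default_rng(seed)
    body = random_nt(rng, CONSENSUS_LENGTH - TIR_LENGTH)
    consensus = body + revcomp(body[:TIR_LENGTH])
    return ElementModel(
        consensus=consensus,
        variants={"FP": (), "KP": (KP_DELETION,)},
        primer_pairs={
            "total_p": (1, CONSENSUS_LENGTH),
            "non_kp": (1000, CONSENSUS_LENGTH),
        },
    )
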