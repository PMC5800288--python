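"""Element-derived piRNA quantification from small-RNA reads.

Order of operations mirrors a standard small-RNA workflow: miRNA reads are
removed first (and counted — they are the normalization denominator), the
survivors are size-filtered to the piRNA window (24-35 nt inclusive), and
the remainder is mapped exactly to the element consensus on both strands.
Abundance is reported as RPM: element piRNA reads per million miRNA reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from ._seq import revcomp
from .element import ElementModel
from .simulate import Read

PIRNA_MIN_LEN = 24
PIRNA_MAX_LEN = 35


def _seq_of(read: Union[Read, str]) -> str:
    return read.sequence if isinstance(read, Read) else read


def size_filter(
    reads: Iterable[Union[Read, str]],
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
) -> list[Union[Read, str]]:
    """Retain reads with length in [min_len, max_len], inclusive."""
    return [r for r in reads if min_len <= len(_seq_of(r)) <= max_len]


def remove_mirnas(
    reads: Iterable[Union[Read, str]], mirna_set: Iterable[str]
) -> tuple[list[Union[Read, str]], int]:
    """Drop reads exactly matching a miRNA on either strand; count them.

    The returned count is the RPM normalization denominator.
    """
    bank = set(mirna_set)
    bank |= {revcomp(m) for m in bank}
    kept: list[Union[Read, str]] = []
    n_mirna = 0
    for r in reads:
        if _seq_of(r) in bank:
            n_mirna += 1
        else:
            kept.append(r)
    return kept, n_mirna


@dataclass
class SmallRNAProfile:
    """Per-position sense/antisense read-start counts over the consensus.

    Positions are 1-based consensus coordinates of the read 5' end (for
    antisense reads, of the consensus base their 5' end pairs with).
    """

    sense: np.ndarray
    antisense: np.ndarray
    total: int = 0
    mirna_count: int = 0
    rpm: float = float("nan")
    sample: str = ""
    unmapped: int = 0

    @classmethod
    def empty(cls, length: int, sample: str = "") -> "SmallRNAProfile":
        return cls(
            sense=np.zeros(length, dtype=np.int64),
            antisense=np.zeros(length, dtype=np.int64),
            sample=sample,
        )

    @property
    def sense_total(self) -> int:
        return int(self.sense.sum())

    @property
    def antisense_total(self) -> int:
        return int(self.antisense.sum())

    def to_frame(self):
        """Positional profile as a DataFrame with 1-based consensus positions."""
        import pandas as pd

        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.sense) + 1),
                "sense": self.sense,
                "antisense": self.antisense,
            }
        )


def _occurrences(hay: str, needle: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        out = []
        i = hay.find(needle)
        while i != -1:
            out.append(i)
            i = hay.find(needle, i + 1)
        return out
    out = []
    n, m = len(hay), len(needle)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(hay[i : i + m], needle):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            out.append(i)
    return out


def map_to_element(
    reads: Iterable[Union[Read, str]],
    model: ElementModel,
    max_mismatch: int = 0,
    sample: str = "",
) -> SmallRNAProfile:
    """Map reads to the element consensus, strand-aware, exact by default.

    Each read is searched on the consensus forward strand (sense) and on its
    reverse complement (antisense).  A read with several equally good hits is
    counted once at a deterministic position: sense hits before antisense,
    then lowest consensus coordinate.  Hits are recorded at the 5'-end
    consensus position of the read.
    """
    consensus = model.consensus
    profile = SmallRNAProfile.empty(len(consensus), sample=sample)
    cache: dict[str, tuple[str, int] | None] = {}
    for r in reads:
        seq = _seq_of(r)
        placement = cache.get(seq, "miss")
        if placement == "miss":
            sense_hits = _occurrences(consensus, seq, max_mismatch)
            if sense_hits:
                placement = ("+", sense_hits[0])
            else:
                anti_hits = _occurrences(consensus, revcomp(seq), max_mismatch)
                if anti_hits:
                    # 5' end of an antisense read pairs with the *end* of the
                    # consensus slice; lowest-coordinate tie-break on the slice start.
                    placement = ("-", anti_hits[0] + len(seq) - 1)
                else:
                    placement = None
            cache[seq] = placement
        if placement is None:
            profile.unmapped += 1
        elif placement[0] == "+":
            profile.sense[placement[1]] += 1
        else:
            profile.antisense[placement[1]] += 1
    profile.total = profile.sense_total + profile.antisense_total
    return profile


def rpm_normalize(element_count: int, mirna_count: int) -> float:
    """Element piRNA reads per million miRNA reads."""
    if mirna_count <= 0:
        raise ValueError("miRNA count must be positive for RPM normalization")
    return element_count * 1e6 / mirna_count


def quantify_pirnas(
    reads: Sequence[Union[Read, str]],
    model: ElementModel,
    mirna_set: Iterable[str],
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
    max_mismatch: int = 0,
    sample: str = "",
) -> SmallRNAProfile:
    """miRNA removal -> size filter -> strand-aware mapping -> RPM."""
    kept, n_mirna = remove_mirnas(reads, mirna_set)
    kept = size_filter(kept, min_len, max_len)
    profile = map_to_element(kept, model, max_mismatch=max_mismatch, sample=sample)
    profile.mirna_count = n_mirna
    profile.rpm = rpm_normalize(profile.total, n_mirna)
    return profile
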