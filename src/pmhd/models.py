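"""Shared domain records: piRNA clusters, planted insertions, called sites.

Coordinate convention throughout the package: intervals are 0-based
half-open internally; single positions in reports (and in these records'
``position`` fields) are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class PiRNACluster:
    """A genomic interval producing abundant piRNAs.

    ``sense_pct``/``antisense_pct`` are the percentages of the cluster's
    piRNA reads on the plus/minus genomic strand; they must sum to 100.
    ``unique_pirnas`` is the count of cluster-unique piRNA species used for
    activity ranking.  ``strandness``, ``activity``, ``rank`` and
    ``precursor_strand`` are filled in by the annotation layer.
    """

    cluster_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    sense_pct: float
    antisense_pct: float
    unique_pirnas: int
    rank: Optional[int] = None
    strandness: Optional[str] = None  # "dual" | "uni"
    activity: Optional[str] = None  # "active" | "low"
    precursor_strand: Optional[str] = None  # "+" | "-" for unistrand clusters

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position_1based: int, chrom: str) -> bool:
        return chrom == self.chrom and self.start < position_1based <= self.end


@dataclass(frozen=True)
class PlantedInsertion:
    """Ground-truth P-element integration planted by the simulator.

    ``occupancy`` is the fraction of individuals in the pooled line that
    carry the insertion (insertional polymorphism within a line).
    """

    chrom: str
    position: int  # 1-based insertion point (first flank base right of the element)
    strand: str  # element orientation relative to the chromosome
    variant: str
    occupancy: float

    def __post_init__(self) -> None:
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class InsertionSite:
    """A called P-element insertion locus.

    ``occupancy`` is supporting reads at this site divided by total
    element-supporting reads in the library — the read-fraction proxy for the
    fraction of pooled individuals carrying the copy.
    """

    chrom: str
    position: int  # 1-based
    strand: str
    supporting_reads: int
    occupancy: float = 0.0
    region_state: str = "unknown"  # "active" | "silent" | "unknown"
    cluster_id: Optional[str] = None
    cluster_orientation: Optional[str] = None  # vs unistrand precursor: "+" sense, "-" antisense
    read_positions: list[int] = field(default_factory=list, repr=False)
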