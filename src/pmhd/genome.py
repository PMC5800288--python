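"""Synthetic reference genome with piRNA-cluster and transcription annotation.

The generator emulates the annotation structure the analysis consumes: a
multi-chromosome nucleotide reference, a set of piRNA-cluster intervals with
per-cluster strand fractions and cluster-unique piRNA counts (142 intervals
in paper-emulation mode, matching the published D. melanogaster cluster
catalogue), and a tiling transcription track whose intervals alternate
between expressed (score > 0) and silent (score = 0) chromatin, standing in
for a modENCODE-style expression summary.

Sequences are seeded-random, not real chromosome sequence: restriction
sites then occur at the ~4^-4 density of random DNA, which is what gives the
junction-library simulator realistic fragment-length variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

from ._seq import random_nt
from .clusters import annotate_clusters
from .models import PiRNACluster, PlantedInsertion

PAPER_N_CLUSTERS = 142


class TrackInterval(NamedTuple):
    """One transcription-track interval; score > 0 means expressed."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    score: float


@dataclass
class GenomeModel:
    """Reference sequences plus cluster and transcription annotation."""

    chromosomes: dict[str, str]
    clusters: list[PiRNACluster] = field(default_factory=list)
    transcription_track: list[TrackInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.clusters:
            size = len(self.chromosomes.get(c.chrom, ""))
            if not (0 <= c.start < c.end <= size):
                raise ValueError(f"cluster {c.cluster_id} outside {c.chrom} bounds")
        by_chrom: dict[str, list[TrackInterval]] = {}
        for t in self.transcription_track:
            if t.score < 0:
                raise ValueError("track score must be >= 0")
            size = len(self.chromosomes.get(t.chrom, ""))
            if not (0 <= t.start < t.end <= size):
                raise ValueError(f"track interval outside {t.chrom} bounds")
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ivals in by_chrom.items():
            ivals = sorted(ivals, key=lambda t: t.start)
            for a, b in zip(ivals, ivals[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping track intervals on {chrom}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def track_score_at(self, chrom: str, position: int) -> Optional[float]:
        """Score of the track interval covering a 1-based position, else None."""
        off = position - 1
        for t in self.transcription_track:
            if t.chrom == chrom and t.start <= off < t.end:
                return t.score
        return None

    def cluster_at(self, chrom: str, position: int) -> Optional[PiRNACluster]:
        """Smallest cluster containing a 1-based position, else None."""
        hits = [c for c in self.clusters if c.contains(position, chrom)]
        if not hits:
            return None
        return min(hits, key=lambda c: (c.length, c.cluster_id))


def make_genome(
    n_chromosomes: int = 3,
    chrom_length: int = 300_000,
    n_clusters: int = 30,
    paper_emulation: bool = False,
    seed: int = 0,
    cluster_length_range: tuple[int, int] = (2_000, 20_000),
    track_interval_mean: int = 10_000,
    dual_fraction: float = 0.5,
) -> GenomeModel:
    """Generate a seeded-random annotated genome.

    ``paper_emulation=True`` forces exactly 142 clusters.  Clusters are
    placed without overlap on an even slot grid; each receives a distinct
    cluster-unique piRNA count and randomized sense/antisense strand
    percentages (roughly ``dual_fraction`` of clusters get both strands
    above the 20% dual-strand threshold).  The transcription track tiles
    every chromosome with alternating score > 0 and score = 0 intervals.

    Raises ``ValueError`` when the requested clusters cannot be placed.
    """
    rng = np.random.default_rng(seed)
    if paper_emulation:
        n_clusters = PAPER_N_CLUSTERS
    chroms = {f"chr{i + 1}": random_nt(rng, chrom_length) for i in range(n_chromosomes)}

    track: list[TrackInterval] = []
    for name, seq in chroms.items():
        pos = 0
        active = bool(rng.integers(0, 2))
        while pos < len(seq):
            span = int(rng.integers(track_interval_mean // 2, track_interval_mean * 3 // 2))
            end = min(pos + span, len(seq))
            score = float(rng.integers(1, 11)) if active else 0.0
            track.append(TrackInterval(name, pos, end, score))
            pos = end
            active = not active

    clusters = _place_clusters(chroms, n_clusters, cluster_length_range, dual_fraction, rng)
    return GenomeModel(chromosomes=chroms, clusters=clusters, transcription_track=track)


def _place_clusters(
    chroms: dict[str, str],
    n_clusters: int,
    length_range: tuple[int, int],
    dual_fraction: float,
    rng: np.random.Generator,
) -> list[PiRNACluster]:
    if n_clusters == 0:
        return []
    min_len, max_len = length_range
    # Non-overlapping placement on an even slot grid across all chromosomes.
    slots: list[tuple[str, int, int]] = []
    total = sum(len(s) for s in chroms.values())
    slot_width = max(min_len + 1, total // max(1, 2 * n_clusters))
    for name, seq in chroms.items():
        for start in range(0, len(seq) - min_len, slot_width):
            slots.append((name, start, min(start + slot_width, len(seq))))
    usable = [s for s in slots if s[2] - s[1] > min_len]
    if n_clusters > len(usable):
        raise ValueError(
            f"cannot place {n_clusters} clusters of >= {min_len} bp: only {len(usable)} slots"
        )
    chosen = rng.choice(len(usable), size=n_clusters, replace=False)
    # Distinct unique-piRNA counts: a shuffled sample without replacement.
    counts = rng.choice(np.arange(100, 100_000), size=n_clusters, replace=False)
    clusters: list[PiRNACluster] = []
    for i, slot_idx in enumerate(sorted(chosen)):
        chrom, lo, hi = usable[slot_idx]
        max_here = min(max_len, hi - lo)
        length = int(rng.integers(min_len, max_here + 1))
        start = int(rng.integers(lo, hi - length + 1))
        if rng.random() < dual_fraction:
            sense = float(rng.uniform(25.0, 75.0))
        else:
            major = float(rng.uniform(85.0, 100.0))
            sense = major if rng.random() < 0.5 else 100.0 - major
        clusters.append(
            PiRNACluster(
                cluster_id=f"cl{i + 1:03d}",
                chrom=chrom,
                start=start,
                end=start + length,
                sense_pct=sense,
                antisense_pct=100.0 - sense,
                unique_pirnas=int(counts[i]),
            )
        )
    annotate_clusters(clusters)
    return clusters


@dataclass(frozen=True)
class PlantSpec:
    """Request for one planted insertion.

    ``target_class`` is one of ``in-cluster``, ``active-region``,
    ``silent-region``, ``uniform``.  ``strand`` and ``cluster_id`` pin the
    element orientation or a specific cluster; left None they are drawn at
    random.
    """

    target_class: str
    variant: str
    occupancy: float
    strand: Optional[str] = None
    cluster_id: Optional[str] = None


TARGET_CLASSES = ("in-cluster", "active-region", "silent-region", "uniform")

# Margin kept clear of chromosome ends so junction fragments stay in bounds.
_EDGE_MARGIN = 2_000


def plant_insertions(
    genome: GenomeModel,
    spec: Sequence[Union[PlantSpec, tuple]],
    seed: int = 0,
) -> list[PlantedInsertion]:
    """Place ground-truth insertions into regions of the requested classes.

    Insertion points are unique.  Raises ``ValueError`` when a requested
    region class does not exist in the genome.
    """
    rng = np.random.default_rng(seed)
    taken: set[tuple[str, int]] = set()
    out: list[PlantedInsertion] = []
    for entry in spec:
        ps = entry if isinstance(entry, PlantSpec) else PlantSpec(*entry)
        if ps.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target class {ps.target_class!r}")
        for _ in range(10_000):
            chrom, pos = _draw_position(genome, ps, rng)
            if (chrom, pos) not in taken:
                break
        else:  # pragma: no cover - pathological saturation
            raise ValueError("could not find a free insertion point")
        taken.add((chrom, pos))
        strand = ps.strand or ("+" if rng.random() < 0.5 else "-")
        out.append(
            PlantedInsertion(
                chrom=chrom, position=pos, strand=strand, variant=ps.variant,
                occupancy=ps.occupancy,
            )
        )
    return out


def _draw_position(
    genome: GenomeModel, ps: PlantSpec, rng: np.random.Generator
) -> tuple[str, int]:
    if ps.target_class == "in-cluster":
        pool = genome.clusters
        if ps.cluster_id is not None:
            pool = [c for c in pool if c.cluster_id == ps.cluster_id]
        if not pool:
            raise ValueError("no piRNA cluster available for in-cluster placement")
        c = pool[rng.integers(0, len(pool))]
        return c.chrom, int(rng.integers(c.start + 1, c.end + 1))
    if ps.target_class in ("active-region", "silent-region"):
        want_active = ps.target_class == "active-region"
        pool2 = [
            t for t in genome.transcription_track
            if (t.score > 0) == want_active and t.end - t.start > 2
        ]
        if not pool2:
            raise ValueError(f"no {ps.target_class} interval in the transcription track")
        t = pool2[rng.integers(0, len(pool2))]
        return t.chrom, int(rng.integers(t.start + 1, t.end + 1))
    # uniform over the genome, away from chromosome ends
    names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[n]) for n in names], dtype=float)
    chrom = names[rng.choice(len(names), p=lengths / lengths.sum())]
    size = len(genome.chromosomes[chrom])
    margin = min(_EDGE_MARGIN, size // 4)
    return chrom, int(rng.integers(margin + 1, size - margin + 1))
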