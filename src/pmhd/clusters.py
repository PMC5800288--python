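"""piRNA-cluster classification and insertion-site cluster annotation.

Clusters are classified as dual-strand when both the sense and the antisense
strand carry strictly more than 20% of the cluster's piRNA reads; otherwise
they are unistrand with the majority strand as precursor.  Activity is a
rank: the top 15 clusters by cluster-unique piRNA count are "active", the
rest "low".  Insertion sites falling inside a cluster are annotated with the
cluster id and — for unistrand clusters — their orientation relative to the
precursor transcript (antisense-oriented copies are the canonical source of
element-silencing piRNAs).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .models import InsertionSite, PiRNACluster

DUAL_STRAND_THRESHOLD_PCT = 20.0
ACTIVE_TOP_N = 15


def classify_strandness(
    sense_pct: float,
    antisense_pct: float,
    threshold_pct: float = DUAL_STRAND_THRESHOLD_PCT,
) -> str:
    """Return "dual" iff both strand percentages are strictly above threshold.

    The two percentages must sum to 100 (within 1e-6).
    """
    if abs(sense_pct + antisense_pct - 100.0) > 1e-6:
        raise ValueError(
            f"strand percentages must sum to 100, got {sense_pct} + {antisense_pct}"
        )
    return "dual" if min(sense_pct, antisense_pct) > threshold_pct else "uni"


def rank_activity(
    clusters: Sequence[PiRNACluster], top_n: int = ACTIVE_TOP_N
) -> list[PiRNACluster]:
    """Rank clusters by cluster-unique piRNA count; top ``top_n`` are active.

    Stable descending sort; ties broken by lexicographic cluster id.  The
    input objects are annotated in place and returned in rank order.
    """
    ranked = sorted(clusters, key=lambda c: (-c.unique_pirnas, c.cluster_id))
    for i, c in enumerate(ranked, start=1):
        c.rank = i
        c.activity = "active" if i <= top_n else "low"
    return ranked


def annotate_clusters(
    clusters: Sequence[PiRNACluster],
    threshold_pct: float = DUAL_STRAND_THRESHOLD_PCT,
    top_n: int = ACTIVE_TOP_N,
) -> list[PiRNACluster]:
    """Fill strandness, precursor strand, rank and activity for all clusters."""
    for c in clusters:
        c.strandness = classify_strandness(c.sense_pct, c.antisense_pct, threshold_pct)
        if c.strandness == "uni":
            c.precursor_strand = "+" if c.sense_pct >= c.antisense_pct else "-"
        else:
            c.precursor_strand = None
    return rank_activity(clusters, top_n)


def assign_membership(
    sites: Iterable[InsertionSite], clusters: Sequence[PiRNACluster]
) -> list[InsertionSite]:
    """Annotate sites with cluster membership and unistrand orientation.

    A site belongs to a cluster when its 1-based insertion point lies inside
    the cluster interval; overlapping clusters are resolved to the smallest.
    For unistrand clusters the orientation is "+" (sense) when the element
    strand equals the precursor strand, "-" (antisense) otherwise; dual
    clusters transcribe both strands, so no orientation call is made.
    """
    out = list(sites)
    for site in out:
        hits = [c for c in clusters if c.contains(site.position, site.chrom)]
        if not hits:
            site.cluster_id = None
            site.cluster_orientation = None
            continue
        c = min(hits, key=lambda c: (c.length, c.cluster_id))
        site.cluster_id = c.cluster_id
        if c.strandness == "uni" and c.precursor_strand is not None:
            site.cluster_orientation = "+" if site.strand == c.precursor_strand else "-"
        else:
            site.cluster_orientation = None
    return out


def cluster_read_fraction(sites: Sequence[InsertionSite]) -> float:
    """Percentage of element-supporting reads at sites inside piRNA clusters."""
    total = sum(s.supporting_reads for s in sites)
    if total == 0:
        raise ValueError("no supporting reads: cluster read fraction undefined")
    in_cluster = sum(s.supporting_reads for s in sites if s.cluster_id is not None)
    return 100.0 * in_cluster / total


def count_by_class(
    sites: Sequence[InsertionSite], clusters: Sequence[PiRNACluster]
) -> dict[tuple[str, str, str | None], int]:
    """Count distinct in-cluster sites per (strandness, activity, orientation).

    Orientation is reported only for unistrand cells (None for dual).
    """
    by_id = {c.cluster_id: c for c in clusters}
    counts: dict[tuple[str, str, str | None], int] = {}
    for site in sites:
        if site.cluster_id is None:
            continue
        c = by_id[site.cluster_id]
        orientation = site.cluster_orientation if c.strandness == "uni" else None
        key = (str(c.strandness), str(c.activity), orientation)
        counts[key] = counts.get(key, 0) + 1
    return counts
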