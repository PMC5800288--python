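"""P/KP variant typing, PCR amplicon prediction and ddCt quantification.

``classify_variant`` aligns a query sequence against the element consensus
by exact k-mer seeding and greedy chaining, reports uncovered internal
consensus intervals (>= 20 bp) as deletions, and calls the variant:

* FP — no deletion (the full-length, transposase-encoding element);
* KP — exactly the canonical (808, 2560) deletion, within a small
  tolerance absorbing junction microhomology;
* other-deleted — any other deletion pattern;
* unknown — no seed match at all.

The qPCR layer implements standard ddCt relative quantification against a
single-copy reference gene (RP49-style) and a reference strain, assuming
perfect doubling per cycle, plus the KP-to-total-P copy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import revcomp
from .element import KP_DELETION, ElementModel

MIN_DELETION_GAP = 20
KP_TOLERANCE_BP = 3
DEFAULT_SEED_K = 15


@dataclass(frozen=True)
class VariantCall:
    """Result of typing a query against the element consensus."""

    variant: str  # "FP" | "KP" | "other-deleted" | "unknown"
    deletions: tuple[tuple[int, int], ...]  # 1-based inclusive consensus intervals
    aligned_fraction: float


def _chain_seed_matches(query: str, consensus: str, k: int) -> list[tuple[int, int]]:
    """Greedy colinear chain of exact k-mer matches (query_pos, cons_pos)."""
    index: dict[str, list[int]] = {}
    for i in range(len(consensus) - k + 1):
        index.setdefault(consensus[i : i + k], []).append(i)
    chain: list[tuple[int, int]] = []
    last_c = -1
    for q in range(0, len(query) - k + 1):
        hits = index.get(query[q : q + k])
        if not hits:
            continue
        nxt = [c for c in hits if c > last_c]
        if not nxt:
            continue
        c = nxt[0]
        chain.append((q, c))
        last_c = c
    return chain


def classify_variant(
    query: str,
    model: ElementModel,
    k: int = DEFAULT_SEED_K,
    min_gap: int = MIN_DELETION_GAP,
    kp_tolerance: int = KP_TOLERANCE_BP,
) -> VariantCall:
    """Type a query sequence as FP / KP / other-deleted / unknown.

    The query is matched on both strands; internal gaps >= ``min_gap`` bp in
    consensus coverage are reported as deletion intervals.
    """
    if len(query) < 50:
        raise ValueError("query must be at least 50 nt")
    consensus = model.consensus
    chain = _chain_seed_matches(query, consensus, k)
    chain_rc = _chain_seed_matches(revcomp(query), consensus, k)
    if len(chain_rc) > len(chain):
        chain = chain_rc
    if not chain:
        return VariantCall("unknown", (), 0.0)

    # Merge covered consensus intervals (0-based half-open).
    covered: list[list[int]] = []
    for _, c in chain:
        if covered and c <= covered[-1][1]:
            covered[-1][1] = max(covered[-1][1], c + k)
        else:
            covered.append([c, c + k])
    aligned = sum(e - s for s, e in covered) / len(consensus)

    deletions: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
        gap = s2 - e1
        if gap >= min_gap:
            deletions.append((e1 + 1, s2))  # 1-based inclusive

    if not deletions:
        return VariantCall("FP", (), aligned)
    if len(deletions) == 1:
        (d_start, d_end) = deletions[0]
        if (
            abs(d_start - KP_DELETION[0]) <= kp_tolerance
            and abs(d_end - KP_DELETION[1]) <= kp_tolerance
        ):
            return VariantCall("KP", (deletions[0],), aligned)
    return VariantCall("other-deleted", tuple(deletions), aligned)


PRIMER_ANNEAL_LEN = 20


def amplicon_products(
    query: str,
    primer_pair: tuple[int, int],
    model: ElementModel,
    anneal_len: int = PRIMER_ANNEAL_LEN,
) -> list[int]:
    """Predict PCR product lengths for a primer pair on a variant template.

    ``primer_pair`` is (forward-start, reverse-end) in 1-based consensus
    coordinates.  The template's deletion intervals are inferred with
    :func:`classify_variant`; a primer whose ``anneal_len``-bp annealing
    window overlaps a deletion yields no product.  Otherwise the product
    length is the consensus span minus the deleted bases inside it.
    """
    fwd_start, rev_end = primer_pair
    if not (1 <= fwd_start <= rev_end <= len(model.consensus)):
        raise ValueError("primer coordinates outside the consensus")
    call = classify_variant(query, model)
    if call.variant == "unknown":
        return []
    fwd_window = (fwd_start, min(fwd_start + anneal_len - 1, rev_end))
    rev_window = (max(rev_end - anneal_len + 1, fwd_start), rev_end)
    deleted = 0
    for d_start, d_end in call.deletions:
        for w_start, w_end in (fwd_window, rev_window):
            if d_start <= w_end and w_start <= d_end:
                return []
        lo = max(d_start, fwd_start)
        hi = min(d_end, rev_end)
        if lo <= hi:
            deleted += hi - lo + 1
    return [rev_end - fwd_start + 1 - deleted]


@dataclass
class QpcrTable:
    """Ct measurements for ddCt quantification.

    ``data`` columns: strain, target, replicate, ct.  ``reference_gene`` is
    the single-copy normalizer target; ``reference_strain`` maps to a
    relative abundance of 1.0.
    """

    data: pd.DataFrame
    reference_gene: str
    reference_strain: str

    def __post_init__(self) -> None:
        required = {"strain", "target", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")


def relative_copy_number(table: QpcrTable, target: str) -> dict[str, float]:
    """ddCt relative abundance of ``target`` per strain.

    dCt = mean Ct(target) - mean Ct(reference gene) per strain; relative
    abundance = 2^-(dCt_strain - dCt_reference_strain).  Assumes perfect
    amplification efficiency (doubling per cycle).
    """
    means = table.data.groupby(["strain", "target"])["ct"].mean()
    strains = sorted(table.data["strain"].unique())
    dct: dict[str, float] = {}
    for strain in strains:
        for t in (target, table.reference_gene):
            if (strain, t) not in means.index:
                raise ValueError(f"strain {strain!r} has no Ct rows for target {t!r}")
        dct[strain] = means[(strain, target)] - means[(strain, table.reference_gene)]
    if table.reference_strain not in dct:
        raise ValueError(f"reference strain {table.reference_strain!r} absent from table")
    ref = dct[table.reference_strain]
    return {s: float(2.0 ** -(d - ref)) for s, d in dct.items()}


def kp_fraction(kp_rel: float, total_rel: float) -> float:
    """KP elements as a percentage of total P-element copies, capped at 100."""
    if total_rel <= 0:
        raise ValueError("total relative copy number must be positive")
    if kp_rel < 0:
        raise ValueError("KP relative copy number must be nonnegative")
    return min(100.0, 100.0 * kp_rel / total_rel)
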