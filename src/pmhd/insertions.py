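"""Insertion-site calling from paired-end junction-library reads.

The caller recovers P-element integration loci in four steps:

1. ``extract_junction_reads`` — keep only pairs containing an exact match to
   an element terminus (either end, either strand), trim element and adapter
   bases, and return the genomic flank in junction-first orientation
   together with the element orientation implied by which terminus matched.
2. ``map_flanks`` — exact k-mer anchor at the junction-proximal end of the
   flank against a 2-bit genome index, extended by direct comparison with at
   most two mismatches; flanks with several equally good loci are dropped as
   ambiguous.
3. ``cluster_sites`` — merge mapped positions within a small window (same
   chromosome and element orientation) into sites at the read-weighted modal
   position; the window also absorbs the target-site duplication and the
   one-base left/right junction asymmetry.
4. ``compute_occupancy`` — supporting reads per site divided by total
   element-supporting reads, the pooled-line occupancy estimate.

``assign_region_state`` and ``region_state_fractions`` then classify each
site by the transcription track covering it (score > 0 active, score = 0
silent, uncovered unknown) and report read-weighted state fractions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import revcomp
from .element import ElementModel
from .genome import GenomeModel
from .models import InsertionSite
from .simulate import ADAPTER, ReadPair

DEFAULT_MIN_ELEMENT_MATCH = 20
DEFAULT_MIN_FLANK = 20
DEFAULT_MAP_K = 31
DEFAULT_MAX_MISMATCHES = 2
DEFAULT_MERGE_WINDOW = 10


@dataclass(frozen=True)
class JunctionFlank:
    """A trimmed genomic flank and the element orientation at its junction.

    The flank is written junction-proximal base first.  ``elem_sign`` is the
    element's sense-strand orientation in the flank's frame: "+" when the
    element 3' terminus abuts the flank, "-" when the 5' terminus does.
    """

    flank: str
    elem_sign: str


def _trim_adapter(flank: str, adapter: str, min_overlap: int = 8) -> str:
    """Remove a full or suffix-partial adapter occurrence from the flank end."""
    i = flank.find(adapter)
    if i != -1:
        return flank[:i]
    for olap in range(min(len(adapter), len(flank)), min_overlap - 1, -1):
        if flank.endswith(adapter[:olap]):
            return flank[: len(flank) - olap]
    return flank


from .element import TERMINUS_CONTEXT as _ORIENT_CONTEXT


def _scan_read(
    read: str, consensus: str, tir_len: int, match_len: int, adapter: str, min_flank: int
) -> Optional[JunctionFlank]:
    t5 = consensus[:match_len]
    t3 = consensus[-match_len:]
    # Because of the TIRs, t3 == revcomp(t5) whenever match_len <= tir_len:
    # a terminus hit only fixes the junction, not which element end it is.
    # Subterminal context (element bases beyond the TIR) resolves the end;
    # reads without context past the TIR are dropped as end-ambiguous.

    # element-before-flank junctions: ...element interior..terminus | flank...
    for motif in {t3, revcomp(t5)}:
        i = read.find(motif)
        if i == -1:
            continue
        j = i + match_len  # junction offset in the read
        cmp_len = min(j, _ORIENT_CONTEXT)
        if cmp_len <= tir_len:
            continue  # cannot resolve which terminus this is
        tail = read[j - cmp_len : j]
        is_three = tail == consensus[-cmp_len:]
        is_five_rc = tail == revcomp(consensus[:cmp_len])
        if is_three == is_five_rc:
            continue
        flank = _trim_adapter(read[j:], adapter)
        if len(flank) >= min_flank:
            return JunctionFlank(flank, "+" if is_three else "-")

    # flank-before-element junctions: ...flank | terminus..element interior...
    for motif in {t5, revcomp(t3)}:
        i = read.find(motif)
        if i == -1:
            continue
        cmp_len = min(len(read) - i, _ORIENT_CONTEXT)
        if cmp_len <= tir_len:
            continue
        head = read[i : i + cmp_len]
        is_five = head == consensus[:cmp_len]
        is_three_rc = head == revcomp(consensus[-cmp_len:])
        if is_five == is_three_rc:
            continue
        flank = _trim_adapter(revcomp(read[:i]), adapter)
        if len(flank) >= min_flank:
            # In junction-first frame the element lies before the flank with
            # its 5' end (sign "-") or its reverse-complemented 3' end ("+").
            return JunctionFlank(flank, "-" if is_five else "+")
    return None


def extract_junction_reads(
    pairs: Iterable[ReadPair],
    element_model: ElementModel,
    adapter: str = ADAPTER,
    min_element_match: int = DEFAULT_MIN_ELEMENT_MATCH,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[JunctionFlank]:
    """Filter pairs to element-junction reads and return trimmed flanks.

    Pairs lacking an exact ``min_element_match``-bp match to either element
    terminus in either mate are discarded; element and adapter bases are
    trimmed; flanks shorter than ``min_flank`` after trimming are dropped.
    """
    consensus = element_model.consensus
    tir = element_model.tir_length
    out: list[JunctionFlank] = []
    for pair in pairs:
        hit = _scan_read(pair.r1, consensus, tir, min_element_match, adapter, min_flank)
        if hit is None:
            hit = _scan_read(pair.r2, consensus, tir, min_element_match, adapter, min_flank)
        if hit is not None:
            out.append(hit)
    return out


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer values at every start offset (k <= 32)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    val = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        val = (val << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    return val


class GenomeIndex:
    """Sorted 2-bit k-mer index over all chromosomes of a genome."""

    def __init__(self, genome: GenomeModel, k: int = DEFAULT_MAP_K) -> None:
        self.genome = genome
        self.k = k
        self._chroms: list[tuple[str, int]] = []  # (name, global offset)
        values = []
        positions = []
        offset = 0
        for name, seq in genome.chromosomes.items():
            self._chroms.append((name, offset))
            vals = _kmer_codes(_encode(seq), k)
            values.append(vals)
            positions.append(np.arange(len(vals), dtype=np.int64) + offset)
            offset += len(seq)
        allv = np.concatenate(values) if values else np.empty(0, dtype=np.uint64)
        allp = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
        order = np.argsort(allv, kind="stable")
        self._values = allv[order]
        self._positions = allp[order]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """All (chrom, local 0-based offset) exact occurrences of a k-mer."""
        if len(kmer) != self.k:
            raise ValueError(f"need a {self.k}-mer")
        code = _encode(kmer)
        if (code == 255).any():
            return []
        val = np.uint64(0)
        for c in code:
            val = (val << np.uint64(2)) | np.uint64(c)
        lo = np.searchsorted(self._values, val, side="left")
        hi = np.searchsorted(self._values, val, side="right")
        return [self._to_local(int(g)) for g in self._positions[lo:hi]]

    def _to_local(self, global_pos: int) -> tuple[str, int]:
        name, base = self._chroms[0]
        for n, off in self._chroms:
            if off <= global_pos:
                name, base = n, off
            else:
                break
        return name, global_pos - base


@dataclass(frozen=True)
class MappedFlank:
    chrom: str
    position: int  # 1-based junction-proximal flank base
    strand: str  # strand of the flank match


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_flanks(
    flanks: Sequence[JunctionFlank],
    genome: GenomeModel,
    k: int = DEFAULT_MAP_K,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    index: Optional[GenomeIndex] = None,
) -> list[Optional[MappedFlank]]:
    """Map flanks to the genome; ambiguous or unplaceable flanks give None.

    The first ``k`` bases of the flank (junction-proximal) are looked up
    exactly on both strands; each candidate locus is extended over the full
    flank allowing at most ``max_mismatches`` substitutions.  A unique
    best-scoring locus wins; ties are reported as unmapped.
    """
    if index is None:
        index = GenomeIndex(genome, k)
    results: list[Optional[MappedFlank]] = []
    for jf in flanks:
        flank = jf.flank
        if len(flank) < k:
            results.append(None)
            continue
        anchor = flank[:k]
        candidates: list[tuple[int, MappedFlank]] = []
        for chrom, off in index.lookup(anchor):
            seq = genome.chromosomes[chrom]
            ref = seq[off : off + len(flank)]
            if len(ref) < len(flank):
                continue
            mm = _mismatches(flank, ref, max_mismatches)
            if mm <= max_mismatches:
                candidates.append((mm, MappedFlank(chrom, off + 1, "+")))
        for chrom, off in index.lookup(revcomp(anchor)):
            seq = genome.chromosomes[chrom]
            end = off + k
            start = end - len(flank)
            if start < 0:
                continue
            ref = revcomp(seq[start:end])
            mm = _mismatches(flank, ref, max_mismatches)
            if mm <= max_mismatches:
                candidates.append((mm, MappedFlank(chrom, end, "-")))
        if not candidates:
            results.append(None)
            continue
        best = min(mm for mm, _ in candidates)
        top = [m for mm, m in candidates if mm == best]
        results.append(top[0] if len(top) == 1 else None)
    return results


def combine_orientation(flank: JunctionFlank, mapped: MappedFlank) -> str:
    """Element strand on the chromosome from flank frame and mapping strand."""
    return flank.elem_sign if mapped.strand == "+" else ("-" if flank.elem_sign == "+" else "+")


def cluster_sites(
    mapped: Sequence[tuple[str, int, str]],
    merge_window: int = DEFAULT_MERGE_WINDOW,
) -> list[InsertionSite]:
    """Merge mapped junction positions into insertion sites.

    ``mapped`` holds (chromosome, 1-based position, element strand) per
    retained read.  Positions within ``merge_window`` of the previous
    position on the same chromosome and strand merge into one site placed at
    the read-weighted modal position (smallest position on ties).
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, pos, strand in mapped:
        by_key.setdefault((chrom, strand), []).append(pos)
    sites: list[InsertionSite] = []
    for (chrom, strand), positions in sorted(by_key.items()):
        positions.sort()
        group: list[int] = []
        for pos in positions:
            if group and pos - group[-1] > merge_window:
                sites.append(_make_site(chrom, strand, group))
                group = []
            group.append(pos)
        if group:
            sites.append(_make_site(chrom, strand, group))
    sites.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return sites


def _make_site(chrom: str, strand: str, positions: list[int]) -> InsertionSite:
    counts = Counter(positions)
    modal = min(sorted(counts), key=lambda p: (-counts[p], p))
    return InsertionSite(
        chrom=chrom,
        position=modal,
        strand=strand,
        supporting_reads=len(positions),
        read_positions=list(positions),
    )


def compute_occupancy(sites: Sequence[InsertionSite]) -> list[InsertionSite]:
    """Set each site's occupancy to its share of element-supporting reads."""
    total = sum(s.supporting_reads for s in sites)
    if total == 0:
        raise ValueError("no supporting reads: occupancy undefined")
    for s in sites:
        s.occupancy = s.supporting_reads / total
    return list(sites)


def assign_region_state(
    sites: Sequence[InsertionSite], genome: GenomeModel
) -> list[InsertionSite]:
    """Label each site active/silent/unknown from the transcription track."""
    for s in sites:
        score = genome.track_score_at(s.chrom, s.position)
        if score is None:
            s.region_state = "unknown"
        else:
            s.region_state = "active" if score > 0 else "silent"
    return list(sites)


def region_state_fractions(
    sites: Sequence[InsertionSite],
) -> tuple[float, float, float]:
    """Read-weighted (active%, silent%, unknown%) over all sites."""
    if not sites:
        raise ValueError("no sites")
    total = sum(s.supporting_reads for s in sites)
    if total == 0:
        raise ValueError("no supporting reads")
    weights = {"active": 0, "silent": 0, "unknown": 0}
    for s in sites:
        weights[s.region_state] += s.supporting_reads
    return tuple(100.0 * weights[k] / total for k in ("active", "silent", "unknown"))


def call_insertions(
    pairs: Iterable[ReadPair],
    genome: GenomeModel,
    element_model: ElementModel,
    adapter: str = ADAPTER,
    min_element_match: int = DEFAULT_MIN_ELEMENT_MATCH,
    k: int = DEFAULT_MAP_K,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    merge_window: int = DEFAULT_MERGE_WINDOW,
    index: Optional[GenomeIndex] = None,
) -> list[InsertionSite]:
    """Full junction-read -> annotated-site pipeline (states included)."""
    flanks = extract_junction_reads(
        pairs, element_model, adapter=adapter, min_element_match=min_element_match
    )
    mapped = map_flanks(flanks, genome, k=k, max_mismatches=max_mismatches, index=index)
    triples = [
        (m.chrom, m.position, combine_orientation(f, m))
        for f, m in zip(flanks, mapped)
        if m is not None
    ]
    sites = cluster_sites(triples, merge_window=merge_window)
    if sites:
        compute_occupancy(sites)
        assign_region_state(sites, genome)
    return sites
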