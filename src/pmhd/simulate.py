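"""Truth-tracked simulators for every sequencing input the pipeline consumes.

Three generators emulate the study design of a paternal-genome P-element
survey:

``simulate_junction_library``
    Restriction-digest / adapter-ligation junction sequencing of a pooled
    DNA sample (default 40 individuals).  Each planted insertion is carried
    by each simulated individual with probability equal to its occupancy;
    HhaI- and TaqI-digested junction fragments (element terminus plus
    flanking genome up to the nearest recognition site) are size-selected to
    300-600 bp, adapter-ligated and emitted as 250-bp read pairs, one mate
    anchored in element sequence and the other entering from the adapter.

``simulate_small_rnas``
    Single-end small-RNA sequencing: 24-35-nt piRNA-class reads drawn from
    element copies that sit inside piRNA clusters (primary reads on the
    cluster precursor strand, a configurable fraction of secondary reads on
    the opposite strand standing in for cleavage-derived ping-pong piRNAs),
    plus a bundled decoy miRNA population used as the normalization
    denominator.  ``embryo_mode`` rescales piRNA output so the true RPM
    falls below 10, reproducing the near-absence of zygotic piRNAs right
    after fertilization.

``simulate_strain_panel``
    Strain-level molecular measurements and gonadal-dysgenesis (GD) scores
    generated from a logistic model in which piRNA abundance and KP-element
    mRNA suppress GD; the generative coefficients are recorded so that the
    regression layer can be validated against ground truth.

Every generator takes an explicit seed and is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import find_sites, mutate_uniform, random_nt, revcomp
from .element import TERMINUS_CONTEXT, ElementModel
from .genome import GenomeModel
from .models import PlantedInsertion

DEFAULT_ENZYMES = ("GCGC", "TCGA")  # HhaI, TaqI recognition sequences
DEFAULT_READ_LENGTH = 250
DEFAULT_SIZE_RANGE = (300, 600)
DEFAULT_POOL_SIZE = 40  # genomic DNA pooled from 40 adult flies

# Fixed 30-mer ligated at the genomic cut end of every junction fragment.
ADAPTER = "CTAATACGACTCACTATAGGGCAGTCAGTG"

PIRNA_MIN_LEN = 24
PIRNA_MAX_LEN = 35
SMALLRNA_READ_LENGTH = 50

# Internal seed for the bundled decoy miRNA set (a synthetic stand-in for a
# miRNA catalogue; fixed so the set is identical across runs and machines).
_MIRNA_SET_SEED = 271828
_N_DECOY_MIRNAS = 50


@dataclass(frozen=True)
class Read:
    name: str
    sequence: str


@dataclass(frozen=True)
class ReadPair:
    name: str
    r1: str
    r2: str


@dataclass
class FragmentInfo:
    """Geometry of one potential junction fragment of a planted insertion."""

    side: str  # "L" | "R"
    enzyme: str
    elem_len: int  # element bases between the internal cut and the terminus
    flank_len: int  # genomic bases between the junction and the flank cut
    selected: bool  # fragment length within the size-selection window
    # Minimal element context (bp before the junction) that distinguishes the
    # two termini; None when the fragment stays ambiguous even at the full
    # context window (e.g. it never leaves the terminal inverted repeat).
    orient_ctx: Optional[int] = 1

    @property
    def length(self) -> int:
        return self.elem_len + self.flank_len

    @property
    def orientable(self) -> bool:
        return self.orient_ctx is not None


@dataclass
class JunctionTruth:
    """Ground truth for one simulated junction library."""

    insertions: list[PlantedInsertion]
    fragments: list[list[FragmentInfo]]
    expected_reads: list[float]
    emitted_reads: list[int]
    background_reads: int
    seed: int

    def informative_indices(
        self,
        read_length: int = DEFAULT_READ_LENGTH,
        min_element_match: int = 20,
        min_mappable_flank: int = 31,
        adapter_len: int = len(ADAPTER),
    ) -> list[int]:
        """Indices of insertions with at least one junction fragment from
        which the caller can in principle recover an oriented, mappable flank.

        A fragment is informative when it survives size selection, carries
        element sequence past the terminal inverted repeat (orientation is
        undecidable within the TIR), and leaves at least
        ``min_mappable_flank`` flanking bases inside one of the two mates.
        This is a deterministic function of digest geometry, independent of
        depth.
        """
        return [
            i
            for i in range(len(self.fragments))
            if self.recoverable_fragments(
                i, read_length, min_element_match, min_mappable_flank, adapter_len
            )
            > 0
        ]

    def recoverable_fragments(
        self,
        index: int,
        read_length: int = DEFAULT_READ_LENGTH,
        min_element_match: int = 20,
        min_mappable_flank: int = 31,
        adapter_len: int = len(ADAPTER),
    ) -> int:
        """Number of junction fragments of one insertion the caller can use."""
        n = 0
        for f in self.fragments[index]:
            if not f.selected or not f.orientable or f.elem_len < min_element_match:
                continue
            need = max(f.orient_ctx, min_element_match)
            via_r1 = (
                f.elem_len + min_mappable_flank <= read_length
                and min(f.flank_len, read_length - f.elem_len) >= min_mappable_flank
            )
            via_r2 = (
                adapter_len + f.flank_len + need <= read_length
                and f.flank_len >= min_mappable_flank
            )
            if via_r1 or via_r2:
                n += 1
        return n


def _orient_context(element_anchored_part: str, consensus: str) -> Optional[int]:
    """Smallest element context (bp before the junction) that identifies the
    terminus, or None if the fragment stays end-ambiguous.

    Within the terminal inverted repeat the two ends are identical, so a
    fragment whose element part never leaves the TIR cannot be oriented by
    the caller.  Once a context length distinguishes the termini, any longer
    context does too (the true terminus keeps matching; the false one cannot
    recover), so the minimum fully characterizes recoverability.
    """
    max_cmp = min(len(element_anchored_part), TERMINUS_CONTEXT)
    for cmp_len in range(1, max_cmp + 1):
        tail = element_anchored_part[-cmp_len:]
        is_three = tail == consensus[-cmp_len:]
        is_five_rc = tail == revcomp(consensus[:cmp_len])
        if is_three != is_five_rc:
            return cmp_len
    return None


def _nearest_cut_left(seq: str, pos: int, motif: str, window: int) -> Optional[int]:
    """Rightmost motif start in ``seq[max(0, pos-window):pos]``, absolute offset."""
    lo = max(0, pos - window)
    sites = find_sites(seq[lo:pos], motif)
    return lo + sites[-1] if sites else None


def _nearest_cut_right(seq: str, pos: int, motif: str, window: int) -> Optional[int]:
    """Leftmost motif start in ``seq[pos:pos+window]``, absolute offset."""
    sites = find_sites(seq[pos : pos + window], motif)
    return pos + sites[0] if sites else None


def simulate_junction_library(
    genome: GenomeModel,
    insertions: Sequence[PlantedInsertion],
    element_model: ElementModel,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
    read_length: int = DEFAULT_READ_LENGTH,
    mean_depth_per_individual: float = 2.0,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    error_rate: float = 0.0,
    n_individuals: int = DEFAULT_POOL_SIZE,
    n_background_pairs: int = 0,
    adapter: str = ADAPTER,
    seed: int = 0,
) -> tuple[list[ReadPair], JunctionTruth]:
    """Simulate a pooled restriction-digest junction-sequencing library.

    For each insertion, each of ``n_individuals`` simulated flies carries it
    with probability equal to its occupancy; every carrier contributes
    Poisson(``mean_depth_per_individual``) read pairs per size-selected
    junction fragment.  Fragment search windows are capped at twice the
    upper size bound, so fragments longer than the selection window are
    simply absent.  Reads shorter than ``read_length`` (fragment plus
    adapter shorter than one mate) are truncated at the molecule end.

    Returns the read pairs and a :class:`JunctionTruth` with per-insertion
    fragment geometry, expected and emitted read counts.
    """
    rng = np.random.default_rng(seed)
    window = 2 * size_range[1]
    pairs: list[ReadPair] = []
    all_fragments: list[list[FragmentInfo]] = []
    expected: list[float] = []
    emitted: list[int] = []

    for idx, ins in enumerate(insertions):
        chrom_seq = genome.chromosomes[ins.chrom]
        p0 = ins.position - 1  # 0-based offset of the first right-flank base
        elem = element_model.variant_sequence(ins.variant)
        g_elem = elem if ins.strand == "+" else revcomp(elem)

        frags: list[FragmentInfo] = []
        junctions: list[tuple[FragmentInfo, str]] = []  # (info, element-anchored seq)
        for enzyme in enzymes:
            elem_sites = find_sites(g_elem, enzyme)
            # Right junction: element 3' (genome orientation) into right flank.
            cut_e = elem_sites[-1] if elem_sites else 0
            cut_f = _nearest_cut_right(chrom_seq, p0, enzyme, window)
            if cut_f is not None:
                elem_part = g_elem[cut_e:]
                flank_part = chrom_seq[p0:cut_f]
                info = FragmentInfo(
                    "R", enzyme, len(elem_part), len(flank_part),
                    size_range[0] <= len(elem_part) + len(flank_part) <= size_range[1],
                    orient_ctx=_orient_context(elem_part, element_model.consensus),
                )
                frags.append(info)
                if info.selected:
                    junctions.append((info, elem_part + flank_part + adapter))
            # Left junction: left flank into element 5' (genome orientation).
            cut_e2 = elem_sites[0] if elem_sites else len(g_elem)
            cut_f2 = _nearest_cut_left(chrom_seq, p0, enzyme, window)
            if cut_f2 is not None:
                elem_part = g_elem[:cut_e2]
                flank_part = chrom_seq[cut_f2:p0]
                info = FragmentInfo(
                    "L", enzyme, len(elem_part), len(flank_part),
                    size_range[0] <= len(elem_part) + len(flank_part) <= size_range[1],
                    orient_ctx=_orient_context(revcomp(elem_part), element_model.consensus),
                )
                frags.append(info)
                if info.selected:
                    junctions.append((info, revcomp(flank_part + elem_part) + adapter))

        all_fragments.append(frags)
        n_selected = sum(1 for f in frags if f.selected)
        expected.append(ins.occupancy * n_individuals * mean_depth_per_individual * n_selected)

        count = 0
        if junctions:
            carriers = int(rng.binomial(n_individuals, ins.occupancy))
            for info, jseq in junctions:
                n_reads = int(rng.poisson(mean_depth_per_individual * carriers))
                for r in range(n_reads):
                    r1 = jseq[:read_length]
                    r2 = revcomp(jseq)[:read_length]
                    if error_rate > 0:
                        r1 = mutate_uniform(r1, error_rate, rng)
                        r2 = mutate_uniform(r2, error_rate, rng)
                    pairs.append(
                        ReadPair(f"ins{idx}:{info.side}:{info.enzyme}:{count}", r1, r2)
                    )
                    count += 1
        emitted.append(count)

    names = list(genome.chromosomes)
    for b in range(n_background_pairs):
        chrom = names[rng.integers(0, len(names))]
        seq = genome.chromosomes[chrom]
        frag_len = int(rng.integers(*size_range))
        start = int(rng.integers(0, max(1, len(seq) - frag_len)))
        frag = seq[start : start + frag_len]
        r1 = mutate_uniform(frag[:read_length], error_rate, rng)
        r2 = mutate_uniform(revcomp(frag)[:read_length], error_rate, rng)
        pairs.append(ReadPair(f"bg:{b}", r1, r2))

    truth = JunctionTruth(
        insertions=list(insertions),
        fragments=all_fragments,
        expected_reads=expected,
        emitted_reads=emitted,
        background_reads=n_background_pairs,
        seed=seed,
    )
    return pairs, truth


def decoy_mirnas() -> list[str]:
    """The bundled synthetic decoy miRNA set (50 sequences, 21-23 nt).

    Generated from a fixed internal seed; a stand-in for a miRNA catalogue
    used only as a normalization denominator and removal target.
    """
    rng = np.random.default_rng(_MIRNA_SET_SEED)
    return [random_nt(rng, int(rng.integers(21, 24))) for _ in range(_N_DECOY_MIRNAS)]


def default_pirna_rates(
    active_rate: float = 400.0, low_rate: float = 40.0, top_n: int = 15
) -> dict:
    """Expected primary piRNA reads per cluster-embedded insertion, by rank."""
    return {"active_rate": active_rate, "low_rate": low_rate, "top_n": top_n}


@dataclass
class SmallRNATruth:
    """Ground truth for one simulated small-RNA library.

    ``mappable_sense``/``mappable_antisense`` count the piRNA reads that are
    exact substrings of the element consensus (reads crossing an internal
    deletion junction of a variant such as KP are element-derived but do not
    map to the consensus), classified with the same sense-first policy the
    quantifier uses.
    """

    sense_reads: int
    antisense_reads: int
    mirna_reads: int
    per_insertion: list[tuple[int, int]]  # (sense, antisense) per planted insertion
    expected_rpm: float
    seed: int
    mappable_sense: int = 0
    mappable_antisense: int = 0

    @property
    def element_reads(self) -> int:
        return self.sense_reads + self.antisense_reads

    @property
    def mappable_reads(self) -> int:
        return self.mappable_sense + self.mappable_antisense


def simulate_small_rnas(
    genome: GenomeModel,
    insertions: Sequence[PlantedInsertion],
    element_model: ElementModel,
    pirna_rate_per_cluster_rank: Optional[dict] = None,
    n_mirna_reads: int = 50_000,
    embryo_mode: bool = False,
    sense_fraction: float = 0.5,
    embryo_scale: float = 2e-7,
    seed: int = 0,
) -> tuple[list[Read], SmallRNATruth]:
    """Simulate a single-end small-RNA library (reads are 24-35-nt piRNAs
    from cluster-embedded element copies plus decoy miRNAs).

    ``pirna_rate_per_cluster_rank`` follows :func:`default_pirna_rates`:
    an insertion in a top-``top_n`` (active) cluster yields
    Poisson(active_rate x occupancy) primary piRNA reads, others
    Poisson(low_rate x occupancy).  Primary reads lie on the precursor
    strand relative to the element (both strands for dual-strand clusters);
    secondary reads on the opposite strand model cleavage-derived ping-pong
    production at ``sense_fraction`` of the primary rate.  ``embryo_mode``
    multiplies all piRNA rates by ``embryo_scale`` x ``n_mirna_reads`` so
    the true RPM lands below 10.
    """
    rng = np.random.default_rng(seed)
    rates = pirna_rate_per_cluster_rank or default_pirna_rates()
    if any(v < 0 for v in rates.values()):
        raise ValueError("piRNA rates must be nonnegative")
    scale = embryo_scale * n_mirna_reads / max(rates["active_rate"], 1.0) if embryo_mode else 1.0

    consensus = element_model.consensus
    consensus_rc = revcomp(consensus)
    reads: list[Read] = []
    per_insertion: list[tuple[int, int]] = []
    sense_total = 0
    anti_total = 0
    mappable_sense = 0
    mappable_anti = 0
    serial = 0
    for ins in insertions:
        cluster = genome.cluster_at(ins.chrom, ins.position)
        if cluster is None:
            per_insertion.append((0, 0))
            continue
        base = rates["active_rate"] if (cluster.rank or 1) <= rates["top_n"] else rates["low_rate"]
        rate = base * ins.occupancy * scale
        elem = element_model.variant_sequence(ins.variant)
        if cluster.strandness == "dual":
            n_sense = int(rng.poisson(rate))
            n_anti = int(rng.poisson(rate))
        else:
            # Element orientation relative to the unistrand precursor: the
            # precursor transcript carries the element on one strand only.
            sense_oriented = ins.strand == cluster.precursor_strand
            primary = int(rng.poisson(rate))
            secondary = int(rng.poisson(rate * sense_fraction))
            n_sense, n_anti = (primary, secondary) if sense_oriented else (secondary, primary)
        for strand, n in (("+", n_sense), ("-", n_anti)):
            for _ in range(n):
                length = int(rng.integers(PIRNA_MIN_LEN, PIRNA_MAX_LEN + 1))
                start = int(rng.integers(0, len(elem) - length + 1))
                seq = elem[start : start + length]
                if strand == "-":
                    seq = revcomp(seq)
                # Sense-first mappability, mirroring the quantifier's policy.
                if seq in consensus:
                    mappable_sense += 1
                elif seq in consensus_rc:
                    mappable_anti += 1
                reads.append(Read(f"pi:{serial}", seq))
                serial += 1
        sense_total += n_sense
        anti_total += n_anti
        per_insertion.append((n_sense, n_anti))

    mirnas = decoy_mirnas()
    if n_mirna_reads:
        picks = rng.integers(0, len(mirnas), size=n_mirna_reads)
        flips = rng.random(n_mirna_reads) < 0.1
        flipped = [revcomp(m) for m in mirnas]
        reads.extend(
            Read(f"mi:{m}", (flipped if flip else mirnas)[i])
            for m, (i, flip) in enumerate(zip(picks, flips))
        )

    expected_rpm = (
        (sense_total + anti_total) / n_mirna_reads * 1e6 if n_mirna_reads else float("nan")
    )
    truth = SmallRNATruth(
        sense_reads=sense_total,
        antisense_reads=anti_total,
        mirna_reads=n_mirna_reads,
        per_insertion=per_insertion,
        expected_rpm=expected_rpm,
        seed=seed,
        mappable_sense=mappable_sense,
        mappable_antisense=mappable_anti,
    )
    return reads, truth


@dataclass
class PanelTruth:
    """Generative parameters behind a simulated strain panel."""

    beta_pirna: float
    beta_kp: float
    intercept: float
    noise_sd: float
    linear_predictor: list[float] = field(default_factory=list)
    seed: int = 0


def simulate_strain_panel(
    n_strains: int,
    beta_pirna: float = -3.0,
    beta_kp: float = -1.0,
    noise_sd: float = 0.5,
    intercept: float = 0.0,
    gd_low_threshold: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PanelTruth]:
    """Simulate per-strain molecular measurements and GD scores.

    GD% = 100 x logistic(intercept + beta_pirna x z(piRNA RPM) +
    beta_kp x z(KP mRNA) + noise).  Negative betas make piRNA abundance and
    KP mRNA suppressors of gonadal dysgenesis.  Predictors are drawn from
    seeded lognormal distributions; the cluster-read fraction co-varies with
    piRNA abundance (cluster-embedded copies drive zygotic piRNA
    production).  F2 and cross-A* GD scores are drawn from the same linear
    predictor with independent noise.
    """
    if n_strains < 4:
        raise ValueError("need at least 4 strains")
    rng = np.random.default_rng(seed)
    pirna = rng.lognormal(mean=np.log(1000.0), sigma=1.0, size=n_strains)
    kp = rng.lognormal(mean=0.0, sigma=1.0, size=n_strains)
    p_mrna = rng.lognormal(mean=0.0, sigma=0.5, size=n_strains)

    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    z_pi, z_kp = z(pirna), z(kp)
    lin = intercept + beta_pirna * z_pi + beta_kp * z_kp

    def gd_from(linpred: np.ndarray) -> np.ndarray:
        noisy = linpred + rng.normal(0.0, noise_sd, size=n_strains)
        return np.clip(100.0 / (1.0 + np.exp(-noisy)), 0.0, 100.0)

    gd_f1 = gd_from(lin)
    gd_f2 = gd_from(lin)
    gd_astar = gd_from(lin)
    cluster_frac = np.clip(20.0 + 10.0 * z_pi + rng.normal(0.0, 2.0, n_strains), 0.0, 100.0)

    df = pd.DataFrame(
        {
            "strain_id": [f"S{i + 1:02d}" for i in range(n_strains)],
            "pirna_rpm": pirna,
            "p_mrna": p_mrna,
            "kp_mrna": kp,
            "cluster_read_fraction": cluster_frac,
            "gd_f1_cross_a": gd_f1,
            "gd_f2": gd_f2,
            "gd_cross_astar": gd_astar,
        }
    )
    df["inducibility"] = np.where(gd_f1 < gd_low_threshold, "low", "high")
    df["susceptibility"] = np.where(gd_astar < gd_low_threshold, "low", "high")
    truth = PanelTruth(
        beta_pirna=beta_pirna,
        beta_kp=beta_kp,
        intercept=intercept,
        noise_sd=noise_sd,
        linear_predictor=lin.tolist(),
        seed=seed,
    )
    return df, truth
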