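"""Insertion calling: extraction, mapping, site merging, occupancy, states."""

import random

import numpy as np
import pytest

from pmhd._seq import random_nt, revcomp
from pmhd.genome import GenomeModel, PlantSpec, TrackInterval, plant_insertions
from pmhd.insertions import (
    GenomeIndex,
    JunctionFlank,
    assign_region_state,
    call_insertions,
    cluster_sites,
    compute_occupancy,
    extract_junction_reads,
    map_flanks,
    region_state_fractions,
)
from pmhd.models import InsertionSite
from pmhd.simulate import ADAPTER, ReadPair, simulate_junction_library


def _random_pair(rng, n=250):
    return ReadPair("r", random_nt(rng, n), random_nt(rng, n))


class TestExtraction:
    def test_pairs_without_element_sequence_are_discarded(self, element, rng):
        pairs = [_random_pair(rng) for _ in range(20)]
        assert extract_junction_reads(pairs, element) == []

    def test_element_end_plus_flank_plus_adapter_yields_exact_flank(self, element, rng):
        flank = random_nt(rng, 60)
        read = element.consensus[-80:] + flank + ADAPTER
        got = extract_junction_reads([ReadPair("r", read, "A" * 30)], element)
        assert len(got) == 1
        assert got[0].flank == flank
        assert got[0].elem_sign == "+"

    def test_five_prime_junction_reports_minus_sign(self, element, rng):
        flank = random_nt(rng, 60)
        read = revcomp(element.consensus[:80]) + flank + ADAPTER
        got = extract_junction_reads([ReadPair("r", read, "A" * 30)], element)
        assert len(got) == 1
        assert got[0].flank == flank
        assert got[0].elem_sign == "-"

    def test_junction_recoverable_from_second_mate(self, element, rng):
        flank = random_nt(rng, 60)
        molecule = element.consensus[-150:] + flank + ADAPTER
        r2 = revcomp(molecule)[:250]
        got = extract_junction_reads([ReadPair("r", "A" * 40, r2)], element)
        assert len(got) == 1 and got[0].flank == flank and got[0].elem_sign == "+"

    def test_retained_count_matches_truth_for_recoverable_fragments(
        self, genome, element, planted
    ):
        pairs, truth = simulate_junction_library(
            genome, planted, element, error_rate=0.0, seed=17
        )
        informative = set(truth.informative_indices(min_mappable_flank=20))
        fully = {
            i
            for i in informative
            if all(
                f.orientable and f.elem_len + 20 <= 250
                for f in truth.fragments[i]
                if f.selected
            )
        }
        keep = [p for p in pairs if int(p.name.split(":")[0][3:]) in fully]
        flanks = extract_junction_reads(keep, element)
        assert len(flanks) == len(keep)


class TestMapping:
    def test_unique_flank_maps_to_its_locus(self, genome, element):
        seq = genome.chromosomes["chr1"]
        flank = seq[10_000:10_060]
        (m,) = map_flanks([JunctionFlank(flank, "+")], genome)
        assert (m.chrom, m.position, m.strand) == ("chr1", 10_001, "+")

    def test_reverse_strand_flank_position_is_junction_proximal(self, genome):
        seq = genome.chromosomes["chr1"]
        flank = revcomp(seq[10_000:10_060])  # proximal base = offset 10_059
        (m,) = map_flanks([JunctionFlank(flank, "+")], genome)
        assert (m.chrom, m.position, m.strand) == ("chr1", 10_060, "-")

    def test_duplicated_flank_is_ambiguous(self, element):
        rng = np.random.default_rng(0)
        segment = random_nt(rng, 200)
        g = GenomeModel(
            chromosomes={
                "c1": random_nt(rng, 1000) + segment + random_nt(rng, 1000),
                "c2": random_nt(rng, 500) + segment + random_nt(rng, 500),
            }
        )
        (m,) = map_flanks([JunctionFlank(segment[:60], "+")], g)
        assert m is None

    def test_foreign_flank_is_unmapped(self, genome, rng):
        (m,) = map_flanks([JunctionFlank(random_nt(rng, 60), "+")], genome)
        assert m is None

    def test_extension_tolerates_two_mismatches_not_three(self, genome):
        seq = genome.chromosomes["chr2"]
        flank = list(seq[20_000:20_080])
        for off in (50, 60):
            flank[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[flank[off]]
        (m,) = map_flanks([JunctionFlank("".join(flank), "+")], genome)
        assert m is not None and m.position == 20_001
        flank[70] = {"A": "C", "C": "A", "G": "T", "T": "G"}[flank[70]]
        (m,) = map_flanks([JunctionFlank("".join(flank), "+")], genome)
        assert m is None


class TestSiteMerging:
    def test_modal_position_and_summed_counts(self):
        mapped = [("chr1", 1000, "+")] * 40 + [("chr1", 1003, "+")] * 2
        (site,) = cluster_sites(mapped)
        assert site.position == 1000 and site.supporting_reads == 42

    def test_distant_positions_stay_separate(self):
        sites = cluster_sites([("chr1", 1000, "+"), ("chr1", 1100, "+")], merge_window=10)
        assert len(sites) == 2

    def test_opposite_orientations_never_merge(self):
        sites = cluster_sites([("chr1", 1000, "+"), ("chr1", 1001, "-")])
        assert len(sites) == 2

    def test_jitter_around_planted_sites_recovers_exactly_three(self, rng):
        truth_positions = [5_000, 9_000, 13_000]
        mapped = [
            ("chrX", p + int(rng.integers(-2, 3)), "+")
            for p in truth_positions
            for _ in range(30)
        ]
        rng.shuffle(mapped)
        sites = cluster_sites(mapped)
        assert len(sites) == 3
        for s, p in zip(sites, truth_positions):
            assert abs(s.position - p) <= 2

    def test_order_invariance(self, genome, element, planted):
        pairs, _ = simulate_junction_library(genome, planted, element, seed=19)
        shuffled = list(pairs)
        random.Random(5).shuffle(shuffled)
        a = call_insertions(pairs, genome, element)
        b = call_insertions(shuffled, genome, element)
        assert [(s.chrom, s.position, s.strand, s.supporting_reads) for s in a] == [
            (s.chrom, s.position, s.strand, s.supporting_reads) for s in b
        ]


class TestOccupancyAndStates:
    def _sites(self, counts, states=None):
        states = states or ["unknown"] * len(counts)
        return [
            InsertionSite("c", 100 * (i + 1), "+", n, region_state=st)
            for i, (n, st) in enumerate(zip(counts, states))
        ]

    def test_single_site_occupancy_one(self):
        (s,) = compute_occupancy(self._sites([7]))
        assert s.occupancy == 1.0

    def test_read_share_arithmetic(self):
        sites = compute_occupancy(self._sites([50, 150]))
        assert [s.occupancy for s in sites] == [0.25, 0.75]

    def test_occupancies_sum_to_one(self, rng):
        counts = rng.integers(1, 500, size=17).tolist()
        sites = compute_occupancy(self._sites(counts))
        assert sum(s.occupancy for s in sites) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_fails(self):
        with pytest.raises(ValueError):
            compute_occupancy(self._sites([0, 0]))

    def test_region_state_from_track(self):
        g = GenomeModel(
            chromosomes={"c": "A" * 300},
            transcription_track=[
                TrackInterval("c", 0, 100, 5.0),
                TrackInterval("c", 100, 200, 0.0),
            ],
        )
        sites = [
            InsertionSite("c", 50, "+", 1),
            InsertionSite("c", 150, "+", 1),
            InsertionSite("c", 250, "+", 1),
        ]
        states = [s.region_state for s in assign_region_state(sites, g)]
        assert states == ["active", "silent", "unknown"]

    def test_state_fraction_arithmetic_and_sum(self):
        sites = self._sites([75, 25], ["active", "silent"])
        active, silent, unknown = region_state_fractions(sites)
        assert (active, silent, unknown) == (75.0, 25.0, 0.0)
        sites = self._sites([13, 19, 7], ["active", "silent", "unknown"])
        assert sum(region_state_fractions(sites)) == pytest.approx(100.0, abs=1e-9)

    def test_all_silent_gives_pure_silent_fraction(self):
        sites = self._sites([5, 9], ["silent", "silent"])
        assert region_state_fractions(sites) == (0.0, 100.0, 0.0)


def test_error_free_calling_recovers_all_informative_sites(genome, element, planted):
    """Recall and precision are 1.0 against detectable truth on clean reads."""
    pairs, truth = simulate_junction_library(genome, planted, element, seed=23)
    sites = call_insertions(pairs, genome, element)
    informative = truth.informative_indices()
    called = {(s.chrom, s.position, s.strand) for s in sites}
    assert len(sites) == len(informative)
    for i in informative:
        p = truth.insertions[i]
        assert any(
            c == p.chrom and st == p.strand and abs(pos - p.position) <= 10
            for c, pos, st in called
        )
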