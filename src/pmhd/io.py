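"""File formats: FASTA/FASTQ via Biopython, BED-style annotation, TSV tables.

Conventions: genomes and element sequences as FASTA; junction libraries as
paired FASTQ (``*_R1.fastq`` / ``*_R2.fastq``); small-RNA libraries as
single-end FASTQ; clusters as BED6+3 (extra columns: sense%, cluster-unique
piRNA count, rank); the transcription track as BED4 with the expression
score in column 4; called sites as BED6 plus a companion TSV carrying
occupancy, region state and cluster membership; qPCR tables and strain
panels as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeModel, TrackInterval
from .models import InsertionSite, PiRNACluster
from .simulate import Read, ReadPair


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _fastq_records(reads: Iterable[tuple[str, str]]):
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        yield rec


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    SeqIO.write(_fastq_records((r.name, r.sequence) for r in reads), str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq_pairs(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    SeqIO.write(_fastq_records((p.name, p.r1) for p in pairs), str(p1), "fastq")
    SeqIO.write(_fastq_records((p.name, p.r2) for p in pairs), str(p2), "fastq")
    return p1, p2


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("R1/R2 files have different read counts")
    return [ReadPair(a.id, str(a.seq), str(b.seq)) for a, b in zip(r1, r2)]


def write_clusters_bed(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    """BED6+3: chrom start end id unique_pirnas strand sense% rank activity."""
    with open(path, "w") as fh:
        for c in clusters:
            strand = c.precursor_strand or "."
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{c.unique_pirnas}\t"
                f"{strand}\t{c.sense_pct:.4f}\t{c.rank if c.rank is not None else '.'}\t"
                f"{c.activity or '.'}\n"
            )


def read_clusters_bed(path: str | Path) -> list[PiRNACluster]:
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            sense = float(f[6])
            clusters.append(
                PiRNACluster(
                    cluster_id=f[3],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    sense_pct=sense,
                    antisense_pct=100.0 - sense,
                    unique_pirnas=int(f[4]),
                    rank=None if f[7] == "." else int(f[7]),
                    activity=None if len(f) < 9 or f[8] == "." else f[8],
                    precursor_strand=None if f[5] == "." else f[5],
                )
            )
    return clusters


def write_track_bed(track: Sequence[TrackInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in track:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.score:g}\n")


def read_track_bed(path: str | Path) -> list[TrackInterval]:
    track = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            track.append(TrackInterval(f[0], int(f[1]), int(f[2]), float(f[3])))
    return track


def write_genome(genome: GenomeModel, outdir: str | Path, stem: str = "genome") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.chromosomes, outdir / f"{stem}.fasta")
    write_clusters_bed(genome.clusters, outdir / "clusters.bed")
    write_track_bed(genome.transcription_track, outdir / "transcription.bed")


def read_genome(outdir: str | Path, stem: str = "genome") -> GenomeModel:
    outdir = Path(outdir)
    return GenomeModel(
        chromosomes=read_fasta(outdir / f"{stem}.fasta"),
        clusters=read_clusters_bed(outdir / "clusters.bed"),
        transcription_track=read_track_bed(outdir / "transcription.bed"),
    )


def sites_to_frame(sites: Sequence[InsertionSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "position": [s.position for s in sites],
            "strand": [s.strand for s in sites],
            "supporting_reads": [s.supporting_reads for s in sites],
            "occupancy": [s.occupancy for s in sites],
            "region_state": [s.region_state for s in sites],
            "cluster_id": [s.cluster_id or "." for s in sites],
            "cluster_orientation": [s.cluster_orientation or "." for s in sites],
        }
    )


def write_sites(sites: Sequence[InsertionSite], prefix: str | Path) -> tuple[Path, Path]:
    """BED6 (name=site id, score=supporting reads) plus the full TSV."""
    prefix = Path(prefix)
    bed = prefix.with_suffix(".bed")
    tsv = prefix.with_suffix(".tsv")
    with open(bed, "w") as fh:
        for i, s in enumerate(sites, 1):
            fh.write(
                f"{s.chrom}\t{s.position - 1}\t{s.position}\tsite{i}\t"
                f"{s.supporting_reads}\t{s.strand}\n"
            )
    sites_to_frame(sites).to_csv(tsv, sep="\t", index=False)
    return bed, tsv


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with header ``strain  target  replicate  ct``."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
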