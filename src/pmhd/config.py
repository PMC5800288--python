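"""Pipeline configuration: one dataclass, one YAML file, one seed.

Defaults mirror the analysis constants of the study design: 20.0% strand
threshold for dual-strand clusters, top-15 activity cutoff, 24-35-nt piRNA
window, GD < 10.0% phenotype criterion, 300-600-bp size selection, 250-bp
paired junction reads, 50-bp small-RNA reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pmhd_out"

    # synthetic genome
    n_chromosomes: int = 3
    chrom_length: int = 300_000
    n_clusters: int = 30
    paper_emulation: bool = False

    # junction library
    enzymes: tuple[str, str] = ("GCGC", "TCGA")
    read_length: int = 250
    size_min: int = 300
    size_max: int = 600
    n_individuals: int = 40
    mean_depth_per_individual: float = 2.0
    error_rate: float = 0.0
    n_background_pairs: int = 0

    # insertion calling
    min_element_match: int = 20
    map_k: int = 31
    max_mismatches: int = 2
    merge_window: int = 10

    # cluster annotation
    strandness_threshold_pct: float = 20.0
    active_top_n: int = 15

    # small RNA quantification
    pirna_min_len: int = 24
    pirna_max_len: int = 35
    smallrna_max_mismatch: int = 0
    n_mirna_reads: int = 50_000

    # phenotype / panel
    gd_low_threshold_pct: float = 10.0
    n_strains: int = 5
    beta_pirna: float = -3.0
    beta_kp: float = -1.0
    panel_noise_sd: float = 0.5

    # demo scale
    demo_insertions_per_strain: int = 8
    demo_in_cluster_per_strain: int = 3

    @property
    def size_range(self) -> tuple[int, int]:
        return (self.size_min, self.size_max)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["enzymes"] = list(self.enzymes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "enzymes" in data:
            data = dict(data)
            data["enzymes"] = tuple(data["enzymes"])
        return cls(**data)
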