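"""End-to-end demo workflow on synthetic data.

``run_demo`` wires every stage together for a panel of simulated paternal
lines sharing one reference genome: plant insertions per line, simulate and
call junction libraries, annotate cluster membership and chromatin state,
simulate and quantify small-RNA libraries, assemble the strain panel (GD
scores generated from the measured molecular quantities through the
suppressive logistic model), and run the association statistics.  A
truth-vs-called comparison section closes the loop on simulator ground
truth.  All randomness flows from the single config seed; outputs are
deterministic byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .clusters import assign_membership, cluster_read_fraction
from .config import PipelineConfig
from .element import make_element_model
from .genome import PlantSpec, make_genome, plant_insertions
from .insertions import GenomeIndex, call_insertions, region_state_fractions
from .simulate import (
    decoy_mirnas,
    simulate_junction_library,
    simulate_small_rnas,
)
from .smallrna import quantify_pirnas
from .stats import hcluster, label_phenotype, multiple_regression, pearson, t_test

logger = logging.getLogger("pmhd")


def _match_sites(sites, truth, informative, merge_window):
    """Greedy 1:1 matching of called sites to informative planted insertions."""
    matched = set()
    hits = 0
    for i in informative:
        ins = truth.insertions[i]
        for j, s in enumerate(sites):
            if j in matched:
                continue
            if (
                s.chrom == ins.chrom
                and s.strand == ins.strand
                and abs(s.position - ins.position) <= merge_window
            ):
                matched.add(j)
                hits += 1
                break
    recall = hits / len(informative) if informative else float("nan")
    precision = hits / len(sites) if sites else float("nan")
    return recall, precision


def run_demo(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline on synthetic data; return the report dict."""
    cfg = config
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    element = make_element_model(cfg.seed)
    genome = make_genome(
        n_chromosomes=cfg.n_chromosomes,
        chrom_length=cfg.chrom_length,
        n_clusters=cfg.n_clusters,
        paper_emulation=cfg.paper_emulation,
        seed=cfg.seed + 1,
    )
    pio.write_genome(genome, out)
    index = GenomeIndex(genome, cfg.map_k)
    mirnas = decoy_mirnas()

    occupancy_cycle = (1.0, 0.5, 0.25)
    strains = [f"S{i + 1:02d}" for i in range(cfg.n_strains)]
    rows = []
    comparison = []
    for si, strain in enumerate(strains):
        strain_seed = cfg.seed * 1000 + si
        n_in = cfg.demo_in_cluster_per_strain
        spec = [
            PlantSpec("in-cluster", "KP" if j % 2 else "FP", occupancy_cycle[j % 3])
            for j in range(n_in)
        ] + [
            PlantSpec("uniform", "KP" if j % 3 else "FP", occupancy_cycle[j % 3])
            for j in range(cfg.demo_insertions_per_strain - n_in)
        ]
        planted = plant_insertions(genome, spec, seed=strain_seed)
        pairs, jtruth = simulate_junction_library(
            genome,
            planted,
            element,
            enzymes=cfg.enzymes,
            read_length=cfg.read_length,
            mean_depth_per_individual=cfg.mean_depth_per_individual,
            size_range=cfg.size_range,
            error_rate=cfg.error_rate,
            n_individuals=cfg.n_individuals,
            n_background_pairs=cfg.n_background_pairs,
            seed=strain_seed + 1,
        )
        logger.info("%s: %d junction read pairs", strain, len(pairs))
        sites = call_insertions(
            pairs,
            genome,
            element,
            min_element_match=cfg.min_element_match,
            k=cfg.map_k,
            max_mismatches=cfg.max_mismatches,
            merge_window=cfg.merge_window,
            index=index,
        )
        assign_membership(sites, genome.clusters)
        logger.info("%s: %d called sites", strain, len(sites))
        pio.write_sites(sites, out / f"{strain}_sites")
        informative = jtruth.informative_indices(
            read_length=cfg.read_length,
            min_element_match=cfg.min_element_match,
            min_mappable_flank=cfg.map_k,
        )
        recall, precision = _match_sites(sites, jtruth, informative, cfg.merge_window)
        comparison.append(
            {
                "strain": strain,
                "planted": len(planted),
                "informative": len(informative),
                "called": len(sites),
                "recall": recall,
                "precision": precision,
            }
        )

        sreads, struth = simulate_small_rnas(
            genome, planted, element, n_mirna_reads=cfg.n_mirna_reads,
            seed=strain_seed + 2,
        )
        profile = quantify_pirnas(
            sreads, element, mirnas,
            min_len=cfg.pirna_min_len, max_len=cfg.pirna_max_len,
            max_mismatch=cfg.smallrna_max_mismatch, sample=strain,
        )
        profile.to_frame().to_csv(out / f"{strain}_pirna_profile.tsv", sep="\t", index=False)

        if sites:
            frac = cluster_read_fraction(sites)
            active, silent, unknown = region_state_fractions(sites)
        else:
            frac = active = silent = unknown = float("nan")
        rows.append(
            {
                "strain_id": strain,
                "pirna_rpm": profile.rpm,
                "cluster_read_fraction": frac,
                "active_pct": active,
                "silent_pct": silent,
                "unknown_pct": unknown,
                "n_sites": len(sites),
                "sense_pirnas": profile.sense_total,
                "antisense_pirnas": profile.antisense_total,
            }
        )

    panel = pd.DataFrame(rows)

    # GD scores from the measured molecular quantities through the
    # suppressive logistic model (piRNA and KP mRNA as suppressors).
    kp_mrna = rng.lognormal(0.0, 1.0, size=len(panel))
    p_mrna = rng.lognormal(0.0, 0.5, size=len(panel))

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_pi = z(np.log1p(panel["pirna_rpm"]))
    z_kp = z(np.log(kp_mrna))
    lin = cfg.beta_pirna * z_pi + cfg.beta_kp * z_kp
    noise = rng.normal(0.0, cfg.panel_noise_sd, size=(3, len(panel)))
    gd = 100.0 / (1.0 + np.exp(-(lin + noise)))
    panel["kp_mrna"] = kp_mrna
    panel["p_mrna"] = p_mrna
    panel["gd_f1_cross_a"] = gd[0]
    panel["gd_f2"] = gd[1]
    panel["gd_cross_astar"] = gd[2]
    panel["inducibility"] = [label_phenotype(g, "A")[0] for g in gd[0]]
    panel["susceptibility"] = [label_phenotype(g, "A*")[0] for g in gd[2]]
    pio.write_panel(panel, out / "panel.tsv")

    r, p, n = pearson(panel["cluster_read_fraction"], panel["pirna_rpm"])
    reg = multiple_regression(
        panel["gd_f1_cross_a"],
        np.column_stack([z_pi, z_kp]),
        names=("pirna", "kp_mrna"),
    )
    dendro = hcluster(
        panel[["pirna_rpm", "cluster_read_fraction", "gd_f1_cross_a"]].to_numpy(),
        labels=list(panel["strain_id"]),
    )
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    low = panel.loc[panel["inducibility"] == "low", "gd_f1_cross_a"]
    high = panel.loc[panel["inducibility"] == "high", "gd_f1_cross_a"]
    if len(low) >= 2 and len(high) >= 2:
        t_stat, t_p = t_test(low, high)
        ttest = {"t": t_stat, "p": t_p, "groups": [int(len(low)), int(len(high))]}
    else:
        ttest = None

    report = {
        "config": {"seed": cfg.seed, "n_strains": cfg.n_strains},
        "panel": panel.to_dict(orient="records"),
        "truth_comparison": comparison,
        "pearson_clusterfrac_vs_rpm": {"r": r, "p": p, "n": n},
        "regression_gd_f1": {
            "predictors": list(reg.predictors),
            "coef": list(reg.coef),
            "std_coef": list(reg.std_coef),
            "partial_corr": list(reg.partial_corr),
            "t": list(reg.t_values),
            "p": list(reg.p_values),
            "df_resid": reg.df_resid,
            "n": reg.n,
        },
        "dendrogram_newick": dendro.to_newick(),
        "t_test_inducibility": ttest,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
    return report
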