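"""End-to-end orchestration: QC -> datasets -> ROH -> islands -> GRM -> scans.

Every stage is a pure function of (inputs, config); ``run_all`` executes the
full study workflow, writes each output table as TSV under the output
directory and returns them in memory as a result bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeMatrix
from .differentiation import call_outliers, fst_per_snp, logistic_by_type, lowess_smooth
from .genotype_io import QCParams, apply_qc, build_datasets
from .grm_roh import build_grm, eigen_scores, recode
from .islands import (
    assemble_islands,
    island_summary,
    roh_membership_matrix,
    significant_snps,
    snp_roh_counts,
)
from .roh_detect import RohParams, detect_roh_all
from .roh_stats import (
    chromosome_distribution,
    classify_lengths,
    count_unique,
    group_summary,
    summarize_animals,
)

logger = logging.getLogger("buffroh")

DATASET_GROUP_COL = {"ALL_DATA": "buffalo_type", "RIVER_DATA": "population", "SWAMP_DATA": "population"}


@dataclass
class PipelineConfig:
    out_dir: Path = Path("results")
    qc: QCParams = field(default_factory=QCParams)
    roh: RohParams = field(default_factory=RohParams)
    hwe_p_threshold: float = 1e-5
    island_quantile: float = 0.99
    island_max_gap_bp: int = 1_000_000
    island_min_snps: int = 2
    grm_threshold_bp: int = 4_000_000
    lowess_span: float = 0.05
    lowess_iterations: int = 3
    genome_length_bp: int | None = None  # default: map span of each dataset


@dataclass
class PipelineResult:
    qc_report: object
    datasets: dict[str, GenotypeMatrix]
    rohs: dict[str, pd.DataFrame]
    animal_summaries: dict[str, pd.DataFrame]
    tracks: dict[str, pd.DataFrame]
    islands: dict[str, pd.DataFrame]
    island_tables: dict[str, pd.DataFrame]
    fst_track: pd.DataFrame
    logistic: pd.DataFrame
    eigen: dict[str, object]
    log: dict


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / name, sep="\t", index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)


def run_all(gm: GenotypeMatrix, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full workflow on a raw genotype panel."""
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    log: dict = {"version": __version__, "n_samples_in": gm.n_samples, "n_snps_in": gm.n_snps}

    logger.info("QC on %d samples x %d SNPs", gm.n_samples, gm.n_snps)
    gm_qc, qc_report = apply_qc(gm, config.qc)
    _write(qc_report.to_frame(), out, "qc_report.tsv")
    log["qc"] = {
        "samples_removed": qc_report.n_samples_removed,
        "snps_removed": qc_report.n_snps_removed_per_filter,
    }

    datasets = build_datasets(gm_qc, config.qc, config.hwe_p_threshold)
    log["datasets"] = {k: {"n_samples": v.n_samples, "n_snps": v.n_snps} for k, v in datasets.items()}

    rohs, animal_summaries, tracks, islands_d, island_tables, eigen = {}, {}, {}, {}, {}, {}
    fst_track = logistic = None
    for name, ds in datasets.items():
        logger.info("%s: detecting ROH on %d x %d", name, ds.n_samples, ds.n_snps)
        segs = detect_roh_all(ds, config.roh)
        rohs[name] = segs
        _write(segs, out, f"{name.lower()}_roh.tsv")

        genome_len = config.genome_length_bp or ds.map_span_bp()
        summary = summarize_animals(segs, ds.samples, genome_len)
        animal_summaries[name] = summary
        _write(summary, out, f"{name.lower()}_animal_summary.tsv")
        _write(group_summary(summary), out, f"{name.lower()}_type_summary.tsv")
        _write(group_summary(summary, by="population"), out, f"{name.lower()}_population_summary.tsv")
        _write(classify_lengths(segs), out, f"{name.lower()}_length_classes.tsv")
        total, unique, carriers = count_unique(segs)
        log.setdefault("roh", {})[name] = {"total": total, "unique": unique}
        _write(carriers.head(50), out, f"{name.lower()}_top_shared_roh.tsv")
        per_chrom, spacing = chromosome_distribution(segs, ds.snps)
        per_chrom.columns = ["_".join(map(str, c)) for c in per_chrom.columns]
        _write(per_chrom.reset_index(), out, f"{name.lower()}_chromosome_distribution.tsv")
        _write(spacing.reset_index(), out, f"{name.lower()}_roh_snp_spacing.tsv")

        track = significant_snps(snp_roh_counts(segs, ds), config.island_quantile)
        tracks[name] = track
        _write(track, out, f"{name.lower()}_snp_roh_track.tsv")
        isl = assemble_islands(track, config.island_max_gap_bp, config.island_min_snps)
        islands_d[name] = isl

        if name == "ALL_DATA":
            fst_track = call_outliers(
                lowess_smooth(fst_per_snp(ds), span=config.lowess_span, iterations=config.lowess_iterations)
            )
            _write(fst_track, out, "all_data_fst.tsv")
            member = roh_membership_matrix(segs, ds)
            logistic = logistic_by_type(member, ds.samples, ds.snps)
            _write(logistic, out, "all_data_logistic.tsv")
            table = island_summary(isl, track, fst_track, logistic)
        else:
            table = island_summary(isl, track)
        island_tables[name] = table
        _write(table, out, f"{name.lower()}_islands.tsv")

        coded = recode(ds, segs, config.grm_threshold_bp)
        G, _, _ = build_grm(coded)
        eig = eigen_scores(G, ds.samples)
        eigen[name] = eig
        _write(
            pd.DataFrame(
                {"eigenvalue": eig.eigenvalues, "percent_variance": eig.percent_variance}
            ).head(20),
            out, f"{name.lower()}_eigenvalues.tsv",
        )
        _write(eig.population_means, out, f"{name.lower()}_eigen_population_means.tsv")

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return PipelineResult(
        qc_report=qc_report,
        datasets=datasets,
        rohs=rohs,
        animal_summaries=animal_summaries,
        tracks=tracks,
        islands=islands_d,
        island_tables=island_tables,
        fst_track=fst_track,
        logistic=logistic,
        eigen=eigen,
        log=log,
    )
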