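"""Pipeline orchestration: chain the analysis stages over one dataset.

Two headline analyses mirror the study design:

* the ChIP analysis — island calling against Input, knockdown-vs-control
  differential islands, island/repeat overlap percentages, repeat-class and
  family enrichment against matched random regions, subfamily enrichment
  matrix, average profiles, and the island fold-change ECDF;
* the expression analysis — RPKM, per-stage differential genes, k-means and
  PCA plumbing, the accelerated-differentiation ordering statistic,
  retroelement expression fold-changes with the expressed-element filter,
  and the element-to-gene proximity report.

Every run is deterministic given the config seed; each written file is
logged with its MD5 checksum.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._stats import substream
from .acceleration import ordering_results_table, run_ordering_analysis
from .errors import ValidationError
from .expression import (
    compute_rpkm,
    detect_de_genes,
    filter_expressed_repeats,
    kmeans_time_course,
    pca_time_course,
    repeat_expression,
    repeat_subfamily_fold_change,
)
from .genome import IntervalSet, sample_random_regions, write_bed
from .islands import call_islands, differential_islands, average_profile, fold_change_ecdf
from .proximity import elements_near_tss, proximity_expression_report
from .repeats import (
    ecdf_ks_enrichment,
    peak_overlap_percentage,
    percent_coverage_per_island,
    subfamily_enrichment_matrix,
)
from .simulate import SyntheticDataset, generate_dataset, write_dataset

logger = logging.getLogger("epirepeat")


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed."""

    seed: int = 0
    outdir: str = "epirepeat_out"
    # island calling
    window_bp: int = 200
    gap_bp: int = 400
    island_fdr: float = 0.001
    # differential islands
    diff_fc: float = 1.5
    diff_fdr: float = 0.001
    # profiles
    profile_flank_bp: int = 5000
    profile_bins: int = 50
    # repeat enrichment
    enrich_n_draws: int = 10
    # differential expression
    de_fc: float = 2.0
    de_fdr: float = 0.001
    de_rpkm_min: float = 3.0
    # clustering
    kmeans_k: int = 20
    # acceleration statistic
    alphas: List[float] = field(default_factory=lambda: [1.5, 2.0, 3.0, 4.0])
    n_boot: int = 300
    n_shuffles: int = 300
    # repeat expression
    rpbm_threshold: float = 0.003
    tss_window_bp: int = 10_000
    make_plots: bool = True
    simulate: Dict = field(default_factory=dict)  # overrides for generate_dataset

    def validate(self) -> None:
        if self.window_bp <= 0 or self.gap_bp < 0:
            raise ValidationError("window_bp must be > 0 and gap_bp >= 0")
        for name in ("island_fdr", "diff_fdr", "de_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.diff_fc < 1 or self.de_fc < 1:
            raise ValidationError("fold-change thresholds must be >= 1")
        if any(a < 1 for a in self.alphas):
            raise ValidationError("alpha thresholds must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", **kwargs)
    digest = hashlib.md5(path.read_bytes()).hexdigest()
    logger.info("wrote %s (md5 %s)", path, digest)
    return path


def run_chip_analysis(ds: SyntheticDataset, config: PipelineConfig, outdir) -> Dict[str, Path]:
    """Islands -> differential islands -> overlaps -> enrichment -> profiles."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}

    logger.info(
        "island calling: window=%d gap=%d fdr=%g", config.window_bp, config.gap_bp,
        config.island_fdr,
    )
    calls = call_islands(
        ds.chip_ctrl, ds.chip_input, config.window_bp, config.gap_bp, config.island_fdr
    )
    islands = IntervalSet(
        [c.interval for c in calls], genome=ds.genome
    )
    call_df = pd.DataFrame(
        dict(
            chrom=[c.interval.chrom for c in calls],
            start=[c.interval.start for c in calls],
            end=[c.interval.end for c in calls],
            chip_count=[c.chip_count for c in calls],
            input_count=[c.input_count for c in calls],
            score=[c.score for c in calls],
            p_value=[c.p_value for c in calls],
            q_value=[c.q_value for c in calls],
        )
    )
    out["islands"] = _write(call_df, outdir / "islands_called.tsv", index=False)
    if len(islands) == 0:
        raise ValidationError("no islands called; cannot continue the ChIP analysis")

    diffs = differential_islands(
        islands, ds.chip_ctrl, ds.chip_kd, config.diff_fc, config.diff_fdr
    )
    diff_df = pd.DataFrame(
        dict(
            chrom=[d.interval.chrom for d in diffs],
            start=[d.interval.start for d in diffs],
            end=[d.interval.end for d in diffs],
            density_ctrl=[d.density_a for d in diffs],
            density_kd=[d.density_b for d in diffs],
            log2_fold_change=[d.log2_fold_change for d in diffs],
            p_value=[d.p_value for d in diffs],
            q_value=[d.q_value for d in diffs],
            call=[d.call for d in diffs],
        )
    )
    out["differential"] = _write(diff_df, outdir / "differential_islands.tsv", index=False)

    overlap_tables = []
    for level in ("class", "family"):
        tbl = peak_overlap_percentage(islands, ds.repeats, level)
        tbl.insert(0, "level", level)
        overlap_tables.append(tbl)
    out["overlap"] = _write(
        pd.concat(overlap_tables, ignore_index=True), outdir / "island_repeat_overlap.tsv",
        index=False,
    )

    null_seed = int(substream(config.seed, "chip/random_regions").integers(2**31))
    random_regions = sample_random_regions(islands, ds.genome, config.enrich_n_draws, null_seed)
    ks_rows = []
    for level in ("class", "family"):
        for key in ds.repeats.keys(level):
            obs = percent_coverage_per_island(islands, ds.repeats, level, key)
            null = percent_coverage_per_island(random_regions, ds.repeats, level, key)
            res = ecdf_ks_enrichment(obs, null, level=level, key=key)
            ks_rows.append(
                dict(
                    level=level,
                    key=key,
                    mean_observed=float(np.mean(res.observed_coverages)),
                    mean_null=float(np.mean(res.null_coverages)),
                    ks_statistic=res.ks_statistic,
                    ks_p_value=res.ks_p_value,
                    direction=res.direction,
                )
            )
    out["enrichment"] = _write(
        pd.DataFrame(ks_rows), outdir / "repeat_enrichment_ks.tsv", index=False
    )

    matrix = subfamily_enrichment_matrix(
        {"islands": islands},
        ds.repeats,
        ds.genome,
        n_draws=config.enrich_n_draws,
        seed=int(substream(config.seed, "chip/matrix").integers(2**31)),
    )
    out["matrix"] = _write(matrix, outdir / "subfamily_enrichment_matrix.tsv")

    profile = average_profile(ds.chip_ctrl, islands, config.profile_flank_bp, config.profile_bins)
    profile_kd = average_profile(ds.chip_kd, islands, config.profile_flank_bp, config.profile_bins)
    prof_df = pd.DataFrame(
        dict(bin=np.arange(config.profile_bins), rpbm_ctrl=profile, rpbm_kd=profile_kd)
    )
    out["profile"] = _write(prof_df, outdir / "average_profile.tsv", index=False)

    ecdf = fold_change_ecdf(islands, ds.chip_ctrl, ds.chip_kd)
    out["ecdf"] = _write(
        pd.DataFrame(dict(log2_fold_change=ecdf.values, cumulative=ecdf.fractions)),
        outdir / "fold_change_ecdf.tsv",
        index=False,
    )
    return out


def run_expression_analysis(
    ds: SyntheticDataset, config: PipelineConfig, outdir
) -> Dict[str, Path]:
    """RPKM -> DE -> k-means/PCA -> acceleration -> repeat expression ->
    proximity."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: Dict[str, Path] = {}
    ds.design.validate_matrix(ds.expression)

    rpkm = compute_rpkm(ds.expression)
    out["rpkm"] = _write(rpkm.round(4), outdir / "rpkm.tsv", index_label="gene_id")

    de_by_stage = {}
    for stage in ds.design.stage_order:
        de = detect_de_genes(
            ds.expression,
            ds.design.samples(genotype="control", stage=stage),
            ds.design.samples(genotype="knockdown", stage=stage),
            fc=config.de_fc,
            fdr=config.de_fdr,
            rpkm_min=config.de_rpkm_min,
        )
        de_by_stage[stage] = de
        out[f"de_{stage}"] = _write(de, outdir / f"de_genes_{stage}.tsv", index_label="gene_id")

    de_union = sorted(
        set().union(*(set(de.index[de["is_de"]]) for de in de_by_stage.values()))
    )
    if len(de_union) >= config.kmeans_k:
        labels, _ = kmeans_time_course(
            rpkm.loc[de_union],
            k=config.kmeans_k,
            seed=int(substream(config.seed, "expr/kmeans").integers(2**31)),
        )
        out["kmeans"] = _write(
            labels.to_frame(), outdir / "kmeans_clusters.tsv", index_label="gene_id"
        )
        pca_input = rpkm.loc[de_union]
    else:
        logger.info("fewer DE genes (%d) than k=%d; skipping k-means", len(de_union),
                    config.kmeans_k)
        pca_input = rpkm
    coords = pca_time_course(pca_input, ds.design)
    out["pca"] = _write(coords, outdir / "pca_coordinates.tsv", index_label="sample_id")

    accel_tables = []
    for stage in ds.design.stage_order[1:]:
        results = run_ordering_analysis(
            rpkm,
            ds.design,
            stage,
            alphas=config.alphas,
            n_boot=config.n_boot,
            n_shuffles=config.n_shuffles,
            seed=config.seed,
        )
        accel_tables.append(ordering_results_table(results))
    accel_df = pd.concat(accel_tables, ignore_index=True)
    out["acceleration"] = _write(accel_df, outdir / "acceleration.tsv", index=False)
    if config.make_plots:
        out["acceleration_plot"] = _plot_acceleration(accel_df, outdir / "acceleration.png")

    per_element_ctrl, _ = repeat_expression(ds.rna_ctrl, ds.repeats)
    per_element_kd, _ = repeat_expression(ds.rna_kd, ds.repeats)
    fc_table = repeat_subfamily_fold_change(ds.rna_ctrl, ds.rna_kd, ds.repeats, level="name")
    out["repeat_fc"] = _write(fc_table, outdir / "repeat_subfamily_fold_change.tsv")

    expressed = filter_expressed_repeats(per_element_ctrl, ds.repeats, config.rpbm_threshold)
    expressed_kd = filter_expressed_repeats(per_element_kd, ds.repeats, config.rpbm_threshold)
    write_bed(expressed, outdir / "expressed_repeats_ctrl.bed")
    write_bed(expressed_kd, outdir / "expressed_repeats_kd.bed")
    out["expressed_repeats"] = outdir / "expressed_repeats_ctrl.bed"

    # proximity: per-element expression fold-change joined to gene DE calls
    scale_c = max(ds.rna_ctrl.library_size, 1) / 1e6
    scale_k = max(ds.rna_kd.library_size, 1) / 1e6
    lengths = (ds.repeats.table["end"] - ds.repeats.table["start"]).to_numpy()
    eps_c = pd.Series(0.5 / lengths / scale_c, index=per_element_ctrl.index)
    eps_k = pd.Series(0.5 / lengths / scale_k, index=per_element_kd.index)
    element_fc = (per_element_kd + eps_k) / (per_element_ctrl + eps_c)

    esc_de = de_by_stage[ds.design.stage_order[0]]
    records = elements_near_tss(ds.repeats.intervals(), ds.gene_models, config.tss_window_bp)
    table, summary = proximity_expression_report(
        records,
        esc_de,
        element_fc,
        island_changes=None,
        genes=ds.gene_models,
        window_bp=config.tss_window_bp,
    )
    out["proximity"] = _write(table, outdir / "proximity_report.tsv", index_label="gene_id")
    summary_df = pd.DataFrame(
        [
            dict(
                n_upregulated=int((table["group"] == "upregulated").sum()),
                n_unchanged=int((table["group"] == "unchanged").sum()),
                ks_statistic=summary.ks_statistic if summary else np.nan,
                ks_p_value=summary.ks_p_value if summary else np.nan,
                direction=summary.direction if summary else "none",
            )
        ]
    )
    out["proximity_summary"] = _write(
        summary_df, outdir / "proximity_summary.tsv", index=False
    )
    return out


def _plot_acceleration(accel_df: pd.DataFrame, path: Path) -> Path:
    """Observed vs expected lagging-fraction bars with error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = list(dict.fromkeys(accel_df["stage"]))
    fig, axes = plt.subplots(len(stages), 1, figsize=(6, 3 * len(stages)), squeeze=False)
    for ax, stage in zip(axes[:, 0], stages):
        sub = accel_df[accel_df["stage"] == stage]
        x = np.arange(len(sub))
        ax.bar(x - 0.2, sub["observed_fraction"], width=0.4, yerr=sub["bootstrap_se"],
               color="firebrick", label="observed")
        ax.bar(x + 0.2, sub["expected_mean"], width=0.4, yerr=sub["expected_sd"],
               color="steelblue", label="expected")
        ax.set_xticks(x)
        ax.set_xticklabels([f"{a:g}" for a in sub["alpha"]])
        ax.set_xlabel("alpha (fold threshold)")
        ax.set_ylabel("lagging fraction")
        ax.set_title(stage)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": "epirepeat"})
    plt.close(fig)
    logger.info("wrote %s", path)
    return path


def run_all(config: PipelineConfig) -> Dict[str, Path]:
    """Simulate the default dataset at the config seed and run both
    headline analyses; everything lands under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(seed=config.seed, **config.simulate)
    write_dataset(ds, outdir / "simulated")
    out = {}
    out.update(run_chip_analysis(ds, config, outdir / "chip"))
    out.update(run_expression_analysis(ds, config, outdir / "expression"))
    config.to_yaml(outdir / "config.yaml")
    return out
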