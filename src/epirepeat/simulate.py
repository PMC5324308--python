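"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a heterochromatin knockdown study
on a desk-scale toy genome: a multi-chromosome genome; a RepeatMasker-style
repeat annotation whose heterochromatic subfamilies are preferentially
co-placed with planted broad islands; ChIP/Input read tracks with Poisson
backgrounds and 10x island enrichment, attenuated in the knockdown at a
known island subset; a two-genotype differentiation time course with
planted differentially expressed and planted accelerated genes; and RNA
read tracks with planted retroelement de-repression, with de-repressed
elements coupled (via their islands) to upregulated genes for the proximity
analysis.

Everything is deterministic given one seed; all randomness flows through
named substreams of that seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ._stats import substream
from .errors import ValidationError
from .expression import ExpressionMatrix, TimeCourseDesign
from .genome import Genome, GenomicInterval, IntervalSet
from .islands import ReadTrack
from .proximity import GeneModel, write_gtf
from .repeats import RepeatAnnotation


@dataclass
class SubfamilyConfig:
    """One repeat subfamily: placement counts and planted effects."""

    name: str
    family: str
    repeat_class: str
    n: int
    length: int
    co_placement: float = 0.0  # probability an element overlaps a planted island
    derepression_fold: float = 1.0  # knockdown/control RNA rate ratio


def default_repeat_config() -> List[SubfamilyConfig]:
    """The standard annotation: 14 heterochromatic LINE/LTR subfamilies
    with island co-placement and graded planted de-repression, plus 6
    neutral SINE/LINE/DNA subfamilies."""
    hetero = [
        ("L1Md_T", "L1", "LINE", 80, 3000, 60.0),
        ("L1Md_Gf", "L1", "LINE", 80, 2500, 40.0),
        ("L1Md_A", "L1", "LINE", 80, 2000, 25.0),
        ("L1Md_F", "L1", "LINE", 80, 1500, 15.0),
        ("L1Md_F2", "L1", "LINE", 80, 1200, 8.0),
        ("L1Md_F3", "L1", "LINE", 80, 1000, 5.0),
        ("MMETn-int", "ERVK", "LTR", 80, 2000, 50.0),
        ("IAPLTR2_Mm", "ERVK", "LTR", 80, 400, 35.0),
        ("IAPEz-int", "ERVK", "LTR", 80, 3000, 20.0),
        ("ETnERV2-int", "ERVK", "LTR", 80, 2500, 12.0),
        ("RLTR10-int", "ERVK", "LTR", 80, 1800, 7.0),
        ("MMERK10C-int", "ERVK", "LTR", 80, 1500, 4.0),
        ("IAP-d-int", "ERVK", "LTR", 80, 2500, 3.0),
        ("RLTR6-int", "ERVK", "LTR", 80, 1200, 2.0),
    ]
    neutral = [
        ("B1_Mm", "Alu", "SINE", 300, 150),
        ("B1_Mus1", "Alu", "SINE", 200, 150),
        ("B2_Mm1a", "B2", "SINE", 200, 190),
        ("B2_Mm1t", "B2", "SINE", 150, 190),
        ("L2a", "L2", "LINE", 150, 400),
        ("Charlie1a", "hAT-Charlie", "DNA", 100, 250),
    ]
    config = [
        SubfamilyConfig(name, fam, cls, n, length, co_placement=0.8, derepression_fold=fold)
        for name, fam, cls, n, length, fold in hetero
    ]
    config += [
        SubfamilyConfig(name, fam, cls, n, length)
        for name, fam, cls, n, length in neutral
    ]
    return config


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    planted_islands: IntervalSet
    attenuated_island_ids: List[str]
    attenuation_factor: float
    enriched_subfamilies: Dict[str, float]  # name -> co-placement probability
    de_gene_ids: Dict[str, float]  # gene -> true knockdown/control fold
    accelerated_gene_ids: List[str]
    de_repressed_subfamilies: Dict[str, float]  # name -> true fold
    coupling: Dict[str, str]  # element_id -> gene_id (via the shared island)
    seed: int


def generate_genome(n_chroms: int = 3, chrom_length: int = 2_000_000, seed: int = 0) -> Genome:
    """Toy genome: n equal chromosomes named chr1..chrN."""
    if chrom_length < 10_000:
        raise ValidationError("chromosome length must be >= 10 kb")
    return Genome([(f"chr{i + 1}", chrom_length) for i in range(n_chroms)])


def plant_islands(
    genome: Genome,
    n_islands: int = 60,
    island_length: int = 2000,
    seed: int = 0,
    anchors: Optional[Sequence[Tuple[str, str, int]]] = None,
    anchor_window: int = 6000,
) -> Tuple[IntervalSet, Dict[str, str]]:
    """Place enriched-island ground truth.

    Islands fill evenly spaced slots (one island per slot, random offset)
    so they never overlap. When ``anchors`` — (gene_id, chrom, tss) tuples —
    are supplied, up to half the islands are instead placed within
    ``anchor_window`` of an anchor TSS; the returned coupling maps those
    island ids to their gene.
    """
    rng = np.random.default_rng(seed)
    anchors = list(anchors or [])
    n_anchored = min(len(anchors), n_islands // 2)
    chosen = [anchors[i] for i in rng.permutation(len(anchors))[:n_anchored]]

    islands: List[GenomicInterval] = []
    coupling: Dict[str, str] = {}
    for k, (gene_id, chrom, tss) in enumerate(chosen):
        clen = genome.length(chrom)
        offset = int(rng.integers(-anchor_window, anchor_window - island_length + 1))
        start = int(np.clip(tss + offset, 0, clen - island_length))
        name = f"island_{k:04d}"
        islands.append(GenomicInterval(chrom, start, start + island_length, name=name))
        coupling[name] = gene_id

    n_free = n_islands - n_anchored
    chroms = genome.chrom_names
    per_chrom = [n_free // len(chroms) + (1 if i < n_free % len(chroms) else 0)
                 for i in range(len(chroms))]
    k = n_anchored
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        clen = genome.length(chrom)
        slot = clen // n_here
        if slot <= island_length:
            raise ValidationError("too many islands for the genome")
        for j in range(n_here):
            offset = int(rng.integers(0, slot - island_length + 1))
            start = j * slot + offset
            islands.append(
                GenomicInterval(chrom, start, start + island_length, name=f"island_{k:04d}")
            )
            k += 1
    return IntervalSet(islands, genome=genome).sorted(), coupling


def generate_repeat_annotation(
    genome: Genome,
    config: Sequence[SubfamilyConfig],
    seed: int = 0,
    planted_islands: Optional[IntervalSet] = None,
) -> RepeatAnnotation:
    """Place repeat elements: uniformly, or overlapping a random planted
    island with each subfamily's co-placement probability."""
    if not config:
        raise ValidationError("repeat config is empty")
    total_bp = sum(c.n * c.length for c in config)
    if total_bp > 0.8 * genome.total_bp:
        raise ValidationError(
            f"requested {total_bp} bp of repeats exceeds 80% of the genome"
        )
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    weights = np.array([genome.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    island_list = list(planted_islands) if planted_islands is not None else []

    rows = []
    for cfg in config:
        if cfg.co_placement > 0 and not island_list:
            raise ValidationError(
                f"{cfg.name}: co_placement > 0 requires planted islands"
            )
        for i in range(cfg.n):
            if cfg.co_placement > 0 and rng.random() < cfg.co_placement:
                isl = island_list[int(rng.integers(len(island_list)))]
                clen = genome.length(isl.chrom)
                lo = max(0, isl.start - cfg.length + 1)
                hi = min(clen - cfg.length, isl.end - 1)
                start = int(rng.integers(lo, max(lo, hi) + 1))
                chrom = isl.chrom
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                start = int(rng.integers(0, genome.length(chrom) - cfg.length + 1))
            rows.append(
                dict(
                    chrom=chrom,
                    start=start,
                    end=start + cfg.length,
                    element_id=f"{cfg.name}|{i:04d}",
                    strand="+" if rng.random() < 0.5 else "-",
                    repeat_class=cfg.repeat_class,
                    repeat_family=cfg.family,
                    repeat_name=cfg.name,
                )
            )
    table = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return RepeatAnnotation(table, genome=genome)


def _poisson_reads(
    rng: np.random.Generator, chrom: str, lo: int, hi: int, rate: float, read_length: int
) -> np.ndarray:
    """Poisson(rate * span) reads with uniform starts in [lo, hi - rl]."""
    span = hi - lo
    n = rng.poisson(rate * span)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    upper = max(lo + 1, hi - read_length + 1)
    return rng.integers(lo, upper, size=n)


def generate_chip_tracks(
    genome: Genome,
    planted_islands: IntervalSet,
    enrichment_fold: float = 10.0,
    background_rate: float = 0.02,
    attenuation: Optional[Mapping[str, float]] = None,
    read_length: int = 36,
    seed: int = 0,
) -> Tuple[ReadTrack, ReadTrack, ReadTrack]:
    """(chip_control, chip_knockdown, input) read tracks.

    Input is Poisson background everywhere; ChIP adds (fold-1) x background
    extra reads inside islands, scaled by the per-island attenuation factor
    in the knockdown track.
    """
    if enrichment_fold < 1:
        raise ValidationError("enrichment_fold must be >= 1")
    attenuation = dict(attenuation or {})
    rng = np.random.default_rng(seed)

    def one_track(island_factor: Mapping[str, float]) -> ReadTrack:
        positions: Dict[str, list] = {c: [] for c in genome.chrom_names}
        for chrom in genome.chrom_names:
            bg = _poisson_reads(rng, chrom, 0, genome.length(chrom), background_rate, read_length)
            positions[chrom].extend(bg.tolist())
        extra_rate = background_rate * (enrichment_fold - 1.0)
        for iv in planted_islands:
            factor = island_factor.get(iv.name, 1.0)
            reads = _poisson_reads(
                rng, iv.chrom, iv.start, iv.end, extra_rate * factor, read_length
            )
            positions[iv.chrom].extend(reads.tolist())
        return ReadTrack(positions, genome, read_length=read_length)

    chip_ctrl = one_track({})
    chip_kd = one_track(attenuation)
    input_track = ReadTrack(
        {
            chrom: _poisson_reads(rng, chrom, 0, genome.length(chrom), background_rate, read_length)
            for chrom in genome.chrom_names
        },
        genome,
        read_length=read_length,
    )
    return chip_ctrl, chip_kd, input_track


def generate_expression_timecourse(
    n_genes: int = 5000,
    stages: Sequence[str] = ("ESC", "EB_d6", "EB_d10"),
    de_fraction: float = 0.05,
    accel_fraction: float = 0.3,
    de_fold: float = 4.0,
    dispersion: float = 0.1,
    depth: float = 8e6,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, TimeCourseDesign, Dict]:
    """Two-genotype differentiation time course with planted effects.

    Non-planted genes are stage-stationary (their expression distribution
    does not change with stage or genotype), so under de_fraction =
    accel_fraction = 0 the knockdown and control values of every gene are
    exchangeable. Accelerated genes get a monotone upward trajectory in the
    control (a per-stage log2 step) and knockdown values one stage ahead of
    the control at every post-ESC stage (extrapolated past the last stage;
    undifferentiated ES cells are unaffected). DE genes get a constant
    knockdown fold at every stage, in a random direction. Counts are
    negative-binomial around the expected values.
    """
    if not 0 <= de_fraction <= 1 or not 0 <= accel_fraction <= 1:
        raise ValidationError("fractions must be in [0, 1]")
    if de_fraction + accel_fraction > 1:
        raise ValidationError("de_fraction + accel_fraction must not exceed 1")
    rng = np.random.default_rng(seed)
    stages = list(stages)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    lengths = rng.integers(500, 10_001, size=n_genes)
    base = rng.lognormal(math.log(16.0), 1.0, size=n_genes)  # baseline RPKM scale

    n_accel = int(round(accel_fraction * n_genes))
    n_de = int(round(de_fraction * n_genes))
    if n_accel > n_genes // 2:
        raise ValidationError("accel_fraction must not exceed 0.5")
    # developmental genes start from low ES-cell baseline (lineage genes are
    # near-silent in ESC), keeping the induced mass a minor library fraction
    low_half = np.argsort(base)[: n_genes // 2]
    accel_idx = low_half[rng.permutation(low_half.size)[:n_accel]]
    remaining = np.setdiff1d(np.arange(n_genes), accel_idx)
    de_idx = remaining[rng.permutation(remaining.size)[:n_de]]
    steps = rng.uniform(1.0, 1.5, size=n_accel)  # log2 increment per stage
    de_sign = rng.choice([-1.0, 1.0], size=n_de)

    n_stages = len(stages)
    mu_ctrl = np.tile(base[:, None], (1, n_stages))
    mu_kd = mu_ctrl.copy()
    for j, gi in enumerate(accel_idx):
        for s in range(n_stages):
            mu_ctrl[gi, s] = base[gi] * 2.0 ** (steps[j] * s)
            # one stage ahead in the knockdown, but only once differentiation starts
            mu_kd[gi, s] = base[gi] * 2.0 ** (steps[j] * (s + 1)) if s >= 1 else base[gi]
    for j, gi in enumerate(de_idx):
        mu_kd[gi, :] *= de_fold ** de_sign[j]

    def draw(mu_rpkm: np.ndarray) -> np.ndarray:
        mu_counts = mu_rpkm * (lengths / 1000.0) * (depth / 1e6)
        if dispersion <= 0:
            return rng.poisson(mu_counts)
        r = 1.0 / dispersion
        p = r / (r + mu_counts)
        return rng.negative_binomial(r, p)

    columns, data, design_rows = [], [], []
    for genotype, mu in (("control", mu_ctrl), ("knockdown", mu_kd)):
        tag = "ctrl" if genotype == "control" else "kd"
        for s, stage in enumerate(stages):
            sample = f"{tag}_{stage}"
            columns.append(sample)
            data.append(draw(mu[:, s]))
            design_rows.append(dict(sample_id=sample, genotype=genotype, stage=stage))

    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"), columns=columns
    ).astype(np.int64)
    matrix = ExpressionMatrix(counts=counts, lengths=pd.Series(lengths, index=counts.index))
    design = TimeCourseDesign(
        pd.DataFrame(design_rows).set_index("sample_id"), stage_order=stages
    )
    truth = dict(
        accelerated_gene_ids=[gene_ids[i] for i in accel_idx],
        accel_steps={gene_ids[i]: float(s) for i, s in zip(accel_idx, steps)},
        de_folds={
            gene_ids[i]: float(de_fold**sign) for i, sign in zip(de_idx, de_sign)
        },
    )
    return matrix, design, truth


def generate_rna_repeat_reads(
    genome: Genome,
    repeats: RepeatAnnotation,
    de_repressed: Mapping[str, float],
    element_rate: float = 0.01,
    background_rate: float = 0.0005,
    library_padding: int = 1_000_000,
    read_length: int = 36,
    seed: int = 0,
) -> Tuple[ReadTrack, ReadTrack]:
    """(rna_control, rna_knockdown) tracks.

    Control reads fall in repeat elements at ``element_rate`` per bp;
    knockdown rates are multiplied by the subfamily's de-repression fold.
    Low-rate background transcription covers the whole genome in both.
    ``library_padding`` counts toward library_size without emitting reads:
    it stands for the genic bulk of a real RNA library, which maps outside
    the repeat space but dominates library-size normalisation.
    """
    if any(f < 0 for f in de_repressed.values()):
        raise ValidationError("de-repression folds must be >= 0")
    if library_padding < 0:
        raise ValidationError("library_padding must be >= 0")
    rng = np.random.default_rng(seed)

    def one_track(fold_of) -> ReadTrack:
        positions: Dict[str, list] = {c: [] for c in genome.chrom_names}
        for chrom in genome.chrom_names:
            bg = _poisson_reads(rng, chrom, 0, genome.length(chrom), background_rate, read_length)
            positions[chrom].extend(bg.tolist())
        for r in repeats.table.itertuples():
            rate = element_rate * fold_of(r.repeat_name)
            if rate <= 0:
                continue
            reads = _poisson_reads(rng, r.chrom, r.start, r.end, rate, read_length)
            positions[r.chrom].extend(reads.tolist())
        n_stored = sum(len(v) for v in positions.values())
        return ReadTrack(
            positions, genome, read_length=read_length,
            library_size=n_stored + library_padding,
        )

    rna_ctrl = one_track(lambda name: 1.0)
    rna_kd = one_track(lambda name: float(de_repressed.get(name, 1.0)))
    return rna_ctrl, rna_kd


def generate_gene_models(
    genome: Genome,
    gene_ids: Sequence[str],
    seed: int = 0,
    span_range: Tuple[int, int] = (2000, 8000),
) -> List[GeneModel]:
    """Evenly slotted, non-overlapping gene models with 2-4 exons each."""
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    n = len(gene_ids)
    per_chrom = [n // len(chroms) + (1 if i < n % len(chroms) else 0) for i in range(len(chroms))]
    genes: List[GeneModel] = []
    idx = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        clen = genome.length(chrom)
        slot = clen // n_here
        if slot <= span_range[1] + 2:
            raise ValidationError("too many genes for the genome")
        for j in range(n_here):
            span = int(rng.integers(span_range[0], span_range[1] + 1))
            start = j * slot + int(rng.integers(0, slot - span + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            edges = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons, replace=False))
            exons = [
                (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
                for k in range(n_exons)
                if edges[2 * k + 1] > edges[2 * k]
            ]
            exons = [(start, start + 1)] if not exons else exons
            genes.append(GeneModel(gene_ids[idx], chrom, strand, start, start + span, exons))
            idx += 1
    return genes


@dataclass
class SyntheticDataset:
    genome: Genome
    islands: IntervalSet
    repeats: RepeatAnnotation
    chip_ctrl: ReadTrack
    chip_kd: ReadTrack
    chip_input: ReadTrack
    rna_ctrl: ReadTrack
    rna_kd: ReadTrack
    expression: ExpressionMatrix
    design: TimeCourseDesign
    gene_models: List[GeneModel]
    truth: SyntheticTruth
    params: Dict


def generate_dataset(
    seed: int = 0,
    n_chroms: int = 3,
    chrom_length: int = 2_000_000,
    n_islands: int = 60,
    island_length: int = 2000,
    enrichment_fold: float = 10.0,
    background_rate: float = 0.02,
    attenuation_factor: float = 0.4,
    attenuated_fraction: float = 0.5,
    repeat_config: Optional[Sequence[SubfamilyConfig]] = None,
    n_genes: int = 5000,
    n_placed_genes: int = 600,
    stages: Sequence[str] = ("ESC", "EB_d6", "EB_d10"),
    de_fraction: float = 0.05,
    accel_fraction: float = 0.3,
    de_fold: float = 4.0,
    dispersion: float = 0.1,
    element_rate: float = 0.01,
    rna_background_rate: float = 0.0005,
    rna_library_padding: int = 1_000_000,
    read_length: int = 36,
) -> SyntheticDataset:
    """Generate a full coherent dataset with one ground truth.

    Knockdown-attenuated islands are preferentially the islands anchored
    near planted upregulated genes, and heterochromatic repeat elements are
    co-placed with islands — so de-repressed elements end up near
    upregulated genes, emulating the coupling between retroelement
    de-repression, loss of the repressive mark, and neighbouring gene
    activation.
    """
    params = {k: v for k, v in locals().items() if k != "repeat_config"}
    config = list(repeat_config) if repeat_config is not None else default_repeat_config()
    params["repeat_config"] = [c.__dict__ for c in config]

    genome = generate_genome(n_chroms, chrom_length, seed)
    expression, design, expr_truth = generate_expression_timecourse(
        n_genes=n_genes,
        stages=stages,
        de_fraction=de_fraction,
        accel_fraction=accel_fraction,
        de_fold=de_fold,
        dispersion=dispersion,
        seed=int(substream(seed, "expression").integers(2**31)),
    )

    up_gene_ids = sorted(g for g, f in expr_truth["de_folds"].items() if f > 1)
    other_ids = [g for g in expression.gene_ids if g not in set(up_gene_ids)]
    fill_rng = substream(seed, "placed_genes")
    n_fill = max(0, n_placed_genes - len(up_gene_ids))
    fill = [other_ids[i] for i in fill_rng.permutation(len(other_ids))[:n_fill]]
    placed_ids = sorted(up_gene_ids + fill)
    gene_models = generate_gene_models(
        genome, placed_ids, seed=int(substream(seed, "gene_models").integers(2**31))
    )
    anchors = [
        (g.gene_id, g.chrom, g.tss) for g in gene_models if g.gene_id in set(up_gene_ids)
    ]

    islands, island_coupling = plant_islands(
        genome,
        n_islands=n_islands,
        island_length=island_length,
        seed=int(substream(seed, "islands").integers(2**31)),
        anchors=anchors,
    )
    repeats = generate_repeat_annotation(
        genome,
        config,
        seed=int(substream(seed, "repeats").integers(2**31)),
        planted_islands=islands,
    )

    # knockdown attenuation: coupled islands first, then random extras
    n_att = int(round(attenuated_fraction * n_islands))
    coupled_ids = sorted(island_coupling)
    att_rng = substream(seed, "attenuation")
    rest = sorted(set(iv.name for iv in islands) - set(coupled_ids))
    extras = [rest[i] for i in att_rng.permutation(len(rest))[: max(0, n_att - len(coupled_ids))]]
    attenuated_ids = sorted(coupled_ids[:n_att] + extras)
    attenuation = {name: attenuation_factor for name in attenuated_ids}

    chip_ctrl, chip_kd, chip_input = generate_chip_tracks(
        genome,
        islands,
        enrichment_fold=enrichment_fold,
        background_rate=background_rate,
        attenuation=attenuation,
        read_length=read_length,
        seed=int(substream(seed, "chip").integers(2**31)),
    )
    de_repressed = {
        c.name: c.derepression_fold for c in config if c.derepression_fold != 1.0
    }
    rna_ctrl, rna_kd = generate_rna_repeat_reads(
        genome,
        repeats,
        de_repressed,
        element_rate=element_rate,
        background_rate=rna_background_rate,
        library_padding=rna_library_padding,
        read_length=read_length,
        seed=int(substream(seed, "rna").integers(2**31)),
    )

    # element -> gene coupling through the shared island
    island_by_name = {iv.name: iv for iv in islands}
    coupled_islands = IntervalSet(
        [island_by_name[i] for i in coupled_ids], genome=genome
    )
    element_coupling: Dict[str, str] = {}
    if len(coupled_islands):
        starts_by_chrom = coupled_islands.by_chrom()
        name_lookup = {
            (iv.chrom, iv.start): island_coupling[iv.name] for iv in coupled_islands
        }
        for r in repeats.table.itertuples():
            if r.repeat_name not in de_repressed:
                continue
            if r.chrom not in starts_by_chrom:
                continue
            starts, ends = starts_by_chrom[r.chrom]
            j = int(np.searchsorted(starts, r.end, side="left"))
            ov = np.minimum(ends[:j], r.end) - np.maximum(starts[:j], r.start)
            hit = np.flatnonzero(ov > 0)
            if hit.size:
                s = int(starts[hit[0]])
                element_coupling[r.element_id] = name_lookup[(r.chrom, s)]

    truth = SyntheticTruth(
        planted_islands=islands,
        attenuated_island_ids=attenuated_ids,
        attenuation_factor=attenuation_factor,
        enriched_subfamilies={c.name: c.co_placement for c in config if c.co_placement > 0},
        de_gene_ids=expr_truth["de_folds"],
        accelerated_gene_ids=expr_truth["accelerated_gene_ids"],
        de_repressed_subfamilies=de_repressed,
        coupling=element_coupling,
        seed=seed,
    )
    return SyntheticDataset(
        genome=genome,
        islands=islands,
        repeats=repeats,
        chip_ctrl=chip_ctrl,
        chip_kd=chip_kd,
        chip_input=chip_input,
        rna_ctrl=rna_ctrl,
        rna_kd=rna_kd,
        expression=expression,
        design=design,
        gene_models=gene_models,
        truth=truth,
        params=params,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> List[Path]:
    """Emit the dataset as plain-text files plus a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _register(path):
        written.append(path)
        return path

    ds.genome.to_chrom_sizes(_register(outdir / "genome.chrom.sizes"))
    from .genome import write_bed  # local import avoids cycle at module load

    write_bed(ds.islands, _register(outdir / "islands_truth.bed"))
    ds.repeats.to_bed(_register(outdir / "repeats.bed"))
    for tag in ("chip_ctrl", "chip_kd", "chip_input", "rna_ctrl", "rna_kd"):
        getattr(ds, tag).to_bed(_register(outdir / f"reads_{tag}.bed"))
    ds.expression.to_tsv(_register(outdir / "counts.tsv"))
    ds.design.to_tsv(_register(outdir / "design.tsv"))
    write_gtf(ds.gene_models, _register(outdir / "genes.gtf"))

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        dict(island_id=ds.truth.attenuated_island_ids)
    ).to_csv(_register(truth_dir / "attenuated_islands.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.truth.de_gene_ids.items()), columns=["gene_id", "true_fold"]
    ).to_csv(_register(truth_dir / "de_genes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        dict(gene_id=sorted(ds.truth.accelerated_gene_ids))
    ).to_csv(_register(truth_dir / "accelerated_genes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.truth.de_repressed_subfamilies.items()), columns=["repeat_name", "true_fold"]
    ).to_csv(_register(truth_dir / "de_repressed_subfamilies.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.truth.coupling.items()), columns=["element_id", "gene_id"]
    ).to_csv(_register(truth_dir / "element_gene_coupling.tsv"), sep="\t", index=False)

    manifest = dict(ds.params)
    manifest["stages"] = list(manifest["stages"])
    with open(_register(outdir / "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return written
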