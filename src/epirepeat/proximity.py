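"""Retroelement-to-gene proximity: elements near transcription start sites,
genic-context annotation, and expression coupling reports.

The proximity window is symmetric around the TSS (default +/- 10 kb);
distances are signed relative to the gene's strand, negative upstream.
Genic context uses the precedence exonic > intronic > intergenic across all
overlapping genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genome import Genome, GenomicInterval, IntervalSet
from .repeats import ecdf_ks_enrichment, EnrichmentResult


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # gene span, 0-based half-open
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise ValidationError(f"gene {self.gene_id}: empty span")
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise ValidationError(f"gene {self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        """Transcription start: span start on +, last base on -."""
        return self.start if self.strand == "+" else self.end - 1


def read_gtf(path) -> List[GeneModel]:
    """Light GTF reader for gene/exon features (1-based closed coordinates
    converted to 0-based half-open). Genes without a gene feature line get
    their span from the exon hull."""
    spans: Dict[str, List] = {}
    exons: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise ParseError(f"{path}: line {lineno}: no gene_id attribute")
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                spans[gene_id] = [chrom, strand, s, e]
            else:
                exons.setdefault(gene_id, []).append((s, e))
                if gene_id not in spans:
                    spans[gene_id] = [chrom, strand, s, e]
                else:
                    spans[gene_id][2] = min(spans[gene_id][2], s)
                    spans[gene_id][3] = max(spans[gene_id][3], e)
    return [
        GeneModel(gid, chrom, strand, s, e, sorted(exons.get(gid, [])))
        for gid, (chrom, strand, s, e) in spans.items()
    ]


def write_gtf(genes: Sequence[GeneModel], path, source: str = "epirepeat") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_bed12(path) -> List[GeneModel]:
    """BED12 gene models (blocks become exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 tab-separated fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


@dataclass
class ProximityRecord:
    gene_id: str
    element_id: str
    context: str  # exonic / intronic / intergenic
    distance: int  # signed bp from TSS to nearest element edge; 0 if overlapping


def annotate_genic_context(
    elements: IntervalSet, genes: Sequence[GeneModel]
) -> List[str]:
    """Per-element label with precedence exonic > intronic > intergenic.

    An element overlapping any exon of any gene is exonic; otherwise an
    element overlapping any gene span is intronic; otherwise intergenic.
    """
    exon_set = IntervalSet(
        [
            GenomicInterval(g.chrom, s, e)
            for g in genes
            for (s, e) in g.exons
        ]
    ).merged()
    span_set = IntervalSet(
        [GenomicInterval(g.chrom, g.start, g.end) for g in genes]
    ).merged()
    exon_by_chrom = exon_set.by_chrom()
    span_by_chrom = span_set.by_chrom()

    def _hits(iv: GenomicInterval, by_chrom) -> bool:
        if iv.chrom not in by_chrom:
            return False
        starts, ends = by_chrom[iv.chrom]
        j = int(np.searchsorted(starts, iv.end, side="left"))
        i = int(np.searchsorted(ends, iv.start, side="right"))
        return j > i

    out = []
    for iv in elements:
        if _hits(iv, exon_by_chrom):
            out.append("exonic")
        elif _hits(iv, span_by_chrom):
            out.append("intronic")
        else:
            out.append("intergenic")
    return out


def elements_near_tss(
    elements: IntervalSet,
    genes: Sequence[GeneModel],
    window_bp: int = 10000,
) -> List[ProximityRecord]:
    """All (gene, element) pairs where the element intersects
    [TSS - window, TSS + window).

    Distance is measured from the TSS to the nearest element edge, 0 when
    the element spans the TSS, and signed in the gene's orientation
    (negative upstream).
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    contexts = annotate_genic_context(elements, genes)
    by_chrom: Dict[str, List[Tuple[int, GenomicInterval, str]]] = {}
    for idx, iv in enumerate(elements):
        by_chrom.setdefault(iv.chrom, []).append((idx, iv, contexts[idx]))
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda t: t[1].start)

    records = []
    for gene in genes:
        if gene.chrom not in by_chrom:
            continue
        tss = gene.tss
        lo, hi = tss - window_bp, tss + window_bp
        starts = np.array([t[1].start for t in by_chrom[gene.chrom]])
        j = int(np.searchsorted(starts, hi, side="left"))
        for idx, iv, context in by_chrom[gene.chrom][:j]:
            if iv.end <= lo or iv.start >= hi:
                continue
            if iv.start <= tss < iv.end:
                raw = 0
            elif iv.start > tss:
                raw = iv.start - tss
            else:
                raw = iv.end - tss  # negative: element entirely left of TSS
            distance = raw if gene.strand == "+" else -raw
            records.append(ProximityRecord(gene.gene_id, iv.name, context, int(distance)))
    return records


def proximity_expression_report(
    records: Sequence[ProximityRecord],
    de_results: pd.DataFrame,
    element_fold_changes: pd.Series,
    island_changes: Optional[pd.DataFrame] = None,
    genes: Optional[Sequence[GeneModel]] = None,
    window_bp: int = 10000,
) -> Tuple[pd.DataFrame, Optional[EnrichmentResult]]:
    """Join TSS-proximal elements with gene DE calls and element expression.

    Per gene: number of nearby elements, mean nearby-element expression
    fold-change, and (when differential-island results plus gene models are
    given) the mean log2 H4K20me3-style density change of nearby islands.
    The summary compares the per-gene mean element fold-change between
    upregulated (is_de and log2FC > 0) and non-DE genes with a KS test.

    Returns (per-gene table, KS result or None). Genes with zero nearby
    elements contribute NaN means but stay in the table.
    """
    up_genes = set(de_results.index[(de_results["is_de"]) & (de_results["log2_fold_change"] > 0)])
    if not up_genes:
        warnings.warn("no upregulated genes; proximity report is empty")
        return pd.DataFrame(
            columns=["n_elements", "mean_element_fc", "mean_island_log2fc", "group"]
        ), None

    per_gene_elements: Dict[str, List[str]] = {}
    for rec in records:
        per_gene_elements.setdefault(rec.gene_id, []).append(rec.element_id)

    island_log2fc_by_gene: Dict[str, float] = {}
    if island_changes is not None and genes is not None and len(island_changes):
        island_set = IntervalSet(
            [
                GenomicInterval(r.chrom, r.start, r.end, name=str(i))
                for i, r in island_changes.iterrows()
            ]
        )
        island_records = elements_near_tss(island_set, genes, window_bp)
        tmp: Dict[str, List[float]] = {}
        for rec in island_records:
            tmp.setdefault(rec.gene_id, []).append(
                float(island_changes.loc[int(rec.element_id), "log2_fold_change"])
            )
        island_log2fc_by_gene = {g: float(np.mean(v)) for g, v in tmp.items()}

    rows = []
    for gene_id in de_results.index:
        element_ids = per_gene_elements.get(gene_id, [])
        fcs = element_fold_changes.reindex(element_ids).dropna()
        rows.append(
            dict(
                gene_id=gene_id,
                n_elements=len(element_ids),
                mean_element_fc=float(fcs.mean()) if len(fcs) else np.nan,
                mean_island_log2fc=island_log2fc_by_gene.get(gene_id, np.nan),
                group="upregulated" if gene_id in up_genes else (
                    "de_other" if bool(de_results.loc[gene_id, "is_de"]) else "unchanged"
                ),
            )
        )
    table = pd.DataFrame(rows).set_index("gene_id")

    with_elements = table[table["n_elements"] > 0]
    obs = with_elements.loc[with_elements["group"] == "upregulated", "mean_element_fc"].dropna()
    null = with_elements.loc[with_elements["group"] == "unchanged", "mean_element_fc"].dropna()
    summary = None
    if len(obs) and len(null):
        summary = ecdf_ks_enrichment(obs.to_numpy(), null.to_numpy(), level="proximity",
                                     key="element_fc_up_vs_unchanged")
    return table, summary
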