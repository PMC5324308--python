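"""Gene and repeat-element expression quantification.

RPKM (reads per kilobase of exon model per million mapped reads) for genes,
RPBM for repeat elements, a self-contained pooled-count binomial test for
differential expression (deliberately simpler than a dispersion-modelling
negative-binomial GLM; see docs), time-course k-means / PCA plumbing, and
retroelement de-repression fold-changes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._stats import bh_qvalues, binom_two_sided
from .errors import ValidationError
from .genome import GenomicInterval, IntervalSet
from .islands import ReadTrack
from .repeats import LEVELS, RepeatAnnotation, _LEVEL_COLS


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts plus exon-model lengths (bp)."""

    counts: pd.DataFrame  # index gene_id, columns sample_id, integer counts
    lengths: pd.Series  # index gene_id, exon-model length in bp

    def __post_init__(self):
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise ValidationError("every gene needs an exon-model length")
        if (self.lengths <= 0).any():
            raise ValidationError("exon-model lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """TSV with columns gene_id, length, then one column per sample."""
        df = pd.read_csv(path, sep="\t")
        if "gene_id" not in df.columns or "length" not in df.columns:
            raise ValidationError("counts TSV needs 'gene_id' and 'length' columns")
        df = df.set_index("gene_id")
        return cls(counts=df.drop(columns=["length"]).astype(np.int64), lengths=df["length"])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class TimeCourseDesign:
    """Maps sample_id -> (genotype, stage), with an explicit stage order."""

    table: pd.DataFrame  # index sample_id, columns genotype, stage
    stage_order: List[str]

    def __post_init__(self):
        missing = set(self.table["stage"]) - set(self.stage_order)
        if missing:
            raise ValidationError(f"stages {missing} not in stage_order")

    def samples(self, genotype: Optional[str] = None, stage: Optional[str] = None) -> List[str]:
        mask = pd.Series(True, index=self.table.index)
        if genotype is not None:
            mask &= self.table["genotype"] == genotype
        if stage is not None:
            mask &= self.table["stage"] == stage
        return list(self.table.index[mask])

    def validate_matrix(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples without a design entry: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path) -> "TimeCourseDesign":
        df = pd.read_csv(path, sep="\t").set_index("sample_id")
        stage_order = list(dict.fromkeys(df["stage"]))
        return cls(df, stage_order)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """count / (length/1000) / (library/1e6), per gene and sample."""
    libs = matrix.counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    kb = matrix.lengths / 1000.0
    return matrix.counts.div(kb, axis=0).div(libs / 1e6, axis=1)


def detect_de_genes(
    matrix: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    fc: float = 2.0,
    fdr: float = 0.001,
    rpkm_min: float = 3.0,
    pseudocount_rpkm: float = 0.1,
) -> pd.DataFrame:
    """Differential expression between two sample groups.

    Genes with RPKM below ``rpkm_min`` in both groups are excluded before
    testing. Counts are pooled per group and tested with a two-sided
    binomial test against the library-size ratio, BH-corrected across the
    tested genes. A gene is DE when q <= ``fdr``, |fold-change| >= ``fc``,
    and it passed the RPKM floor.

    Returns one row per gene: log2_fold_change (B relative to A), p_value,
    q_value (NaN for untested genes), rpkm_a, rpkm_b, tested, is_de.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise ValidationError("both sample groups must be non-empty")
    if fc < 1:
        raise ValidationError("fc must be >= 1")
    rpkm = compute_rpkm(matrix)
    rpkm_a = rpkm[samples_a].mean(axis=1)
    rpkm_b = rpkm[samples_b].mean(axis=1)
    tested = (rpkm_a >= rpkm_min) | (rpkm_b >= rpkm_min)

    counts_a = matrix.counts[samples_a].sum(axis=1)
    counts_b = matrix.counts[samples_b].sum(axis=1)
    lib_a = int(matrix.counts[samples_a].to_numpy().sum())
    lib_b = int(matrix.counts[samples_b].to_numpy().sum())
    p_null = lib_a / (lib_a + lib_b)

    p_values = pd.Series(np.nan, index=matrix.counts.index)
    q_values = pd.Series(np.nan, index=matrix.counts.index)
    if tested.any():
        p_tested = binom_two_sided(
            counts_a[tested].to_numpy(), (counts_a + counts_b)[tested].to_numpy(), p_null
        )
        p_values[tested] = p_tested
        q_values[tested] = bh_qvalues(p_tested)

    log2fc = np.log2((rpkm_b + pseudocount_rpkm) / (rpkm_a + pseudocount_rpkm))
    is_de = tested & (q_values <= fdr) & (log2fc.abs() >= math.log2(fc))
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p_values,
            "q_value": q_values,
            "rpkm_a": rpkm_a,
            "rpkm_b": rpkm_b,
            "tested": tested,
            "is_de": is_de.fillna(False),
        }
    )


def kmeans_time_course(
    rpkm: pd.DataFrame, k: int = 20, seed: int = 0
) -> Tuple[pd.Series, np.ndarray]:
    """Cluster gene expression patterns: per-gene z-score of log2(RPKM+1),
    then k-means with a fixed seed. Returns (labels, centroids)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(rpkm) < k:
        raise ValidationError(f"need >= k={k} genes, got {len(rpkm)}")
    x = np.log2(rpkm.to_numpy(dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    labels = km.fit_predict(z)
    return pd.Series(labels, index=rpkm.index, name="cluster"), km.cluster_centers_


def pca_time_course(rpkm: pd.DataFrame, design: TimeCourseDesign) -> pd.DataFrame:
    """Sample coordinates on the first two principal components of
    log2(RPKM+1), centered. Sign convention: the control sample at the
    earliest stage has negative PC1."""
    if rpkm.shape[1] < 3:
        raise ValidationError("PCA needs >= 3 samples")
    x = np.log2(rpkm.to_numpy(dtype=float) + 1.0).T  # samples x genes
    if np.allclose(x, x[0]):
        raise ValidationError("expression matrix is constant across samples")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    out = pd.DataFrame(coords, index=rpkm.columns, columns=["PC1", "PC2"])
    anchor = [
        s for s in design.samples(genotype="control", stage=design.stage_order[0])
        if s in out.index
    ]
    if anchor and out.loc[anchor[0], "PC1"] > 0:
        out["PC1"] = -out["PC1"]
    return out


def repeat_expression(
    track: ReadTrack, repeats: RepeatAnnotation
) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-element RPBM and per-label aggregate densities.

    A read is assigned to every element it overlaps, once per element. The
    aggregate density of a label is total reads in its elements divided by
    the total element bp, per million mapped reads.
    """
    if len(repeats) == 0:
        raise ValidationError("repeat annotation is empty")
    scale = max(track.library_size, 1) / 1e6
    tbl = repeats.table
    counts = np.empty(len(tbl), dtype=np.int64)
    for chrom, grp in tbl.groupby("chrom", sort=False):
        counts[grp.index.to_numpy()] = track.count_in(
            chrom, grp["start"].to_numpy(), grp["end"].to_numpy()
        )
    lengths = (tbl["end"] - tbl["start"]).to_numpy()
    per_element = pd.Series(counts / lengths / scale, index=tbl["element_id"], name="rpbm")

    agg_rows = []
    helper = tbl.assign(_count=counts, _length=lengths)
    for level in LEVELS:
        col = _LEVEL_COLS[level]
        grouped = helper.groupby(col)[["_count", "_length"]].sum()
        for key, row in grouped.iterrows():
            agg_rows.append(
                dict(
                    level=level,
                    key=key,
                    n_elements=int((tbl[col] == key).sum()),
                    total_bp=int(row["_length"]),
                    reads=int(row["_count"]),
                    rpbm=row["_count"] / row["_length"] / scale,
                )
            )
    return per_element, pd.DataFrame(agg_rows)


def filter_expressed_repeats(
    per_element_rpbm: pd.Series, repeats: RepeatAnnotation, threshold: float = 0.003
) -> IntervalSet:
    """Elements whose tag density is strictly greater than ``threshold``
    RPBM (the expressed-repeat filter; an element at exactly the threshold
    is excluded)."""
    keep = set(per_element_rpbm.index[per_element_rpbm > threshold])
    rows = repeats.table[repeats.table["element_id"].isin(keep)]
    return IntervalSet(
        [
            GenomicInterval(r.chrom, r.start, r.end, name=r.element_id, strand=r.strand)
            for r in rows.itertuples()
        ],
        genome=repeats.genome,
    )


def repeat_subfamily_fold_change(
    track_a: ReadTrack,
    track_b: ReadTrack,
    repeats: RepeatAnnotation,
    level: str = "name",
    pseudocount_reads: float = 0.5,
) -> pd.DataFrame:
    """Per-label expression fold-change of B relative to A.

    Fold-change = (aggregate density_B + eps_B) / (aggregate density_A +
    eps_A), where eps is half a read over the label's total bp, library
    normalized. Swapping A and B inverts every fold-change.
    """
    _, agg_a = repeat_expression(track_a, repeats)
    _, agg_b = repeat_expression(track_b, repeats)
    a = agg_a[agg_a["level"] == level].set_index("key")
    b = agg_b[agg_b["level"] == level].set_index("key")
    eps_a = pseudocount_reads / a["total_bp"] / (max(track_a.library_size, 1) / 1e6)
    eps_b = pseudocount_reads / b["total_bp"] / (max(track_b.library_size, 1) / 1e6)
    fc = (b["rpbm"] + eps_b) / (a["rpbm"] + eps_a)
    out = pd.DataFrame(
        {
            "density_a": a["rpbm"],
            "density_b": b["rpbm"],
            "fold_change": fc,
        }
    )
    out.index.name = level
    return out.sort_values("fold_change", ascending=False)
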