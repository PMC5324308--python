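"""Repeat-element annotation and enrichment of island sets against matched
random-region nulls.

Repeats carry the RepeatMasker-style three-level hierarchy: class (LINE,
LTR, ...), family (L1, ERVK, ...), and name — the subfamily, the finest
label (L1Md_T, IAPLTR2_Mm, ...). Enrichment compares the per-island percent
coverage of a label between an observed island set and length/chromosome/
count-matched random regions, with a two-sample Kolmogorov-Smirnov test on
the two coverage ECDFs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._stats import substream
from .errors import ParseError, ValidationError
from .genome import (
    Genome,
    GenomicInterval,
    IntervalSet,
    island_overlap_percent,
    overlap_fraction,
    sample_random_regions,
)

LEVELS = ("class", "family", "name")
_LEVEL_COLS = {"class": "repeat_class", "family": "repeat_family", "name": "repeat_name"}


class RepeatAnnotation:
    """Interval annotation with a class -> family -> name hierarchy.

    Backed by a DataFrame with columns chrom, start, end, element_id,
    strand, repeat_class, repeat_family, repeat_name. The hierarchy must be
    functional: each name maps to exactly one family, each family to one
    class.
    """

    def __init__(self, table: pd.DataFrame, genome: Optional[Genome] = None):
        required = ["chrom", "start", "end", "element_id", "strand",
                    "repeat_class", "repeat_family", "repeat_name"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValidationError(f"repeat table missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        if table["element_id"].duplicated().any():
            raise ValidationError("duplicate element_id in repeat annotation")
        for col, parent in (("repeat_name", "repeat_family"), ("repeat_family", "repeat_class")):
            n_parents = table.groupby(col)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"hierarchy is not a function: {col} value(s) {list(bad.index)} "
                    f"map to multiple {parent} values"
                )
        self.table = table
        self.genome = genome
        self._subsets: Dict[tuple, IntervalSet] = {}

    def __len__(self) -> int:
        return len(self.table)

    def keys(self, level: str) -> List[str]:
        if level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {level!r}")
        return sorted(self.table[_LEVEL_COLS[level]].unique())

    def subset(self, level: str, key: str) -> IntervalSet:
        """Intervals of all elements carrying the given label."""
        if level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {level!r}")
        cache_key = (level, key)
        if cache_key not in self._subsets:
            rows = self.table[self.table[_LEVEL_COLS[level]] == key]
            self._subsets[cache_key] = IntervalSet(
                [
                    GenomicInterval(r.chrom, r.start, r.end, name=r.element_id, strand=r.strand)
                    for r in rows.itertuples()
                ],
                genome=self.genome,
            )
        return self._subsets[cache_key]

    def intervals(self) -> IntervalSet:
        return IntervalSet(
            [
                GenomicInterval(r.chrom, r.start, r.end, name=r.element_id, strand=r.strand)
                for r in self.table.itertuples()
            ],
            genome=self.genome,
        )

    @classmethod
    def from_bed(cls, path, genome: Optional[Genome] = None) -> "RepeatAnnotation":
        """BED6+3 reader: columns 7-9 are class, family, name."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith(("track", "#")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ParseError(f"{path}: line {lineno}: expected >= 9 tab-separated fields")
                rows.append(
                    dict(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        element_id=fields[3],
                        strand=fields[5],
                        repeat_class=fields[6],
                        repeat_family=fields[7],
                        repeat_name=fields[8],
                    )
                )
        return cls(pd.DataFrame(rows), genome=genome)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.table.itertuples():
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.element_id}\t0\t{r.strand}\t"
                    f"{r.repeat_class}\t{r.repeat_family}\t{r.repeat_name}\n"
                )

    @classmethod
    def from_repeatmasker_out(cls, path, genome: Optional[Genome] = None) -> "RepeatAnnotation":
        """Reader for RepeatMasker .out-style whitespace tables.

        Expects the standard layout: three header lines, then columns with
        query sequence (5), begin (6), end (7), strand (9), repeat name
        (10), and class/family (11, "class/family" or "class"). Coordinates
        are 1-based inclusive and converted to 0-based half-open.
        """
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields or not fields[0].isdigit():
                    continue  # header / blank lines
                if len(fields) < 11:
                    raise ParseError(f"{path}: line {lineno}: expected >= 11 whitespace fields")
                chrom = fields[4]
                start, end = int(fields[5]) - 1, int(fields[6])
                strand = "+" if fields[8] in ("+",) else "-"
                name = fields[9]
                cf = fields[10].split("/")
                rclass = cf[0]
                rfamily = cf[1] if len(cf) > 1 else cf[0]
                rows.append(
                    dict(
                        chrom=chrom,
                        start=start,
                        end=end,
                        element_id=f"{name}_{lineno}",
                        strand=strand,
                        repeat_class=rclass,
                        repeat_family=rfamily,
                        repeat_name=name,
                    )
                )
        return cls(pd.DataFrame(rows), genome=genome)


@dataclass
class EnrichmentResult:
    level: str
    key: str
    observed_coverages: np.ndarray
    null_coverages: np.ndarray
    ks_statistic: float
    ks_p_value: float
    direction: str  # enriched / depleted / none


def percent_coverage_per_island(
    islands: IntervalSet, repeats: RepeatAnnotation, level: str, key: str
) -> np.ndarray:
    """Per-island fraction of bases covered by elements of one label."""
    if key not in repeats.keys(level):
        raise ValidationError(
            f"unknown {level} key {key!r}; available: {repeats.keys(level)}"
        )
    return overlap_fraction(islands, repeats.subset(level, key))


def ecdf_ks_enrichment(
    observed: Sequence[float],
    null: Sequence[float],
    level: str = "",
    key: str = "",
) -> EnrichmentResult:
    """Two-sample KS comparison of observed vs null coverage distributions.

    D is the sup-gap of the two ECDFs; the p-value is the asymptotic
    two-sided one. Direction is "enriched" when the observed mean coverage
    exceeds the null mean (ECDF shifted right), "depleted" when below.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValidationError("ecdf_ks_enrichment requires two non-empty samples")
    res = stats.ks_2samp(observed, null, alternative="two-sided", method="asymp")
    d, p = float(res.statistic), float(min(res.pvalue, 1.0))
    if d == 0.0 or observed.mean() == null.mean():
        direction = "none"
    else:
        direction = "enriched" if observed.mean() > null.mean() else "depleted"
    return EnrichmentResult(level, key, observed, null, d, p, direction)


def peak_overlap_percentage(
    islands: IntervalSet, repeats: RepeatAnnotation, level: str, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Per label: percentage of islands overlapping >= 1 element, sorted
    descending."""
    if len(islands) == 0:
        raise ValidationError("peak_overlap_percentage requires a non-empty island set")
    rows = []
    for key in repeats.keys(level):
        subset = repeats.subset(level, key)
        pct = island_overlap_percent(islands, subset, min_overlap_bp) if len(subset) else 0.0
        rows.append((key, pct))
    df = pd.DataFrame(rows, columns=["key", "percent_islands_overlapping"])
    return df.sort_values(
        "percent_islands_overlapping", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def subfamily_enrichment_matrix(
    island_sets: Mapping[str, IntervalSet],
    repeats: RepeatAnnotation,
    genome: Genome,
    n_draws: int = 10,
    seed: int = 0,
    level: str = "name",
    floor_percent: float = 0.5,
) -> pd.DataFrame:
    """Enrichment-ratio matrix: rows = repeat labels, columns = island sets.

    Each entry is the observed percentage of islands overlapping the label,
    divided by the mean overlap percentage across matched random draws
    (pooled, floored at ``floor_percent`` to keep ratios finite).
    """
    if not island_sets:
        raise ValidationError("at least one island set is required")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    keys = repeats.keys(level)
    data = {}
    for col_idx, (set_name, islands) in enumerate(island_sets.items()):
        rng_seed = int(substream(seed, f"enrichment_matrix/{set_name}").integers(2**31))
        random_regions = sample_random_regions(islands, genome, n_draws, rng_seed)
        col = []
        for key in keys:
            subset = repeats.subset(level, key)
            if len(subset) == 0:
                col.append(np.nan)
                continue
            obs = island_overlap_percent(islands, subset)
            null = island_overlap_percent(random_regions, subset)
            col.append(obs / max(null, floor_percent))
        data[set_name] = col
    return pd.DataFrame(data, index=pd.Index(keys, name=level))


def cluster_rows(matrix: pd.DataFrame) -> List[str]:
    """Row order from average-linkage hierarchical clustering of the
    enrichment profiles (presentation plumbing for heatmaps)."""
    values = matrix.fillna(0.0).to_numpy()
    if len(matrix) < 3:
        return list(matrix.index)
    link = hierarchy.linkage(values, method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [matrix.index[i] for i in order]
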