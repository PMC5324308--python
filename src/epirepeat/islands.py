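"""Broad-domain ChIP-seq island calling and island-level density analysis.

The caller emulates the spatial-clustering ("SICER-style") approach to broad
histone marks: the genome is tiled into fixed windows, windows whose ChIP
read count clears a permissive Poisson eligibility threshold are clustered
across short gaps into islands, and each island is then scored against the
library-scaled Input (chromatin) control with a Poisson test, with
Benjamini-Hochberg control across islands. Default parameters are a 200 bp
window, a 400 bp gap, and FDR 0.001.

Densities are RPBM: reads per base per million mapped reads.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._stats import bh_qvalues, binom_two_sided
from .errors import ParseError, ValidationError
from .genome import Genome, GenomicInterval, IntervalSet, read_bed


class ReadTrack:
    """Mapped single-end reads: per-chromosome sorted start positions.

    Reads are fixed length; a read at position p covers [p, p + read_length).
    ``library_size`` defaults to the number of stored reads but may be larger
    (reads mapped outside the stored chromosomes).
    """

    def __init__(
        self,
        positions: Mapping[str, Sequence[int]],
        genome: Genome,
        read_length: int = 36,
        library_size: Optional[int] = None,
    ):
        if read_length < 1:
            raise ValidationError("read_length must be >= 1")
        self.genome = genome
        self.read_length = int(read_length)
        self.positions: Dict[str, np.ndarray] = {}
        n_stored = 0
        for chrom, pos in positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size == 0:
                continue
            arr = np.sort(arr)
            clen = genome.length(chrom)
            if arr[0] < 0 or arr[-1] >= clen:
                raise ValidationError(f"read position out of bounds on {chrom}")
            self.positions[chrom] = arr
            n_stored += arr.size
        self.n_reads = n_stored
        self.library_size = int(library_size) if library_size is not None else n_stored
        if self.library_size < n_stored:
            raise ValidationError("library_size smaller than number of stored reads")

    @classmethod
    def from_bed(cls, path, genome: Genome, read_length: int = 36) -> "ReadTrack":
        """Read positions from a BED file of mapped reads (start used)."""
        iset = read_bed(path, genome=genome)
        grouped: Dict[str, list] = {}
        for iv in iset:
            grouped.setdefault(iv.chrom, []).append(iv.start)
        return cls(grouped, genome, read_length=read_length)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.positions:
                for p in self.positions[chrom]:
                    fh.write(f"{chrom}\t{p}\t{p + self.read_length}\n")

    @classmethod
    def from_bedgraph(cls, path, genome: Genome, read_length: int = 36) -> "ReadTrack":
        """Convert a bedGraph of per-bin read counts into pseudo-positions.

        Each bin's count is laid out as evenly spaced read starts within the
        bin; fine structure below bin resolution is not recoverable.
        """
        grouped: Dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith(("track", "#")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}: line {lineno}: expected 4 fields")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                count = int(round(value))
                if count <= 0:
                    continue
                pos = np.linspace(start, max(start, end - 1), count).astype(np.int64)
                grouped.setdefault(chrom, []).extend(pos.tolist())
        return cls(grouped, genome, read_length=read_length)

    def count_in(self, chrom: str, start, end) -> np.ndarray:
        """Vectorised count of reads overlapping [start, end) intervals.

        A read at p overlaps iff p + read_length > start and p < end.
        """
        start = np.atleast_1d(np.asarray(start, dtype=np.int64))
        end = np.atleast_1d(np.asarray(end, dtype=np.int64))
        pos = self.positions.get(chrom)
        if pos is None:
            return np.zeros(start.shape, dtype=np.int64)
        lo = np.searchsorted(pos, start - self.read_length + 1, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return hi - lo

    def count_interval(self, interval: GenomicInterval) -> int:
        return int(self.count_in(interval.chrom, interval.start, interval.end)[0])


def compute_rpbm(track: ReadTrack, interval: GenomicInterval) -> float:
    """Read density in reads per base per million mapped reads."""
    if track.library_size <= 0:
        raise ValidationError("library_size must be positive")
    count = track.count_interval(interval)
    return count / interval.length / (track.library_size / 1e6)


def rpbm_vector(track: ReadTrack, intervals: IntervalSet) -> np.ndarray:
    """RPBM for every interval of a set (same formula as compute_rpbm)."""
    if track.library_size <= 0:
        raise ValidationError("library_size must be positive")
    out = np.zeros(len(intervals), dtype=float)
    scale = track.library_size / 1e6
    for i, iv in enumerate(intervals):
        out[i] = track.count_in(iv.chrom, iv.start, iv.end)[0] / iv.length / scale
    return out


@dataclass
class IslandCall:
    interval: GenomicInterval
    chip_count: int
    input_count: int
    score: float
    p_value: float
    q_value: float


@dataclass
class DifferentialIsland:
    interval: GenomicInterval
    density_a: float
    density_b: float
    log2_fold_change: float  # log2 of (A density / B density), pseudocounted
    p_value: float
    q_value: float
    call: str  # increased / decreased / unaltered, change of B relative to A


def _eligibility_threshold(lam: float, eligibility_p: float) -> int:
    """Smallest read count whose Poisson upper tail is <= eligibility_p."""
    k = int(stats.poisson.ppf(1.0 - eligibility_p, lam)) + 1
    while stats.poisson.sf(k - 1, lam) > eligibility_p:
        k += 1
    return k


def call_islands(
    chip: ReadTrack,
    input_track: ReadTrack,
    window_bp: int = 200,
    gap_bp: int = 400,
    fdr: float = 0.001,
    eligibility_p: float = 0.2,
) -> List[IslandCall]:
    """Identify read-enriched islands of the ChIP track relative to Input.

    Windows of ``window_bp`` are eligible when their ChIP count clears the
    Poisson upper-tail threshold at ``eligibility_p`` under the genome-wide
    background rate; eligible windows separated by <= ``gap_bp`` of
    ineligible windows merge into one island. Island significance is a
    Poisson test of the ChIP count against the library-scaled Input count
    (floored at the genome-wide background expectation), BH-corrected.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    if gap_bp < 0:
        raise ValidationError("gap_bp must be non-negative")
    if chip.genome != input_track.genome:
        raise ValidationError("chip and input tracks are on different genomes")
    genome = chip.genome
    if chip.n_reads == 0:
        return []

    lam = chip.n_reads * window_bp / genome.total_bp
    k_min = _eligibility_threshold(lam, eligibility_p)
    gap_windows = gap_bp // window_bp

    raw: List[Tuple[GenomicInterval, float]] = []
    for chrom in genome.chrom_names:
        clen = genome.length(chrom)
        n_windows = (clen + window_bp - 1) // window_bp
        pos = chip.positions.get(chrom)
        if pos is None:
            continue
        counts = np.bincount(pos // window_bp, minlength=n_windows)
        eligible = np.flatnonzero(counts >= k_min)
        if eligible.size == 0:
            continue
        # cluster eligible windows across gaps of <= gap_windows ineligible ones
        breaks = np.flatnonzero(np.diff(eligible) > gap_windows + 1)
        starts_idx = np.concatenate(([0], breaks + 1))
        ends_idx = np.concatenate((breaks, [eligible.size - 1]))
        window_p = stats.poisson.sf(counts - 1, lam)
        for si, ei in zip(starts_idx, ends_idx):
            w0, w1 = int(eligible[si]), int(eligible[ei])
            island = GenomicInterval(chrom, w0 * window_bp, min((w1 + 1) * window_bp, clen))
            members = eligible[si : ei + 1]
            score = float(np.sum(-np.log(np.clip(window_p[members], 1e-300, None))))
            raw.append((island, score))

    if not raw:
        return []

    p_values = np.empty(len(raw))
    chip_counts = np.empty(len(raw), dtype=np.int64)
    input_counts = np.empty(len(raw), dtype=np.int64)
    lib_ratio = chip.library_size / max(input_track.library_size, 1)
    for i, (island, _) in enumerate(raw):
        c = chip.count_interval(island)
        n = input_track.count_interval(island)
        expected = max(n * lib_ratio, lam * island.length / window_bp)
        p_values[i] = stats.poisson.sf(c - 1, expected)
        chip_counts[i] = c
        input_counts[i] = n
    q_values = bh_qvalues(p_values)

    calls = [
        IslandCall(island, int(c), int(n), score, float(p), float(q))
        for (island, score), c, n, p, q in zip(raw, chip_counts, input_counts, p_values, q_values)
        if q <= fdr
    ]
    calls.sort(key=lambda ic: (ic.interval.chrom, ic.interval.start))
    return calls


def _island_densities(
    islands: IntervalSet, track: ReadTrack, pseudocount_reads: float = 0.5
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-island (count, RPBM, pseudocount-in-RPBM-units) for a track."""
    counts = np.array([track.count_interval(iv) for iv in islands], dtype=np.int64)
    lengths = np.array([iv.length for iv in islands], dtype=float)
    scale = track.library_size / 1e6
    dens = counts / lengths / scale
    eps = pseudocount_reads / lengths / scale
    return counts, dens, eps


def differential_islands(
    islands: IntervalSet,
    track_a: ReadTrack,
    track_b: ReadTrack,
    fc_threshold: float = 1.5,
    fdr: float = 0.001,
    pseudocount_reads: float = 0.5,
) -> List[DifferentialIsland]:
    """Compare ChIP enrichment between two samples at fixed islands.

    Per island, a two-sided binomial test of count_A out of count_A+count_B
    against the library-size ratio, BH-corrected across islands. ``call`` is
    the direction of change in B relative to A: "decreased" when the A/B
    density fold-change exceeds ``fc_threshold`` at q <= ``fdr``.
    """
    if len(islands) == 0:
        raise ValidationError("differential_islands requires a non-empty island set")
    if track_a.n_reads == 0 and track_b.n_reads == 0:
        raise ValidationError("both tracks are empty")
    if fc_threshold < 1:
        raise ValidationError("fc_threshold must be >= 1")

    counts_a, dens_a, eps_a = _island_densities(islands, track_a, pseudocount_reads)
    counts_b, dens_b, eps_b = _island_densities(islands, track_b, pseudocount_reads)
    p_null = track_a.library_size / (track_a.library_size + track_b.library_size)
    p_values = binom_two_sided(counts_a, counts_a + counts_b, p_null)
    q_values = bh_qvalues(p_values)
    log2fc = np.log2((dens_a + eps_a) / (dens_b + eps_b))

    thr = math.log2(fc_threshold)
    out = []
    for iv, da, db, lfc, p, q in zip(islands, dens_a, dens_b, log2fc, p_values, q_values):
        if q <= fdr and lfc >= thr and fc_threshold > 1:
            call = "decreased"
        elif q <= fdr and lfc <= -thr and fc_threshold > 1:
            call = "increased"
        else:
            call = "unaltered"
        out.append(DifferentialIsland(iv, float(da), float(db), float(lfc), float(p), float(q), call))
    return out


def average_profile(
    track: ReadTrack, anchors: IntervalSet, flank_bp: int, n_bins: int
) -> np.ndarray:
    """Mean RPBM per bin across anchor midpoints +/- flank_bp.

    Anchors whose window would be truncated at a chromosome edge are
    dropped; an error is raised if none survive.
    """
    if len(anchors) == 0:
        raise ValidationError("average_profile requires a non-empty anchor set")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if flank_bp < 1:
        raise ValidationError("flank_bp must be >= 1")
    bin_width = 2.0 * flank_bp / n_bins
    scale = track.library_size / 1e6
    total = np.zeros(n_bins)
    n_used = 0
    for iv in anchors:
        mid = (iv.start + iv.end) // 2
        lo, hi = mid - flank_bp, mid + flank_bp
        if lo < 0 or hi > track.genome.length(iv.chrom):
            continue
        edges = lo + np.round(np.arange(n_bins + 1) * bin_width).astype(np.int64)
        counts = track.count_in(iv.chrom, edges[:-1], edges[1:])
        widths = (edges[1:] - edges[:-1]).astype(float)
        total += counts / widths / scale
        n_used += 1
    if n_used == 0:
        raise ValidationError("all anchors were dropped at chromosome edges")
    return total / n_used


@dataclass
class Ecdf:
    """Sorted sample values with cumulative fractions (a step ECDF)."""

    values: np.ndarray
    fractions: np.ndarray

    def __call__(self, x) -> np.ndarray:
        return np.searchsorted(self.values, x, side="right") / self.values.size


def fold_change_ecdf(
    islands: IntervalSet,
    track_a: ReadTrack,
    track_b: ReadTrack,
    pseudocount_reads: float = 0.5,
) -> Ecdf:
    """ECDF over islands of log2((density_B + eps) / (density_A + eps)).

    A curve shifted left of zero indicates a systematic density decrease in
    B relative to A across the island set.
    """
    if len(islands) == 0:
        raise ValidationError("fold_change_ecdf requires a non-empty island set")
    _, dens_a, eps_a = _island_densities(islands, track_a, pseudocount_reads)
    _, dens_b, eps_b = _island_densities(islands, track_b, pseudocount_reads)
    values = np.sort(np.log2((dens_b + eps_b) / (dens_a + eps_a)))
    fractions = np.arange(1, values.size + 1) / values.size
    return Ecdf(values, fractions)
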