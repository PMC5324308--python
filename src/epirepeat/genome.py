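"""Genomic coordinate primitives: genomes, intervals, BED I/O, overlap
statistics, and the matched random-region null sampler.

All coordinates are 0-based half-open (BED convention). Touching intervals
([0,10) and [10,20)) do not overlap. Strand is carried through I/O but
ignored by every overlap and coverage computation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

from .errors import ParseError, ValidationError


class Genome:
    """An ordered set of named chromosomes with lengths in bp."""

    def __init__(self, chrom_lengths: Mapping[str, int] | Iterable[Tuple[str, int]]):
        if not isinstance(chrom_lengths, Mapping):
            pairs = list(chrom_lengths)
            names = [name for name, _ in pairs]
            if len(set(names)) != len(names):
                raise ValidationError("duplicate chromosome names in genome")
            chrom_lengths = dict(pairs)
        self._lengths: Dict[str, int] = {}
        for name, length in chrom_lengths.items():
            length = int(length)
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")
            self._lengths[str(name)] = length

    @property
    def chrom_names(self) -> List[str]:
        return list(self._lengths)

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return dict(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"Genome({self._lengths!r})"

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated fields")
                try:
                    pairs.append((fields[0], int(fields[1])))
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: non-integer length {fields[1]!r}") from None
        return cls(pairs)

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A collection of genomic intervals, optionally bound to a genome.

    Binding to a genome validates that every interval lies within its
    chromosome. Computations that need per-chromosome sorted arrays build
    and cache them lazily.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), genome: Optional[Genome] = None):
        self.intervals: List[GenomicInterval] = list(intervals)
        self.genome = genome
        if genome is not None:
            for iv in self.intervals:
                if iv.chrom not in genome:
                    raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > genome.length(iv.chrom):
                    raise ValidationError(
                        f"interval {iv.chrom}:[{iv.start},{iv.end}) exceeds "
                        f"chromosome length {genome.length(iv.chrom)}"
                    )
        self._by_chrom_cache: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def sorted(self) -> "IntervalSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(ivs, genome=self.genome)

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays sorted by start."""
        if self._by_chrom_cache is None:
            grouped: Dict[str, List[Tuple[int, int]]] = {}
            for iv in self.intervals:
                grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
            cache = {}
            for chrom, pairs in grouped.items():
                pairs.sort()
                arr = np.array(pairs, dtype=np.int64).reshape(-1, 2)
                cache[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
            self._by_chrom_cache = cache
        return self._by_chrom_cache

    def merged(self) -> "IntervalSet":
        """Union of the set: pairwise non-overlapping, sorted intervals.

        Touching intervals are not merged (half-open semantics: [0,10) and
        [10,20) are disjoint).
        """
        out = []
        for chrom in sorted(self.by_chrom()):
            starts, ends = self.by_chrom()[chrom]
            cur_s, cur_e = None, None
            for s, e in zip(starts, ends):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s < cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
        return IntervalSet(out, genome=self.genome)

    @property
    def total_bp(self) -> int:
        """Number of distinct bases covered (union semantics)."""
        return sum(iv.length for iv in self.merged())


def read_bed(path, genome: Optional[Genome] = None) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet (0-based half-open, as BED is)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return IntervalSet(intervals, genome=genome)


def write_bed(intervals: IntervalSet, path, columns: Optional[int] = None) -> None:
    """Write BED3 or BED6; BED6 whenever any interval carries annotation."""
    if columns is None:
        annotated = any(
            iv.name != "." or iv.score != 0.0 or iv.strand != "." for iv in intervals
        )
        columns = 6 if annotated else 3
    with open(path, "w") as fh:
        for iv in intervals:
            if columns == 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
                )


def _covered_bases(start: int, end: int, mstarts: np.ndarray, mends: np.ndarray) -> int:
    """Bases of [start, end) covered by merged (disjoint, sorted) intervals."""
    if mstarts.size == 0:
        return 0
    i = int(np.searchsorted(mends, start, side="right"))
    j = int(np.searchsorted(mstarts, end, side="left"))
    if j <= i:
        return 0
    s = np.maximum(mstarts[i:j], start)
    e = np.minimum(mends[i:j], end)
    return int(np.sum(e - s))


def overlap_fraction(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query fraction of bases covered by the union of the subject set.

    Overlapping subject intervals are merged first, so covered bases are
    never double-counted; the result is invariant under merging the subject.
    """
    if query.genome is not None and subject.genome is not None and query.genome != subject.genome:
        raise ValidationError("query and subject are bound to different genomes")
    merged = subject.merged().by_chrom()
    out = np.zeros(len(query), dtype=float)
    for idx, iv in enumerate(query):
        if iv.chrom not in merged:
            continue
        mstarts, mends = merged[iv.chrom]
        out[idx] = _covered_bases(iv.start, iv.end, mstarts, mends) / iv.length
    return out


def island_overlap_percent(
    set_a: IntervalSet, set_b: IntervalSet, min_overlap_bp: int = 1
) -> float:
    """Percentage of A intervals that overlap >= min_overlap_bp bases of
    any single B interval."""
    if len(set_a) == 0:
        raise ValidationError("island_overlap_percent undefined for an empty query set")
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    if len(set_b) == 0:
        return 0.0
    b_by_chrom = set_b.by_chrom()
    hits = 0
    for iv in set_a:
        if iv.chrom not in b_by_chrom:
            continue
        bstarts, bends = b_by_chrom[iv.chrom]
        j = int(np.searchsorted(bstarts, iv.end, side="left"))
        if j == 0:
            continue
        ov = np.minimum(bends[:j], iv.end) - np.maximum(bstarts[:j], iv.start)
        if ov.size and int(ov.max()) >= min_overlap_bp:
            hits += 1
    return 100.0 * hits / len(set_a)


def sample_random_regions(
    template: IntervalSet, genome: Genome, n_draws_per_region: int, seed: int
) -> IntervalSet:
    """Matched random-region null: for each template interval, draw
    n_draws_per_region intervals of identical length, uniformly placed on
    the same chromosome.

    This is the "random genomic sequences of comparable size and frequency"
    null: equal count, identical lengths, same chromosome, uniform start.
    Sampled regions may overlap each other.
    """
    if n_draws_per_region < 1:
        raise ValidationError("n_draws_per_region must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for idx, iv in enumerate(template):
        clen = genome.length(iv.chrom)
        if iv.length > clen:
            raise ValidationError(
                f"template interval of length {iv.length} exceeds chromosome "
                f"{iv.chrom} ({clen} bp)"
            )
        starts = rng.integers(0, clen - iv.length + 1, size=n_draws_per_region)
        for k, s in enumerate(starts):
            out.append(
                GenomicInterval(iv.chrom, int(s), int(s) + iv.length, name=f"rand_{idx}_{k}")
            )
    return IntervalSet(out, genome=genome)
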