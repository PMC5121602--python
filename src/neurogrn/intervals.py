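"""Genomic interval data model, interval algebra, and BED/chrom-sizes I/O.

All coordinates are 0-based half-open (BED convention). An interval
``chrom:[start, end)`` covers bases ``start .. end-1``; two intervals share a
base iff ``a.start < b.end and b.start < a.end``. Sorting is lexicographic by
chromosome name, then start, then end, with stable ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = [
    "BedDialect",
    "BedParseError",
    "ValidationError",
    "GenomicInterval",
    "IntervalSet",
    "ChromSizes",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "intersect",
    "subtract",
    "merge_union",
    "midpoint",
    "covered_bp",
]

BED_DIALECTS = ("bed3", "bed6", "bed6+1", "bed12")
BedDialect = str

_MIN_COLUMNS = {"bed3": 3, "bed6": 6, "bed6+1": 7, "bed12": 12}


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """An interval violates its invariants (coordinates or chromosome bounds)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional score and BED12 block structure.

    ``score`` carries the seventh BED column (per-replicate FDR for scored peak
    files) when present. ``thick_start``/``thick_end`` and the block fields are
    only populated for BED12 records and feed gene-model construction.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."
    thick_start: int | None = None
    thick_end: int | None = None
    block_sizes: tuple[int, ...] | None = None
    block_starts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def midpoint(iv: GenomicInterval) -> int:
    """Midpoint anchor, ``floor((start + end) / 2)``."""
    return (iv.start + iv.end) // 2


@dataclass
class ChromSizes:
    """Chromosome name -> length (bp) table governing interval bounds."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")

    @property
    def genome_length(self) -> int:
        return sum(self.sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.sizes:
            raise ValidationError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.sizes[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.sizes[iv.chrom]}"
            )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    ``normalize()`` sorts by (chrom, start, end) and optionally validates
    against a :class:`ChromSizes` table; the algebra functions require
    normalized inputs only for their documented sort-order guarantees — they
    normalize defensively.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, sorted_flag: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sorted_flag = sorted_flag

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self.intervals)})"

    def normalize(self, chrom_sizes: ChromSizes | None = None) -> "IntervalSet":
        if chrom_sizes is not None:
            for iv in self.intervals:
                chrom_sizes.validate(iv)
        self.intervals.sort(key=GenomicInterval.sort_key)
        self.sorted_flag = True
        return self

    def copy(self) -> "IntervalSet":
        return IntervalSet(self.intervals, sorted_flag=self.sorted_flag)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for chrom, ivs in self.by_chrom().items():
            trees[chrom] = IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
        return trees


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def intersect(a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    """Intervals of ``a`` overlapping some single interval of ``b`` by >= ``min_overlap_bp``.

    Output is a subset of ``a`` (original coordinates, untrimmed); the
    operation is idempotent: ``intersect(intersect(a, b), b) == intersect(a, b)``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = b.trees()
    hits = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for q in tree.overlap(iv.start, iv.end):
            if min(iv.end, q.end) - max(iv.start, q.begin) >= min_overlap_bp:
                hits.append(iv)
                break
    return IntervalSet(hits).normalize()


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Whole-interval subtraction: drop every interval of ``a`` sharing >= 1 bp
    with any interval of ``b``; surviving intervals are never trimmed."""
    trees = b.trees()
    kept = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            continue
        kept.append(iv)
    return IntervalSet(kept).normalize()


def merge_union(a: IntervalSet) -> IntervalSet:
    """Fuse overlapping or bookended intervals into maximal intervals.

    Scores and names are dropped (merged regions are new entities); covered
    base pairs are preserved.
    """
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(a.by_chrom().items()):
        ivs = sorted(ivs, key=GenomicInterval.sort_key)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged, sorted_flag=True)


def covered_bp(a: IntervalSet) -> int:
    """Total bases covered by the set (union coverage)."""
    return sum(len(iv) for iv in merge_union(a))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_score(tok: str, lineno: int) -> float | None:
    if tok in (".", ""):
        return None
    try:
        return float(tok)
    except ValueError:
        raise BedParseError(f"line {lineno}: unparsable score {tok!r}") from None


def read_bed(path: str | Path, dialect: BedDialect = "bed6+1") -> IntervalSet:
    """Read a BED file of the given dialect into an :class:`IntervalSet`.

    For ``bed6+1`` the seventh column is stored as ``score`` (interpreted
    downstream as a per-peak FDR); for ``bed6`` the fifth column is the score.
    ``bed12`` rows retain thick coordinates and block structure.
    """
    if dialect not in _MIN_COLUMNS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    ncol = _MIN_COLUMNS[dialect]
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tok = line.split("\t")
            if len(tok) < ncol:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= {ncol} columns for "
                    f"{dialect}, got {len(tok)}"
                )
            try:
                start, end = int(tok[1]), int(tok[2])
            except ValueError:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            kwargs: dict = {}
            if dialect != "bed3":
                kwargs["name"] = tok[3]
                kwargs["score"] = _parse_score(tok[4], lineno)
                kwargs["strand"] = tok[5]
            if dialect == "bed6+1":
                kwargs["score"] = _parse_score(tok[6], lineno)
            if dialect == "bed12":
                n_blocks = int(tok[9])
                kwargs["thick_start"] = int(tok[6])
                kwargs["thick_end"] = int(tok[7])
                kwargs["block_sizes"] = tuple(
                    int(x) for x in tok[10].rstrip(",").split(",")
                )
                kwargs["block_starts"] = tuple(
                    int(x) for x in tok[11].rstrip(",").split(",")
                )
                if len(kwargs["block_sizes"]) != n_blocks:
                    raise BedParseError(
                        f"{path}: line {lineno}: blockCount {n_blocks} does not "
                        f"match blockSizes"
                    )
            try:
                out.append(GenomicInterval(tok[0], start, end, **kwargs))
            except ValidationError as e:
                raise ValidationError(f"{path}: line {lineno}: {e}") from None
    return IntervalSet(out)


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    return format(score, "g")


def write_bed(ivs: IntervalSet, path: str | Path, dialect: BedDialect = "bed6+1") -> None:
    """Write intervals in the given BED dialect (tab-separated, no header)."""
    if dialect not in _MIN_COLUMNS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect != "bed3":
                cols += [iv.name, "0" if dialect == "bed6+1" else _fmt_score(iv.score), iv.strand]
            if dialect == "bed6+1":
                cols.append(_fmt_score(iv.score))
            if dialect == "bed12":
                bs = iv.block_sizes or (len(iv),)
                bo = iv.block_starts or (0,)
                cols += [
                    str(iv.thick_start if iv.thick_start is not None else iv.start),
                    str(iv.thick_end if iv.thick_end is not None else iv.end),
                    "0",
                    str(len(bs)),
                    ",".join(map(str, bs)) + ",",
                    ",".join(map(str, bo)) + ",",
                ]
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tok = line.split("\t")
            if len(tok) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected 2 columns")
            sizes[tok[0]] = int(tok[1])
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.sizes.items():
            fh.write(f"{name}\t{length}\n")
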