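"""Genome coordinate system: chromosome sizes, fixed-width bins, regions, BED I/O.

All coordinates are 0-based half-open internally (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

#: chromosomes removed from every bin universe unless overridden
DEFAULT_EXCLUDE = ("chrX", "chrY", "chrM")


class ParseError(ValueError):
    """Raised on malformed genomic text input; message names the offending line."""


class ChromSizes:
    """Ordered map of chromosome name -> length (bp).

    Insertion order is preserved and defines the global chromosome ordering
    used by binning and contact-pair canonicalization.
    """

    def __init__(self, items: Iterable[tuple[str, int]]):
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if not name:
                raise ValueError("empty chromosome name")
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"non-positive length for {name!r}: {length}")
            self._sizes[name] = length
        self._order = {c: i for i, c in enumerate(self._sizes)}

    def __len__(self) -> int:
        return len(self._sizes)

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    def items(self):
        return self._sizes.items()

    def order(self, name: str) -> int:
        """Rank of a chromosome in the global ordering."""
        return self._order[name]

    def total_length(self, exclude: Sequence[str] = ()) -> int:
        ex = set(exclude)
        return sum(L for c, L in self._sizes.items() if c not in ex)


def load_chrom_sizes(path) -> ChromSizes:
    """Read a 2-column UCSC-style chrom.sizes TSV.

    Lines beginning with '#' are ignored.  Duplicates, non-positive lengths
    and malformed lines raise :class:`ParseError` naming the line number.
    """
    items: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            if length < 1:
                raise ParseError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            items.append((name, length))
    return ChromSizes(items)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class Region:
    """Half-open 0-based genomic interval, optionally named/scored/directed.

    ``direction`` is +1 for increased, -1 for decreased signal.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    direction: int | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """A labelled list of regions (e.g. one differential-mark BED track)."""

    regions: list[Region] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def chroms(self) -> set[str]:
        return {r.chrom for r in self.regions}


class GenomeBins:
    """Fixed-width tiling of the retained genome.

    Bins are half-open intervals ``[k*w, min((k+1)*w, L))`` per chromosome;
    the global index is dense ``0..B-1`` in chromosome-then-position order.
    """

    def __init__(self, sizes: ChromSizes, bin_width: int, exclude: Sequence[str] = DEFAULT_EXCLUDE):
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        self.sizes = sizes
        self.bin_width = int(bin_width)
        self.excluded = tuple(c for c in exclude if c in sizes)
        ex = set(exclude)
        self.chroms = [c for c in sizes if c not in ex]
        if not self.chroms:
            raise ValueError("no chromosomes retained after exclusion")
        self._n_bins = {c: -(-sizes[c] // bin_width) for c in self.chroms}
        self._offset: dict[str, int] = {}
        off = 0
        for c in self.chroms:
            self._offset[c] = off
            off += self._n_bins[c]
        self.n_bins = off

    def __len__(self) -> int:
        return self.n_bins

    def n_bins_of(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def offset_of(self, chrom: str) -> int:
        return self._offset[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing 0-based position ``pos``."""
        if chrom not in self._offset:
            raise KeyError(chrom)
        if pos < 0 or pos >= self.sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offset[chrom] + pos // self.bin_width

    def bin_record(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global bin index."""
        if index < 0 or index >= self.n_bins:
            raise IndexError(index)
        for c in self.chroms:
            n = self._n_bins[c]
            if index < self._offset[c] + n:
                k = index - self._offset[c]
                start = k * self.bin_width
                return c, start, min(start + self.bin_width, self.sizes[c])
        raise IndexError(index)  # pragma: no cover

    def chrom_of(self, index: int) -> str:
        return self.bin_record(index)[0]

    def records(self) -> Iterator[tuple[str, int, int, int]]:
        """Yield (chrom, start, end, global_index) over all bins."""
        i = 0
        for c in self.chroms:
            L = self.sizes[c]
            for k in range(self._n_bins[c]):
                yield c, k * self.bin_width, min((k + 1) * self.bin_width, L), i
                i += 1

    def chrom_of_array(self, indices: np.ndarray) -> np.ndarray:
        """Vectorized chromosome lookup: maps global bin indices to chrom rank."""
        bounds = np.array([self._offset[c] for c in self.chroms] + [self.n_bins])
        return np.searchsorted(bounds, np.asarray(indices), side="right") - 1


def make_bins(sizes: ChromSizes, bin_width: int, exclude: Sequence[str] = DEFAULT_EXCLUDE) -> GenomeBins:
    """Tile the retained genome at ``bin_width``; excluded chromosomes get no bins."""
    return GenomeBins(sizes, bin_width, exclude)


AssignMode = Literal["any_overlap", "midpoint"]


def assign_regions_to_bins(
    regions: RegionSet,
    bins: GenomeBins,
    mode: AssignMode = "any_overlap",
) -> tuple[dict[int, list[int]], dict]:
    """Map each region to the global bin indices it occupies.

    ``any_overlap`` returns every intersected bin; ``midpoint`` the single bin
    containing ``floor((start+end)/2)``.  Regions on unknown or excluded
    chromosomes are skipped with a warning and tallied in the report.

    Returns (mapping region-position -> bin indices, report dict).
    """
    if mode not in ("any_overlap", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    mapping: dict[int, list[int]] = {}
    skipped = 0
    w = bins.bin_width
    for idx, r in enumerate(regions):
        if r.chrom not in bins._offset:
            skipped += 1
            continue
        L = bins.sizes[r.chrom]
        off = bins.offset_of(r.chrom)
        if mode == "midpoint":
            mid = min(r.midpoint, L - 1)
            mapping[idx] = [off + mid // w]
        else:
            first = r.start // w
            last = min(r.end - 1, L - 1) // w
            mapping[idx] = [off + k for k in range(first, last + 1)]
    if skipped:
        warnings.warn(f"{skipped} region(s) on excluded/unknown chromosomes skipped")
    report = {"n_regions": len(regions), "n_assigned": len(mapping), "n_skipped": skipped}
    return mapping, report


def region_bins(regions: RegionSet, bins: GenomeBins, mode: AssignMode = "any_overlap") -> set[int]:
    """Deduplicated set of bin indices occupied by a region set."""
    mapping, _ = assign_regions_to_bins(regions, bins, mode)
    return {b for bs in mapping.values() for b in bs}


def read_bed(path, label: str | None = None) -> RegionSet:
    """Read BED3/BED6 (0-based half-open); '#' comment lines tolerated.

    The name field is kept; strand is parsed but ignored downstream.  A name
    suffix of ``:up``/``:down`` (as written by :func:`write_bed`) is decoded
    into the region direction.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            direction = None
            if name and name.endswith((":up", ":down")):
                base, _, tag = name.rpartition(":")
                direction = 1 if tag == "up" else -1
                name = base or None
            regions.append(Region(fields[0], start, end, name=name, score=score, direction=direction))
    return RegionSet(regions, label=label if label is not None else str(path))


def write_bed(regions: RegionSet, path) -> None:
    """Write BED; direction (if set) is encoded as a ``:up``/``:down`` name suffix."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.name if r.name is not None else f"region{i}"
            if r.direction is not None:
                name = f"{name}:{'up' if r.direction > 0 else 'down'}"
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")
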