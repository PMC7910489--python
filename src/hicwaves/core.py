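"""Core genomic containers shared by every pipeline stage.

Hi-C observations are summarised as counts of read pairs whose two ends fall
into a pair of fixed-width genomic bins.  This module provides the bin /
bin-pair containers, plain-text (BEDPE, BED, TSV) input and output, blacklist
filtering and the count-per-million utilities used throughout the package.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBin",
    "Binning",
    "make_bins",
    "LibraryInfo",
    "RegionSet",
    "BinPairCountTable",
    "read_bedpe_counts",
    "write_bedpe_counts",
    "filter_regions",
    "log_cpm",
    "ave_log_cpm",
]


class GenomicBin(NamedTuple):
    """One fixed-width genomic bin; ``index`` is its genome-wide rank."""

    chrom: str
    start: int
    end: int
    index: int


class Binning:
    """A genome-wide tiling of chromosomes into fixed-width bins.

    The last bin of a chromosome may be shorter when the chromosome length is
    not a multiple of the bin width; partial bins are kept so that the tiling
    is gap-free and deterministic.
    """

    def __init__(self, chrom_sizes: Mapping[str, int], bin_width: int):
        if not chrom_sizes:
            raise ValueError("chrom_sizes is empty: at least one chromosome is required")
        if bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {bin_width}")
        for chrom, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")
        self.chrom_sizes = dict(chrom_sizes)
        self.bin_width = int(bin_width)
        self.chroms = list(self.chrom_sizes)

        starts, ends, chrom_ids = [], [], []
        self._offset = {}  # chrom -> index of its first bin
        for ci, chrom in enumerate(self.chroms):
            size = self.chrom_sizes[chrom]
            self._offset[chrom] = len(starts)
            s = np.arange(0, size, self.bin_width, dtype=np.int64)
            e = np.minimum(s + self.bin_width, size)
            starts.extend(s.tolist())
            ends.extend(e.tolist())
            chrom_ids.extend([ci] * len(s))
        self.start = np.asarray(starts, dtype=np.int64)
        self.end = np.asarray(ends, dtype=np.int64)
        self.chrom_id = np.asarray(chrom_ids, dtype=np.int64)
        self.n_bins = len(self.start)

    @property
    def mid(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def chrom_of(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(self.chroms, dtype=object)[self.chrom_id[index]]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Genome-wide index of the bin containing position ``pos``."""
        size = self.chrom_sizes[chrom]
        if not 0 <= pos < size:
            raise ValueError(f"position {pos} outside {chrom} (size {size})")
        return self._offset[chrom] + int(pos) // self.bin_width

    def bins(self) -> list[GenomicBin]:
        chroms = self.chrom_of(np.arange(self.n_bins))
        return [
            GenomicBin(chroms[i], int(self.start[i]), int(self.end[i]), i)
            for i in range(self.n_bins)
        ]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Binning)
            and self.chrom_sizes == other.chrom_sizes
            and self.bin_width == other.bin_width
        )


def make_bins(chrom_sizes: Mapping[str, int], bin_width: int) -> list[GenomicBin]:
    """Tile each chromosome into ``bin_width`` bins with consecutive indices."""
    return Binning(chrom_sizes, bin_width).bins()


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library: condition group, replicate and total depth."""

    name: str
    group: str
    replicate: int
    lib_size: int

    def __post_init__(self):
        if self.lib_size <= 0:
            raise ValueError(f"library {self.name!r} has non-positive lib_size")


class RegionSet:
    """A queryable set of genomic intervals (blacklists, peaks, promoters).

    Intervals are merged per chromosome so overlap queries are two binary
    searches per query interval.
    """

    def __init__(self, regions: Iterable[tuple] = ()):
        self.regions = [
            (str(r[0]), int(r[1]), int(r[2]), (r[3] if len(r) > 3 else ""))
            for r in regions
        ]
        for chrom, start, end, _ in self.regions:
            if start >= end:
                raise ValueError(f"invalid region {chrom}:{start}-{end} (start >= end)")
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.regions:
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._merged[chrom] = (arr[:, 0], arr[:, 1])

    def __len__(self) -> int:
        return len(self.regions)

    def overlaps(self, chroms: Sequence[str], starts, ends) -> np.ndarray:
        """Boolean array: does each query interval overlap any region?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(starts), dtype=bool)
        chroms = np.asarray(chroms, dtype=object)
        for chrom in np.unique(chroms):
            if chrom not in self._merged:
                continue
            ms, me = self._merged[chrom]
            sel = chroms == chrom
            # overlap iff some merged interval has start < query_end and end > query_start
            idx = np.searchsorted(ms, ends[sel], side="left") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = me[idx[ok]] > starts[sel][ok]
            out[sel] = hit
        return out

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", compression="infer",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
        )
        return cls(df.itertuples(index=False, name=None))

    def to_bed(self, path) -> None:
        with _open_write(path) as fh:
            for chrom, start, end, name in sorted(self.regions):
                tail = f"\t{name}" if name else ""
                fh.write(f"{chrom}\t{start}\t{end}{tail}\n")


def _open_write(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


@dataclass
class BinPairCountTable:
    """Counts of Hi-C read pairs per bin pair per library.

    Pairs are stored upper-triangle canonical: ``anchor1`` index >= ``anchor2``
    index, no duplicate keys.  ``counts`` has one column per library, ordered
    as ``libraries``.
    """

    binning: Binning
    anchor1: np.ndarray  # genome-wide bin indices
    anchor2: np.ndarray
    counts: np.ndarray  # (n_pairs, n_libraries), non-negative integers
    libraries: list[LibraryInfo] = field(default_factory=list)

    def __post_init__(self):
        self.anchor1 = np.asarray(self.anchor1, dtype=np.int64)
        self.anchor2 = np.asarray(self.anchor2, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.anchor1):
            raise ValueError("counts must be (n_pairs, n_libraries)")
        if len(self.libraries) != self.counts.shape[1]:
            raise ValueError("one counts column per library is required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self._canonicalize()

    def _canonicalize(self):
        swap = self.anchor1 < self.anchor2
        if np.any(swap):
            a1 = self.anchor1.copy()
            self.anchor1[swap] = self.anchor2[swap]
            self.anchor2[swap] = a1[swap]
        order = np.lexsort((self.anchor2, self.anchor1))
        self.anchor1 = self.anchor1[order]
        self.anchor2 = self.anchor2[order]
        self.counts = self.counts[order]
        key = self.anchor1 * self.binning.n_bins + self.anchor2
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate bin-pair keys after canonicalization")

    def __len__(self) -> int:
        return len(self.anchor1)

    @property
    def n_libraries(self) -> int:
        return len(self.libraries)

    @property
    def lib_sizes(self) -> np.ndarray:
        return np.asarray([lib.lib_size for lib in self.libraries], dtype=float)

    @property
    def is_intra(self) -> np.ndarray:
        b = self.binning
        return b.chrom_id[self.anchor1] == b.chrom_id[self.anchor2]

    @property
    def spans(self) -> np.ndarray:
        """Midpoint distance in bp; NaN for inter-chromosomal pairs."""
        mid = self.binning.mid
        out = np.abs(mid[self.anchor1] - mid[self.anchor2]).astype(float)
        out[~self.is_intra] = np.nan
        return out

    def subset(self, mask) -> "BinPairCountTable":
        return BinPairCountTable(
            self.binning, self.anchor1[mask].copy(), self.anchor2[mask].copy(),
            self.counts[mask].copy(), list(self.libraries),
        )

    def with_counts(self, counts) -> "BinPairCountTable":
        return BinPairCountTable(
            self.binning, self.anchor1.copy(), self.anchor2.copy(),
            np.asarray(counts), list(self.libraries),
        )

    def to_frame(self) -> pd.DataFrame:
        b = self.binning
        df = pd.DataFrame(
            {
                "chrom1": b.chrom_of(self.anchor1),
                "start1": b.start[self.anchor1],
                "end1": b.end[self.anchor1],
                "chrom2": b.chrom_of(self.anchor2),
                "start2": b.start[self.anchor2],
                "end2": b.end[self.anchor2],
            }
        )
        for j, lib in enumerate(self.libraries):
            df[lib.name] = self.counts[:, j]
        return df


def write_bedpe_counts(table: BinPairCountTable, path) -> None:
    """Write a bin-pair count table as BEDPE with one count column per library."""
    df = table.to_frame()
    with _open_write(path) as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bedpe_counts(path, binning: Binning, libraries: Sequence[LibraryInfo]) -> BinPairCountTable:
    """Read BEDPE bin-pair counts; anchors are canonicalized on ingest.

    Coordinates must lie exactly on the boundaries of ``binning``; counts must
    be non-negative integers.  Errors report the offending 1-based data line.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, compression="infer")
    if df.shape[1] != 6 + len(libraries):
        raise ValueError(
            f"expected {6 + len(libraries)} columns "
            f"(6 BEDPE + {len(libraries)} count columns), found {df.shape[1]}"
        )
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    df.columns = cols + [lib.name for lib in libraries]

    counts = np.empty((len(df), len(libraries)), dtype=np.int64)
    for j, lib in enumerate(libraries):
        vals = pd.to_numeric(df[lib.name], errors="coerce").to_numpy()
        bad = ~np.isfinite(vals) | (vals % 1 != 0) | (vals < 0)
        if np.any(bad):
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"{path}: line {line}: count for library {lib.name!r} "
                f"is not a non-negative integer"
            )
        counts[:, j] = vals.astype(np.int64)

    anchors = np.empty((len(df), 2), dtype=np.int64)
    for k, side in enumerate(("1", "2")):
        for row, (chrom, start, end) in enumerate(
            zip(df[f"chrom{side}"], df[f"start{side}"], df[f"end{side}"])
        ):
            try:
                idx = binning.bin_index(str(chrom), int(start))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: line {row + 1}: {exc}") from None
            if binning.start[idx] != start or binning.end[idx] != end:
                raise ValueError(
                    f"{path}: line {row + 1}: interval {chrom}:{start}-{end} "
                    f"is not on a bin boundary of the declared {binning.bin_width} bp binning"
                )
            anchors[row, k] = idx
    return BinPairCountTable(binning, anchors[:, 0], anchors[:, 1], counts, list(libraries))


def filter_regions(table: BinPairCountTable, exclude: RegionSet) -> BinPairCountTable:
    """Drop every pair with either anchor overlapping an excluded region."""
    if len(exclude) == 0:
        return table
    b = table.binning
    bad = np.zeros(len(table), dtype=bool)
    for anchor in (table.anchor1, table.anchor2):
        bad |= exclude.overlaps(b.chrom_of(anchor), b.start[anchor], b.end[anchor])
    return table.subset(~bad)


def log_cpm(counts, lib_sizes, prior: float = 0.5) -> np.ndarray:
    """log2 counts-per-million with a library-size-scaled prior count.

    Follows the aveLogCPM convention: the prior added to each library's count
    is scaled by its library size relative to the mean, and twice the prior is
    added to the library size, so that doubling all counts and library sizes
    leaves the result unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    if prior < 0:
        raise ValueError("prior count must be non-negative")
    scaled = prior * lib_sizes / lib_sizes.mean()
    return np.log2((counts + scaled) / (lib_sizes + 2 * scaled) * 1e6)


def ave_log_cpm(counts, lib_sizes, prior: float = 0.5) -> np.ndarray:
    """Per-feature average abundance: log2 of the mean prior-augmented CPM."""
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    scaled = prior * lib_sizes / lib_sizes.mean()
    cpm = (counts + scaled) / (lib_sizes + 2 * scaled) * 1e6
    return np.log2(cpm.mean(axis=-1))
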