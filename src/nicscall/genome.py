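"""Genomic coordinate frame shared by the whole pipeline.

Copy-number analysis of low-coverage embryo sequencing works on fixed-width
genomic bins (1 Mb by default): reads are counted per bin, normalized, and
segmented.  This module provides the bin grid (an hg19-like chromosome set
with per-bin GC fraction and a usability mask), read-count containers, and
their plain-text I/O.

Coordinates are 0-based half-open throughout (BED dialect on disk).
Chromosome order is fixed as 1..22, X, Y.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIN_SIZE = 1_000_000

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES = CHROMOSOMES[:22]
#: chromosomes entering concordance analyses (22 autosomes + X; Y is report-only)
CONCORDANCE_CHROMS = CHROMOSOMES[:23]
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

ASSAYS = ("whole", "TE", "medium", "blank")


def chrom_sort_key(chrom: str) -> int:
    """Rank of a chromosome label in the fixed 1..22, X, Y order."""
    try:
        return _CHROM_RANK[str(chrom)]
    except KeyError:
        raise ValueError(f"unknown chromosome label: {chrom!r}") from None


def load_hg19_lengths() -> dict[str, int]:
    """Packaged hg19 chromosome lengths (bp), so no download is ever needed."""
    ref = importlib.resources.files("nicscall.data") / "hg19_chrom_lengths.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": np.int64})
    return dict(zip(df["chrom"], df["length"]))


@dataclass
class BinGrid:
    """Ordered 1 Mb bins covering a chromosome set.

    Attributes
    ----------
    chrom, start, end : arrays, one entry per bin (half-open intervals).
    gc : GC fraction per bin in [0, 1].
    mask : True where the bin is usable for analysis.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    mask: np.ndarray
    bin_size: int = BIN_SIZE

    def __post_init__(self):
        n = len(self.chrom)
        for name in ("start", "end", "gc", "mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"grid field {name} has wrong length")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc fractions must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def lengths_bp(self) -> np.ndarray:
        return self.end - self.start

    @property
    def is_autosome(self) -> np.ndarray:
        return np.isin(self.chrom, AUTOSOMES)

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Positional indices of the bins of one chromosome."""
        return np.flatnonzero(self.chrom == str(chrom))

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_length(self, chrom: str) -> int:
        idx = self.chrom_index(chrom)
        return int(self.end[idx[-1]])

    def with_gc(self, gc: np.ndarray) -> "BinGrid":
        return replace(self, gc=np.asarray(gc, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "gc": self.gc,
                "mask": self.mask.astype(int),
            }
        )

    def matches(self, chrom, start, end) -> bool:
        return (
            len(chrom) == self.n_bins
            and np.array_equal(np.asarray(chrom, dtype=object), self.chrom)
            and np.array_equal(np.asarray(start), self.start)
            and np.array_equal(np.asarray(end), self.end)
        )


def synthetic_gc(chrom: np.ndarray, start: np.ndarray, bin_size: int = BIN_SIZE) -> np.ndarray:
    """Deterministic smooth pseudo-GC track centred near 0.42.

    A low-frequency sinusoid per chromosome plus reproducible small-scale
    structure (fixed internal seed, so the same grid always gets the same
    track — grids must be bit-stable).
    """
    n = len(chrom)
    gc = np.empty(n)
    rng = np.random.default_rng(19_820_417)  # fixed: grid determinism
    pos = np.asarray(start, dtype=float) / bin_size
    ranks = np.array([chrom_sort_key(c) for c in chrom], dtype=float)
    wave = 0.05 * np.sin(2 * np.pi * pos / 80.0 + ranks) + 0.02 * np.sin(
        2 * np.pi * pos / 11.0 + 2.0 * ranks
    )
    rough = rng.normal(0.0, 0.008, size=n)
    gc = 0.42 + wave + rough
    return np.clip(gc, 0.30, 0.60)


def build_bin_grid(
    genome_spec: dict[str, int] | None = None,
    bin_size: int = BIN_SIZE,
    gc: np.ndarray | None = None,
) -> BinGrid:
    """Tile each chromosome with half-open ``bin_size`` bins.

    Every bin is ``bin_size`` bp except the last of each chromosome, which
    keeps the remainder.  ``genome_spec`` maps chromosome label -> length in
    bp; defaults to the packaged hg19 table.  GC comes from ``gc`` if given,
    otherwise from the deterministic synthetic track.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if genome_spec is None:
        genome_spec = load_hg19_lengths()
    for c, length in genome_spec.items():
        if str(c) not in _CHROM_RANK:
            raise ValueError(f"unknown chromosome label: {c!r}")
        if length <= 0:
            raise ValueError(f"chromosome {c} has non-positive length {length}")

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for c in sorted(genome_spec, key=chrom_sort_key):
        length = int(genome_spec[c])
        edges = list(range(0, length, bin_size)) + [length]
        for lo, hi in zip(edges[:-1], edges[1:]):
            chroms.append(str(c))
            starts.append(lo)
            ends.append(hi)

    chrom_arr = np.array(chroms, dtype=object)
    start_arr = np.array(starts, dtype=np.int64)
    end_arr = np.array(ends, dtype=np.int64)
    if gc is None:
        gc = synthetic_gc(chrom_arr, start_arr, bin_size)
    mask = np.ones(len(chrom_arr), dtype=bool)
    return BinGrid(chrom_arr, start_arr, end_arr, np.asarray(gc, dtype=float), mask, bin_size)


@dataclass
class CountTable:
    """Per-bin raw read counts for one sample of one embryo."""

    grid: BinGrid
    counts: np.ndarray
    sample_id: str = ""
    assay: str = "whole"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.grid.n_bins:
            raise ValueError("counts length does not match grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay label: {self.assay!r}")
        self.counts = self.counts.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.grid.chrom,
                "start": self.grid.start,
                "end": self.grid.end,
                "count": self.counts,
            }
        )


def write_count_table(table: CountTable, path) -> None:
    """TSV with header lines recording sample identity (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={table.sample_id}\n")
        fh.write(f"# assay={table.assay}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)


def read_count_table(path, grid: BinGrid) -> CountTable:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"count table missing column(s): {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValueError("negative count in table")
    if not grid.matches(df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()):
        raise ValueError("count table bins do not match the grid")
    return CountTable(
        grid,
        df["count"].to_numpy(),
        sample_id=meta.get("sample_id", ""),
        assay=meta.get("assay", "whole"),
    )


def bin_reads(read_positions: pd.DataFrame, grid: BinGrid) -> CountTable:
    """Assign each read (chrom, pos) to exactly one bin by half-open containment.

    Total count is preserved; any out-of-bounds position aborts with a count
    of offenders.
    """
    if not {"chrom", "pos"}.issubset(read_positions.columns):
        raise ValueError("read positions need columns: chrom, pos")
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    bad = 0
    for c, sub in read_positions.groupby("chrom", sort=False):
        c = str(c)
        idx = grid.chrom_index(c)
        if len(idx) == 0:
            bad += len(sub)
            continue
        length = grid.chrom_length(c)
        pos = sub["pos"].to_numpy()
        oob = (pos < 0) | (pos >= length)
        bad += int(oob.sum())
        pos = pos[~oob]
        # bins of one chromosome are contiguous from 0, so division locates them
        which = np.minimum(pos // grid.bin_size, len(idx) - 1).astype(np.int64)
        np.add.at(counts, idx[0] + which, 1)
    if bad:
        raise ValueError(f"{bad} read position(s) outside chromosome bounds")
    return CountTable(grid, counts)
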