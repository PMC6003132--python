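"""Fixed-width genomic bin maps and per-bin read counting.

The imbalance pipeline operates on read counts in non-overlapping 1-Mb
windows tiled across a reference genome.  This module builds the bin map
(with per-bin GC fraction when a FASTA is available) and counts usable
alignments per bin.
"""

from __future__ import annotations


from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_MIN_MAPQ = 30

#: chromosome names treated as sex chromosomes (either naming dialect)
SEX_CHROM_NAMES = frozenset({"chrX", "chrY", "X", "Y"})

BIN_COLUMNS = ["chrom", "start", "end", "gc_fraction", "usable"]


class ChromosomeDialectError(ValueError):
    """Alignments and bin map use different chromosome naming dialects."""


@dataclass
class BinMap:
    """Ordered fixed-width windows over a genome.

    ``bins`` has one row per window with columns ``chrom`` (str),
    ``start``/``end`` (0-based half-open), ``gc_fraction`` (GC proportion of
    unambiguous bases, NaN when built without sequence) and ``usable``
    (False for windows that are mostly ambiguous bases).
    """

    genome_build: str
    bins: pd.DataFrame
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.bins = self.bins.reset_index(drop=True)
        missing = set(BIN_COLUMNS) - set(self.bins.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.bins.groupby("chrom", sort=False)["end"].max().to_dict()

    @property
    def has_gc(self) -> bool:
        return bool(np.isfinite(self.bins["gc_fraction"].to_numpy()).any())

    @property
    def usable(self) -> np.ndarray:
        return self.bins["usable"].to_numpy(dtype=bool)

    @property
    def gc_fraction(self) -> np.ndarray:
        return self.bins["gc_fraction"].to_numpy(dtype=float)

    @property
    def is_autosome(self) -> np.ndarray:
        """True for bins on non-sex chromosomes."""
        return ~self.bins["chrom"].isin(SEX_CHROM_NAMES).to_numpy()

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` (0-based) on ``chrom``."""
        offsets = self._chrom_offsets()
        if chrom not in offsets:
            raise KeyError(chrom)
        start, n = offsets[chrom]
        idx = pos // self.bin_size
        if idx >= n or pos < 0:
            raise IndexError(f"position {pos} outside {chrom}")
        return start + idx

    def _chrom_offsets(self) -> dict[str, tuple[int, int]]:
        if not hasattr(self, "_offsets"):
            offsets: dict[str, tuple[int, int]] = {}
            grouped = self.bins.groupby("chrom", sort=False)
            for chrom, grp in grouped:
                offsets[str(chrom)] = (int(grp.index[0]), len(grp))
            self._offsets = offsets
        return self._offsets

    # -- on-disk format: BED with two extra columns -------------------------
    def to_bed(self, path: str | Path) -> None:
        df = self.bins.copy()
        df.insert(3, "name", [f"bin_{i}" for i in range(len(df))])
        df["usable"] = df["usable"].astype(int)
        with open(path, "w") as fh:
            fh.write(f"#genome_build={self.genome_build}\tbin_size={self.bin_size}\n")
            df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")

    @classmethod
    def from_bed(cls, path: str | Path) -> "BinMap":
        build, bin_size = "unknown", DEFAULT_BIN_SIZE
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for token in first.lstrip("#").split():
                key, _, value = token.partition("=")
                if key == "genome_build":
                    build = value
                elif key == "bin_size":
                    bin_size = int(value)
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "name", "gc_fraction", "usable"],
        )
        df["usable"] = df["usable"].astype(bool)
        return cls(build, df[BIN_COLUMNS], bin_size=bin_size)


def _tile_chromosome(chrom: str, length: int, bin_size: int) -> list[tuple[str, int, int]]:
    return [
        (chrom, start, min(start + bin_size, length))
        for start in range(0, length, bin_size)
    ]


def _read_chrom_sizes(source: str | Path | Mapping[str, int]) -> list[tuple[str, int]]:
    if isinstance(source, Mapping):
        return [(str(c), int(n)) for c, n in source.items()]
    df = pd.read_csv(source, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    return list(df.itertuples(index=False, name=None))


def hg19_chrom_sizes(autosomes_only: bool = False) -> dict[str, int]:
    """Chromosome lengths of the hg19 assembly (packaged table)."""
    path = resources.files("ciascore.data") / "hg19.chrom.sizes"
    sizes = dict(_read_chrom_sizes(str(path)))
    if autosomes_only:
        sizes = {c: n for c, n in sizes.items() if c not in SEX_CHROM_NAMES}
    return sizes


def build_bin_map(
    fasta: str | Path | None = None,
    chrom_sizes: str | Path | Mapping[str, int] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    genome_build: str = "custom",
    max_n_fraction: float = 0.5,
) -> BinMap:
    """Tile a genome into fixed-size windows.

    Provide either a ``fasta`` (GC fraction and N-masking are computed from
    sequence) or a ``chrom_sizes`` table (two tab-separated columns, or a
    mapping), in which case ``gc_fraction`` is NaN and GC normalization is
    unavailable downstream.

    Windows whose sequence is more than ``max_n_fraction`` ambiguous bases
    are flagged ``usable = False``.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if (fasta is None) == (chrom_sizes is None):
        raise ValueError("provide exactly one of fasta or chrom_sizes")

    records: list[dict] = []
    if fasta is not None:
        fa = Fasta(str(fasta), rebuild=True)
        names = list(fa.keys())
        if not names:
            raise ValueError("FASTA contains no sequences")
        for chrom in names:
            length = len(fa[chrom])
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has zero length")
            for _, start, end in _tile_chromosome(chrom, length, bin_size):
                seq = str(fa[chrom][start:end]).upper()
                counts = Counter(seq)
                length_window = len(seq)
                acgt = sum(counts[b] for b in "ACGT")
                gc = counts["G"] + counts["C"]
                n_frac = 1.0 - acgt / length_window if length_window else 1.0
                gc_frac = gc / acgt if acgt else np.nan
                records.append(
                    dict(chrom=chrom, start=start, end=end,
                         gc_fraction=gc_frac, usable=n_frac <= max_n_fraction)
                )
    else:
        sizes = _read_chrom_sizes(chrom_sizes)
        if not sizes:
            raise ValueError("chromosome sizes table is empty")
        for chrom, length in sizes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
            for _, start, end in _tile_chromosome(chrom, int(length), bin_size):
                records.append(
                    dict(chrom=chrom, start=start, end=end,
                         gc_fraction=np.nan, usable=True)
                )
    return BinMap(genome_build, pd.DataFrame.from_records(records), bin_size=bin_size)


@dataclass
class RawCountProfile:
    """Per-bin unique-read counts for one sample, aligned to a BinMap."""

    sample_id: str
    bin_counts: np.ndarray
    filter_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_counts = np.asarray(self.bin_counts, dtype=np.int64)
        if (self.bin_counts < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def total_usable_reads(self) -> int:
        return int(self.bin_counts.sum())

    def to_tsv(self, path: str | Path, bin_map: BinMap) -> None:
        if len(self.bin_counts) != bin_map.n_bins:
            raise ValueError("profile length does not match bin map")
        df = bin_map.bins[["chrom", "start", "end"]].copy()
        df["count"] = self.bin_counts
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, bin_map: BinMap | None = None,
                 sample_id: str | None = None) -> "RawCountProfile":
        df = pd.read_csv(path, sep="\t")
        if "count" not in df.columns:
            raise ValueError(f"{path}: expected a 'count' column")
        if bin_map is not None and len(df) != bin_map.n_bins:
            raise ValueError(
                f"{path}: {len(df)} rows but bin map has {bin_map.n_bins} bins"
            )
        name = sample_id or Path(path).stem
        return cls(name, df["count"].to_numpy())


_FILTER_KEYS = ("unmapped", "secondary", "supplementary", "duplicate",
                "low_mapq", "unknown_chrom")


def _check_dialect(read_chroms: Iterable[str], map_chroms: set[str]) -> None:
    unknown = set(read_chroms) - map_chroms
    toggled = {
        c[3:] if c.startswith("chr") else "chr" + c for c in unknown
    }
    if unknown and not (set(read_chroms) & map_chroms) and (toggled & map_chroms):
        raise ChromosomeDialectError(
            "chromosome naming dialect mismatch: alignments use names like "
            f"{sorted(unknown)[:3]} but the bin map uses names like "
            f"{sorted(map_chroms)[:3]}"
        )


def count_reads(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    bin_map: BinMap,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    sample_id: str | None = None,
) -> RawCountProfile:
    """Count usable reads per bin from a SAM/BAM file or read iterable.

    A read is retained if it is mapped, primary, non-supplementary,
    non-duplicate and has mapping quality >= ``min_mapq`` (the operational
    definition of a uniquely mapped read); it increments the single bin
    containing its leftmost aligned base.  Excluded reads are tallied by
    reason in ``filter_report``.
    """
    close_me = None
    name = sample_id
    if isinstance(alignments, (str, Path)):
        path = Path(alignments)
        close_me = pysam.AlignmentFile(str(path), require_index=False)
        reads: Iterable[pysam.AlignedSegment] = close_me
        name = name or path.stem
        _check_dialect(close_me.references, set(bin_map.chromosomes))
    else:
        reads = alignments
        name = name or "sample"

    counts = np.zeros(bin_map.n_bins, dtype=np.int64)
    report = dict.fromkeys(_FILTER_KEYS, 0)
    offsets = bin_map._chrom_offsets()
    map_chroms = set(offsets)
    bin_size = bin_map.bin_size
    try:
        for read in reads:
            if read.is_unmapped:
                report["unmapped"] += 1
            elif read.is_secondary:
                report["secondary"] += 1
            elif read.is_supplementary:
                report["supplementary"] += 1
            elif read.is_duplicate:
                report["duplicate"] += 1
            elif read.mapping_quality < min_mapq:
                report["low_mapq"] += 1
            elif read.reference_name not in map_chroms:
                _check_dialect([read.reference_name], map_chroms)
                report["unknown_chrom"] += 1
            else:
                start, n = offsets[read.reference_name]
                idx = read.reference_start // bin_size
                if idx >= n:
                    report["unknown_chrom"] += 1
                else:
                    counts[start + idx] += 1
    finally:
        if close_me is not None:
            close_me.close()
    return RawCountProfile(name, counts, filter_report=report)
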