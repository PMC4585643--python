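"""Cluster-free parallelization: split the genome into bins, assign by rotation.

Variant calling parallelizes over genomic intervals. The genome (or a set
of target regions) is chopped into equally sized bins whose size is chosen
dynamically from the total span and the process count, clamped between
50 kbp and 1 Mbp: large enough to amortize per-bin overhead, small enough
to stay fine-grained. Bins are dealt to the N processes by rotation
(process = bin rank mod N) so no two adjacent bins land on the same
process — uneven read coverage then spreads across workers and all
processes finish in similar time. Each process's bins are written to one
BED file; the N files partition the input regions exactly.

Coordinates are 0-based half-open throughout this module (BED dialect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .vcf_io import GenomeIndex

__all__ = [
    "Bin",
    "MIN_BIN_BP",
    "MAX_BIN_BP",
    "compute_bin_size",
    "generate_bins",
    "assign_bins",
    "write_bin_beds",
    "read_bed",
]

MIN_BIN_BP = 50_000
MAX_BIN_BP = 1_000_000

Region = tuple[str, int, int]  # chrom, start (0-based), end (exclusive)


@dataclass(frozen=True)
class Bin:
    """Half-open genomic interval with its genome-order rank and process."""

    chrom: str
    start: int
    end: int
    global_index: int
    process: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty bin {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def compute_bin_size(
    total_bp: int,
    n_processes: int,
    min_bp: int = MIN_BIN_BP,
    max_bp: int = MAX_BIN_BP,
) -> int:
    """Dynamic bin size: ceil(total/N) clamped to [min_bp, max_bp]."""
    if total_bp < 1 or n_processes < 1:
        raise ValueError("total_bp and n_processes must be positive")
    if min_bp < 1 or max_bp < min_bp:
        raise ValueError("need 1 <= min_bp <= max_bp")
    return max(min_bp, min(max_bp, math.ceil(total_bp / n_processes)))


def _as_regions(regions: Sequence[Region] | GenomeIndex) -> list[Region]:
    if isinstance(regions, GenomeIndex):
        return [(name, 0, length) for name, length in regions]
    return list(regions)


def generate_bins(
    regions: Sequence[Region] | GenomeIndex, bin_size: int
) -> list[Bin]:
    """Chop sorted, non-overlapping regions left-to-right into bins.

    Every bin has exactly *bin_size* bp except the last bin of each region;
    bins never cross region (hence chromosome) boundaries and their union
    is the input, base-pair exact.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    region_list = _as_regions(regions)
    last: dict[str, int] = {}
    for chrom, start, end in region_list:
        if end <= start or start < 0:
            raise ValueError(f"invalid region {chrom}:{start}-{end}")
        if chrom in last and start < last[chrom]:
            raise ValueError(
                f"regions overlap or are unsorted at {chrom}:{start}-{end}"
            )
        last[chrom] = end
    bins: list[Bin] = []
    for chrom, start, end in region_list:
        pos = start
        while pos < end:
            stop = min(pos + bin_size, end)
            bins.append(Bin(chrom, pos, stop, global_index=len(bins)))
            pos = stop
    return bins


def assign_bins(bins: Sequence[Bin], n_processes: int) -> list[Bin]:
    """Rotation assignment: process = global_index mod N."""
    if n_processes < 1:
        raise ValueError("n_processes must be positive")
    return [replace(b, process=b.global_index % n_processes) for b in bins]


def write_bin_beds(
    bins: Sequence[Bin], n_processes: int, out_prefix: str | Path
) -> list[Path]:
    """Write one BED per process: ``<prefix>.0.bed`` ... ``<prefix>.N-1.bed``."""
    out_prefix = Path(out_prefix)
    paths = [out_prefix.parent / f"{out_prefix.name}.{i}.bed" for i in range(n_processes)]
    handles = [open(p, "w") for p in paths]
    try:
        for b in bins:
            if b.process is None:
                raise ValueError("bins must be assigned before writing")
            handles[b.process].write(f"{b.chrom}\t{b.start}\t{b.end}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


def read_bed(path: str | Path) -> list[Region]:
    """Read a 3+-column BED file (0-based half-open)."""
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: BED line with <3 columns: {line!r}")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions
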