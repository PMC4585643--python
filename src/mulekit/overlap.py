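"""Multi-set variant concordance: Venn partition counts and rates.

Call sets (typically one per caller or per data set, 2-5 of them) are
partitioned into Venn regions. SNVs use exact key equality on
(chromosome, position, reference allele, alternate allele), one key per
alternate allele of a multiallelic record. Non-SNVs, normalized upstream,
are intervalized — the record reduces to its position, extended 10 bp
towards both ends, i.e. the closed interval [pos-10, pos+10] — and two
intervals overlap when they share a chromosome and intersect. Because
interval overlap is not transitive, overlapping non-SNVs are clustered by
single linkage (connected components of the pairwise overlap graph) and
one cluster counts as one Venn unit in the region of the sources present
in it.

The concordance rate is the percentage of Venn units falling in the
all-sources region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

from .vcf_io import VariantRecord

__all__ = [
    "SnvKey",
    "NonSnvInterval",
    "snv_keys",
    "nonsnv_intervals",
    "venn_counts",
    "nonsnv_clusters",
    "venn_counts_nonsnv",
    "concordance_rate",
    "NONSNV_FLANK",
]

NONSNV_FLANK = 10  # bp extension towards both ends

SnvKey = tuple  # (chrom, pos, ref, alt)


@dataclass(frozen=True)
class NonSnvInterval:
    """Closed interval standing in for one non-SNV record."""

    chrom: str
    start: int
    end: int
    source: str
    record: VariantRecord | None = field(default=None, compare=False, hash=False)

    def overlaps(self, other: "NonSnvInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def snv_keys(records: Iterable[VariantRecord]) -> set[SnvKey]:
    """One (chrom, pos, ref, alt) key per alternate allele of each SNV record."""
    keys = set()
    for rec in records:
        if rec.is_snv:
            for alt in rec.alts:
                keys.add((rec.chrom, rec.pos, rec.ref, alt))
    return keys


def nonsnv_intervals(
    records: Iterable[VariantRecord], source: str, flank: int = NONSNV_FLANK
) -> list[NonSnvInterval]:
    """Intervalize non-SNV records: position point extended by *flank* bp."""
    return [
        NonSnvInterval(rec.chrom, rec.pos - flank, rec.pos + flank, source, rec)
        for rec in records
        if not rec.is_snv
    ]


def _check_k(k: int) -> None:
    if k < 2:
        raise ValueError("concordance needs at least 2 sets")
    if k > 5:
        raise ValueError("at most 5 sets supported (Venn regions grow as 2^k)")


def venn_counts(sets: dict[str, set[Hashable]]) -> dict[frozenset[str], int]:
    """Partition the union of keyed sets into Venn region counts.

    Returns every non-empty combination of source labels mapped to the
    number of keys found in exactly those sources; counts sum to |union|.
    """
    _check_k(len(sets))
    regions: Counter[frozenset[str]] = Counter()
    union: set[Hashable] = set().union(*sets.values())
    for key in union:
        members = frozenset(label for label, s in sets.items() if key in s)
        regions[members] += 1
    return dict(regions)


def nonsnv_clusters(
    interval_sets: dict[str, Sequence[NonSnvInterval]],
) -> list[list[NonSnvInterval]]:
    """Single-linkage clusters of overlapping intervals across all sources.

    Implemented as a genome-order sweep: after sorting by (chrom, start),
    intervals chain into one cluster while each starts at or before the
    running maximum end — exactly the connected components of the pairwise
    overlap graph for 1-D intervals.
    """
    intervals = [iv for ivs in interval_sets.values() for iv in ivs]
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.source))
    clusters: list[list[NonSnvInterval]] = []
    current: list[NonSnvInterval] = []
    current_chrom: str | None = None
    current_end = 0
    for iv in intervals:
        if current and iv.chrom == current_chrom and iv.start <= current_end:
            current.append(iv)
            current_end = max(current_end, iv.end)
        else:
            if current:
                clusters.append(current)
            current = [iv]
            current_chrom = iv.chrom
            current_end = iv.end
    if current:
        clusters.append(current)
    return clusters


def venn_counts_nonsnv(
    interval_sets: dict[str, Sequence[NonSnvInterval]],
) -> dict[frozenset[str], int]:
    """Venn region counts over non-SNV clusters (one cluster = one unit)."""
    _check_k(len(interval_sets))
    regions: Counter[frozenset[str]] = Counter()
    for cluster in nonsnv_clusters(interval_sets):
        regions[frozenset(iv.source for iv in cluster)] += 1
    return dict(regions)


def concordance_rate(venn: dict[frozenset[str], int]) -> float | None:
    """Percent of Venn units shared by all sources; None for an empty union."""
    total = sum(venn.values())
    if total == 0:
        return None
    labels = frozenset().union(*venn.keys())
    return 100.0 * venn.get(labels, 0) / total
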