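"""Variant normalization: left-align and trim indel representations.

Different callers emit the same indel in different coordinates ("TGGG>TGG"
and "TG>T" both delete one G of a run). Normalization rewrites every record
to the unique leftmost, minimal representation so equivalent calls compare
equal under the merge keys. The algorithm operates jointly on the whole
allele set {ref} ∪ alts of a record (records are never split into
biallelics):

1. While all alleles end in the same nucleotide, drop that nucleotide; if
   any allele becomes empty, prepend the reference base at pos-1 to every
   allele and decrement pos.
2. While all alleles begin with the same nucleotide and every allele has
   length >= 2, drop that first nucleotide and increment pos.

The result is idempotent and invariant under reference-padding of the
input. SNVs are untouched (both loops are no-ops for single-base alleles).
N bases participate in trimming like any fixed nucleotide.
"""

from __future__ import annotations

from pathlib import Path

import pyfaidx

from .vcf_io import (
    GenomeIndex,
    VariantRecord,
    VcfHeader,
    fetch_reference,
    open_fasta,
    read_vcf_records,
    write_vcf,
)

__all__ = ["NormalizeError", "normalize_variant", "normalize_records", "normalize_file"]


class NormalizeError(ValueError):
    pass


def normalize_variant(record: VariantRecord, genome: pyfaidx.Fasta) -> VariantRecord:
    """Return the left-aligned, trimmed form of *record*.

    The record's ref must match the reference at its position; a record that
    would need left-extension past the contig start is an error. Genotype
    allele indices are preserved (the allele list order never changes).
    """
    observed = fetch_reference(genome, record.chrom, record.pos, record.pos + len(record.ref) - 1)
    if observed != record.ref:
        raise NormalizeError(
            f"ref mismatch at {record.chrom}:{record.pos}: record has "
            f"{record.ref!r}, reference has {observed!r}"
        )
    alleles = [record.ref, *record.alts]
    pos = record.pos

    # right-trim shared suffix, left-extending when an allele empties
    while len({a[-1] for a in alleles}) == 1:
        alleles = [a[:-1] for a in alleles]
        if any(not a for a in alleles):
            if pos == 1:
                raise NormalizeError(
                    f"cannot left-extend past contig start at {record.chrom}:{record.pos}"
                )
            base = fetch_reference(genome, record.chrom, pos - 1, pos - 1)
            alleles = [base + a for a in alleles]
            pos -= 1

    # left-trim shared prefix while every allele keeps >= 1 base
    while all(len(a) >= 2 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1

    if pos == record.pos and alleles[0] == record.ref and alleles[1:] == list(record.alts):
        return record
    return record.copy(pos=pos, ref=alleles[0], alts=alleles[1:])


def normalize_records(
    records: list[VariantRecord], genome: pyfaidx.Fasta, genome_index: GenomeIndex | None = None
) -> list[VariantRecord]:
    """Normalize every record and re-sort by genome order. Count-preserving."""
    if genome_index is None:
        genome_index = GenomeIndex((name, len(genome[name])) for name in genome.keys())
    out = []
    for record in records:
        try:
            out.append(normalize_variant(record, genome))
        except (NormalizeError, ValueError, KeyError) as exc:
            raise NormalizeError(f"record {record.chrom}:{record.pos}: {exc}") from exc
    out.sort(key=genome_index.sort_key)
    return out


def normalize_file(
    vcf: str | Path, reference: str | Path, out: str | Path
) -> tuple[VcfHeader, list[VariantRecord]]:
    """Normalize a whole VCF file; output is genome-sorted."""
    genome = open_fasta(reference)
    genome_index = GenomeIndex.from_fasta(reference)
    header, records = read_vcf_records(vcf)
    normalized = normalize_records(records, genome, genome_index)
    write_vcf(header, normalized, out, genome=genome_index)
    return header, normalized
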