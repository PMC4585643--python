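"""Call-set summary statistics: Ti/Tv, het/hom, and the MAF filter.

Ti/Tv is counted per alternate allele of SNV records: transitions are the
purine-purine and pyrimidine-pyrimidine swaps (A<->G, C<->T), everything
else among single-base substitutions is a transversion. Het/hom counts one
sample's genotypes: heterozygous = two distinct alleles, homozygous = two
identical non-reference alleles (hom-ref carries no variant signal and is
excluded, as are missing calls).

The MAF filter keeps records whose pre-computed INFO allele-frequency
annotation is at most the threshold or absent; frequencies are never
recomputed here.
"""

from __future__ import annotations

from typing import Sequence

from .vcf_io import VariantRecord

__all__ = ["titv_ratio", "het_hom_ratio", "maf_filter", "record_af"]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def titv_ratio(records: Sequence[VariantRecord]) -> tuple[int, int, float | None]:
    """(transitions, transversions, ti/tv or None when tv == 0)."""
    ti = tv = 0
    for rec in records:
        if not rec.is_snv:
            continue
        for alt in rec.alts:
            if (rec.ref, alt) in _TRANSITIONS:
                ti += 1
            else:
                tv += 1
    return ti, tv, (ti / tv if tv else None)


def het_hom_ratio(
    records: Sequence[VariantRecord], sample: str
) -> tuple[int, int, float | None]:
    """(het, hom_alt, het/hom_alt or None when hom_alt == 0) for one sample."""
    het = hom_alt = 0
    seen = False
    for rec in records:
        call = rec.genotypes.get(sample)
        if call is None:
            continue
        seen = True
        if call.is_missing:
            continue
        if call.is_het:
            het += 1
        elif call.is_hom_alt:
            hom_alt += 1
    if records and not seen:
        raise KeyError(f"sample {sample!r} not present in records")
    return het, hom_alt, (het / hom_alt if hom_alt else None)


def record_af(record: VariantRecord, af_key: str) -> float | None:
    """Annotated allele frequency of a record, or None if unannotated.

    Multiallelic annotations (comma-separated) reduce to their maximum — the
    most common allele decides whether the site counts as common.
    """
    if af_key not in record.info:
        return None
    raw = record.info[af_key]
    try:
        return max(float(v) for v in str(raw).split(","))
    except ValueError as exc:
        raise ValueError(
            f"unparseable {af_key} value {raw!r} at {record.chrom}:{record.pos}"
        ) from exc


def maf_filter(
    records: Sequence[VariantRecord], af_key: str = "AF", threshold: float = 0.01
) -> list[VariantRecord]:
    """Keep rare/novel records: annotated frequency <= threshold, or absent."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return [
        rec
        for rec in records
        if (af := record_af(rec, af_key)) is None or af <= threshold
    ]
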