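"""Multi-caller merging and M-of-N consensus extraction.

Records from different callers are grouped by a merge key: SNVs overlap
when chromosome and position agree; non-SNVs (indels etc., normalized
upstream) overlap when chromosome, position and reference allele agree.
Within a key, alternate alleles are pooled; the chromosome, position and
reference columns stay as-is; QUAL and the genotype (with its GQ) come from
the highest-priority supporting caller, with genotype allele indices
remapped onto the pooled alt list. A merged record is PASS iff at least one
input record was unfiltered (PASS or '.'); otherwise its FILTER is the
union of the observed filter names.

Caller priority is GATK > SAMtools > FreeBayes > VarScan > SOAPsnp;
unrecognized labels keep their given order after the recognized ones.

Provenance is written per record into INFO tags ``CALLERS`` (supporting
source labels) and ``NCALLERS`` (their count), which make M-of-N consensus
extraction re-runnable from the merged file alone: an M-of-N consensus call
is a merge key supported by at least M of the N input files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .normalize import normalize_records
from .vcf_io import (
    GenomeIndex,
    GenotypeCall,
    MISSING_CALL,
    VariantRecord,
    VcfHeader,
    open_fasta,
    read_vcf_records,
    write_vcf,
)

__all__ = [
    "CALLER_PRIORITY",
    "MergedRecord",
    "caller_priority",
    "merge_key",
    "merge_records",
    "merge_vcfs",
    "extract_consensus",
    "extract_consensus_file",
    "split_and_recombine",
]

CALLER_PRIORITY = ("gatk", "samtools", "freebayes", "varscan", "soapsnp")

CALLERS_META = (
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Source files supporting this call">'
)
NCALLERS_META = (
    '##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Number of source files supporting this call">'
)

MergeKey = tuple  # ("snv", chrom, pos) | ("nonsnv", chrom, pos, ref)


def merge_key(record: VariantRecord) -> MergeKey:
    if record.is_snv:
        return ("snv", record.chrom, record.pos)
    return ("nonsnv", record.chrom, record.pos, record.ref)


def caller_priority(sources: list[str]) -> list[str]:
    """Order source labels by caller priority; unknown labels keep order."""
    rank = {name: i for i, name in enumerate(CALLER_PRIORITY)}
    known = sorted(
        (s for s in sources if s.lower() in rank), key=lambda s: rank[s.lower()]
    )
    unknown = [s for s in sources if s.lower() not in rank]
    return known + unknown


@dataclass
class MergedRecord:
    """A merged variant plus the set of sources that support its key."""

    record: VariantRecord
    supporters: frozenset[str]
    n_sources: int

    @property
    def n_supporters(self) -> int:
        return len(self.supporters)


def _remap_genotypes(
    genotypes: dict[str, GenotypeCall], old_alleles: list[str], new_alleles: list[str]
) -> dict[str, GenotypeCall]:
    index_map = {i: new_alleles.index(a) for i, a in enumerate(old_alleles)}
    out = {}
    for sample, call in genotypes.items():
        if call.is_missing:
            out[sample] = call
        else:
            a, b = call.alleles()
            out[sample] = GenotypeCall(
                (index_map[a], index_map[b]), call.phased, call.gq, call.dp
            )
    return out


def merge_records(records: list[VariantRecord], n_sources: int | None = None) -> MergedRecord:
    """Merge records sharing one merge key, given in priority order."""
    if not records:
        raise ValueError("nothing to merge")
    keys = {merge_key(r) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple merge keys: {sorted(keys)}")
    first = records[0]

    pooled = [first.ref, *first.alts]
    for rec in records[1:]:
        for alt in rec.alts:
            if alt not in pooled:
                pooled.append(alt)
    # an SNV key can legitimately pool records whose ref agrees (same locus);
    # a later alt equal to the first ref stays where the ref already sits
    alts = [a for a in pooled[1:] if a != first.ref]

    if any(rec.is_unfiltered for rec in records):
        filters: list[str] | None = ["PASS"]
    else:
        names: list[str] = []
        for rec in records:
            for name in rec.filters or []:
                if name not in names:
                    names.append(name)
        filters = names or None

    genotypes = _remap_genotypes(
        first.genotypes, [first.ref, *first.alts], [first.ref, *alts]
    )
    supporters = frozenset(r.source for r in records if r.source is not None)
    merged = first.copy(alts=alts, filters=filters, genotypes=genotypes)
    merged.info = dict(first.info)
    return MergedRecord(merged, supporters, n_sources or len(records))


def _tagged(merged: MergedRecord) -> VariantRecord:
    rec = merged.record.copy()
    rec.info["CALLERS"] = ",".join(sorted(merged.supporters))
    rec.info["NCALLERS"] = merged.n_supporters
    return rec


def _group_and_merge(
    records: list[VariantRecord],
    priority: list[str],
    genome_index: GenomeIndex,
    n_sources: int,
) -> list[MergedRecord]:
    rank = {label: i for i, label in enumerate(priority)}
    groups: dict[MergeKey, list[VariantRecord]] = {}
    for rec in records:
        groups.setdefault(merge_key(rec), []).append(rec)
    merged = []
    for group in groups.values():
        group.sort(key=lambda r: rank.get(r.source, len(rank)))
        merged.append(merge_records(group, n_sources=n_sources))
    merged.sort(key=lambda m: genome_index.sort_key(m.record))
    return merged


def merge_vcfs(
    vcfs: list[tuple[str | Path, str]],
    reference: str | Path,
    out: str | Path | None = None,
    priority: list[str] | None = None,
    allow_sample_mismatch: bool = False,
) -> list[MergedRecord]:
    """Normalize and merge single-sample VCFs from one sample.

    ``vcfs`` is a list of (path, source label) pairs. Inputs are normalized,
    grouped by merge key, and merged with the highest-priority caller first
    at every key. If *out* is given the merged VCF (with CALLERS/NCALLERS
    tags) is written there.
    """
    genome = open_fasta(reference)
    genome_index = GenomeIndex.from_fasta(reference)
    labels = [label for _, label in vcfs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate source labels")
    order = caller_priority(labels) if priority is None else list(priority)

    all_records: list[VariantRecord] = []
    sample_name: str | None = None
    header_samples: list[str] = []
    for path, label in vcfs:
        header, records = read_vcf_records(path, source=label)
        if len(header.samples) > 1:
            raise ValueError(
                f"{path}: multi-sample input ({header.samples}); split first "
                "(see split_and_recombine)"
            )
        if header.samples:
            if sample_name is None:
                sample_name = header.samples[0]
                header_samples = header.samples
            elif header.samples[0] != sample_name and not allow_sample_mismatch:
                raise ValueError(
                    f"sample name disagreement: {sample_name!r} vs {header.samples[0]!r} "
                    f"in {path} (pass allow_sample_mismatch to override)"
                )
        all_records.extend(normalize_records(records, genome, genome_index))

    merged = _group_and_merge(all_records, order, genome_index, n_sources=len(vcfs))
    if out is not None:
        header = VcfHeader.minimal(header_samples, extra_meta=[CALLERS_META, NCALLERS_META], genome=genome_index)
        write_vcf(header, [_tagged(m) for m in merged], out, genome=genome_index)
    return merged


def extract_consensus(merged: list[MergedRecord], m: int) -> list[MergedRecord]:
    """Keep merge keys supported by at least *m* of the input files."""
    if not merged:
        return []
    n = merged[0].n_sources
    if not 1 <= m <= n:
        raise ValueError(f"m={m} outside [1, {n}]")
    return [rec for rec in merged if rec.n_supporters >= m]


def extract_consensus_file(
    merged_vcf: str | Path, m: int, out: str | Path
) -> list[VariantRecord]:
    """Consensus extraction from a merged VCF via its NCALLERS tags."""
    header, records = read_vcf_records(merged_vcf)
    sources: set[str] = set()
    for rec in records:
        if "CALLERS" not in rec.info or "NCALLERS" not in rec.info:
            raise ValueError(
                f"{merged_vcf}: record {rec.chrom}:{rec.pos} lacks CALLERS/NCALLERS "
                "provenance tags (not a mulekit-merged VCF?)"
            )
        sources.update(str(rec.info["CALLERS"]).split(","))
    n = len(sources)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} outside [1, {n}]")
    kept = [rec for rec in records if int(rec.info["NCALLERS"]) >= m]
    write_vcf(header, kept, out)
    return kept


def split_and_recombine(
    vcfs: list[tuple[str | Path, str]],
    reference: str | Path,
    out: str | Path | None = None,
    priority: list[str] | None = None,
) -> list[MergedRecord]:
    """Merge multi-sample caller VCFs: split per sample, merge, recombine.

    Every caller must carry the same sample set. Each sample's calls are
    merged independently; the resulting loci are unioned across samples, a
    sample without a call at a locus getting a missing genotype. Supporters
    at a locus are the union of the per-sample supporters.
    """
    genome = open_fasta(reference)
    genome_index = GenomeIndex.from_fasta(reference)
    labels = [label for _, label in vcfs]
    order = caller_priority(labels) if priority is None else list(priority)
    rank = {label: i for i, label in enumerate(order)}

    sample_sets: dict[str, list[str]] = {}
    per_source: dict[str, tuple[VcfHeader, list[VariantRecord]]] = {}
    for path, label in vcfs:
        header, records = read_vcf_records(path, source=label)
        per_source[label] = (header, records)
        sample_sets[label] = header.samples
    reference_samples = sample_sets[labels[0]]
    if not reference_samples:
        raise ValueError("inputs carry no samples")
    for label, samples in sample_sets.items():
        if set(samples) != set(reference_samples):
            raise ValueError(
                f"sample set mismatch: {labels[0]} has {sorted(reference_samples)}, "
                f"{label} has {sorted(samples)}"
            )

    # per-sample single-sample merge
    per_sample_merged: dict[str, dict[MergeKey, MergedRecord]] = {}
    for sample in reference_samples:
        records = []
        for label in labels:
            _, recs = per_source[label]
            for rec in recs:
                call = rec.genotypes.get(sample, MISSING_CALL)
                if call.is_missing:
                    continue  # this caller made no call for this sample here
                single = rec.copy(genotypes={sample: call})
                records.append(single)
        records = normalize_records(records, genome, genome_index)
        merged = _group_and_merge(records, order, genome_index, n_sources=len(vcfs))
        per_sample_merged[sample] = {merge_key(m.record): m for m in merged}

    # recombine across samples
    all_keys: set[MergeKey] = set()
    for keyed in per_sample_merged.values():
        all_keys.update(keyed)

    combined: list[MergedRecord] = []
    for key in all_keys:
        present = [
            (sample, per_sample_merged[sample][key])
            for sample in reference_samples
            if key in per_sample_merged[sample]
        ]
        # base record: the per-sample merge whose top supporter has highest priority
        base_sample, base = min(
            present, key=lambda sm: min(rank.get(s, len(rank)) for s in sm[1].supporters)
        )
        pooled = [base.record.ref, *base.record.alts]
        for _, m in present:
            for alt in m.record.alts:
                if alt not in pooled:
                    pooled.append(alt)
        alts = [a for a in pooled[1:] if a != base.record.ref]
        genotypes: dict[str, GenotypeCall] = {}
        for sample in reference_samples:
            if sample in per_sample_merged and key in per_sample_merged[sample]:
                m = per_sample_merged[sample][key]
                call = m.record.genotypes.get(sample, MISSING_CALL)
                if not call.is_missing:
                    remapped = _remap_genotypes(
                        {sample: call},
                        [m.record.ref, *m.record.alts],
                        [base.record.ref, *alts],
                    )
                    genotypes[sample] = remapped[sample]
                    continue
            genotypes[sample] = MISSING_CALL
        supporters = frozenset().union(*(m.supporters for _, m in present))
        rec = base.record.copy(alts=alts, genotypes=genotypes)
        combined.append(MergedRecord(rec, supporters, len(vcfs)))

    combined.sort(key=lambda m: genome_index.sort_key(m.record))
    if out is not None:
        header = VcfHeader.minimal(
            reference_samples, extra_meta=[CALLERS_META, NCALLERS_META], genome=genome_index
        )
        write_vcf(header, [_tagged(m) for m in combined], out, genome=genome_index)
    return combined
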