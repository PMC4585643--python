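"""Data model and I/O for the formats the toolkit touches.

The in-memory unit of everything downstream (merging, trio statistics,
concordance) is :class:`VariantRecord`: one VCF data line with its per-sample
genotypes and a ``source`` label recording which caller produced it.
Multiallelic lines are kept as single records; classification into SNV
vs non-SNV (indels etc.) is record-level and drives which merge key and
which overlap rule applies downstream.

Only the modeled fields are round-tripped (CHROM, POS, ID, REF, ALT, QUAL,
FILTER, INFO, and GT/GQ/DP per sample); other FORMAT fields are dropped on
read. Haploid genotypes are promoted to homozygous diploid with a warning,
because the trio statistics assume two alleles per individual; ploidy above
two is an error. Symbolic alternate alleles (``<DEL>``, breakends) are
rejected: every merge and normalization rule operates on sequence alleles.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pyfaidx

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "GenomeIndex",
    "VcfHeader",
    "TrioPedigree",
    "VcfParseError",
    "read_vcf",
    "read_vcf_records",
    "write_vcf",
    "open_fasta",
    "fetch_reference",
    "write_ped_map",
]

_VALID_ALLELE_CHARS = set("ACGTN")


class VcfParseError(ValueError):
    """Malformed VCF content; message carries the offending line number."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at a locus.

    ``allele_indices`` is ``None`` for a missing call, otherwise a pair of
    allele indices (0 = REF, i = i-th ALT). A partially missing diploid call
    (``./1``) is treated as missing: every downstream statistic needs both
    alleles.
    """

    allele_indices: tuple[int, int] | None = None
    phased: bool = False
    gq: int | None = None
    dp: int | None = None

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    def alleles(self) -> tuple[int, int]:
        if self.allele_indices is None:
            raise ValueError("missing genotype has no alleles")
        return self.allele_indices

    @property
    def is_het(self) -> bool:
        a = self.alleles()
        return a[0] != a[1]

    @property
    def is_hom_alt(self) -> bool:
        a = self.alleles()
        return a[0] == a[1] != 0

    def to_vcf(self) -> str:
        if self.allele_indices is None:
            return "./."
        sep = "|" if self.phased else "/"
        return sep.join(str(i) for i in self.allele_indices)


MISSING_CALL = GenotypeCall()


@dataclass
class VariantRecord:
    """One VCF data line.

    ``filters`` is ``None`` for ``.`` (no filtering applied), ``["PASS"]``,
    or a list of filter names. ``source`` is provenance (the caller label),
    not a VCF column.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    ids: list[str] = field(default_factory=list)
    qual: float | None = None
    filters: list[str] | None = None
    info: dict[str, object] = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    source: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if not self.alts:
            raise ValueError("alts must be non-empty")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"duplicate alt alleles at {self.chrom}:{self.pos}")
        if self.ref in self.alts:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be non-negative or missing")
        n_alt = len(self.alts)
        for sample, call in self.genotypes.items():
            if call.allele_indices is None:
                continue
            for i in call.allele_indices:
                if not 0 <= i <= n_alt:
                    raise ValueError(
                        f"allele index {i} out of range for sample {sample} "
                        f"at {self.chrom}:{self.pos}"
                    )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_unfiltered(self) -> bool:
        """True for FILTER '.' or PASS (the PASS-propagation rule's sense)."""
        return self.filters is None or self.filters == ["PASS"]

    def allele_seq(self, index: int) -> str:
        """Sequence of allele *index* (0 = ref)."""
        return self.ref if index == 0 else self.alts[index - 1]

    def copy(self, **changes) -> "VariantRecord":
        rec = replace(self, **changes)
        rec.alts = list(rec.alts)
        rec.ids = list(rec.ids)
        rec.info = dict(rec.info)
        rec.genotypes = dict(rec.genotypes)
        return rec


class GenomeIndex:
    """Ordered contig names and lengths — the coordinate authority.

    Built from a ``.fai`` file (or an indexed FASTA); contig order is the
    file order and defines the genome sort order used everywhere.
    """

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._entries = list(entries)
        names = [n for n, _ in self._entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names in genome index")
        for name, length in self._entries:
            if length < 1:
                raise ValueError(f"contig {name} has non-positive length")
        self._rank = {name: i for i, (name, _) in enumerate(self._entries)}
        self._length = dict(self._entries)

    @classmethod
    def from_fai(cls, path: str | Path) -> "GenomeIndex":
        entries = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                entries.append((fields[0], int(fields[1])))
        return cls(entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        fa = pyfaidx.Fasta(str(path))  # builds .fai if absent
        return cls((name, len(fa[name])) for name in fa.keys())

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._rank

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._entries]

    def length(self, name: str) -> int:
        if name not in self._length:
            raise KeyError(f"contig {name!r} not in genome index")
        return self._length[name]

    def rank(self, name: str) -> int:
        if name not in self._rank:
            raise KeyError(f"contig {name!r} not in genome index")
        return self._rank[name]

    def total_bp(self) -> int:
        return sum(l for _, l in self._entries)

    def sort_key(self, record: VariantRecord) -> tuple[int, int]:
        return (self.rank(record.chrom), record.pos)


@dataclass
class VcfHeader:
    """Meta lines (``##...``) plus the sample names of the #CHROM line."""

    meta_lines: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    @classmethod
    def minimal(
        cls,
        samples: Sequence[str] = (),
        extra_meta: Sequence[str] = (),
        genome: "GenomeIndex | None" = None,
    ) -> "VcfHeader":
        lines = ["##fileformat=VCFv4.2", *extra_meta]
        if genome is not None:
            lines += [f"##contig=<ID={name},length={length}>" for name, length in genome]
        if samples:
            lines += [
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            ]
        return cls(meta_lines=lines, samples=list(samples))

    def with_info_line(self, line: str) -> "VcfHeader":
        if line in self.meta_lines:
            return self
        return VcfHeader(self.meta_lines + [line], list(self.samples))


# ---------------------------------------------------------------------------
# reading


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _check_allele(allele: str, lineno: int, what: str) -> str:
    allele = allele.upper()
    if allele.startswith("<") or "[" in allele or "]" in allele:
        raise VcfParseError(
            f"line {lineno}: symbolic {what} allele {allele!r} not supported "
            "(sequence alleles only)"
        )
    if not allele or not set(allele) <= _VALID_ALLELE_CHARS:
        raise VcfParseError(f"line {lineno}: invalid {what} allele {allele!r}")
    return allele


def _parse_gt(gt: str, n_alt: int, lineno: int, sample: str) -> GenotypeCall:
    phased = "|" in gt
    parts = gt.replace("|", "/").split("/")
    if any(p == "." for p in parts) or gt == ".":
        return MISSING_CALL
    try:
        indices = [int(p) for p in parts]
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: bad GT {gt!r} for sample {sample}") from exc
    if len(indices) == 1:
        warnings.warn(
            f"line {lineno}: haploid genotype {gt!r} for sample {sample} "
            "promoted to homozygous diploid",
            stacklevel=2,
        )
        indices = indices * 2
    if len(indices) != 2:
        raise VcfParseError(
            f"line {lineno}: ploidy {len(indices)} for sample {sample} unsupported "
            "(diploid contract)"
        )
    for i in indices:
        if not 0 <= i <= n_alt:
            raise VcfParseError(
                f"line {lineno}: allele index {i} out of range for sample {sample}"
            )
    return GenotypeCall(allele_indices=(indices[0], indices[1]), phased=phased)


def _parse_info(text: str) -> dict[str, object]:
    info: dict[str, object] = {}
    if text == "." or not text:
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            info[key] = value
        else:
            info[item] = True
    return info


def _parse_line(line: str, lineno: int, samples: list[str], source: str | None) -> VariantRecord:
    fields = line.rstrip("\n").split("\t")
    n_expected = 8 + (1 + len(samples) if samples else 0)
    if len(fields) < min(8, n_expected) or (samples and len(fields) < n_expected):
        raise VcfParseError(
            f"line {lineno}: expected {n_expected} columns, got {len(fields)}"
        )
    if len(fields) < 8:
        raise VcfParseError(f"line {lineno}: expected at least 8 columns, got {len(fields)}")
    chrom, pos_s, ids_s, ref_s, alt_s, qual_s, filt_s, info_s = fields[:8]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: bad POS {pos_s!r}") from exc
    if not ref_s or ref_s == ".":
        raise VcfParseError(f"line {lineno}: missing REF column value")
    if not alt_s or alt_s == ".":
        raise VcfParseError(f"line {lineno}: missing ALT column value")
    ref = _check_allele(ref_s, lineno, "reference")
    alts = [_check_allele(a, lineno, "alternate") for a in alt_s.split(",")]
    ids = [] if ids_s == "." else ids_s.split(";")
    qual = None if qual_s == "." else float(qual_s)
    filters = None if filt_s == "." else filt_s.split(";")
    info = _parse_info(info_s)

    genotypes: dict[str, GenotypeCall] = {}
    if samples:
        fmt = fields[8].split(":")
        if "GT" not in fmt:
            raise VcfParseError(f"line {lineno}: FORMAT lacks GT")
        gt_i = fmt.index("GT")
        gq_i = fmt.index("GQ") if "GQ" in fmt else None
        dp_i = fmt.index("DP") if "DP" in fmt else None
        for sample, cell in zip(samples, fields[9:]):
            vals = cell.split(":")
            call = _parse_gt(vals[gt_i], len(alts), lineno, sample)
            if not call.is_missing:
                gq = dp = None
                if gq_i is not None and gq_i < len(vals) and vals[gq_i] not in (".", ""):
                    gq = int(float(vals[gq_i]))
                if dp_i is not None and dp_i < len(vals) and vals[dp_i] not in (".", ""):
                    dp = int(float(vals[dp_i]))
                call = GenotypeCall(call.allele_indices, call.phased, gq, dp)
            genotypes[sample] = call

    try:
        return VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alts=alts, ids=ids, qual=qual,
            filters=filters, info=info, genotypes=genotypes, source=source,
        )
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: {exc}") from exc


def _source_from_path(path: str | Path) -> str:
    name = Path(path).name
    for suffix in (".gz", ".vcf"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_vcf(path: str | Path, source: str | None = None) -> tuple[VcfHeader, Iterator[VariantRecord]]:
    """Read a VCF (plain or gzip); returns header and a record iterator.

    ``source`` overrides the caller label otherwise derived from the filename.
    Records are yielded in file order; no data line is silently dropped.
    """
    if source is None:
        source = _source_from_path(path)
    fh = _open_text(path)
    meta: list[str] = []
    samples: list[str] = []
    lineno = 0
    for line in fh:
        lineno += 1
        line = line.rstrip("\n")
        if line.startswith("##"):
            meta.append(line)
        elif line.startswith("#CHROM"):
            cols = line.split("\t")
            if len(cols) > 9:
                samples = cols[9:]
            elif len(cols) == 9:
                raise VcfParseError(f"line {lineno}: FORMAT column without samples")
            break
        elif line.startswith("#"):
            meta.append(line)
        else:
            raise VcfParseError(f"line {lineno}: data line before #CHROM header")
    header = VcfHeader(meta_lines=meta, samples=samples)

    def _records() -> Iterator[VariantRecord]:
        nonlocal lineno
        with fh:
            for raw in fh:
                lineno += 1
                if not raw.strip():
                    continue
                yield _parse_line(raw, lineno, samples, source)

    return header, _records()


def read_vcf_records(path: str | Path, source: str | None = None) -> tuple[VcfHeader, list[VariantRecord]]:
    header, it = read_vcf(path, source=source)
    return header, list(it)


# ---------------------------------------------------------------------------
# writing


def _format_qual(qual: float | None) -> str:
    if qual is None:
        return "."
    if float(qual).is_integer():
        return str(int(qual))
    return repr(float(qual))


def _format_info(info: dict[str, object]) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if value is True:
            parts.append(key)
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


def format_record(record: VariantRecord, samples: Sequence[str]) -> str:
    fields = [
        record.chrom,
        str(record.pos),
        ";".join(record.ids) if record.ids else ".",
        record.ref,
        ",".join(record.alts),
        _format_qual(record.qual),
        ";".join(record.filters) if record.filters is not None else ".",
        _format_info(record.info),
    ]
    if samples:
        calls = [record.genotypes.get(s, MISSING_CALL) for s in samples]
        has_gq = any(c.gq is not None for c in calls)
        has_dp = any(c.dp is not None for c in calls)
        fmt = ["GT"] + (["GQ"] if has_gq else []) + (["DP"] if has_dp else [])
        fields.append(":".join(fmt))
        for call in calls:
            cell = [call.to_vcf()]
            if has_gq:
                cell.append("." if call.gq is None else str(call.gq))
            if has_dp:
                cell.append("." if call.dp is None else str(call.dp))
            fields.append(":".join(cell))
    return "\t".join(fields)


def _check_sorted(records: Sequence[VariantRecord], genome: GenomeIndex | None) -> None:
    if genome is not None:
        keys = [genome.sort_key(r) for r in records]
    else:
        # without a genome index, chroms must form contiguous blocks in first-
        # appearance order and positions must be non-decreasing within a block
        order: dict[str, int] = {}
        for r in records:
            if r.chrom not in order:
                order[r.chrom] = len(order)
        keys = [(order[r.chrom], r.pos) for r in records]
    for i in range(1, len(keys)):
        if keys[i] < keys[i - 1]:
            a, b = records[i - 1], records[i]
            raise ValueError(
                f"records out of order: {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def write_vcf(
    header: VcfHeader,
    records: Sequence[VariantRecord],
    path: str | Path,
    genome: GenomeIndex | None = None,
) -> Path:
    """Write records (already genome-sorted) under the given header."""
    _check_sorted(records, genome)
    path = Path(path)
    samples = header.samples
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        columns += ["FORMAT", *samples]
    meta = header.meta_lines or ["##fileformat=VCFv4.2"]
    with open(path, "w", encoding="utf-8") as fh:
        for line in meta:
            fh.write(line + "\n")
        fh.write("\t".join(columns) + "\n")
        for record in records:
            fh.write(format_record(record, samples) + "\n")
    return path


# ---------------------------------------------------------------------------
# reference access


def open_fasta(path: str | Path) -> pyfaidx.Fasta:
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def fetch_reference(genome: pyfaidx.Fasta | str | Path, chrom: str, start: int, end: int) -> str:
    """Uppercase reference subsequence, 1-based inclusive coordinates."""
    if not isinstance(genome, pyfaidx.Fasta):
        genome = open_fasta(genome)
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} not in reference")
    length = len(genome[chrom])
    if not 1 <= start <= end <= length:
        raise ValueError(
            f"coordinates {chrom}:{start}-{end} out of bounds (contig length {length})"
        )
    return str(genome[chrom][start - 1 : end]).upper()


# ---------------------------------------------------------------------------
# PLINK PED/MAP export


@dataclass(frozen=True)
class TrioPedigree:
    """Father/mother/child sample IDs with sexes for PED export."""

    father: str
    mother: str
    child: str
    family_id: str = "FAM1"
    child_sex: int = 1  # 1 male, 2 female, 0 unknown

    @property
    def samples(self) -> tuple[str, str, str]:
        return (self.father, self.mother, self.child)


def write_ped_map(
    records: Sequence[VariantRecord],
    pedigree: TrioPedigree,
    ped_path: str | Path,
    map_path: str | Path,
) -> tuple[Path, Path]:
    """Export trio genotypes to PLINK PED/MAP text files.

    MAP rows: chrom, locus id, genetic distance 0, bp position. PED rows: the
    six pedigree columns then two allele columns per locus, missing as 0 0.
    Alleles are written as their sequences (so indels export their full
    ref/alt strings).
    """
    for rec in records:
        for sample in pedigree.samples:
            if sample not in rec.genotypes:
                raise KeyError(
                    f"sample {sample!r} absent at {rec.chrom}:{rec.pos}"
                )
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for rec in records:
            locus_id = rec.ids[0] if rec.ids else f"{rec.chrom}:{rec.pos}"
            fh.write(f"{rec.chrom}\t{locus_id}\t0\t{rec.pos}\n")

    rows = [
        (pedigree.father, "0", "0", "1"),
        (pedigree.mother, "0", "0", "2"),
        (pedigree.child, pedigree.father, pedigree.mother, str(pedigree.child_sex)),
    ]
    with open(ped_path, "w") as fh:
        for sample, pid, mid, sex in rows:
            cols = [pedigree.family_id, sample, pid, mid, sex, "-9"]
            for rec in records:
                call = rec.genotypes[sample]
                if call.is_missing:
                    cols += ["0", "0"]
                else:
                    cols += [rec.allele_seq(i) for i in call.alleles()]
            fh.write("\t".join(cols) + "\n")
    return ped_path, map_path
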