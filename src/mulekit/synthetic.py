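"""Seeded generators for reference genomes, multi-caller call sets and trios.

These generators produce the toolkit's demo and test inputs: a uniform
random reference FASTA, per-caller VCFs whose concordance structure is
fully known (a membership log records which caller carries which truth
variant), and a family-trio VCF with Mendelian errors injected at logged
loci. All randomness flows from one numpy PCG64 generator seeded from the
config, so every artifact is byte-reproducible.

Two constructions double as oracles for the rest of the toolkit:

* Indel representation jitter pads a normalized indel with matching
  reference bases (prepend the base at pos-1 / append the base following
  the ref allele) — the exact inverse of normalization, so the jittered
  record is haplotype-equivalent by construction and must normalize back
  to its canonical form.
* Mendelian error injection edits a child allele so the edited locus
  scores exactly one error of the logged class: a drop-in replaces an
  allele with one absent from both parents; a drop-out removes an
  obligate allele of a homozygous parent (requiring the replacement to
  remain parental, else the event would be a drop-in — when no locus
  structure admits a drop-out, a drop-in is injected instead so the total
  injected error rate is exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyfaidx

from .normalize import normalize_variant
from .vcf_io import (
    GenomeIndex,
    GenotypeCall,
    MISSING_CALL,
    VariantRecord,
    VcfHeader,
    write_vcf,
)

__all__ = [
    "CallerSpec",
    "TrioSpec",
    "SimulationConfig",
    "CallsetSim",
    "TrioSim",
    "TrioEvent",
    "simulate_reference",
    "simulate_callsets",
    "simulate_trio",
]

_BASES = np.array(list("ACGT"))

AF_META = '##INFO=<ID=AF,Number=A,Type=Float,Description="Annotated allele frequency">'


def _check_rate(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CallerSpec:
    """One simulated caller: how much of the truth it sees and how it writes it."""

    label: str
    sensitivity: float = 0.9
    false_positives: int = 0
    jitter: float = 0.0  # probability an indel is emitted in a padded form

    def __post_init__(self) -> None:
        _check_rate(f"{self.label}.sensitivity", self.sensitivity)
        _check_rate(f"{self.label}.jitter", self.jitter)
        if self.false_positives < 0:
            raise ValueError("false_positives must be >= 0")


@dataclass(frozen=True)
class TrioSpec:
    """Per-locus injection rates for the simulated trio."""

    adi_rate: float = 0.0
    ado_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        _check_rate("adi_rate", self.adi_rate)
        _check_rate("ado_rate", self.ado_rate)
        _check_rate("missing_rate", self.missing_rate)
        if self.adi_rate + self.ado_rate > 1.0:
            raise ValueError("adi_rate + ado_rate must not exceed 1")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    n_chrom: int = 2
    chrom_length: int = 100_000
    n_variants: int = 200
    snv_fraction: float = 0.8
    callers: tuple[CallerSpec, ...] = (
        CallerSpec("gatk", 0.9, 5, 0.5),
        CallerSpec("samtools", 0.9, 5, 0.5),
        CallerSpec("freebayes", 0.9, 5, 0.5),
        CallerSpec("varscan", 0.9, 5, 0.5),
    )
    trio: TrioSpec = TrioSpec()
    common_fraction: float = 0.3  # fraction of variants annotated MAF > 1%

    def __post_init__(self) -> None:
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if self.chrom_length < 1000:
            raise ValueError("chrom_length must be >= 1000")
        _check_rate("snv_fraction", self.snv_fraction)
        _check_rate("common_fraction", self.common_fraction)
        labels = [c.label for c in self.callers]
        if len(set(labels)) != len(labels):
            raise ValueError("caller labels must be unique")


def _rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


# ---------------------------------------------------------------------------
# reference


def simulate_reference(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a random reference FASTA plus its .fai; deterministic per seed."""
    rng = _rng(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "reference.fa"
    with open(fasta_path, "w") as fh:
        for i in range(config.n_chrom):
            seq = "".join(rng.choice(_BASES, size=config.chrom_length))
            fh.write(f">chr{i + 1}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    for ext in (".fai",):  # rebuild the index from scratch
        idx = Path(str(fasta_path) + ext)
        if idx.exists():
            idx.unlink()
    pyfaidx.Faidx(str(fasta_path))
    return fasta_path


# ---------------------------------------------------------------------------
# shared variant-site machinery

_SITE_SPACING = 40  # grid spacing; keeps normalized/jittered sites disjoint


def _site_grid(genome_index: GenomeIndex, margin: int = 20) -> list[tuple[str, int]]:
    grid = []
    for chrom, length in genome_index:
        grid.extend(
            (chrom, int(p))
            for p in range(margin, length - margin, _SITE_SPACING)
        )
    return grid


def _draw_positions(
    rng: np.random.Generator, grid: list[tuple[str, int]], n: int
) -> list[tuple[str, int]]:
    if n > len(grid):
        raise ValueError(
            f"cannot place {n} variants: only {len(grid)} candidate sites "
            "(increase chrom_length or lower n_variants)"
        )
    picks = rng.choice(len(grid), size=n, replace=False)
    sites = [grid[i] for i in picks]
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def _make_variant(
    rng: np.random.Generator,
    fasta: pyfaidx.Fasta,
    chrom: str,
    pos: int,
    is_snv: bool,
) -> VariantRecord:
    """Canonical (normalized) biallelic variant anchored near *pos*."""
    anchor = str(fasta[chrom][pos - 1]).upper()
    if is_snv:
        rec = VariantRecord(chrom, pos, anchor, [_other_base(rng, anchor)])
    else:
        length = int(rng.integers(1, 11))
        if rng.random() < 0.5:  # deletion
            ref = str(fasta[chrom][pos - 1 : pos - 1 + length + 1]).upper()
            rec = VariantRecord(chrom, pos, ref, [anchor])
        else:  # insertion
            ins = "".join(rng.choice(_BASES, size=length))
            rec = VariantRecord(chrom, pos, anchor, [anchor + ins])
    return normalize_variant(rec, fasta)


def _annotate_af(rng: np.random.Generator, rec: VariantRecord, common_fraction: float) -> None:
    u = rng.random()
    if u < common_fraction:
        rec.info["AF"] = f"{rng.uniform(0.011, 0.5):.4f}"
    elif u < common_fraction + (1 - common_fraction) / 2:
        rec.info["AF"] = f"{rng.uniform(0.0, 0.01):.4f}"
    # else unannotated: a novel variant


def _sample_call(rng: np.random.Generator) -> GenotypeCall:
    indices = (0, 1) if rng.random() < 0.7 else (1, 1)
    return GenotypeCall(indices, False, int(rng.integers(30, 100)), int(rng.integers(10, 60)))


# ---------------------------------------------------------------------------
# representation jitter (inverse of normalization)


def pad_representation(
    rec: VariantRecord,
    fasta: pyfaidx.Fasta,
    left: int = 0,
    right: int = 0,
) -> VariantRecord:
    """Reference-pad a record: haplotype-equivalent, un-normalized form.

    Appending the reference base that follows the ref allele to every
    allele (right pad) or prepending the base at pos-1 (left pad) never
    changes the described haplotypes; normalization undoes both exactly.
    """
    chrom_len = len(fasta[rec.chrom])
    pos, ref, alts = rec.pos, rec.ref, list(rec.alts)
    for _ in range(right):
        nxt = pos + len(ref)
        if nxt > chrom_len:
            break
        base = str(fasta[rec.chrom][nxt - 1]).upper()
        ref += base
        alts = [a + base for a in alts]
    for _ in range(left):
        if pos == 1:
            break
        base = str(fasta[rec.chrom][pos - 2]).upper()
        ref = base + ref
        alts = [base + a for a in alts]
        pos -= 1
    return rec.copy(pos=pos, ref=ref, alts=alts)


# ---------------------------------------------------------------------------
# multi-caller call sets


@dataclass
class CallsetSim:
    truth_path: Path
    truth_records: list[VariantRecord]
    caller_paths: dict[str, Path]
    membership: dict[tuple[str, int], frozenset[str]]  # truth (chrom,pos) -> callers
    false_positives: dict[str, list[VariantRecord]]


def simulate_callsets(
    config: SimulationConfig, reference: str | Path, out_dir: str | Path
) -> CallsetSim:
    """Generate truth + per-caller VCFs with known concordance structure.

    Each caller carries each truth variant with its sensitivity, plus its
    own false positives at fresh sites; with its jitter probability an
    indel is written in a padded (un-normalized) representation. The
    membership log is the ground truth for every downstream concordance
    and consensus computation.
    """
    rng = _rng(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = pyfaidx.Fasta(str(reference), sequence_always_upper=True)
    genome_index = GenomeIndex.from_fasta(reference)
    grid = _site_grid(genome_index)

    n_fp = sum(c.false_positives for c in config.callers)
    sites = _draw_positions(rng, grid, config.n_variants + n_fp)
    truth_sites, fp_sites = sites[: config.n_variants], sites[config.n_variants :]
    fp_order = rng.permutation(len(fp_sites))

    truth_records = []
    for chrom, pos in truth_sites:
        rec = _make_variant(rng, fasta, chrom, pos, rng.random() < config.snv_fraction)
        rec.qual = float(int(rng.integers(30, 100)))
        rec.filters = ["PASS"]
        rec.genotypes = {"SAMPLE": _sample_call(rng)}
        _annotate_af(rng, rec, config.common_fraction)
        truth_records.append(rec)
    truth_records.sort(key=genome_index.sort_key)
    if len({(r.chrom, r.pos) for r in truth_records}) != len(truth_records):
        raise RuntimeError("normalized truth positions collided; widen site spacing")

    header = VcfHeader.minimal(["SAMPLE"], extra_meta=[AF_META], genome=genome_index)
    truth_path = out_dir / "truth.vcf"
    write_vcf(header, truth_records, truth_path, genome=genome_index)

    membership: dict[tuple[str, int], set[str]] = {
        (r.chrom, r.pos): set() for r in truth_records
    }
    caller_paths: dict[str, Path] = {}
    fp_log: dict[str, list[VariantRecord]] = {}
    fp_cursor = 0
    for spec in config.callers:
        records = []
        for rec in truth_records:
            if rng.random() >= spec.sensitivity:
                continue
            membership[(rec.chrom, rec.pos)].add(spec.label)
            out = rec.copy(source=spec.label, qual=float(int(rng.integers(30, 100))))
            if not rec.is_snv and rng.random() < spec.jitter:
                left = int(rng.integers(0, 3))
                right = int(rng.integers(0, 3))
                if left == right == 0:
                    right = 1
                out = pad_representation(out, fasta, left=left, right=right)
            records.append(out)
        fps = []
        for _ in range(spec.false_positives):
            chrom, pos = fp_sites[fp_order[fp_cursor]]
            fp_cursor += 1
            fp = _make_variant(rng, fasta, chrom, pos, rng.random() < config.snv_fraction)
            fp.qual = float(int(rng.integers(30, 100)))
            fp.filters = ["PASS"]
            fp.genotypes = {"SAMPLE": _sample_call(rng)}
            fp.source = spec.label
            fps.append(fp)
        records.extend(fps)
        records.sort(key=genome_index.sort_key)
        path = out_dir / f"{spec.label}.vcf"
        write_vcf(header, records, path, genome=genome_index)
        caller_paths[spec.label] = path
        fp_log[spec.label] = fps

    return CallsetSim(
        truth_path=truth_path,
        truth_records=truth_records,
        caller_paths=caller_paths,
        membership={k: frozenset(v) for k, v in membership.items()},
        false_positives=fp_log,
    )


# ---------------------------------------------------------------------------
# trio


@dataclass(frozen=True)
class TrioEvent:
    chrom: str
    pos: int
    kind: str  # "adi" | "ado"
    masked: bool  # True if the locus lost a genotype to missingness


@dataclass
class TrioSim:
    vcf_path: Path
    records: list[VariantRecord]
    events: list[TrioEvent]

    @property
    def visible_events(self) -> list[TrioEvent]:
        return [e for e in self.events if not e.masked]

    def visible_counts(self) -> tuple[int, int]:
        adi = sum(1 for e in self.visible_events if e.kind == "adi")
        ado = sum(1 for e in self.visible_events if e.kind == "ado")
        return adi, ado


def _novel_alt(rng: np.random.Generator, rec: VariantRecord) -> str:
    """An allele sequence distinct from ref and every existing alt."""
    if rec.is_snv:
        return _other_base(rng, rec.ref, *rec.alts)
    for base in "ACGT":
        for candidate in (rec.ref[0] + base, rec.ref[0] + base + base):
            if candidate != rec.ref and candidate not in rec.alts:
                return candidate
    raise RuntimeError("could not construct a novel allele")


def simulate_trio(
    config: SimulationConfig, reference: str | Path, out_dir: str | Path
) -> TrioSim:
    """Generate a FATHER/MOTHER/CHILD VCF with logged Mendelian errors.

    Parents draw genotypes from a per-site allele frequency; the child
    inherits one allele from each parent. Per locus, with probability
    adi_rate an allele drop-in is injected and with probability ado_rate a
    drop-out (falling back to drop-in where the genotypes admit none), so
    injected events occur at rate adi_rate + ado_rate exactly. Genotypes
    are then masked missing at missing_rate; the event log records whether
    each injected locus survived masking.
    """
    rng = _rng(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = pyfaidx.Fasta(str(reference), sequence_always_upper=True)
    genome_index = GenomeIndex.from_fasta(reference)
    sites = _draw_positions(rng, _site_grid(genome_index), config.n_variants)
    spec = config.trio

    records: list[VariantRecord] = []
    events: list[TrioEvent] = []
    for chrom, pos in sites:
        rec = _make_variant(rng, fasta, chrom, pos, rng.random() < config.snv_fraction)
        _annotate_af(rng, rec, config.common_fraction)
        q = rng.uniform(0.2, 0.8)  # alt allele frequency at this site
        father = tuple(int(rng.random() < q) for _ in range(2))
        mother = tuple(int(rng.random() < q) for _ in range(2))
        child = [father[int(rng.integers(2))], mother[int(rng.integers(2))]]

        u = rng.random()
        kind = None
        if u < spec.adi_rate:
            kind = "adi"
        elif u < spec.adi_rate + spec.ado_rate:
            kind = "ado"

        if kind == "ado":
            # drop an obligate allele of a homozygous parent; the replacement
            # (the child's other-parent allele) must differ from it and stays
            # parental, so the locus scores exactly one drop-out
            eligible = []
            if father[0] == father[1] and child[1] != father[0]:
                eligible.append(0)  # replace the paternal transmission
            if mother[0] == mother[1] and child[0] != mother[0]:
                eligible.append(1)
            if eligible:
                slot = eligible[int(rng.integers(len(eligible)))]
                child[slot] = child[1 - slot]
            else:
                kind = "adi"

        if kind == "adi":
            parental = set(father) | set(mother)
            if parental == {0, 1}:
                rec.alts = rec.alts + [_novel_alt(rng, rec)]
                novel = len(rec.alts)  # index of the appended allele
            else:
                novel = 1 - next(iter(parental))
            child[int(rng.integers(2))] = novel

        calls = {}
        masked = False
        for name, alleles in (("FATHER", father), ("MOTHER", mother), ("CHILD", tuple(child))):
            if rng.random() < spec.missing_rate:
                calls[name] = MISSING_CALL
                masked = True
            else:
                calls[name] = GenotypeCall(
                    (alleles[0], alleles[1]), False,
                    int(rng.integers(30, 100)), int(rng.integers(10, 60)),
                )
        rec.genotypes = calls
        if kind is not None:
            events.append(TrioEvent(rec.chrom, rec.pos, kind, masked))
        records.append(rec)

    records.sort(key=genome_index.sort_key)
    header = VcfHeader.minimal(["FATHER", "MOTHER", "CHILD"], extra_meta=[AF_META], genome=genome_index)
    vcf_path = Path(out_dir) / "trio.vcf"
    write_vcf(header, records, vcf_path, genome=genome_index)
    return TrioSim(vcf_path=vcf_path, records=records, events=events)
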