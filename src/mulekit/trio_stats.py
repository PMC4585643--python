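"""Trio Mendelian error statistics: allele drop-in/drop-out, IBS, error rate.

A *trio call* is a locus genotyped (non-missing) in father, mother and
child; only trio calls enter any tally. At each trio call the child's two
alleles are checked against the four possible transmissions (one allele
from each parent); the transmission minimizing mismatches is taken, and
each irreconcilable child allele counts as one Mendelian error event:

* allele drop-in (ADI)  — the child allele appears in neither parent;
* allele drop-out (ADO) — the child allele is parental, so the real
  violation is a missed obligate transmission.

The classification is well defined: a child allele matchable under *some*
transmission necessarily occurs in a parent, so under any mismatch-minimal
transmission the set of truly-novel unmatched alleles is the same, and
every other unmatched allele is parental (ADO) regardless of which optimal
transmission is chosen.

The Mendelian error rate is (ADI + ADO) / number of trio calls. IBS
(identical-by-state) counts per parent the size of the multiset
intersection of child and parent alleles (0, 1 or 2).

All chromosomes are treated as autosomal diploid; the rare-variant view
(`maf_stratified_rate`) keeps loci whose INFO allele-frequency annotation
is at most the threshold or absent (absent = novel).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .var_stats import record_af
from .vcf_io import GenotypeCall, TrioPedigree, VariantRecord, read_vcf_records

__all__ = [
    "TrioCounts",
    "locus_mendel",
    "ibs_with_parent",
    "trio_summary",
    "maf_stratified_rate",
]


@dataclass
class TrioCounts:
    n_trio_calls: int = 0
    adi: int = 0
    ado: int = 0
    ibs_father: Counter = field(default_factory=Counter)
    ibs_mother: Counter = field(default_factory=Counter)

    @property
    def n_errors(self) -> int:
        return self.adi + self.ado

    @property
    def error_rate(self) -> float | None:
        """(ADI + ADO) / trio calls; None when there are no trio calls."""
        if self.n_trio_calls == 0:
            return None
        return self.n_errors / self.n_trio_calls


def _require_call(call: GenotypeCall, who: str) -> tuple[int, int]:
    if call.is_missing:
        raise ValueError(f"{who} genotype is missing; trio loci must be pre-filtered")
    return call.alleles()


def locus_mendel(
    father: GenotypeCall, mother: GenotypeCall, child: GenotypeCall
) -> tuple[int, int]:
    """Mendelian error events at one locus, as (adi, ado)."""
    f = _require_call(father, "father")
    m = _require_call(mother, "mother")
    c = _require_call(child, "child")
    parental = set(f) | set(m)
    child_ms = Counter(c)

    best_unmatched: Counter | None = None
    best_k = 3
    for fa in f:
        for ma in m:
            unmatched = child_ms - Counter((fa, ma))
            k = sum(unmatched.values())
            if k < best_k:
                best_k, best_unmatched = k, unmatched
    adi = sum(n for allele, n in best_unmatched.items() if allele not in parental)
    return adi, best_k - adi


def ibs_with_parent(child: GenotypeCall, parent: GenotypeCall) -> int:
    """Alleles shared by state (multiset intersection size), in {0, 1, 2}."""
    c = Counter(_require_call(child, "child"))
    p = Counter(_require_call(parent, "parent"))
    return sum((c & p).values())


def trio_summary(
    vcf: str | Path | Sequence[VariantRecord], pedigree: TrioPedigree
) -> TrioCounts:
    """Scan a multi-sample VCF and accumulate trio Mendelian statistics.

    Loci where any trio member is missing are excluded from every tally.
    """
    if isinstance(vcf, (str, Path)):
        header, records = read_vcf_records(vcf)
        for sample in pedigree.samples:
            if sample not in header.samples:
                raise KeyError(f"sample {sample!r} not in VCF header {header.samples}")
    else:
        records = list(vcf)

    counts = TrioCounts()
    for rec in records:
        calls = [rec.genotypes.get(s) for s in pedigree.samples]
        if any(c is None or c.is_missing for c in calls):
            continue
        father, mother, child = calls
        adi, ado = locus_mendel(father, mother, child)
        counts.n_trio_calls += 1
        counts.adi += adi
        counts.ado += ado
        counts.ibs_father[ibs_with_parent(child, father)] += 1
        counts.ibs_mother[ibs_with_parent(child, mother)] += 1
    return counts


def maf_stratified_rate(
    vcf: str | Path | Sequence[VariantRecord],
    pedigree: TrioPedigree,
    af_key: str = "AF",
    threshold: float = 0.01,
) -> TrioCounts:
    """Trio statistics restricted to rare/novel variants.

    Keeps loci whose *af_key* INFO annotation is <= *threshold* or absent
    (unannotated variants are treated as novel and kept); the common
    remainder is discarded, mirroring a MAF > threshold filter.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if isinstance(vcf, (str, Path)):
        header, records = read_vcf_records(vcf)
        for sample in pedigree.samples:
            if sample not in header.samples:
                raise KeyError(f"sample {sample!r} not in VCF header {header.samples}")
    else:
        records = list(vcf)
    rare = [
        rec
        for rec in records
        if (af := record_af(rec, af_key)) is None or af <= threshold
    ]
    return trio_summary(rare, pedigree)
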