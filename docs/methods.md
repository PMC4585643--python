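# Methods

This note records the definitions, algorithms and design choices behind
`mulekit`, and what the synthetic-data tests do and do not establish about
real sequencing data.

## Data model

A `VariantRecord` is one VCF data line: chrom, 1-based pos, ref, an ordered
deduplicated alt list, qual, filters, INFO map, per-sample genotypes, and a
`source` label naming the originating caller. A record is an **SNV** iff
ref and every alt are single bases; everything else (primarily indels) is
**non-SNV**. This record-level split decides which merge key and which
overlap rule applies.

Genotypes are diploid pairs of allele indices. Haploid calls (`1`) are
promoted to homozygous diploid on read with a warning — the trio statistics
assume two alleles per individual — and ploidy > 2 is an error. A partially
missing call (`./1`) is treated as missing, since every downstream
statistic needs both alleles. Symbolic alts (`<DEL>`, breakends) are
rejected: all merge and normalization rules operate on sequence alleles.
FILTER `.` and `PASS` both count as "unfiltered" for the PASS-propagation
rule; any other value means filtered. Chromosome names match exactly (no
`chr` aliasing — silent aliasing corrupts merges). VCF positions are
1-based; all BED output is 0-based half-open.

Known limitation: sex chromosomes are treated as autosomal diploid; there
is no hemizygosity rule. Users analyzing chrX/chrY trios should interpret
the ADI/ADO tallies there with care.

## Variant normalization

Different callers write the same indel at different coordinates. To make
equivalent calls compare equal, every record is rewritten to its leftmost
minimal representation by operating jointly on the allele set
{ref} ∪ alts:

1. while all alleles end in the same base, drop that base; if an allele
   empties, prepend the reference base at pos−1 to every allele and
   decrement pos (error if pos is already 1);
2. while all alleles start with the same base and all have length ≥ 2,
   drop that base and increment pos.

Records are not split into biallelics — merging operates on whole records,
so multiallelic alleles must trim together. `N` participates in trimming
like any fixed base. SNVs are no-ops. The procedure is idempotent and
exactly inverts reference-padding, which is how the synthetic generator
manufactures representation jitter (pad a canonical indel left/right with
matching reference bases). Normalization runs once on all inputs before
any merging; for SNVs this is harmless, for indels it is what makes merge
keys collide correctly. The test suite cross-checks the output against
`bcftools norm` record-for-record on simulated jittered call sets.

## Consensus merging

Overlap keys: SNVs overlap when (chrom, pos) agree; non-SNVs overlap when
(chrom, pos, ref) agree. Within a key, records are ordered by caller
priority (GATK > SAMtools > FreeBayes > VarScan > SOAPsnp, unknown labels
after those in input order), and:

- chrom/pos/ref come from the first record and never change;
- alts are pooled in priority-then-appearance order, deduplicated;
- qual and genotypes (with GQ) come from the first record, genotype allele
  indices remapped onto the pooled alt list (conflict-free, as genotypes
  come from a single source record);
- FILTER is PASS iff any input record is unfiltered, else the union of
  observed filter names;
- provenance goes to INFO tags `CALLERS`/`NCALLERS`, which make M-of-N
  extraction re-runnable from the merged file alone.

Consensus membership is counted at key level, not per allele: a file
"contains" a call if it has any record with that key. The M-of-N output is
monotone by construction (output(m+1) ⊆ output(m)); m=1 is the union.

Multi-sample inputs are split into per-sample call streams, merged
per sample, then recombined into one multi-sample VCF over the union of
loci, with missing genotypes where a sample has no call. At a shared key
the recombined alts pool across samples in sample order and qual/filters
come from the per-sample merge whose top supporter has the highest caller
priority; supporters are the union. The merged (normalized) representation
is what appears in output.

Out of scope by design: genotype reconciliation across callers
(majority-vote genotypes), INFO unification beyond provenance, gVCF.

## Trio Mendelian statistics

A **trio call** is a locus genotyped in father, mother and child; loci with
any missing member are excluded from every tally. At each trio call the
four possible transmissions (one allele from each parent) are enumerated;
the transmission minimizing mismatches against the child's allele multiset
is taken, and each of the k unmatched child alleles (k ∈ {0,1,2}) is one
error event:

- **ADI** if the allele occurs in neither parent's genotype,
- **ADO** otherwise (the allele is parental; the irreconcilable part is a
  missed obligate transmission).

The classification does not depend on which mismatch-minimal transmission
is chosen: an allele matchable under *some* transmission necessarily occurs
in a parent, so the truly-novel unmatched alleles are identical across all
optima and every other unmatched allele is parental. One unmatched pair is
one error — ADI and ADO are never double-counted for the same event — so
ADI + ADO equals the number of irreconcilable alleles, and a locus can
contribute up to 2 errors. The error rate is (ADI + ADO) / trio calls,
undefined (reported missing) when there are no trio calls.

IBS with a parent is the multiset intersection size of the two genotypes'
alleles (0, 1 or 2), tallied per parent as a histogram over trio calls.
The implementation is validated against exhaustive enumeration of all
transmissions and matchings on every biallelic (27 combinations) and
triallelic trio genotype configuration.

The rare-variant view keeps loci whose INFO allele-frequency annotation
(e.g. `AF`) is ≤ the threshold (default 1%) **or absent** — unannotated
variants are treated as novel. Frequencies are read, never recomputed;
multiallelic annotations reduce to their maximum.

## Concordance (Venn) analysis

SNVs are partitioned by exact (chrom, pos, ref, alt) keys, one key per alt
allele of a multiallelic record. Non-SNVs, after normalization, are
**intervalized**: the record reduces to its position extended 10 bp toward
both ends, the closed interval [pos−10, pos+10]. (The alternative reading —
span of the ref allele ±10 — is a one-function swap in
`overlap.nonsnv_intervals`.) Interval overlap is not transitive, so
overlapping non-SNVs are clustered by single linkage (connected components
of the pairwise overlap graph, computed by a genome-order sweep) and one
cluster is one Venn unit, assigned to the region of the sources present in
it. The concordance rate is 100 × (all-sources region) / (all units); the
denominator is the union, not a mean set size. Counts are the tested
artifact; no diagram image is rendered.

## Binning and scheduling

Bin size is ceil(total_bp / N) clamped to [50 kbp, 1 Mbp] (both bounds
overridable). The clamp bounds are the load-balancing compromise: bins
large enough to amortize per-process overhead, small enough to stay
fine-grained; the formula gives one bin per process for small inputs and
max-size bins for genome-scale ones. Regions are chopped left-to-right;
only the last bin of a region may be short; bins never cross region or
chromosome boundaries, and their union is bp-exact. Rotation assignment is
process = global_index mod N — the minimal rule guaranteeing adjacent bins
go to different processes, which spreads coverage hot-spots across workers.
One BED file per process is written; together they partition the input.
The correctness contract is scatter/gather equivalence: any per-region
computation summed over the N BEDs equals the whole-region answer.

Pipeline tasks form a DAG (prerequisite → dependent). `topo_order` uses
lexicographic topological sorting (deterministic; ties broken by task id)
and reports a concrete cycle on failure. `run_graph` executes up to
`max_parallel` runnable tasks (all prerequisites finished) at a time,
persisting a line-oriented status file (`task_id TAB status TAB command`)
after every state change; a re-invocation skips finished tasks, re-runs
interrupted ones, and a corrupt status file is an error rather than a
silent restart. On failure no new task starts and dependents stay waiting.
The executor is an injected callable; only local (thread) execution ships —
no cluster submission.

## Synthetic data

The generators emulate the discordance structure of multi-caller analyses
and the error structure of trio studies, with one numpy PCG64 RNG per run
(fully deterministic per seed, platform-stable).

- **Reference**: uniform random A/C/G/T contigs (default 2 × 100 kb).
- **Call sets**: truth variants (default 200; 80% SNVs, indels 1–10 bp) at
  distinct normalized positions on a 40 bp site grid — wide enough that
  normalization shifts and ±10 bp intervalization never collide across
  sites. Each caller (default four, at 90% sensitivity, 5 private false
  positives, 50% jitter — discordance of the magnitude seen between real
  callers) carries each truth variant independently with its sensitivity;
  indels are emitted reference-padded with the jitter probability. The
  membership log is exact ground truth for concordance and consensus.
- **Trio**: parents draw genotypes from a per-site allele frequency
  ~U(0.2, 0.8); the child inherits one allele from each parent. Per locus,
  one error is injected with probability adi_rate + ado_rate. An ADI
  replaces a child allele with one absent from both parents (adding a
  third allele to the site when the parents jointly carry both existing
  ones). An ADO requires a homozygous parent a/a and a child whose other
  allele c ≠ a; the transmitted a is replaced by c. A short argument shows
  each injected event scores exactly one error of its class under the
  min-mismatch rule: for ADO the transmitted pair always contains the
  unmatched obligate allele a ∉ {b, c}, leaving exactly one parental
  unmatched child allele; for ADI the novel allele is unmatched under
  every transmission while the remaining allele is parental and matchable.
  When a locus admits no ADO (no obligate allele can be dropped), an ADI
  is injected instead, so the total injected error rate is exactly the
  configured sum; the log records what was actually injected and whether
  the locus later lost a genotype to missingness (default 2% per
  genotype).

What passing tests show — and what they do not: the simulators exercise
representation ambiguity, caller discordance, Mendelian violations and
missingness, so they validate the *bookkeeping and algorithms* end to end.
They do not model read-level noise, alignment artifacts, coverage-dependent
genotype quality, linkage, or locus-dependent error rates; measured
concordance or error rates on real data will differ from the simulated
values even when the algorithms are correct.

## Numerical and procedural choices

- Problem sizes in tests and the acceptance script (20,000 trio loci,
  10,000 truth variants for the binomial check, 1,000 jittered indels, 20
  consensus trials) give standard errors comfortably below the asserted
  tolerances (e.g. 3 SE ≈ 0.3 percentage points for the 2% trio rate) while
  keeping a full run under a minute on one core.
- Statistical assertions use 3-standard-error bands; set-valued and
  conservation assertions are exact.
- Degenerate inputs: empty VCFs round-trip; an empty union yields a
  missing concordance rate; zero trio calls yield a missing error rate;
  Ti/Tv is missing when no transversion is seen; het/hom is missing when
  no hom-alt genotype is seen.
- Ti/Tv counts each alt allele of a multiallelic SNV independently;
  "homozygote" in het/hom means hom-alt only.
- Merged VCF qual/genotype provenance is resolved per key by caller
  priority, not by global file order, so permuting input files never
  changes the output.
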