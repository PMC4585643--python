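# mulekit

Multi-caller variant-calling pipelines disagree: the same sample run through
GATK, SAMtools, FreeBayes and VarScan yields call sets with substantial
discordance, concentrated in indels (whose VCF representation is ambiguous)
and in rare variants. `mulekit` is a toolkit for the computational stages
that sit *around* the callers in such a pipeline:

- **Variant normalization** — left-align and trim indel alleles to the
  unique minimal representation, so `TGGG>TGG` and `TG>T` (the same one-G
  deletion) compare equal.
- **Consensus merging** — merge per-caller VCFs by overlap key (SNVs:
  chromosome + position; non-SNVs: chromosome + position + reference
  allele), pool alternate alleles, keep QUAL/genotype from the
  highest-priority caller (GATK > SAMtools > FreeBayes > VarScan > SOAPsnp),
  mark PASS iff any input left the call unfiltered, and extract *M-of-N*
  consensus call sets (calls supported by at least M of N callers).
- **Trio Mendelian statistics** — for a father/mother/child VCF, count
  allele drop-ins (ADI: a child allele present in neither parent), allele
  drop-outs (ADO: a missed obligate transmission), per-parent IBS
  histograms, and the Mendelian error rate
  (ADI + ADO) / (loci genotyped in all three members), optionally
  restricted to rare variants (annotated MAF ≤ 1% or unannotated).
- **Concordance / Venn analysis** — partition 2–5 call sets into Venn
  regions (SNVs by exact chrom/pos/ref/alt key; non-SNVs as ±10 bp
  intervals clustered by single linkage) and report the fraction shared by
  all sets.
- **Call-set statistics** — Ti/Tv ratio, het/hom-alt ratio, MAF filtering,
  PLINK PED/MAP export.
- **Cluster-free parallelization** — split the genome into equally sized
  bins (dynamic size clamped to [50 kbp, 1 Mbp]), assign bins to N worker
  processes by rotation so adjacent bins never share a process, write one
  BED per process; order pipeline tasks by topological sort of their
  dependency graph and execute them resumably through a persisted status
  file.
- **Synthetic data** — seeded generators for reference FASTA, multi-caller
  call sets with controlled sensitivity/false positives/representation
  jitter, and trio VCFs with logged Mendelian-error injections; the logs
  are ground truth for every statistic above.

## Worked example

Simulate a 2 × 100 kb genome with four callers at 90% sensitivity, 5 false
positives each, and 50% indel-representation jitter, then merge and analyze:

```bash
mulekit simulate --preset callers --seed 42 --out demo
mulekit merge --vcf gatk=demo/gatk.vcf --vcf samtools=demo/samtools.vcf \
              --vcf freebayes=demo/freebayes.vcf --vcf varscan=demo/varscan.vcf \
              --ref demo/reference.fa --out demo/merged.vcf
# -> merged 4 call sets into 220 records -> demo/merged.vcf
mulekit consensus --merged demo/merged.vcf -m 2 --out demo/cons2.vcf
# -> 199 consensus calls (m=2) -> demo/cons2.vcf
```

220 merged records are the union of 200 truth variants recovered by at
least one caller plus 20 caller-specific false positives; requiring support
from ≥ 2 of 4 callers drops every false positive and keeps 199 of the 200
truth variants (at 90% sensitivity the expected 2-of-4 recovery is the
binomial tail P(X ≥ 2) = 99.63%).

```bash
mulekit venn --vcf gatk=demo/gatk.vcf --vcf samtools=demo/samtools.vcf \
             --ref demo/reference.fa --out demo/venn
# -> snv: 159 units, concordance 76.10% -> demo/venn.snv.tsv
# -> nonsnv: 48 units, concordance 77.08% -> demo/venn.nonsnv.tsv
```

Two independent 90%-sensitive callers with private false positives share
roughly 0.9·0.9 of the truth plus nothing else, hence ~76% concordance.

```bash
mulekit simulate --preset trio --seed 42 --out trio
mulekit trio-stats --vcf trio/trio.vcf --father FATHER --mother MOTHER --child CHILD
# metric  value
# trio_calls      192
# adi     2
# ado     1
# mendel_error_rate_pct   1.5625
# ibs_father_0    2
# ...
```

192 of 200 simulated loci are genotyped in all three members (2% missing
rate per genotype); the three injected errors (2 drop-ins, 1 drop-out,
injection rate 1% + 1%) are recovered exactly, giving 3/192 = 1.56%.

Equivalent library calls live in `mulekit.consensus`, `mulekit.trio_stats`,
`mulekit.overlap`, `mulekit.binning`, `mulekit.scheduler` and
`mulekit.synthetic`; see `docs/methods.md` for the underlying definitions.

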