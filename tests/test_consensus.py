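"""Merging, priority, PASS propagation and M-of-N consensus extraction."""

from itertools import permutations

import numpy as np
import pytest

from mulekit.consensus import (
    caller_priority,
    extract_consensus,
    extract_consensus_file,
    merge_key,
    merge_records,
    merge_vcfs,
    split_and_recombine,
)
from mulekit.synthetic import (
    CallerSpec,
    SimulationConfig,
    pad_representation,
    simulate_callsets,
    simulate_reference,
)
from mulekit.vcf_io import (
    GenotypeCall,
    VariantRecord,
    VcfHeader,
    fetch_reference,
    read_vcf_records,
    write_vcf,
)


class TestCallerPriority:
    def test_known_callers_ordered(self):
        assert caller_priority(["varscan", "gatk", "samtools"]) == [
            "gatk", "samtools", "varscan",
        ]

    def test_singleton(self):
        assert caller_priority(["freebayes"]) == ["freebayes"]

    def test_unknown_labels_stable(self):
        assert caller_priority(["customcallerB", "customcallerA"]) == [
            "customcallerB", "customcallerA",
        ]

    def test_unknowns_follow_knowns(self):
        assert caller_priority(["myCaller", "soapsnp", "gatk"]) == [
            "gatk", "soapsnp", "myCaller",
        ]


def _snv(pos, alts, qual=None, filters=None, source=None, gt=(0, 1), gq=None):
    return VariantRecord(
        "chr1", pos, "A", list(alts), qual=qual, filters=filters, source=source,
        genotypes={"S": GenotypeCall(gt, gq=gq)},
    )


class TestMergeRecords:
    def test_alt_pooling_qual_and_pass_rule(self):
        r1 = _snv(100, ["G"], qual=50, filters=["LowQual"], source="f1", gq=40)
        r2 = _snv(100, ["T"], qual=30, filters=["PASS"], source="f2")
        merged = merge_records([r1, r2])
        rec = merged.record
        assert rec.alts == ["G", "T"]
        assert rec.qual == 50  # from the first (priority-ordered) input
        assert rec.genotypes["S"].gq == 40
        assert rec.filters == ["PASS"]  # unfiltered in at least one input
        assert merged.supporters == {"f1", "f2"}

    def test_all_filtered_unions_filter_names(self):
        r1 = _snv(100, ["G"], filters=["LowQual"], source="f1")
        r2 = _snv(100, ["G"], filters=["q10", "LowQual"], source="f2")
        assert merge_records([r1, r2]).record.filters == ["LowQual", "q10"]

    def test_identical_records_pool_idempotently(self):
        r1 = _snv(100, ["G"], qual=9, filters=["PASS"], source="f1")
        r2 = _snv(100, ["G"], qual=9, filters=["PASS"], source="f2")
        merged = merge_records([r1, r2])
        assert merged.record.alts == ["G"]
        assert merged.n_supporters == 2

    def test_single_record_is_identity(self):
        r1 = _snv(100, ["G"], qual=7, filters=["PASS"], source="only")
        merged = merge_records([r1])
        assert merged.record.alts == ["G"] and merged.supporters == {"only"}

    def test_genotype_indices_remapped_to_pooled_alts(self):
        # first record's alt T must keep pointing at T after pooling
        r1 = _snv(100, ["T"], source="f1", gt=(1, 1))
        r2 = _snv(100, ["G", "T"], source="f2")
        merged = merge_records([r1, r2])
        rec = merged.record
        assert rec.alts == ["T", "G"]
        assert rec.genotypes["S"].allele_indices == (1, 1)
        assert rec.alts[rec.genotypes["S"].allele_indices[0] - 1] == "T"

    def test_mixed_keys_rejected(self):
        r1 = _snv(100, ["G"])
        r2 = _snv(101, ["G"])
        with pytest.raises(ValueError, match="multiple merge keys"):
            merge_records([r1, r2])


class TestMergeKeys:
    def test_snv_key_ignores_ref_nonsnv_key_keeps_it(self):
        snv = VariantRecord("chr1", 100, "A", ["G"])
        indel = VariantRecord("chr1", 100, "AT", ["A"])
        assert merge_key(snv) == ("snv", "chr1", 100)
        assert merge_key(indel) == ("nonsnv", "chr1", 100, "AT")
        assert merge_key(snv) != merge_key(indel)


@pytest.fixture
def two_caller_files(tmp_path, reference, fasta, genome_index):
    """file1: 3 SNVs; file2: 2 of them plus the same deletion in jittered form."""

    def ref_at(pos, span=1):
        return fetch_reference(fasta, "chr1", pos, pos + span - 1)

    def snv(pos):
        ref = ref_at(pos)
        alt = "A" if ref != "A" else "G"
        return VariantRecord("chr1", pos, ref, [alt], qual=50.0, filters=["PASS"],
                             genotypes={"S": GenotypeCall((0, 1))})

    deletion = VariantRecord("chr1", 5000, ref_at(5000, 3), [ref_at(5000)],
                             qual=40.0, filters=["PASS"],
                             genotypes={"S": GenotypeCall((0, 1))})
    from mulekit.normalize import normalize_variant

    canon = normalize_variant(deletion, fasta)
    jittered = pad_representation(canon, fasta, left=1, right=1)

    f1 = sorted([snv(1000), snv(2000), snv(3000), canon], key=genome_index.sort_key)
    f2 = sorted([snv(2000), snv(3000), jittered], key=genome_index.sort_key)
    h = VcfHeader.minimal(["S"])
    p1 = write_vcf(h, f1, tmp_path / "c1.vcf", genome=genome_index)
    p2 = write_vcf(h, f2, tmp_path / "c2.vcf", genome=genome_index)
    return p1, p2, canon


class TestMergeVcfs:
    def test_jittered_deletion_merges_to_one_key(self, tmp_path, reference, two_caller_files):
        p1, p2, canon = two_caller_files
        merged = merge_vcfs([(p1, "c1"), (p2, "c2")], reference, out=tmp_path / "m.vcf")
        assert len(merged) == 4  # 3 SNVs + 1 shared deletion
        dels = [m for m in merged if not m.record.is_snv]
        assert len(dels) == 1
        assert dels[0].supporters == {"c1", "c2"}
        assert (dels[0].record.pos, dels[0].record.ref) == (canon.pos, canon.ref)

    def test_provenance_tags_written(self, tmp_path, reference, two_caller_files):
        p1, p2, _ = two_caller_files
        out = tmp_path / "m.vcf"
        merged = merge_vcfs([(p1, "c1"), (p2, "c2")], reference, out=out)
        _, records = read_vcf_records(out)
        assert [int(r.info["NCALLERS"]) for r in records] == [
            m.n_supporters for m in merged
        ]
        assert all(
            set(str(r.info["CALLERS"]).split(",")) == set(m.supporters)
            for r, m in zip(records, merged)
        )

    def test_snv_and_indel_at_same_position_stay_separate(
        self, tmp_path, reference, fasta, genome_index
    ):
        pos = 7000
        ref3 = fetch_reference(fasta, "chr1", pos, pos + 2)
        snv = VariantRecord("chr1", pos, ref3[0], ["A" if ref3[0] != "A" else "C"])
        indel = VariantRecord("chr1", pos, ref3, [ref3[0]])
        h = VcfHeader.minimal()
        p1 = write_vcf(h, [snv], tmp_path / "a.vcf", genome=genome_index)
        p2 = write_vcf(h, [indel], tmp_path / "b.vcf", genome=genome_index)
        merged = merge_vcfs([(p1, "a"), (p2, "b")], reference)
        assert len(merged) == 2
        assert {m.n_supporters for m in merged} == {1}

    def test_input_order_does_not_matter(self, tmp_path, reference, two_caller_files):
        p1, p2, _ = two_caller_files
        a = merge_vcfs([(p1, "c1"), (p2, "c2")], reference)
        b = merge_vcfs([(p2, "c2"), (p1, "c1")], reference)
        keyed_a = {merge_key(m.record): (m.supporters, m.record.qual) for m in a}
        keyed_b = {merge_key(m.record): (m.supporters, m.record.qual) for m in b}
        assert keyed_a == keyed_b

    def test_multisample_input_rejected(self, tmp_path, reference, genome_index):
        rec = VariantRecord("chr1", 100, "A", ["G"], genotypes={
            "X": GenotypeCall((0, 1)), "Y": GenotypeCall((0, 0)),
        })
        p = write_vcf(VcfHeader.minimal(["X", "Y"]), [rec], tmp_path / "ms.vcf")
        with pytest.raises(ValueError, match="multi-sample"):
            merge_vcfs([(p, "a")], reference)


class TestExtractConsensus:
    def test_brute_force_oracle_and_nesting(self, tmp_path):
        rng = np.random.default_rng(17)
        for trial in range(5):
            config = SimulationConfig(
                seed=int(rng.integers(2**31)), n_variants=60,
                callers=tuple(
                    CallerSpec(label, 0.7, 3, 0.5)
                    for label in ("gatk", "samtools", "freebayes", "varscan")
                ),
            )
            work = tmp_path / f"t{trial}"
            ref = simulate_reference(config, work)
            sim = simulate_callsets(config, ref, work)
            merged = merge_vcfs(
                [(p, label) for label, p in sim.caller_paths.items()], ref
            )
            # oracle: count key membership directly from the caller files
            member: dict = {}
            for label, path in sim.caller_paths.items():
                from mulekit.normalize import normalize_file

                _, records = normalize_file(path, ref, work / f"{label}.norm.vcf")
                for rec in records:
                    member.setdefault(merge_key(rec), set()).add(label)
            previous = None
            for m in (4, 3, 2, 1):
                got = {merge_key(rec.record) for rec in extract_consensus(merged, m)}
                expect = {k for k, s in member.items() if len(s) >= m}
                assert got == expect, (trial, m)
                if previous is not None:
                    assert previous <= got  # output(m+1) ⊆ output(m)
                previous = got
            assert previous == set(member)  # m=1 is the union

    def test_m_out_of_range(self, tmp_path, reference, two_caller_files):
        p1, p2, _ = two_caller_files
        merged = merge_vcfs([(p1, "c1"), (p2, "c2")], reference)
        with pytest.raises(ValueError, match="m=3"):
            extract_consensus(merged, 3)

    def test_extraction_from_file_matches_in_memory(self, tmp_path, reference, two_caller_files):
        p1, p2, _ = two_caller_files
        out = tmp_path / "merged.vcf"
        merged = merge_vcfs([(p1, "c1"), (p2, "c2")], reference, out=out)
        kept = extract_consensus_file(out, 2, tmp_path / "cons.vcf")
        assert len(kept) == len(extract_consensus(merged, 2))


class TestSplitAndRecombine:
    def _trio_vcf(self, tmp_path, genome_index, fasta, name, drop_child=False):
        from mulekit.vcf_io import MISSING_CALL

        def ref_at(pos):
            return fetch_reference(fasta, "chr1", pos, pos)

        records = []
        for pos in (1000, 2000):
            ref = ref_at(pos)
            alt = "A" if ref != "A" else "G"
            gts = {
                "F": GenotypeCall((0, 1)),
                "M": GenotypeCall((0, 0)),
                "C": MISSING_CALL if drop_child and pos == 2000 else GenotypeCall((0, 1)),
            }
            records.append(
                VariantRecord("chr1", pos, ref, [alt], qual=30.0,
                              filters=["PASS"], genotypes=gts)
            )
        return write_vcf(VcfHeader.minimal(["F", "M", "C"]), records,
                         tmp_path / name, genome=genome_index)

    def test_union_of_loci_with_missing_genotypes(
        self, tmp_path, reference, fasta, genome_index
    ):
        p1 = self._trio_vcf(tmp_path, genome_index, fasta, "a.vcf")
        p2 = self._trio_vcf(tmp_path, genome_index, fasta, "b.vcf", drop_child=True)
        out = tmp_path / "multi.vcf"
        merged = split_and_recombine([(p1, "gatk"), (p2, "samtools")], reference, out=out)
        assert len(merged) == 2
        header, records = read_vcf_records(out)
        assert header.samples == ["F", "M", "C"]
        assert all(not r.genotypes["F"].is_missing for r in records)
        assert merged[0].supporters == {"gatk", "samtools"}

    def test_single_sample_single_caller_identity(self, tmp_path, reference, fasta, genome_index):
        rec = VariantRecord("chr1", 1000, fetch_reference(fasta, "chr1", 1000, 1000),
                            ["A" if fetch_reference(fasta, "chr1", 1000, 1000) != "A" else "G"],
                            qual=12.0, genotypes={"S": GenotypeCall((1, 1))})
        p = write_vcf(VcfHeader.minimal(["S"]), [rec], tmp_path / "one.vcf")
        merged = split_and_recombine([(p, "gatk")], reference)
        assert len(merged) == 1
        out = merged[0].record
        assert (out.pos, out.ref, out.alts, out.qual) == (rec.pos, rec.ref, rec.alts, 12.0)
        assert out.genotypes["S"].allele_indices == (1, 1)

    def test_sample_set_mismatch_errors(self, tmp_path, reference, fasta, genome_index):
        p1 = self._trio_vcf(tmp_path, genome_index, fasta, "a.vcf")
        rec = VariantRecord("chr1", 100, "A", ["G"], genotypes={"Z": GenotypeCall((0, 1))})
        p2 = write_vcf(VcfHeader.minimal(["Z"]), [rec], tmp_path / "z.vcf")
        with pytest.raises(ValueError, match="sample set mismatch"):
            split_and_recombine([(p1, "gatk"), (p2, "samtools")], reference)
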