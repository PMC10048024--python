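"""VCF/GVF I/O, record selection, and multi-sample integration."""

import numpy as np
import pytest

from equindel.loci import MISSING, GenotypeMatrix, VariantLocus
from equindel.vcf_io import (
    integrate,
    natural_chrom_order,
    read_chrom_table,
    read_known_set,
    read_vcf,
    write_chrom_table,
    write_known_set_gvf,
    write_known_set_vcf,
    write_vcf,
)

HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
)


def _write(tmp_path, name, body, samples=("S1",)):
    p = tmp_path / name
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    p.write_text(HEADER + cols + "\n" + body)
    return str(p)


class TestReadVcf:
    def test_indel_loaded_with_delta(self, tmp_path):
        path = _write(tmp_path, "a.vcf", "20\t100\t.\tC\tCAGCAGAAAAGA\t50\t.\t.\tGT\t0/1\n")
        m = read_vcf(path)
        assert m.n_loci == 1
        assert m.loci[0].size_delta == +11

    def test_snv_and_mnp_excluded(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t50\t.\t.\tGT\t0/1\n"       # SNV
            "1\t200\t.\tACGT\tTCGA\t50\t.\t.\tGT\t0/1\n"  # equal-length MNP
            "1\t300\t.\tA\tAT\t50\t.\t.\tGT\t0/1\n"       # insertion
        )
        m = read_vcf(_write(tmp_path, "b.vcf", body))
        assert [l.pos for l in m.loci] == [300]

    def test_mixed_record_drops_snv_allele_and_remaps(self, tmp_path):
        body = "1\t100\t.\tA\tG,AT\t50\t.\t.\tGT\t1/2\n"
        m = read_vcf(_write(tmp_path, "c.vcf", body))
        assert m.loci[0].alts == ("AT",)
        # allele 1 (SNV) was dropped -> call referencing it becomes missing
        assert (m.calls[0, 0] == MISSING).all()

    def test_missing_genotype_parsed(self, tmp_path):
        body = "1\t100\t.\tA\tAT\t50\t.\t.\tGT\t./.\n"
        m = read_vcf(_write(tmp_path, "d.vcf", body))
        assert (m.calls[0, 0] == MISSING).all()


class TestRoundTrip:
    def test_write_read_preserves_sites_and_genotypes(self, sim_population, tmp_path):
        path = str(tmp_path / "rt.vcf")
        write_vcf(path, sim_population.matrix)
        back = read_vcf(path)
        assert [l.key for l in back.loci] == [l.key for l in sim_population.matrix.loci]
        assert back.samples == sim_population.matrix.samples
        assert (back.calls == sim_population.matrix.calls).all()

    def test_info_fields_survive_round_trip(self, sim_population, tmp_path):
        path = str(tmp_path / "rt2.vcf")
        write_vcf(path, sim_population.matrix)
        back = read_vcf(path)
        for a, b in zip(back.info[:200], sim_population.matrix.info[:200]):
            assert a["DP"] == b["DP"]
            assert a["QUAL"] == pytest.approx(b["QUAL"], abs=1e-3)
            assert a["ANN"] == b["ANN"]


class TestIntegrate:
    def test_distinct_alts_merge_to_multiallelic(self, tmp_path):
        p1 = _write(tmp_path, "s1.vcf", "3\t500\t.\tT\tTA\t50\t.\t.\tGT\t0/1\n", samples=("A",))
        p2 = _write(tmp_path, "s2.vcf", "3\t500\t.\tT\tTAA\t50\t.\t.\tGT\t1/1\n", samples=("B",))
        m = integrate([p1, p2])
        assert m.n_loci == 1
        assert m.loci[0].alts == ("TA", "TAA")
        assert list(m.calls[0, 0]) == [0, 1]
        assert list(m.calls[0, 1]) == [2, 2]

    def test_single_file_identity(self, sim_bundle):
        path = sim_bundle.paths["sample_vcfs"][0]
        direct = read_vcf(path)
        merged = integrate([path])
        assert merged.n_samples == 1
        assert {l.key for l in merged.loci} == {l.key for l in direct.loci}
        by_key_direct = {l.key: direct.calls[i, 0].tolist() for i, l in enumerate(direct.loci)}
        for i, l in enumerate(merged.loci):
            assert merged.calls[i, 0].tolist() == by_key_direct[l.key]

    def test_duplicate_sample_name_rejected(self, tmp_path):
        p1 = _write(tmp_path, "x1.vcf", "1\t100\t.\tA\tAT\t50\t.\t.\tGT\t0/1\n", samples=("A",))
        p2 = _write(tmp_path, "x2.vcf", "1\t200\t.\tA\tAT\t50\t.\t.\tGT\t0/1\n", samples=("A",))
        with pytest.raises(ValueError, match="duplicate sample"):
            integrate([p1, p2])

    def test_absent_record_missing_by_default_hom_ref_on_flag(self, tmp_path):
        p1 = _write(tmp_path, "y1.vcf", "1\t100\t.\tA\tAT\t50\t.\t.\tGT\t0/1\n", samples=("A",))
        p2 = _write(tmp_path, "y2.vcf", "1\t900\t.\tC\tCG\t50\t.\t.\tGT\t0/1\n", samples=("B",))
        m = integrate([p1, p2])
        assert (m.calls[0, 1] == MISSING).all()
        m2 = integrate([p1, p2], assume_hom_ref=True)
        assert list(m2.calls[0, 1]) == [0, 0]

    def test_round_trip_against_generator_truth(self, sim_bundle):
        """Integrating all per-sample VCFs reconstructs the generator's
        genotypes exactly (allele-sequence-wise) at every emitted locus
        that any sample carries."""
        merged = integrate(
            sim_bundle.paths["sample_vcfs"],
            assume_hom_ref=True,
            chrom_order=[c for c, _ in sim_bundle.config.chromosomes],
        )
        truth_m = sim_bundle.matrix
        by_anchor = {(l.chrom, l.pos, l.ref): i for i, l in enumerate(truth_m.loci)}
        n_checked = 0
        for i, locus in enumerate(merged.loci):
            j = by_anchor[(locus.chrom, locus.pos, locus.ref)]
            tl = truth_m.loci[j]
            for s, sample in enumerate(merged.samples):
                st = truth_m.samples.index(sample)
                got = sorted(
                    "" if g == 0 else locus.alts[g - 1] for g in merged.calls[i, s]
                )
                exp = sorted(
                    "" if g == 0 else tl.alts[g - 1] for g in truth_m.calls[j, st]
                )
                assert got == exp
                n_checked += 1
        assert n_checked > 1000
        # loci absent from the merge are exactly those no sample carries
        merged_anchors = {(l.chrom, l.pos, l.ref) for l in merged.loci}
        for j, tl in enumerate(truth_m.loci):
            if (tl.chrom, tl.pos, tl.ref) not in merged_anchors:
                assert (truth_m.calls[j] == 0).all()

    def test_order_independent_up_to_sample_order(self, sim_bundle):
        paths = list(sim_bundle.paths["sample_vcfs"][:6])
        a = integrate(paths)
        b = integrate(paths[::-1])
        assert [l.key for l in a.loci] == [l.key for l in b.loci]
        perm = [b.samples.index(s) for s in a.samples]
        assert (a.calls == b.calls[:, perm]).all()


class TestKnownSet:
    def test_gvf_insertion_stored_as_insertion_key(self, tmp_path):
        p = tmp_path / "k.gvf"
        p.write_text(
            "##gvf-version 1.0\n"
            "1\tEnsembl\tinsertion\t101\t100\t.\t+\t.\tID=rs1;Reference_seq=-;Variant_seq=A\n"
        )
        ks = read_known_set(str(p), "gvf")
        assert ("ins", "1", 101, "A") in ks.keys

    def test_same_variants_identical_keys_across_formats(self, sim_bundle):
        kv = read_known_set(sim_bundle.paths["known_vcf"], "vcf")
        kg = read_known_set(sim_bundle.paths["known_gvf"], "gvf")
        assert set(kv.keys) == set(kg.keys)
        assert len(kv) > 0

    def test_empty_file_empty_set(self, tmp_path):
        p = tmp_path / "empty.gvf"
        p.write_text("##gvf-version 1.0\n")
        ks = read_known_set(str(p), "gvf")
        assert len(ks) == 0
        locus = VariantLocus("1", 10, "A", ("AT",))
        assert not ks.contains_locus(locus)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "k.bed"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            read_known_set(str(p), "bed")


class TestChromTable:
    def test_round_trip(self, tmp_path):
        table = {"1": 3_000_000, "X": 1_500_000, "MT": 16_660}
        p = str(tmp_path / "chrom.tsv")
        write_chrom_table(p, table)
        assert read_chrom_table(p) == table

    def test_natural_order(self):
        assert natural_chrom_order(["X", "2", "MT", "10", "1"]) == ["1", "2", "10", "X", "MT"]
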