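"""ANN parsing, precedence, region tallies, frameshift logic, densities."""

import numpy as np
import pytest

from equindel.annotation import (
    FRAMESHIFT,
    NON_FRAMESHIFT,
    AnnotationRecord,
    all_alt_frameshift_genes,
    annotate_matrix,
    frameshift_consistency,
    frequency_density,
    parse_ann,
    region_tally,
)
from equindel.loci import VariantLocus
from equindel.popstats import site_frequencies
from tests.conftest import make_matrix

INS = VariantLocus("1", 100, "A", ("AT",))


def _ann(term, gene="G1", gene_id="ENSG1", biotype="protein_coding", impact="MODIFIER"):
    return f"AT|{term}|{impact}|{gene}|{gene_id}|transcript|{gene_id}.t1|{biotype}"


class TestParseAnn:
    def test_frameshift_term_maps_to_exon_frameshift(self):
        rec, bad = parse_ann(_ann("frameshift_variant"), INS)
        assert (rec.region_class, rec.effect_class) == ("exon", FRAMESHIFT)
        assert bad == 0

    def test_precedence_intron_over_downstream(self):
        ann = ",".join([_ann("downstream_gene_variant"), _ann("intron_variant")])
        rec, _ = parse_ann(ann, INS)
        assert rec.region_class == "intron"

    def test_precedence_exon_over_everything(self):
        ann = ",".join(
            [_ann("intron_variant"), _ann("conservative_inframe_insertion"),
             _ann("upstream_gene_variant")]
        )
        rec, _ = parse_ann(ann, INS)
        assert rec.region_class == "exon" and rec.effect_class == NON_FRAMESHIFT

    def test_empty_ann_yields_unannotated_intergenic(self):
        rec, _ = parse_ann(None, INS)
        assert rec.region_class == "intergenic" and rec.unannotated

    def test_malformed_entries_counted_and_skipped(self):
        rec, bad = parse_ann("garbage," + _ann("intron_variant"), INS)
        assert bad == 1 and rec.region_class == "intron"

    def test_pseudogene_biotype_overrides(self):
        rec, _ = parse_ann(
            _ann("non_coding_transcript_exon_variant", biotype="processed_pseudogene"), INS
        )
        assert rec.region_class == "pseudogene"

    def test_round_trip_on_generator_output(self, sim_population):
        records, warnings = annotate_matrix(
            sim_population.matrix.loci, sim_population.matrix.info
        )
        assert warnings == 0
        truth = sim_population.truth
        for rec, row in zip(records, truth.itertuples()):
            assert rec.region_class == row.region_class
            assert rec.gene_id == row.gene_id


class TestRegionTally:
    def test_partition_property(self, sim_population):
        records, _ = annotate_matrix(sim_population.matrix.loci, sim_population.matrix.info)
        tally = region_tally(records)
        assert int(tally.to_numpy().sum()) == len(records)

    def test_matches_generator_truth_exactly(self, sim_population):
        from equindel.loci import chromosome_compartment

        records, _ = annotate_matrix(sim_population.matrix.loci, sim_population.matrix.info)
        tally = region_tally(records)
        truth = sim_population.truth
        for comp in ("autosomes", "X", "MT"):
            sub = truth[[chromosome_compartment(c) == comp for c in truth["chrom"]]]
            for region, n in sub["region_class"].value_counts().items():
                assert tally.loc[region, comp] == n

    def test_collapsed_view_folds_noncoding_rows(self, sim_population):
        records, _ = annotate_matrix(sim_population.matrix.loci, sim_population.matrix.info)
        full = region_tally(records)
        collapsed = region_tally(records, collapsed=True)
        assert collapsed.loc["exon"].sum() == (
            full.loc["exon"].sum() + full.loc["lncRNA"].sum() + full.loc["pseudogene"].sum()
        )
        assert collapsed.loc["intron"].sum() == full.loc["intron"].sum() + full.loc["splice-site"].sum()
        assert collapsed.to_numpy().sum() == full.to_numpy().sum()

    def test_all_intergenic_single_row(self):
        records = [AnnotationRecord(VariantLocus("1", i * 50 + 10, "A", ("AT",)), "intergenic", "other", "") for i in range(5)]
        tally = region_tally(records)
        assert tally.loc["intergenic", "autosomes"] == 5
        assert tally.to_numpy().sum() == 5


class TestFrameshiftConsistency:
    def test_rule_frameshift_iff_not_multiple_of_three(self):
        for delta, ref, alt, expected in [
            (+1, "A", "AT", FRAMESHIFT),
            (-3, "ACGT", "A", NON_FRAMESHIFT),
            (+11, "C", "CAGCAGAAAAGA", FRAMESHIFT),
        ]:
            locus = VariantLocus("1", 100, ref, (alt,))
            term = "frameshift_variant" if expected == FRAMESHIFT else "conservative_inframe_deletion"
            rec, _ = parse_ann(_ann(term).replace("AT|", f"{alt}|"), locus)
            effect, discrepant = frameshift_consistency(rec)
            assert effect == expected and not discrepant

    def test_label_wins_and_discrepancy_reported(self):
        # an 11-bp insertion labelled non-frameshift (annotation context
        # can override the naive length rule)
        locus = VariantLocus("1", 100, "C", ("CAGCAGAAAAGA",))
        rec, _ = parse_ann(_ann("conservative_inframe_insertion"), locus)
        effect, discrepant = frameshift_consistency(rec)
        assert effect == NON_FRAMESHIFT and discrepant

    def test_generator_labels_always_consistent(self, sim_population):
        records, _ = annotate_matrix(sim_population.matrix.loci, sim_population.matrix.info)
        n_coding = 0
        for rec in records:
            if rec.is_coding_exonic and rec.locus.is_diallelic:
                _, discrepant = frameshift_consistency(rec)
                assert not discrepant
                n_coding += 1
        assert n_coding > 0


class TestAllAltFrameshiftGenes:
    def _setup(self, genotypes, gene="GENE_A", gene_id="ENSG_A"):
        locus = VariantLocus("5", 100, "A", ("AT",))
        m = make_matrix(genotypes, locus=locus)
        freqs = site_frequencies(m)
        rec, _ = parse_ann(_ann("frameshift_variant", gene=gene, gene_id=gene_id), locus)
        return [rec], freqs

    def test_all_alt_locus_lists_gene(self):
        records, freqs = self._setup([(1, 1)] * 10)
        df = all_alt_frameshift_genes(records, freqs)
        assert df["gene_id"].tolist() == ["ENSG_A"]

    def test_one_ref_carrier_excludes_gene(self):
        records, freqs = self._setup([(1, 1)] * 9 + [(0, 1)])
        assert all_alt_frameshift_genes(records, freqs).empty

    def test_synthetic_gene_count_recovered(self):
        """Construct a population with a known number of genes carrying
        reference-free frameshift exonic loci; the scan recovers all."""
        rng = np.random.default_rng(1)
        records, freqs = [], []
        expected = set()
        for g in range(40):
            gene_id = f"ENSG{g:04d}"
            all_alt = g < 23
            genotypes = [(1, 1)] * 12 if all_alt else [(0, 1)] * 12
            locus = VariantLocus("2", 1000 + 50 * g, "A", ("AT",))
            m = make_matrix(genotypes, locus=locus)
            freqs.extend(site_frequencies(m))
            rec, _ = parse_ann(_ann("frameshift_variant", gene_id=gene_id), locus)
            records.append(rec)
            if all_alt:
                expected.add(gene_id)
        df = all_alt_frameshift_genes(records, freqs)
        assert set(df["gene_id"]) == expected
        assert df["gene_id"].nunique() == 23


class TestFrequencyDensity:
    def test_rows_sum_to_hundred(self, sim_population):
        records, _ = annotate_matrix(sim_population.matrix.loci, sim_population.matrix.info)
        freqs = site_frequencies(sim_population.matrix)
        df = frequency_density(records, freqs)
        for _, row in df.iterrows():
            assert row.sum() == pytest.approx(100.0, abs=0.01)

    def test_all_mass_in_first_bin_for_ref_free_category(self):
        locus = VariantLocus("1", 100, "A", ("AT",))
        m = make_matrix([(1, 1)] * 8, locus=locus)
        rec, _ = parse_ann(_ann("frameshift_variant"), locus)
        df = frequency_density([rec], site_frequencies(m), n_bins=10)
        assert df.loc[FRAMESHIFT].iloc[0] == pytest.approx(100.0)

    def test_uniform_frequencies_roughly_flat(self):
        rng = np.random.default_rng(2)
        records, freqs = [], []
        for i in range(4000):
            locus = VariantLocus("1", 10 + 40 * i, "A", ("AT",))
            n_alt = int(rng.integers(0, 21))
            genotypes = [(1, 1)] * (n_alt // 2) + [(0, 1)] * (n_alt % 2)
            genotypes += [(0, 0)] * (10 - len(genotypes))
            m = make_matrix(genotypes, locus=locus)
            freqs.extend(site_frequencies(m))
            records.append(parse_ann(_ann("intron_variant"), locus)[0])
        df = frequency_density(records, freqs, n_bins=5)
        row = df.loc["intron"]
        # 21 discrete frequency values over 5 bins: each bin carries 4 or 5
        # of them, so a flat population lands every bin in 19% +/- a few
        assert (row > 10.0).all() and (row < 30.0).all()
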