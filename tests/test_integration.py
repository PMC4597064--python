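"""Integration pipeline: filters, joins, glyphs, derived tables."""

import numpy as np
import pandas as pd
import pytest

from _oracles import canon, canon_rows, nl_pipeline
from omiclone.fixtures import (
    FixtureConfig,
    example_case_bundle,
    generate_bundle,
    key_genes_of,
    tsg_genes_of,
)
from omiclone.integration import (
    FilterSettings,
    Glyph,
    build_D,
    build_I,
    build_J,
    build_integrated,
    distinct_mutations,
    filter_wes,
    integrate,
    key_gene_table,
    mutated_key_gene_methylation,
    paired_compare,
    rna_table,
    transcripts_for,
    tsg_methylation_table,
)
from omiclone.relations import (
    GeneListEntry,
    MethylationProbe,
    WesVariant,
    empty_relation,
    relation,
)


def _wes(chrom="1", pos=1000, dp=100, af=30.0, gene="ENSG1", symbol="G1",
         impact="MODERATE", exp="E1", change="c.1A>G"):
    return WesVariant(
        chromosome=chrom, position=pos, dna_depth=dp, dna_allelic_freq=af,
        ensembl_gene_id=gene, gene_symbol=symbol, dna_change=change,
        amino_acid_change=None, effect_impact=impact, experiment_id=exp,
    )


class TestFilterWes:
    def test_boundaries_inclusive(self):
        w = relation([_wes(af=4.0, dp=20), _wes(pos=2000, af=100.0, dp=1000)])
        assert len(filter_wes(w)) == 2

    @pytest.mark.parametrize("af,dp", [(3.9, 100), (30.0, 19), (30.0, 1001)])
    def test_out_of_range_dropped(self, af, dp):
        w = relation([_wes(af=af, dp=dp)])
        assert len(filter_wes(w)) == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        rows = [
            _wes(pos=int(p), af=float(round(a, 2)), dp=int(d))
            for p, a, d in zip(
                rng.integers(1, 10**6, 80), rng.uniform(0, 100, 80), rng.integers(1, 1500, 80)
            )
        ]
        w = relation(rows)
        s = FilterSettings()
        got = filter_wes(w, s)
        want = [r for r in rows if s.min_vaf <= r.dna_allelic_freq <= s.max_vaf
                and s.min_depth <= r.dna_depth <= s.max_depth]
        assert len(got) == len(want)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            FilterSettings(min_vaf=50, max_vaf=10)


class TestJoinLegs:
    def test_low_impact_variants_excluded_from_I(self, presentation):
        w = relation([_wes(impact="LOW"), _wes(pos=2000, impact="MODIFIER"),
                      _wes(pos=3000, impact="MODERATE")])
        I = build_I(w, empty_relation(MethylationProbe))
        assert list(I["position"]) == [3000]

    def test_unmethylated_gene_carries_null_probe_fields(self):
        w = relation([_wes(impact="HIGH")])
        I = build_I(w, empty_relation(MethylationProbe))
        assert len(I) == 1 and pd.isna(I.loc[0, "target_id"]) and pd.isna(I.loc[0, "avg_beta"])

    def test_zero_fpkm_transcripts_excluded(self, presentation):
        r = presentation.r.copy()
        r.loc[r["ensembl_transcript_id"] == "ENST00000377970", "fpkm"] = 0.0
        J = build_J(presentation.rv, r)
        assert "ENST00000377970" not in set(J["ensembl_transcript_id"])

    def test_two_positive_transcripts_give_two_rows_per_rna_variant(self, presentation):
        J = build_J(presentation.rv, presentation.r)
        myc_pos = presentation.rv.loc[0, "position"]
        assert (J["position"] == myc_pos).sum() == 2

    def test_count_strictly_positive_in_D(self, presentation):
        h = presentation.h.copy()
        h.loc[0, "count"] = 0
        D = build_D(presentation.rv, h)
        assert h.loc[0, "ensembl_gene_id"] not in set(
            presentation.rv.merge(D, on=["chromosome", "position"])["ensembl_gene_id"]
        ) or (h["count"] > 0).any()
        D1 = build_D(presentation.rv, presentation.h.assign(count=1))
        assert len(D1) == len(presentation.rv)


class TestIntegrated:
    def test_variant_without_rna_match_is_wes_only(self):
        w = relation([_wes()])
        bundle = example_case_bundle("presentation")
        I = build_I(w, empty_relation(MethylationProbe))
        integ = build_integrated(I, build_J(bundle.rv, bundle.r), build_D(bundle.rv, bundle.h), bundle.c)
        assert list(integ["glyph"]) == [int(Glyph.WES_ONLY)]
        assert pd.isna(integ.loc[0, "rna_depth"])

    def test_worked_case_glyphs(self, presentation):
        w_hat = distinct_mutations(integrate(presentation))
        glyph = dict(zip(w_hat["gene_symbol"], w_hat["glyph"]))
        assert glyph["MYC"] == int(Glyph.WES_PLUS_RNA)
        assert glyph["SETD2"] == int(Glyph.WES_PLUS_RNA)
        assert glyph["TET2"] == int(Glyph.WES_PLUS_RNA)
        assert glyph["DNA2"] == int(Glyph.WES_ONLY)
        assert glyph["TNFRSF11A"] == int(Glyph.WES_ONLY)

    def test_no_variant_lost_by_integration(self, sim_bundle):
        s = FilterSettings()
        w = filter_wes(sim_bundle.w, s)
        w = w[w["effect_impact"].isin(["MODERATE", "HIGH"])]
        integ = integrate(sim_bundle, s)
        assert (
            integ[["chromosome", "position"]].drop_duplicates().shape[0]
            == w[["chromosome", "position"]].drop_duplicates().shape[0]
        )

    def test_glyph_partition(self, sim_bundle):
        w_hat = distinct_mutations(integrate(sim_bundle))
        assert set(w_hat["glyph"]) <= {int(Glyph.WES_ONLY), int(Glyph.WES_PLUS_RNA)}

    def test_variant_matched_by_three_transcripts_dedups_to_one_row(self, relapse):
        # relapse SETD2 has four transcripts; the distinct relation keeps one row
        integ = integrate(relapse)
        setd2 = integ[integ["gene_symbol"] == "SETD2"]
        assert len(setd2) == 4
        w_hat = distinct_mutations(integ)
        assert (w_hat["gene_symbol"] == "SETD2").sum() == 1


class TestDerivedTables:
    def test_transcripts_for_expressed_locus(self, presentation):
        integ = integrate(presentation)
        w_hat = distinct_mutations(integ)
        myc = w_hat[w_hat["gene_symbol"] == "MYC"].iloc[0]
        tx = transcripts_for(myc, integ)
        got = set(zip(tx["ensembl_transcript_id"], tx["fpkm"]))
        assert got == {("ENST00000377970", 42.0), ("ENST00000524013", 58.0)}

    def test_transcripts_for_wes_only_locus_is_empty(self, presentation):
        integ = integrate(presentation)
        w_hat = distinct_mutations(integ)
        dna2 = w_hat[w_hat["gene_symbol"] == "DNA2"].iloc[0]
        assert len(transcripts_for(dna2, integ)) == 0

    def test_key_gene_table_worked_case(self, presentation):
        table = key_gene_table(integrate(presentation), key_genes_of(presentation.key_genes))
        assert len(table) == 5
        expressed = set(table[table["rna_expressed"]]["gene_symbol"])
        assert expressed == {"MYC", "SETD2", "TET2"}

    def test_key_gene_table_empty_list(self, presentation):
        table = key_gene_table(integrate(presentation), empty_relation(GeneListEntry))
        assert len(table) == 0

    def test_rna_table_relapse_has_eight_transcripts(self, relapse):
        table = rna_table(integrate(relapse))
        assert len(table) == 8
        assert (table["gene_symbol"] == "MTOR").sum() == 2

    def test_rna_table_empty_without_rna_evidence(self):
        bundle = generate_bundle(FixtureConfig(seed=1, n_variants=20, fraction_rna_expressed=0.0))
        assert len(rna_table(integrate(bundle))) == 0


class TestTsgMethylation:
    def test_worked_presentation_case(self, presentation):
        table = tsg_methylation_table(
            presentation.m, presentation.h, tsg_genes_of(presentation.key_genes)
        )
        assert len(table) == 10  # every probe in the export passes the criteria
        silenced = set(table[table["silenced"]]["gene_symbol"])
        assert silenced == {"BRCA1", "CEBPA", "MSH2", "SOCS1"}

    def test_worked_relapse_case(self, relapse):
        table = tsg_methylation_table(relapse.m, relapse.h, tsg_genes_of(relapse.key_genes))
        silenced = set(table[table["silenced"]]["gene_symbol"])
        assert silenced == {"AXIN1", "BRCA1", "MEN1", "MSH2", "RUNX1", "SOCS1"}

    def test_beta_threshold_boundary(self, presentation):
        m = relation(
            [
                MethylationProbe("cg1", 0.249, "Promoter Associated", "Island", "ENSG00000012048", "PRES"),
                MethylationProbe("cg2", 0.25, "Promoter Associated", "Island", "ENSG00000012048", "PRES"),
            ]
        )
        table = tsg_methylation_table(m, presentation.h, tsg_genes_of(presentation.key_genes))
        assert list(table["target_id"]) == ["cg2"]

    def test_annotation_criteria_case_insensitive(self, presentation):
        m = relation(
            [
                MethylationProbe("cg1", 0.5, " promoter associated ", "ISLAND", "ENSG00000012048", "PRES"),
                MethylationProbe("cg2", 0.5, "Gene Body", "Island", "ENSG00000012048", "PRES"),
                MethylationProbe("cg3", 0.5, "Promoter Associated", "N_Shore", "ENSG00000012048", "PRES"),
            ]
        )
        table = tsg_methylation_table(m, presentation.h, tsg_genes_of(presentation.key_genes))
        assert list(table["target_id"]) == ["cg1"]

    def test_output_subset_of_probes_and_silenced_iff_zero_count(self, sim_bundle):
        table = tsg_methylation_table(sim_bundle.m, sim_bundle.h, tsg_genes_of(sim_bundle.key_genes))
        assert set(table["target_id"]) <= set(sim_bundle.m["target_id"])
        counts = dict(zip(sim_bundle.h["ensembl_gene_id"], sim_bundle.h["count"]))
        for _, row in table.iterrows():
            assert row["silenced"] == (counts.get(row["ensembl_gene_id"], 0) == 0)

    def test_mutation_restricted_variant_only_covers_mutated_genes(self, presentation):
        integ = integrate(presentation)
        table = mutated_key_gene_methylation(integ, presentation.key_genes)
        mutated = set(presentation.w["ensembl_gene_id"])
        assert set(table["ensembl_gene_id"]) <= mutated


class TestPairedComparison:
    def test_identical_samples_have_no_unique_variants(self, presentation):
        common, u1, u2 = paired_compare(presentation.w, presentation.w)
        assert len(u1) == 0 and len(u2) == 0
        assert len(common) == presentation.w[["chromosome", "position"]].drop_duplicates().shape[0]

    def test_disjoint_samples_have_no_common_variants(self):
        w1 = relation([_wes(pos=100)])
        w2 = relation([_wes(pos=200)])
        common, u1, u2 = paired_compare(w1, w2)
        assert len(common) == 0 and len(u1) == 1 and len(u2) == 1

    def test_worked_case_gained_genes(self, presentation, relapse):
        common, gained, lost = paired_compare(relapse.w, presentation.w)
        assert sorted(gained["gene_symbol"]) == ["KRAS", "MLL3", "MTOR"]
        assert len(lost) == 0
        assert len(common) == 5

    def test_shared_and_new_transcripts_worked_case(self, presentation, relapse):
        from omiclone.relations import difference_on, intersect_on

        r_pres = presentation.r
        r_rel = relapse.r
        myc_pres = r_pres[r_pres["ensembl_gene_id"] == "ENSG00000136997"]
        shared = intersect_on(myc_pres, r_rel, ["ensembl_transcript_id"])
        assert set(shared["ensembl_transcript_id"]) == {"ENST00000377970", "ENST00000524013"}
        setd2_rel = r_rel[r_rel["ensembl_gene_id"] == "ENSG00000181555"]
        new = difference_on(setd2_rel, r_pres, ["ensembl_transcript_id"])
        assert set(new["ensembl_transcript_id"]) == {"ENST00000445387", "CUFF.29743.3"}


@pytest.mark.parametrize("seed", range(12))
def test_full_pipeline_matches_monolithic_oracle(seed):
    """Filter + joins + CN annotation + glyph equal one nested-loop pass."""
    rng = np.random.default_rng(seed)
    cfg = FixtureConfig(
        seed=seed,
        n_variants=int(rng.integers(5, 60)),
        fraction_rna_expressed=float(rng.uniform(0, 0.8)),
    )
    bundle = generate_bundle(cfg)
    w_hat = distinct_mutations(integrate(bundle))
    cols = ["chromosome", "position", "gene_symbol", "copy_number", "glyph"]
    want = nl_pipeline(bundle)
    assert canon(w_hat, cols) == canon_rows(want, cols)
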