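"""Variant filtering, adaptive-gene identification, spectrum tabulation."""

import pandas as pd
import pytest

from bfatools.mutations import (
    CurationOverrides,
    classify_mutation,
    filter_variants,
    identify_adaptive_genes,
    load_adaptive_mutation_fixture,
    match_clone_barcodes,
    ploidy_overlap,
    tabulate_spectrum,
)

# Printed "Total mutations" column of the curated adaptive-mutation table,
# keyed by (home environment, ploidy, gene).
EXPECTED_TOTALS = {
    ("CLM", "2N", "PDR1"): 15,
    ("CLM", "2N", "PDR3"): 5,
    ("CLM", "1N", "PDR1"): 29,
    ("CLM", "1N", "PDR3"): 7,
    ("FLC4", "2N", "CYC8"): 2,
    ("FLC4", "2N", "HAP1"): 1,
    ("FLC4", "2N", "PDR1"): 1,
    ("FLC4", "2N", "SSO2"): 2,
    ("FLC4", "2N", "TUP1"): 3,
    ("FLC4", "2N", "VPS35"): 2,
    ("FLC4", "2N", "YHK8"): 2,
    ("FLC4", "1N", "CSG2"): 3,
    ("FLC4", "1N", "CYC8"): 4,
    ("FLC4", "1N", "HAP1"): 2,
    ("FLC4", "1N", "PDR1"): 2,
    ("FLC4", "1N", "PDR3"): 2,
    ("FLC4", "1N", "PDR5"): 4,
    ("FLC4", "1N", "ROX1"): 3,
    ("FLC4", "1N", "SKN7"): 4,
    ("FLC4", "1N", "SUR1"): 11,
    ("FLC4", "1N", "SXM1"): 3,
    ("FLC4", "1N", "TUP1"): 1,
    ("FLC4", "1N", "UPC2"): 3,
    ("GlyEtOH", "2N", "HAP1"): 3,
    ("GlyEtOH", "2N", "HEM2"): 2,
    ("GlyEtOH", "2N", "HEM3"): 7,
    ("GlyEtOH", "2N", "IRA1"): 1,
    ("GlyEtOH", "2N", "IRA2"): 1,
    ("GlyEtOH", "2N", "NDI1"): 2,
    ("GlyEtOH", "2N", "WHI2"): 4,
    ("GlyEtOH", "1N", "GPB2"): 2,
    ("GlyEtOH", "1N", "IRA1"): 19,
    ("GlyEtOH", "1N", "IRA2"): 9,
    ("GlyEtOH", "1N", "SSK2"): 2,
    ("GlyEtOH", "1N", "WHI2"): 1,
    ("GlyEtOH", "1N", "YTA6"): 2,
}


class TestMutationParser:
    @pytest.mark.parametrize(
        "mutation,expected",
        [
            ("F1047V", "missense"),
            ("+/E768G", "missense"),
            ("Q610*", "nonsense"),
            ("+/Y261*", "nonsense"),
            ("I416_fs", "coding_indel"),
            ("NA729_fs", "coding_indel"),
            ("E701*_fs", "nonsense"),
            ("627963T>A", "non_coding"),
            ("+/131054G>GT", "non_coding"),
            ("S753SVYRSFAHYS", "coding_indel"),
            ("V1471ETHKFNCSNKRSEIDQTSSN", "coding_indel"),
            ("+/IYVTSI1483I", "coding_indel"),
            ("ILV1729I", "coding_indel"),
            ("K1474E, V1485I", "missense"),
            ("M1T", "missense"),
        ],
    )
    def test_dialect(self, mutation, expected):
        assert classify_mutation(mutation) == expected

    def test_garbage_rejected(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            classify_mutation("banana")


class TestSpectrum:
    def test_every_row_total_matches_printed_table(self):
        spectrum = tabulate_spectrum(load_adaptive_mutation_fixture())
        got = {
            (r.home_environment, r.ploidy, r.gene): r.total
            for r in spectrum.itertuples()
        }
        assert got == EXPECTED_TOTALS

    def test_class_counts_sum_to_total(self):
        spectrum = tabulate_spectrum(load_adaptive_mutation_fixture())
        parts = spectrum[["missense", "nonsense", "coding_indel", "non_coding"]]
        assert (parts.sum(axis=1) == spectrum["total"]).all()

    def test_named_cells(self):
        spectrum = tabulate_spectrum(load_adaptive_mutation_fixture())
        row = spectrum.set_index(["home_environment", "ploidy", "gene"])
        clm_pdr1 = row.loc[("CLM", "2N", "PDR1")]
        assert clm_pdr1["total"] == 15 and clm_pdr1["missense"] == 15
        assert row.loc[("GlyEtOH", "1N", "IRA1")]["total"] == 19

    def test_empty_input_empty_table(self):
        out = tabulate_spectrum(pd.DataFrame(columns=["home_environment", "ploidy", "gene", "mutation"]))
        assert out.empty


class TestPloidyOverlap:
    def test_clotrimazole_only_shared_targets(self):
        overlap = ploidy_overlap(tabulate_spectrum(load_adaptive_mutation_fixture()))
        clm = overlap["CLM"]
        assert clm["shared"] == {"PDR1", "PDR3"}
        assert clm["haploid_only"] == set() and clm["diploid_only"] == set()

    def test_glycerol_ethanol_membership(self):
        overlap = ploidy_overlap(tabulate_spectrum(load_adaptive_mutation_fixture()))
        gly = overlap["GlyEtOH"]
        assert {"HEM2", "HEM3", "NDI1"} <= gly["diploid_only"]
        assert {"GPB2", "SSK2", "YTA6"} <= gly["haploid_only"]
        assert {"IRA1", "IRA2", "WHI2", "HAP1"} & (gly["shared"] | gly["diploid_only"])
        assert {"IRA1", "IRA2", "WHI2"} <= gly["shared"]

    def test_single_ploidy_input_all_exclusive(self):
        entries = pd.DataFrame(
            {
                "home_environment": ["X"] * 2,
                "ploidy": ["1N"] * 2,
                "gene": ["G1", "G2"],
                "mutation": ["A1T", "C2G"],
            }
        )
        overlap = ploidy_overlap(tabulate_spectrum(entries))
        assert overlap["X"]["haploid_only"] == {"G1", "G2"}
        assert overlap["X"]["shared"] == set()


def _variant(**kw):
    base = dict(
        clone="c1",
        condition="CLM_1N",
        ploidy="1N",
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="T",
        gene="PDR1",
        effect_class="missense",
        zygosity="hom",
        quality=500.0,
        clone_coverage=40.0,
        ref_depth=0,
        alt_depth=30,
    )
    base.update(kw)
    return base


def _padding(ploidy="1N", n=9):
    # filler clones so that a singleton variant stays under the 12%
    # condition-level background fraction
    return [
        _variant(clone=f"pad{i}", pos=50_000 + i, ploidy=ploidy) for i in range(n)
    ]


class TestVariantFilters:
    def test_mitochondrial_dropped(self):
        df = pd.DataFrame([_variant(), _variant(chrom="chrM", pos=2)] + _padding())
        kept = filter_variants(df)
        assert (kept["chrom"] != "chrM").all()
        assert 1000 in kept["pos"].values

    def test_flo_genes_dropped(self):
        df = pd.DataFrame([_variant(), _variant(gene="FLO1", pos=5)] + _padding())
        kept = filter_variants(df)
        assert "FLO1" not in kept["gene"].values
        assert 1000 in kept["pos"].values

    @pytest.mark.parametrize(
        "ploidy,coverage,kept", [("1N", 9, False), ("1N", 10, True), ("2N", 14, False), ("2N", 15, True)]
    )
    def test_coverage_thresholds(self, ploidy, coverage, kept):
        df = pd.DataFrame(
            [_variant(ploidy=ploidy, clone_coverage=coverage)] + _padding(ploidy)
        )
        assert (1000 in filter_variants(df)["pos"].values) == kept

    def test_background_variant_dropped(self):
        # same variant in 2 of 10 clones of one condition: 20% > 12%
        rows = [_variant(clone=f"c{i}", pos=1000 + i) for i in range(10)]
        rows += [_variant(clone="c0", pos=9000), _variant(clone="c1", pos=9000)]
        kept = filter_variants(pd.DataFrame(rows))
        assert 9000 not in kept["pos"].values
        assert 1000 in kept["pos"].values

    def test_low_quality_dropped_unless_whitelisted(self):
        df = pd.DataFrame([_variant(quality=149.0)] + _padding())
        assert 1000 not in filter_variants(df)["pos"].values
        overrides = CurationOverrides(keep={("chr1", 1000, "A", "T")})
        assert 1000 in filter_variants(df, overrides=overrides)["pos"].values

    def test_het_high_ref_ratio_flagged_not_dropped(self):
        df = pd.DataFrame(
            [_variant(zygosity="het", ref_depth=30, alt_depth=9, ploidy="2N", clone_coverage=40)]
            + _padding("2N")
        )
        kept = filter_variants(df)
        row = kept[kept["pos"] == 1000]
        assert len(row) == 1 and row["suspected_contamination"].iloc[0]

    def test_ratio_exactly_3_not_flagged(self):
        df = pd.DataFrame(
            [_variant(zygosity="het", ref_depth=30, alt_depth=10, ploidy="2N", clone_coverage=40)]
            + _padding("2N")
        )
        kept = filter_variants(df)
        assert not kept[kept["pos"] == 1000]["suspected_contamination"].iloc[0]

    def test_order_independence(self):
        rows = [
            _variant(clone=f"c{i}", pos=100 + i, quality=200 + i) for i in range(10)
        ]
        df = pd.DataFrame(rows)
        a = filter_variants(df)
        b = filter_variants(df.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_override_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            filter_variants(pd.DataFrame([_variant()]), overrides={"allow": []})


class TestAdaptiveGenes:
    def _variants(self):
        rows = [
            _variant(clone="c1", gene="PDR1", pos=100),
            _variant(clone="c2", gene="PDR1", pos=200),
            _variant(clone="c3", gene="SINGLE", pos=300),
            _variant(clone="c4", gene="UNFIT", pos=400),
            _variant(clone="c5", gene="UNFIT", pos=500),
            _variant(clone="c6", gene="NONCOD", pos=600, effect_class="non_coding"),
            _variant(clone="c7", gene="NONCOD", pos=700, effect_class="non_coding"),
        ]
        return pd.DataFrame(rows)

    def _fitness(self):
        return {
            "c1": 0.2,
            "c2": 0.15,
            "c3": 0.3,
            "c4": -0.1,
            "c5": -0.02,
            "c6": 0.2,
            "c7": 0.2,
        }

    def test_rules(self):
        genes, candidates, deferred = identify_adaptive_genes(
            self._variants(), self._fitness()
        )
        assert genes["CLM_1N"] == {"PDR1"}
        assert set(candidates["gene"]) == {"PDR1"}
        assert deferred == []

    def test_single_lineage_gene_excluded(self):
        genes, _, _ = identify_adaptive_genes(self._variants(), self._fitness())
        assert "SINGLE" not in genes["CLM_1N"]

    def test_negative_median_fitness_excluded(self):
        genes, _, _ = identify_adaptive_genes(self._variants(), self._fitness())
        assert "UNFIT" not in genes["CLM_1N"]

    def test_noncoding_only_gene_excluded(self):
        genes, _, _ = identify_adaptive_genes(self._variants(), self._fitness())
        assert "NONCOD" not in genes["CLM_1N"]

    def test_allowlist_admits_curated_gene(self):
        genes, _, _ = identify_adaptive_genes(
            self._variants(), self._fitness(), pathway_allowlist=["SINGLE"]
        )
        assert "SINGLE" in genes["CLM_1N"]

    def test_missing_fitness_deferred_with_warning(self):
        genes, _, deferred = identify_adaptive_genes(self._variants(), {})
        assert any("PDR1" in d for d in deferred)
        assert genes["CLM_1N"] == set()


class TestCloneBarcodeMatching:
    KNOWN = ["AAAAAAAAAACCCCCCCCCC", "GGGGGGGGGGTTTTTTTTTT"]

    def test_three_fold_margin_assigned(self):
        reads = {"c": {self.KNOWN[0]: 6, self.KNOWN[1]: 2}}
        assert match_clone_barcodes(reads, self.KNOWN)["c"] == self.KNOWN[0]

    def test_single_read_unassigned(self):
        reads = {"c": {self.KNOWN[0]: 1}}
        assert match_clone_barcodes(reads, self.KNOWN)["c"] is None

    def test_2_5_fold_unassigned(self):
        reads = {"c": {self.KNOWN[0]: 5, self.KNOWN[1]: 2}}
        assert match_clone_barcodes(reads, self.KNOWN)["c"] is None

    def test_single_deletion_error_corrects_to_known(self):
        erroneous = self.KNOWN[0][:5] + self.KNOWN[0][6:]  # one base deleted
        reads = {"c": {erroneous: 3}}
        assert match_clone_barcodes(reads, self.KNOWN)["c"] == self.KNOWN[0]

    def test_unknown_barcode_reads_ignored(self):
        reads = {"c": {"TTTTTTTTTTTTTTTTTTTT": 50}}
        assert match_clone_barcodes(reads, self.KNOWN)["c"] is None
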