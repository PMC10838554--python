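"""Codon counting, RSCU, and start/stop classification."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocharacter._util import round_half_up
from mitocharacter.annotation import parse_feature_table
from mitocharacter.codons import (
    ALL_CODONS,
    CodonCounts,
    classify_start_stop,
    codon_family_totals,
    compute_rscu,
    count_codons,
    extract_codons,
    incomplete_stop_genes,
    stop_kind_from_length,
    synonymous_families,
)


class TestExtractCodons:
    @pytest.mark.parametrize(
        "cds,n_codons,tail",
        [("ATGAAATAA", 3, ""), ("ATGAAAT", 2, "T"), ("AT", 0, "AT"), ("", 0, "")],
    )
    def test_split(self, cds, n_codons, tail):
        codons, t = extract_codons(cds)
        assert len(codons) == n_codons and t == tail

    def test_length_784_cds_gives_261_codons(self):
        codons, tail = extract_codons("A" * 784)
        assert len(codons) == 261 and len(tail) == 1


class TestCountCodons:
    def test_toy_single_pcg(self, toy):
        F, make = toy
        ann = make([F("nad1", 1, 9)], 9)
        cc = count_codons(ann, "ATGAAATAA", "pcg_concat")
        assert cc.counts["AUG"] == 1 and cc.counts["AAA"] == 1 and cc.counts["UAA"] == 1
        assert cc.total == 3

    def test_whole_genome_frame1_total_is_floor_length_over_3(self, default_synthetic):
        seq, ann, _ = default_synthetic
        cc = count_codons(ann, seq, "whole_genome_frame1")
        assert len(seq) == 17827
        assert cc.total == 17827 // 3 == 5942

    def test_pcg_concat_total_is_sum_of_floored_gene_lengths(self, default_synthetic):
        seq, ann, _ = default_synthetic
        from mitocharacter.annotation import feature_length

        cc = count_codons(ann, seq, "pcg_concat")
        assert cc.total == sum(
            feature_length(f, ann.length) // 3 for f in ann.pcgs
        )

    def test_synthetic_truth_exact(self, default_synthetic):
        from collections import Counter

        seq, ann, truth = default_synthetic
        cc = count_codons(ann, seq, "pcg_concat")
        agg = Counter()
        for counts in truth.pcg_codon_counts.values():
            agg.update(counts)
        assert cc.counts == CodonCounts(dict(agg), source="truth").counts

    def test_short_pcg_is_an_error(self, toy):
        F, make = toy
        ann = make([F("nad1", 1, 2)], 4)
        with pytest.raises(ValueError, match="nad1"):
            count_codons(ann, "ATGG", "pcg_concat")


class TestRscu:
    def test_two_member_family(self):
        df = compute_rscu({"UUU": 56, "UUC": 154}, decimals=2).set_index("codon")
        assert df.loc["UUC", "rscu"] == 1.47
        assert df.loc["UUU", "rscu"] == 0.53

    def test_six_member_serine_family(self):
        counts = {"UCU": 93, "UCC": 123, "UCA": 93, "UCG": 31, "AGU": 53, "AGC": 126}
        df = compute_rscu(counts, decimals=2).set_index("codon")
        assert df.loc["AGC", "rscu"] == 1.46

    def test_equal_counts_give_unit_rscu(self):
        df = compute_rscu({c: 7 for c in ALL_CODONS}).set_index("codon")
        assert (df["rscu"] == 1.0).all()

    def test_zero_total_family_is_missing(self):
        df = compute_rscu({"UUU": 3}).set_index("codon")
        assert math.isnan(df.loc["CAU", "rscu"])
        assert df.loc["UUU", "rscu"] == 2.0

    def test_family_map_must_partition(self):
        with pytest.raises(ValueError, match="64 codons"):
            compute_rscu({"UUU": 1}, family_map={"UUU": "F"})

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 500), min_size=64, max_size=64),
           st.integers(2, 9))
    def test_family_sum_conservation_and_scaling_invariance(self, counts, k):
        counts = dict(zip(ALL_CODONS, counts))
        df = compute_rscu(counts)
        for fam, grp in df.groupby("family"):
            if grp["count"].sum() > 0:
                assert grp["rscu"].sum() == pytest.approx(len(grp))
        scaled = compute_rscu({c: k * n for c, n in counts.items()})
        pd.testing.assert_series_equal(df["rscu"], scaled["rscu"])

    def test_vertebrate_mito_family_map_differs(self):
        std = synonymous_families("standard")
        mito = synonymous_families("vertebrate_mitochondrial")
        assert std["AGA"] == "R" and mito["AGA"] == "*"
        assert std["UGA"] == "*" and mito["UGA"] == "W"
        assert std["AUA"] == "I" and mito["AUA"] == "M"


class TestFamilyTotals:
    def test_reference_ranking(self, ref_codon_usage):
        counts = dict(zip(ref_codon_usage["codon"], ref_codon_usage["count"]))
        totals = codon_family_totals(compute_rscu(counts))
        by_family = dict(zip(totals["family"], totals["count"]))
        assert by_family["P"] == 715 and totals.attrs["most_frequent"] == "P"
        assert by_family["W"] == 30 and totals.attrs["least_frequent"] == "W"

    def test_all_zero_counts_give_empty_ranking(self):
        totals = codon_family_totals(compute_rscu({c: 0 for c in ALL_CODONS}))
        assert totals.attrs["most_frequent"] is None
        assert totals.attrs["least_frequent"] is None


class TestStartStop:
    def test_complete_stop(self):
        sc = classify_start_stop("nad1", "ATGAAATAA")
        assert (sc.start_codon, sc.stop_kind, sc.stop_text) == ("ATG", "complete", "TAA")
        assert not sc.warnings

    def test_incomplete_T(self):
        sc = classify_start_stop("cox3", "ATGAAAT")
        assert sc.stop_kind == "incomplete_T" and sc.stop_text == "T(AA)"

    def test_incomplete_TA(self):
        sc = classify_start_stop("g", "ATGAAATA")
        assert sc.stop_kind == "incomplete_TA" and sc.stop_text == "TA(A)"

    def test_non_canonical_terminal_codon_flagged(self):
        sc = classify_start_stop("g", "ATGAAA")
        assert any("non-canonical" in w for w in sc.warnings)

    def test_agg_and_aga_are_complete_stops(self):
        for stop in ("AGA", "AGG", "TAG"):
            sc = classify_start_stop("g", "ATG" + stop)
            assert sc.stop_kind == "complete" and not sc.warnings

    @pytest.mark.parametrize("length,kind", [
        (9, "complete"), (784, "incomplete_T"), (1378, "incomplete_T"),
        (8, "incomplete_TA"),
    ])
    def test_stop_kind_from_length(self, length, kind):
        assert stop_kind_from_length(length) == kind

    def test_incomplete_stop_genes_from_reference_coordinates(self, ref_ann):
        assert incomplete_stop_genes(ref_ann) == {
            "cox3": "incomplete_T", "nad4": "incomplete_T",
        }
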