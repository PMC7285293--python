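"""Neighborhood detection, classification, survey counts and matching."""

import numpy as np
import pytest

from clusterscout import (
    MULTI_FAMILY_CLUSTER,
    SINGLE_FAMILY_TANDEM,
    FamilyCatalog,
    GeneModel,
    NeighborhoodRegion,
    classify_region,
    detect_neighborhoods,
    match_regions,
    read_region_table,
    summarize_survey,
    write_region_table,
)
from conftest import chain_oracle, make_region, random_annotation


class TestDetect:
    def test_thalianol_like_cluster(self, thalianol_like_genes, thalianol_catalog):
        regions = detect_neighborhoods(thalianol_like_genes, thalianol_catalog)
        assert len(regions) == 1
        (r,) = regions
        assert r.members == ("THAS", "THAH", "THAD", "CYP705A12")
        assert sorted(r.families) == ["P450", "P450", "P450", "TPS"]
        assert r.category == MULTI_FAMILY_CLUSTER
        assert r.strict_cluster is False  # two distinct families only
        assert (r.span_start, r.span_end) == (5_000, 23_000)

    def test_two_genes_below_min_genes(self):
        genes = [
            GeneModel("a", "chr1", 1_000, 2_000),
            GeneModel("b", "chr1", 3_000, 4_000),
        ]
        catalog = FamilyCatalog(assignments={"a": "P450", "b": "P450"})
        assert detect_neighborhoods(genes, catalog, min_genes=3) == []

    def test_gap_constraint_splits_chain(self):
        genes = [
            GeneModel("a", "chr1", 1_000, 2_000),
            GeneModel("b", "chr1", 3_000, 4_000),
            GeneModel("c", "chr1", 5_000, 6_000),
            GeneModel("d", "chr1", 200_000, 201_000),  # far downstream
        ]
        catalog = FamilyCatalog(assignments={g.gene_id: "UGT" for g in genes})
        regions = detect_neighborhoods(genes, catalog, max_gap_bp=50_000)
        assert [r.members for r in regions] == [("a", "b", "c")]

    def test_intervening_constraint_splits_chain(self):
        genes = [GeneModel(f"f{i}", "chr1", 1 + 3_000 * i, 2_000 + 3_000 * i)
                 for i in range(3)]
        # 4 unassigned genes between f2 and f3 with max_intervening=3
        genes += [GeneModel(f"u{i}", "chr1", 10_000 + 1_500 * i, 11_000 + 1_500 * i)
                  for i in range(4)]
        genes += [GeneModel("f3", "chr1", 17_000, 18_000),
                  GeneModel("f4", "chr1", 19_000, 20_000),
                  GeneModel("f5", "chr1", 21_000, 22_000)]
        catalog = FamilyCatalog(
            assignments={f"f{i}": "TPS" for i in range(6)}
        )
        regions = detect_neighborhoods(genes, catalog, max_intervening=3)
        assert sorted(r.members for r in regions) == [
            ("f0", "f1", "f2"), ("f3", "f4", "f5")
        ]
        merged = detect_neighborhoods(genes, catalog, max_intervening=4)
        assert [r.members for r in merged] == [("f0", "f1", "f2", "f3", "f4", "f5")]

    def test_catalog_orphans_warned_and_ignored(self, caplog):
        genes = [GeneModel("a", "chr1", 1, 100)]
        catalog = FamilyCatalog(assignments={"a": "P450", "ghost": "TPS"})
        with caplog.at_level("WARNING"):
            assert detect_neighborhoods(genes, catalog) == []
        assert "absent from the annotation" in caplog.text

    def test_empty_gene_list(self):
        assert detect_neighborhoods([], FamilyCatalog()) == []

    def test_matches_chain_enumeration_oracle_on_random_genomes(self):
        rng = np.random.default_rng(2024)
        for trial in range(30):
            n = int(rng.integers(10, 200))
            genes, catalog = random_annotation(rng, n)
            max_iv = int(rng.integers(0, 5))
            max_gap = int(rng.integers(5_000, 120_000))
            got = {
                r.member_set
                for r in detect_neighborhoods(
                    genes, catalog, max_intervening=max_iv, max_gap_bp=max_gap
                )
            }
            want = chain_oracle(genes, catalog, max_iv, max_gap, 3)
            assert got == want, f"trial {trial}: n={n} iv={max_iv} gap={max_gap}"

    def test_input_order_and_strand_invariance(self):
        rng = np.random.default_rng(5)
        genes, catalog = random_annotation(rng, 120)
        flipped = [
            GeneModel(g.gene_id, g.chrom, g.start, g.end,
                      "-" if g.strand == "+" else "+", g.product)
            for g in genes
        ]
        shuffled = list(genes)
        rng.shuffle(shuffled)
        base = [r.members for r in detect_neighborhoods(genes, catalog)]
        assert [r.members for r in detect_neighborhoods(shuffled, catalog)] == base
        assert [r.members for r in detect_neighborhoods(flipped, catalog)] == base

    def test_region_members_are_disjoint_and_maximal(self):
        rng = np.random.default_rng(9)
        genes, catalog = random_annotation(rng, 150, family_rate=0.6)
        regions = detect_neighborhoods(genes, catalog)
        seen = set()
        for r in regions:
            assert not (r.member_set & seen)
            seen |= r.member_set
        # maximality: every region must also appear in the oracle's maximal set
        oracle = chain_oracle(genes, catalog, 3, 50_000, 3)
        assert {r.member_set for r in regions} == oracle

    @pytest.mark.parametrize("param", ["max_gap_bp", "max_intervening"])
    def test_chain_count_monotone_in_proximity_constraints(self, param):
        """Loosening a proximity constraint can only merge maximal chains,
        so the chain count (singleton family genes included) never grows
        and the member coverage of emitted regions never shrinks."""
        rng = np.random.default_rng(17)
        genes, catalog = random_annotation(rng, 180, family_rate=0.5)
        n_family = sum(g.gene_id in catalog for g in genes)
        grids = {
            "max_gap_bp": [5_000, 20_000, 50_000, 150_000, 600_000],
            "max_intervening": [0, 1, 2, 4, 8, 50],
        }
        chain_counts, totals = [], []
        for v in grids[param]:
            pairs_up = detect_neighborhoods(genes, catalog, min_genes=2,
                                            **{param: v})
            covered = sum(r.n_members for r in pairs_up)
            chain_counts.append(len(pairs_up) + (n_family - covered))
            emitted = detect_neighborhoods(genes, catalog, **{param: v})
            totals.append(sum(r.n_members for r in emitted))
        assert chain_counts == sorted(chain_counts, reverse=True)
        assert totals == sorted(totals)


class TestClassify:
    def test_two_families_is_cluster_not_strict(self):
        r = make_region("r1", "abcd", ["P450", "P450", "P450", "TPS"])
        assert r.category == MULTI_FAMILY_CLUSTER
        assert r.strict_cluster is False

    def test_three_families_is_strict_cluster(self):
        r = make_region("r1", "abc", ["P450", "2ODD", "UGT"])
        assert r.category == MULTI_FAMILY_CLUSTER and r.strict_cluster

    def test_single_family_is_tandem_with_dominant(self):
        r = make_region("r1", "abcd", ["UGT"] * 4)
        assert r.category == SINGLE_FAMILY_TANDEM
        assert r.dominant_family == "UGT"

    def test_min_distinct_families_below_two_rejected(self):
        r = make_region("r1", "ab c".split(), ["P450", "TPS", "UGT"])
        with pytest.raises(ValueError):
            classify_region(r, min_distinct_families=1)


class TestSurveySummary:
    @pytest.mark.parametrize(
        "label,n_cluster,tandems,total",
        [
            ("A. thaliana", 39, {"P450": 28, "2ODD": 16, "TPS": 6, "PKS": 5, "UGT": 15}, 109),
            ("O. sativa", 34, {"P450": 57, "2ODD": 15, "TPS": 10, "PKS": 10, "UGT": 37}, 163),
            ("S. lycopersicum", 50, {"P450": 30, "2ODD": 24, "TPS": 8, "PKS": 9, "UGT": 30}, 151),
            ("L. japonicus", 18, {"P450": 29, "2ODD": 7, "TPS": 5, "PKS": 4, "UGT": 7}, 70),
        ],
    )
    def test_survey_arithmetic_on_published_style_counts(
        self, label, n_cluster, tandems, total
    ):
        """Counts shaped like a four-species genomic survey must satisfy
        cluster + sum(tandem-by-family) == total."""
        regions, k = [], 0
        for _ in range(n_cluster):
            regions.append(make_region(f"c{k}", [f"m{k}a", f"m{k}b", f"m{k}c"],
                                       ["P450", "TPS", "UGT"]))
            k += 1
        for fam, n in tandems.items():
            for _ in range(n):
                regions.append(make_region(f"t{k}", [f"m{k}a", f"m{k}b", f"m{k}c"],
                                           [fam] * 3))
                k += 1
        summary = summarize_survey(regions, label)
        assert summary.n_cluster_regions == n_cluster
        assert summary.n_tandem_by_family == tandems
        assert summary.n_tandem_regions == sum(tandems.values())
        assert summary.n_total_regions == total

    def test_empty_region_list(self):
        s = summarize_survey([], "empty")
        assert s.n_total_regions == s.n_cluster_regions == s.n_tandem_regions == 0

    def test_unclassified_region_rejected(self):
        r = NeighborhoodRegion("r1", "chr1", 1, 10, ("a", "b", "c"),
                               ("P450", "P450", "P450"))
        with pytest.raises(ValueError, match="unclassified"):
            summarize_survey([r], "x")


class TestMatchRegions:
    def test_identity(self):
        regions = [make_region(f"r{i}", [f"g{i}a", f"g{i}b", f"g{i}c"],
                               ["P450"] * 3) for i in range(4)]
        assert match_regions(regions, regions) == (1.0, 1.0)

    def test_empty_detected_vs_truth(self):
        truth = [make_region("t", "abc", ["UGT"] * 3)]
        assert match_regions([], truth) == (1.0, 0.0)
        assert match_regions([], []) == (1.0, 1.0)

    def test_merged_detection_counted_by_hand(self):
        """Ten planted regions; a loose detector merges two of them into
        one. Hand enumeration: the merged region has Jaccard 3/6 = 0.5
        with each parent, matching exactly one of them greedily, so 9 of
        10 truth regions are matched (recall 0.9) and all 9 detected
        regions match (precision 1.0)."""
        truth = [make_region(f"t{i}", [f"g{i}{c}" for c in "abc"], ["TPS"] * 3)
                 for i in range(10)]
        detected = [make_region(f"d{i}", [f"g{i}{c}" for c in "abc"], ["TPS"] * 3)
                    for i in range(8)]
        detected.append(make_region(
            "d_merged",
            [f"g8{c}" for c in "abc"] + [f"g9{c}" for c in "abc"],
            ["TPS"] * 6,
        ))
        precision, recall = match_regions(detected, truth, min_jaccard=0.5)
        assert precision == 1.0
        assert recall == pytest.approx(0.9)

    def test_jaccard_threshold_excludes_weak_overlap(self):
        truth = [make_region("t", ["a", "b", "c", "d"], ["TPS"] * 4)]
        detected = [make_region("d", ["a", "x", "y"], ["TPS"] * 3)]
        # Jaccard 1/6 < 0.5
        assert match_regions(detected, truth) == (0.0, 0.0)


class TestRegionTableRoundtrip:
    def test_roundtrip(self, tmp_path, thalianol_like_genes, thalianol_catalog):
        regions = detect_neighborhoods(thalianol_like_genes, thalianol_catalog)
        p = tmp_path / "regions.tsv"
        write_region_table(regions, p)
        assert read_region_table(p) == regions
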