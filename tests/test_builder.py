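"""Cluster chaining, family/tissue/annotation builders, catalog merging."""

import random

import pytest

from mirenrich.builder import (
    GenomicLocus,
    TSIRecord,
    build_annotation_sets,
    build_clusters,
    build_family_sets,
    build_tissue_sets,
    loci_to_gff3,
    merge_catalogs,
    read_gff3_loci,
    read_mifam,
)
from mirenrich.catalog import Catalog, Category
from mirenrich.errors import ValidationError
from mirenrich.fixtures import FixtureSpec, make_random_catalog, make_random_loci

from conftest import oracle_clusters


def partition(categories):
    return {frozenset(c.members) for c in categories}


class TestClusters:
    def test_canonical_chaining_example(self, three_loci):
        # gaps: 43,899 bp (chains) and 74,899 bp (breaks)
        cats = build_clusters(three_loci, max_gap=50_000)
        assert partition(cats) == {frozenset({"mir-a", "mir-b"})}
        assert cats[0].class_label == "cluster"

    def test_single_locus_no_cluster(self):
        assert build_clusters([GenomicLocus("mir-a", "chr1", 10, 20)]) == []

    def test_exact_boundary_gap_is_inclusive(self):
        loci = [
            GenomicLocus("mir-a", "chr1", 1000, 1100),
            # gap = 51101 - 1100 - 1 = 50,000 exactly
            GenomicLocus("mir-b", "chr1", 51101, 51200),
        ]
        assert partition(build_clusters(loci, max_gap=50_000)) == {
            frozenset({"mir-a", "mir-b"})
        }
        assert build_clusters(loci, max_gap=49_999) == []

    def test_overlapping_loci_gap_zero(self):
        loci = [
            GenomicLocus("mir-a", "chr1", 1000, 2000),
            GenomicLocus("mir-b", "chr1", 1500, 2500),
        ]
        assert partition(build_clusters(loci, max_gap=0)) == {
            frozenset({"mir-a", "mir-b"})
        }

    def test_duplicate_locus_rejected(self):
        loc = GenomicLocus("mir-a", "chr1", 10, 20)
        with pytest.raises(ValidationError):
            build_clusters([loc, loc])

    def test_natural_sort_naming(self):
        loci = [
            GenomicLocus("mir-10a", "chr1", 100, 200),
            GenomicLocus("mir-2", "chr1", 300, 400),
        ]
        (cat,) = build_clusters(loci)
        assert cat.id == "mir-2-cluster"
        assert cat.display_name == "mir-2 cluster"

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("max_gap", [0, 10_000, 50_000, 200_000])
    def test_matches_connected_components_oracle(self, seed, max_gap):
        loci = make_random_loci(FixtureSpec(seed=seed, n_loci=24, n_chroms=3))
        got = partition(build_clusters(loci, max_gap=max_gap))
        assert got == oracle_clusters(loci, max_gap)

    @pytest.mark.parametrize("seed", range(4))
    def test_same_strand_matches_oracle(self, seed):
        loci = make_random_loci(FixtureSpec(seed=seed, n_loci=20))
        got = partition(build_clusters(loci, max_gap=50_000, same_strand=True))
        assert got == oracle_clusters(loci, 50_000, same_strand=True)

    def test_input_order_invariance(self):
        loci = make_random_loci(FixtureSpec(seed=11, n_loci=30, n_chroms=2))
        base = partition(build_clusters(loci, max_gap=50_000))
        rng = random.Random(5)
        for _ in range(5):
            shuffled = loci[:]
            rng.shuffle(shuffled)
            assert partition(build_clusters(shuffled, max_gap=50_000)) == base

    def test_monotone_in_max_gap(self):
        """Enlarging the gap can only merge clusters, never split them."""
        loci = make_random_loci(FixtureSpec(seed=2, n_loci=24, n_chroms=2))
        prev = partition(build_clusters(loci, max_gap=1_000))
        for gap in (20_000, 50_000, 130_000, 10**7):
            cur = partition(build_clusters(loci, max_gap=gap))
            for small in prev:
                assert any(small <= big for big in cur)
            prev = cur

    def test_gff3_round_trip(self, tmp_path, three_loci):
        path = tmp_path / "loci.gff3"
        loci_to_gff3(three_loci, path)
        again = read_gff3_loci(path)
        assert sorted(again, key=lambda l: l.start) == three_loci


class TestFamilies:
    def test_mir181_family(self):
        cats = build_family_sets(
            [("mir-181", "miR-181 family",
              ["hsa-miR-181a", "hsa-miR-181b", "hsa-miR-181c", "hsa-miR-181d"])]
        )
        (fam,) = cats
        assert fam.size == 4
        assert fam.class_label == "family"
        assert "mir-181a" in fam.members

    def test_singleton_dropped_and_dedup(self):
        cats = build_family_sets(
            [
                ("solo", "solo", ["miR-9"]),
                ("dup", "dup", ["miR-1", "hsa-miR-1", "miR-2"]),
            ]
        )
        assert [c.id for c in cats] == ["dup"]
        assert cats[0].size == 2

    def test_mifam_stanzas(self, tmp_path):
        p = tmp_path / "mifam.dat"
        p.write_text(
            "AC MIPF0000001\nID mir-17\n"
            "MI MI0000071 hsa-mir-17\nMI MI0000093 hsa-mir-106a\n//\n"
            "AC MIPF0000002\nID mir-lonely\nMI MI0009999 hsa-mir-9999\n//\n"
        )
        fams = read_mifam(p)
        assert len(fams) == 2
        cats = build_family_sets(fams)
        (c,) = cats  # singleton family dropped
        assert c.id == "MIPF0000001"
        assert c.members == {"mir-17", "mir-106a"}


class TestTissue:
    def test_inclusive_threshold(self):
        records = [
            TSIRecord("mir-1", 0.9),
            TSIRecord("mir-21", 0.3),
            TSIRecord("mir-124", 0.7),  # exactly at threshold: kept
        ]
        grouping = {"mir-1": "heart", "mir-21": "liver", "mir-124": "brain"}
        cats = build_tissue_sets(records, grouping, threshold=0.7)
        assert {c.display_name: set(c.members) for c in cats} == {
            "heart specific": {"mir-1"},
            "brain specific": {"mir-124"},
        }

    def test_threshold_one_excludes_all(self):
        records = [TSIRecord("mir-1", 0.99)]
        assert build_tissue_sets(records, {"mir-1": "heart"}, threshold=1.0) == []

    def test_tsi_range_validated(self):
        with pytest.raises(ValidationError):
            TSIRecord("mir-1", 1.2)
        with pytest.raises(ValidationError):
            build_tissue_sets([], {}, threshold=2.0)

    @pytest.mark.parametrize("threshold", [0.0, 0.35, 0.7, 0.95])
    def test_matches_naive_filter(self, threshold):
        from mirenrich.fixtures import make_random_tsi

        records, grouping = make_random_tsi(FixtureSpec(seed=4, universe_size=80))
        cats = build_tissue_sets(records, grouping, threshold=threshold)
        naive = {}
        for r in records:
            if r.tsi >= threshold:
                naive.setdefault(grouping[r.mirna], set()).add(r.mirna)
        expected = {t: m for t, m in naive.items()}
        assert {c.display_name.removesuffix(" specific"): set(c.members)
                for c in cats} == expected


class TestAnnotation:
    def test_muscle_development_set(self, ami):
        rows = [("Muscle development", "function", m)
                for m in ami.muscle_members]
        (cat,) = build_annotation_sets(rows, source_tag="curated")
        assert cat.size == 11
        assert cat.class_label == "function"
        assert "curated" in cat.display_name

    def test_duplicate_rows_counted_once(self):
        rows = [("s", "disease", "miR-1"), ("s", "disease", "hsa-miR-1")]
        (cat,) = build_annotation_sets(rows)
        assert cat.size == 1

    def test_row_order_invariance(self):
        rows = [("a", "function", "miR-1"), ("b", "function", "miR-2"),
                ("a", "function", "miR-3")]
        fwd = build_annotation_sets(rows)
        rev = build_annotation_sets(list(reversed(rows)))
        assert {(c.id, c.members) for c in fwd} == {(c.id, c.members) for c in rev}

    def test_empty_member_rejected(self):
        from mirenrich.errors import FormatError

        with pytest.raises(FormatError):
            build_annotation_sets([("s", "function", "  ")])


class TestMerge:
    def test_disjoint_counts_sum(self):
        a = Catalog([Category("f1", "family", "f1", frozenset({"mir-1", "mir-2"}))])
        b = Catalog([Category("c1", "cluster", "c1", frozenset({"mir-3", "mir-4"}))])
        merged = merge_catalogs([a, b])
        assert len(merged) == 2
        assert len(merged.universe) == 4

    def test_overlapping_universe_counted_once(self):
        a = Catalog([Category("f1", "family", "f1", frozenset({"mir-1", "mir-2"}))])
        b = Catalog([Category("d1", "disease", "d1", frozenset({"mir-1", "mir-9"}))])
        assert len(merge_catalogs([a, b]).universe) == 3

    def test_id_collision_suffixed(self):
        a = Catalog([Category("x", "family", "x", frozenset({"mir-1", "mir-2"}))])
        b = Catalog([Category("x", "cluster", "x", frozenset({"mir-3", "mir-4"}))])
        merged = merge_catalogs([a, b])
        assert [c.id for c in merged] == ["x", "x-cluster"]

    def test_five_class_merge_preserves_per_class_counts(self):
        parts = []
        for label_seed in range(5):
            parts.append(make_random_catalog(
                FixtureSpec(seed=label_seed, n_per_class=4)))
        # each generated catalog already spans all five classes; merge of
        # five of them must multiply each class count by five
        merged = merge_catalogs(parts)
        counts = merged.class_counts()
        assert counts == {lab: 20 for lab in counts}
        assert len(merged) == sum(len(p) for p in parts)
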