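import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bulktrap as bt
from bulktrap.classifier import iter_canonical_kmers, resolve_hits

from kraken_oracle import (
    canon,
    oracle_classify,
    oracle_kmer_species,
    paths_from_tree,
    rc,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


@given(dna)
@settings(deadline=None)
def test_canonicalization_is_strand_symmetric(seq):
    assert bt.canonical_kmer(seq) == bt.canonical_kmer(bt.reverse_complement(seq))


class TestBuildIndex:
    def test_single_genome_maps_every_kmer_to_its_species(self, toy_tree):
        genomes = bt.GenomeSet({"g1s1": "ACGTACGGTTCA"})
        index = bt.build_index(genomes, toy_tree, k=5)
        assert set(index.kmer_to_taxon.values()) == {"g1s1"}

    def test_identical_genomes_in_different_genera_map_to_lca(self):
        tree = bt.make_taxonomy(2, 1)  # two genera in one family
        seq = "ACGTTGCAAGGTC"
        genomes = bt.GenomeSet({"g1s1": seq, "g2s1": seq})
        index = bt.build_index(genomes, tree, k=5)
        lca = tree.lca(["g1s1", "g2s1"])
        assert tree.rank(lca) == "family"
        assert set(index.kmer_to_taxon.values()) == {lca}

    def test_index_equals_exhaustive_enumeration(self, toy_tree):
        genomes = bt.GenomeSet(
            {"g1s1": "ACGTACGGTTCA", "g1s2": "ACGTACGCTTGA", "g2s1": "TTGACCGGATCA"}
        )
        index = bt.build_index(genomes, toy_tree, k=5)
        expected = {}
        for kmer, species in oracle_kmer_species(genomes.sequences, 5).items():
            expected[kmer] = (
                next(iter(species)) if len(species) == 1 else toy_tree.lca(species)
            )
        assert index.kmer_to_taxon == expected

    def test_k_longer_than_shortest_genome_rejected(self, toy_tree):
        genomes = bt.GenomeSet({"g1s1": "ACGTACG"})
        with pytest.raises(ValueError, match="shortest genome"):
            bt.build_index(genomes, toy_tree, k=8)

    def test_non_acgt_windows_skipped_and_counted(self, toy_tree):
        # lowercase input is upper-cased; N breaks k-mers
        sequences = {"g1s1": "ACGTACGGTTCA", "g1s2": "ACGTNCGGTTCA"}
        table = oracle_kmer_species({k: v for k, v in sequences.items()}, 5)
        index = bt.build_index(
            bt.GenomeSet({"g1s1": sequences["g1s1"]}), toy_tree, k=5
        )
        # windows spanning the N would contribute 5 k-mers
        assert all("N" not in kmer for kmer in table)
        assert index.skipped_kmers == 0


class TestClassifyRead:
    def test_random_bases_absent_from_genomes_unclassified(self, toy_tree, toy_genomes):
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        rng = np.random.default_rng(0)
        # a fresh random read almost surely shares no 31-mer with the genomes
        read = "".join(rng.choice(list("ACGT"), size=100))
        assert bt.classify_read(read, index) is None

    def test_identical_genomes_tie_resolves_to_lca(self):
        tree = bt.make_taxonomy(1, 2)
        seq = "ACGTTGCAAGGTCAGTTACAGGCAT"
        genomes = bt.GenomeSet({"g1s1": seq, "g1s2": seq})
        index = bt.build_index(genomes, tree, k=7)
        assert bt.classify_read(seq[:15], index) == "g1"

    def test_read_shorter_than_k_unclassified(self, toy_tree, toy_genomes):
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        assert bt.classify_read("ACGTACGT", index) is None

    def test_error_free_reads_assigned_to_ancestor_or_self(self, toy_tree, toy_genomes):
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        frame = pd.DataFrame(
            np.full((1, 6), 1 / 6),
            index=["s1"],
            columns=toy_tree.ids_at_rank("species"),
        )
        reads = bt.make_reads(
            toy_genomes, bt.CommunityTable(frame), n_reads=1000,
            read_length=80, error_rate=0.0, seed=13,
        )["s1"]
        for read in reads:
            assigned = bt.classify_read(read.sequence, index)
            assert assigned is not None
            assert toy_tree.is_ancestor_or_self(assigned, read.species)


@pytest.fixture(scope="module")
def three_dbs():
    tree = bt.make_taxonomy(3, 1)
    genomes = bt.make_genomes(tree, length=300, divergence=0.2, seed=21)
    indexes = [
        bt.build_index(bt.GenomeSet({sid: genomes.sequences[sid]}), tree, k=31,
                       name=f"db{i + 1}")
        for i, sid in enumerate(["g1s1", "g2s1", "g3s1"])
    ]
    return tree, genomes, indexes


@pytest.fixture(scope="module")
def sample_report(toy_tree, toy_genomes, toy_community):
    index = bt.build_index(toy_genomes, toy_tree, k=31)
    reads = bt.make_reads(toy_genomes, toy_community, n_reads=300,
                          read_length=80, error_rate=0.005, seed=41)["sample01"]
    report, _ = bt.classify_sample(reads, index, sample="sample01")
    return report, reads


class TestSequentialClassification:

    def test_exclusive_fixture_partitions_exactly(self, three_dbs):
        tree, genomes, indexes = three_dbs
        frame = pd.DataFrame(
            {"g1s1": [1 / 3], "g2s1": [1 / 3], "g3s1": [1 / 3]}, index=["s1"]
        )
        rng_reads = []
        for sid in ["g1s1", "g2s1", "g3s1"]:
            single = bt.CommunityTable(pd.DataFrame({sid: [1.0]}, index=["s1"]))
            rng_reads += bt.make_reads(genomes, single, n_reads=100, read_length=80,
                                       error_rate=0.0, seed=5)["s1"]
        reports, unclassified = bt.classify_sample_sequential(rng_reads, indexes)
        assert [r.clade_reads(tree.root) for r in reports] == [100, 100, 100]
        assert unclassified == []

    def test_read_matching_only_second_database(self, three_dbs):
        tree, genomes, indexes = three_dbs
        read = bt.Read("r", genomes.sequences["g2s1"][:80], "g2s1")
        reports, unclassified = bt.classify_sample_sequential([read], indexes)
        assert reports[0].classified() == 0
        assert reports[1].classified() == 1
        assert reports[2].n_reads == 0
        assert unclassified == []

    def test_empty_read_set_gives_all_zero_reports(self, three_dbs):
        tree, _, indexes = three_dbs
        reports, unclassified = bt.classify_sample_sequential([], indexes)
        assert unclassified == []
        for report in reports:
            assert report.n_reads == 0
            assert report.clade_reads(tree.root) == 0

    def test_conservation_with_random_reads(self, three_dbs):
        tree, genomes, indexes = three_dbs
        rng = np.random.default_rng(17)
        reads = [
            bt.Read(f"r{i}", "".join(rng.choice(list("ACGT"), size=80)), "")
            for i in range(50
            )
        ]
        frame = pd.DataFrame({"g1s1": [0.5], "g3s1": [0.5]}, index=["s1"])
        reads += bt.make_reads(genomes, bt.CommunityTable(frame), n_reads=150,
                               read_length=80, error_rate=0.01, seed=30)["s1"]
        reports, unclassified = bt.classify_sample_sequential(reads, indexes)
        classified = sum(r.classified() for r in reports)
        assert classified + len(unclassified) == len(reads)
        for report in reports:
            assert report.clade_reads(tree.root) == report.classified()


class TestReportSemantics:
    def test_clade_counts_are_recursive_sums(self, toy_tree, sample_report):
        report, _ = sample_report
        for nid in toy_tree.depth_first():
            expected = report.direct_reads.get(nid, 0) + sum(
                report.clade_reads(c) for c in toy_tree.children(nid)
            )
            assert report.clade_reads(nid) == expected

    def test_root_clade_plus_unclassified_is_total(self, toy_tree, sample_report):
        report, reads = sample_report
        assert report.clade_reads(toy_tree.root) + report.unclassified == len(reads)

    def test_distinct_minimisers_bounded_by_read_kmers(self, toy_tree, sample_report):
        report, reads = sample_report
        all_kmers = set()
        for read in reads:
            for kmer, ok in iter_canonical_kmers(read.sequence, 31):
                if ok:
                    all_kmers.add(kmer)
        assert report.clade_distinct_minimisers(toy_tree.root) <= len(all_kmers)

    def test_strand_symmetry_of_reports(self, toy_tree, toy_genomes, sample_report):
        report, reads = sample_report
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        flipped = [
            bt.Read(r.name, bt.reverse_complement(r.sequence), r.species) for r in reads
        ]
        rc_report, _ = bt.classify_sample(flipped, index, sample="sample01")
        assert rc_report.to_table().equals(report.to_table())

    def test_dilution_with_random_reads_preserves_distinct_counts(
        self, toy_tree, toy_genomes, sample_report
    ):
        report, reads = sample_report
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        rng = np.random.default_rng(55)
        noise = [
            bt.Read(f"noise{i}", "".join(rng.choice(list("ACGT"), size=80)), "")
            for i in range(100)
        ]
        diluted, _ = bt.classify_sample(list(reads) + noise, index, sample="sample01")
        for genus in toy_tree.ids_at_rank("genus"):
            assert diluted.clade_distinct_minimisers(genus) == report.clade_distinct_minimisers(genus)


class TestReportIO:
    def test_round_trip(self, tmp_path, toy_tree, toy_genomes, toy_community):
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        reads = bt.make_reads(toy_genomes, toy_community, n_reads=100,
                              read_length=80, error_rate=0.0, seed=3)["sample01"]
        report, _ = bt.classify_sample(reads, index)
        path = tmp_path / "report.tsv"
        bt.write_report(report, path)
        parsed = bt.read_report(path)
        pd.testing.assert_frame_equal(
            parsed.table, report.to_table(), check_dtype=False
        )
        pd.testing.assert_series_equal(
            parsed.distinct_minimisers_by_rank("genus"),
            report.distinct_minimisers_by_rank("genus"),
        )

    def test_empty_report_is_single_unclassified_row(self, tmp_path, toy_tree):
        report = bt.ClassificationReport(tree=toy_tree)
        table = report.to_table()
        assert len(table) == 1
        assert table.iloc[0]["rank_code"] == "U"
        assert table.iloc[0]["percent"] == 100.0

    def test_percent_sums_to_100_over_top_level_rows(self, toy_tree, toy_genomes,
                                                     toy_community):
        index = bt.build_index(toy_genomes, toy_tree, k=31)
        reads = bt.make_reads(toy_genomes, toy_community, n_reads=200,
                              read_length=80, error_rate=0.02, seed=9)["sample02"]
        report, _ = bt.classify_sample(reads, index)
        table = report.to_table()
        top = table[table["rank_code"].isin(["U", "R"])]
        assert top["percent"].sum() == pytest.approx(100.0, abs=0.1)


class TestOracleEquivalence:
    def test_small_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(2024)
        for trial in range(10):
            tree = bt.make_taxonomy(2, 2)
            k = int(rng.integers(3, 8))
            length = int(rng.integers(2 * k, 51))
            sequences = {
                sid: "".join(rng.choice(list("ACGT"), size=length))
                for sid in ["g1s1", "g1s2", "g2s1", "g2s2"]
            }
            genomes = bt.GenomeSet(sequences)
            index = bt.build_index(genomes, tree, k=k)
            kmer_species = oracle_kmer_species(sequences, k)
            node_paths = paths_from_tree(tree)
            for _ in range(30):
                src = rng.choice(list(sequences))
                seq = sequences[src]
                start = int(rng.integers(0, len(seq) - k + 1))
                read = seq[start : start + int(rng.integers(k, len(seq) - start + 1))]
                expected = oracle_classify(read, kmer_species, node_paths, tree, k)
                assert bt.classify_read(read, index) == expected
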