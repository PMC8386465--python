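import numpy as np
import pytest

from rrnsplit.catalog import Catalog, GenomeRecord, SeqCopy
from rrnsplit.clustering import opticlust_partition
from rrnsplit.distances import neighbor_pairs
from rrnsplit.variants import (
    dereplicate,
    genome_variant_stats,
    mean_variants_per_copy,
    species_accumulation,
)


def make_genome(acc, species, seqs):
    return GenomeRecord(
        acc, species, [SeqCopy(f"{acc}|{i}", acc, s) for i, s in enumerate(seqs, 1)]
    )


class TestDereplicate:
    def test_exact_equality_defines_membership(self):
        t = dereplicate([("ACGT", "G1", "A b"), ("ACGT", "G2", "A b"), ("ACGA", "G1", "A b")])
        assert t.n_asvs == 2
        counts = sorted(sum(n for _, _, n in mem) for mem in t.members.values())
        assert counts == [1, 2]

    def test_ids_dense_by_first_occurrence(self):
        t = dereplicate([("TTTT", "G1", "A b"), ("AAAA", "G1", "A b"), ("TTTT", "G2", "C d")])
        assert t.asv_of == {"TTTT": 1, "AAAA": 2}

    def test_partition_invariant_under_input_order(self):
        rng = np.random.default_rng(5)
        seqs = [("".join(rng.choice(list("ACGT"), 8)), f"G{i%3}", "A b") for i in range(30)]
        t1 = dereplicate(seqs)
        perm = [seqs[i] for i in rng.permutation(len(seqs))]
        t2 = dereplicate(perm)
        groups1 = {frozenset(s for s, a in t1.asv_of.items() if a == k) for k in t1.members}
        groups2 = {frozenset(s for s, a in t2.asv_of.items() if a == k) for k in t2.members}
        assert groups1 == groups2

    def test_ten_distinct_copies_make_ten_asvs(self):
        # two genomes, five copies each, all ten copies pairwise distinct:
        # dereplication yields ten ASVs even though only two genomes exist
        seqs = [
            (f"ACGTAC{b}{g}", f"G{g}", f"Staphylococcus s{g}")
            for g in (1, 2)
            for b in "ACGTN"
        ]
        t = dereplicate(seqs)
        assert t.n_asvs == 10

    def test_empty_input(self):
        t = dereplicate([])
        assert t.n_asvs == 0 and t.n_sequences == 0

    def test_conservation_of_counts(self):
        rng = np.random.default_rng(0)
        seqs = [("".join(rng.choice(list("ACGT"), 6)), "G1", "A b") for _ in range(100)]
        t = dereplicate(seqs)
        assert t.n_sequences == 100


class TestGenomeVariantStats:
    def test_five_of_seven_distinct(self):
        seqs = ["AAAA", "AAAA", "AAAA", "AAAC", "AAAG", "AAAT", "AACA"]
        g = make_genome("G1", "Escherichia coli", seqs)
        cat = Catalog([g])
        region = {c.copy_id: c.unaligned_seq for c in g.copies}
        table = dereplicate([(region[c.copy_id], "G1", "Escherichia coli") for c in g.copies])
        (stat,) = genome_variant_stats(cat, table, region)
        assert stat.copy_number == 7
        assert stat.n_asvs == 5
        assert stat.variants_per_copy == pytest.approx(5 / 7)

    def test_single_copy_genome_has_ratio_one(self):
        g = make_genome("G1", "A b", ["ACGT"])
        region = {"G1|1": "ACGT"}
        table = dereplicate([("ACGT", "G1", "A b")])
        (stat,) = genome_variant_stats(Catalog([g]), table, region)
        assert stat.n_asvs == 1 and stat.variants_per_copy == 1.0

    def test_genome_with_no_surviving_copies_omitted(self):
        g1 = make_genome("G1", "A b", ["ACGT"])
        g2 = make_genome("G2", "C d", ["TTTT"])
        region = {"G1|1": "ACGT"}  # G2's copy dropped at extraction
        table = dereplicate([("ACGT", "G1", "A b")])
        stats = genome_variant_stats(Catalog([g1, g2]), table, region)
        assert [s.accession for s in stats] == ["G1"]

    def test_identical_copy_genomes_mean_ratio(self):
        # all-identical copies: variants_per_copy = 1/copy_number per genome
        genomes = [make_genome(f"G{k}", f"S s{k}", ["ACGT"] * k) for k in (2, 4)]
        cat = Catalog(genomes)
        region = {c.copy_id: c.unaligned_seq for g in genomes for c in g.copies}
        table = dereplicate(
            [(c.unaligned_seq, g.accession, g.species_key) for g in genomes for c in g.copies]
        )
        stats = genome_variant_stats(cat, table, region)
        assert {s.accession: s.variants_per_copy for s in stats} == {"G2": 0.5, "G4": 0.25}
        means = mean_variants_per_copy(stats)
        assert means["per_genome_mean"] == pytest.approx((0.5 + 0.25) / 2)
        assert means["pooled_ratio"] == pytest.approx(2 / 6)


class TestSpeciesAccumulation:
    def test_two_single_copy_genomes_with_distinct_sequences(self):
        genomes = [make_genome("G1", "A b", ["ACGT"]), make_genome("G2", "A b", ["ACGA"])]
        cat = Catalog(genomes)
        region = {c.copy_id: c.unaligned_seq for g in genomes for c in g.copies}
        table = dereplicate(
            [(c.unaligned_seq, g.accession, g.species_key) for g in genomes for c in g.copies]
        )
        (acc,) = species_accumulation(cat, table, region)
        assert acc.total_distinct_variants == 2
        assert acc.n_genomes == 2
        assert acc.variants_per_operon_ratio() == 2.0

    def test_single_genome_species_degenerates_to_genome_stat(self):
        g = make_genome("G1", "A b", ["ACGT", "ACGA", "ACGT"])
        region = {c.copy_id: c.unaligned_seq for c in g.copies}
        table = dereplicate([(c.unaligned_seq, "G1", "A b") for c in g.copies])
        (acc,) = species_accumulation(Catalog([g]), table, region)
        assert acc.total_distinct_variants == 2

    def test_variant_pool_from_single_copy_genomes(self):
        """k single-copy genomes drawn from v distinct sequences pool to
        exactly v variants (exhaustively checked against a direct set count)."""
        rng = np.random.default_rng(11)
        pool = ["AAAA", "AACA", "AAGA", "AATA"]
        draws = [pool[i] for i in rng.integers(0, 4, size=9)]
        genomes = [make_genome(f"G{i}", "M tuberculosis", [s]) for i, s in enumerate(draws)]
        cat = Catalog(genomes)
        region = {c.copy_id: c.unaligned_seq for g in genomes for c in g.copies}
        table = dereplicate(
            [(c.unaligned_seq, g.accession, g.species_key) for g in genomes for c in g.copies]
        )
        (acc,) = species_accumulation(cat, table, region)
        assert acc.total_distinct_variants == len(set(draws))
        assert acc.total_distinct_variants >= max(1 for _ in genomes)


def test_dereplication_equals_clustering_at_threshold_zero():
    """Exact dereplication and MCC clustering at t=0 induce the same partition
    of the input sequences."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        seqs = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(20)]
        table = dereplicate([(s, "G", "A b") for s in seqs])
        nbrs = neighbor_pairs(seqs, d_max=0.10)
        part = opticlust_partition(nbrs, threshold=0.0, seed=1)
        derep_groups = {
            frozenset(i for i, s in enumerate(seqs) if table.asv_of[s] == a)
            for a in table.members
        }
        assert part.as_sets() == derep_groups
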