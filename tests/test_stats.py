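import numpy as np
import pytest

from rrnsplit.catalog import Catalog, GenomeRecord, SeqCopy
from rrnsplit.clustering import opticlust_partition
from rrnsplit.distances import neighbor_pairs
from rrnsplit.simulate import SynthConfig, generate_community, inject_shared_variant
from rrnsplit.stats import (
    StatConfig,
    analyze_subset,
    collapse_summary,
    default_threshold_grid,
    genome_intact,
    lump_curve,
    max_randomization_iqr,
    randomized_analysis,
    sample_one_genome_per_species,
    summarize_randomizations,
    threshold_curves,
)
from rrnsplit.variants import dereplicate


def region_map(catalog):
    """Identity 'region': every copy survives with its own full sequence."""
    return {
        c.copy_id: (c.unaligned_seq, c.aligned_seq)
        for g in catalog.genomes
        for c in g.copies
    }


def make_genome(acc, species, seqs):
    return GenomeRecord(
        acc, species, [SeqCopy(f"{acc}|{i}", acc, s) for i, s in enumerate(seqs, 1)]
    )


class TestDefaultGrid:
    def test_spans_quarter_to_ten_percent(self):
        grid = default_threshold_grid()
        assert grid[0] == 0.0025 and grid[-1] == 0.1 and len(grid) == 40
        steps = {round(b - a, 6) for a, b in zip(grid, grid[1:])}
        assert steps == {0.0025}


class TestSampling:
    def make_catalog(self):
        genomes = [make_genome("G1", "A b", ["ACGT"])]
        genomes += [make_genome(f"G2{i}", "C d", ["AAAA"]) for i in range(2)]
        genomes += [make_genome(f"G3{i}", "E f", ["TTTT"]) for i in range(5)]
        return Catalog(genomes)

    def test_exactly_one_genome_per_species(self):
        sub = sample_one_genome_per_species(self.make_catalog(), seed=0)
        assert sub.n_genomes == 3
        assert all(len(v) == 1 for v in sub.species_index.values())

    def test_singleton_species_always_selected(self):
        for seed in range(5):
            sub = sample_one_genome_per_species(self.make_catalog(), seed=seed)
            assert "G1" in {g.accession for g in sub.genomes}

    def test_same_seed_same_subset(self):
        cat = self.make_catalog()
        a = sample_one_genome_per_species(cat, seed=42)
        b = sample_one_genome_per_species(cat, seed=42)
        assert [g.accession for g in a.genomes] == [g.accession for g in b.genomes]

    def test_selection_is_uniform_over_genomes(self):
        cat = self.make_catalog()
        picks = [
            {g.accession for g in sample_one_genome_per_species(cat, seed=s).genomes}
            for s in range(200)
        ]
        counts = {f"G3{i}": sum(f"G3{i}" in p for p in picks) for i in range(5)}
        assert all(20 < c < 60 for c in counts.values())  # ~40 each


class TestGenomeIntact:
    def setup_method(self):
        self.genomes = [
            make_genome("G1", "A b", ["AAAA"]),
            make_genome("G2", "C d", ["CCCC", "CCCA"]),
        ]
        triples = [
            (c.unaligned_seq, g.accession, g.species_key)
            for g in self.genomes
            for c in g.copies
        ]
        self.table = dereplicate(triples)
        self.nbrs = neighbor_pairs(
            [s for s in self.table.sequences], d_max=0.5
        )

    def test_single_asv_genome_is_intact(self):
        part = opticlust_partition(self.nbrs, 0.0, seed=0)
        assert genome_intact(self.genomes[0], self.table, part)

    def test_split_genome_not_intact(self):
        part = opticlust_partition(self.nbrs, 0.0, seed=0)
        assert not genome_intact(self.genomes[1], self.table, part)

    def test_merged_genome_intact(self):
        part = opticlust_partition(self.nbrs, 0.25, seed=0)
        assert genome_intact(self.genomes[1], self.table, part)


class TestSummaries:
    def test_median_of_three(self):
        s = summarize_randomizations("x", [0.1, 0.2, 0.3])
        assert s.median == pytest.approx(0.2)

    def test_identical_replicates_zero_iqr(self):
        s = summarize_randomizations("x", [0.5] * 10)
        assert s.iqr == 0.0

    def test_linear_interpolation_quantiles(self):
        vals = list(range(1, 101))
        s = summarize_randomizations("x", vals)
        assert s.median == pytest.approx(50.5)
        assert s.iqr == pytest.approx(np.percentile(vals, 75) - np.percentile(vals, 25))


def small_stat_config(**kw):
    defaults = dict(
        thresholds=(0.01, 0.02, 0.03, 0.05),
        n_randomizations=3,
        min_species_per_copy_class=0,
        master_seed=1,
    )
    defaults.update(kw)
    return StatConfig(**defaults)


class TestAnalyzeSubset:
    def test_identical_copies_intact_everywhere(self):
        cfg = SynthConfig(n_species=6, copies_per_genome=3, intragenomic_subs=0, seed=2)
        cat = generate_community(cfg).catalog
        res = analyze_subset(cat, "whole", region_map(cat), small_stat_config())
        assert res.fraction_intact[3] == [1.0] * 4
        assert res.collapse_threshold(3) == 0.01

    def test_split_genomes_collapse_at_constructed_distance(self):
        # one within-genome pair at 30/1500 = 0.02; no cross-genome bridging
        cfg = SynthConfig(n_species=8, copies_per_genome=3, intragenomic_subs=[0, 30], seed=3)
        cat = generate_community(cfg).catalog
        res = analyze_subset(cat, "whole", region_map(cat), small_stat_config())
        assert res.fraction_intact[3] == [0.0, 1.0, 1.0, 1.0]
        assert res.collapse_threshold(3) == 0.02

    def test_lumping_fraction_with_shared_variant(self):
        # 10 species, one identical sequence shared by exactly two of them,
        # all other ASVs species-private: 11 ASVs, one multi-species
        cfg = SynthConfig(n_species=10, copies_per_genome=2, intragenomic_subs=[1], seed=4)
        community = generate_community(cfg)
        inject_shared_variant(community, 2, 7, seed=5)
        cat = community.catalog
        res = analyze_subset(cat, "whole", region_map(cat), small_stat_config())
        table = dereplicate(
            [(c.unaligned_seq, g.accession, g.species_key) for g in cat.genomes for c in g.copies]
        )
        expected = (
            sum(1 for a in table.members if len(table.species_of(a)) > 1)
            / table.n_asvs
        )
        assert res.asv_fraction_multi == pytest.approx(expected)
        assert expected > 0

    def test_single_otu_when_threshold_exceeds_diameter(self):
        genomes = [
            make_genome("G1", "A b", ["AAAA"]),
            make_genome("G2", "C d", ["AAAC"]),
        ]
        cat = Catalog(genomes)
        cfg = StatConfig(
            thresholds=(0.5,), n_randomizations=1,
            min_species_per_copy_class=0, master_seed=0, d_max=1.0,
        )
        res = analyze_subset(cat, "whole", region_map(cat), cfg)
        assert res.fraction_multi == [1.0]


class TestRandomizedAnalysis:
    def make_community(self):
        cfg = SynthConfig(
            n_species=6, genomes_per_species=2, copies_per_genome=3,
            intragenomic_subs=[0, 30], seed=11,
        )
        return generate_community(cfg).catalog

    def test_replicates_reproducible_from_master_seed(self):
        cat = self.make_community()
        cfg = small_stat_config()
        maps = {"whole": region_map(cat)}
        r1 = randomized_analysis(cat, maps, cfg)
        r2 = randomized_analysis(cat, maps, cfg)
        for a, b in zip(r1, r2):
            assert a.fraction_intact == b.fraction_intact
            assert a.fraction_multi == b.fraction_multi

    def test_collapse_summary_median_and_filter(self):
        cat = self.make_community()
        cfg = small_stat_config()
        results = randomized_analysis(cat, {"whole": region_map(cat)}, cfg)
        summary = collapse_summary(results, cfg)
        row = summary[(summary.region == "whole") & (summary.copy_class == 3)]
        assert row.median_collapse_threshold.iloc[0] == pytest.approx(0.02)
        # with a high species floor the class disappears
        strict = collapse_summary(results, small_stat_config(min_species_per_copy_class=100))
        assert strict.empty

    def test_threshold_and_lump_curves(self):
        cat = self.make_community()
        cfg = small_stat_config()
        results = randomized_analysis(cat, {"whole": region_map(cat)}, cfg)
        (curve,) = threshold_curves(results, cfg, "whole")
        assert curve.copy_class == 3
        assert curve.collapse_threshold == pytest.approx(0.02)
        assert all(0 <= f <= 1 for f in curve.fraction_intact)
        lc = lump_curve(results, cfg, "whole")
        assert lc.asv_fraction_multi == 0.0
        assert all(f == 0.0 for f in lc.fraction_multi)  # well-separated species

    def test_max_iqr_zero_for_deterministic_community(self):
        # every species has identical genome structure, so all randomizations agree
        cat = self.make_community()
        cfg = small_stat_config()
        results = randomized_analysis(cat, {"whole": region_map(cat)}, cfg)
        assert max_randomization_iqr(results, cfg) == 0.0


def test_asv_fraction_equals_otu_fraction_at_threshold_zero():
    cfg = SynthConfig(
        n_species=8, copies_per_genome=2, intragenomic_subs=[1],
        shared_variant_links=((0, 4),), seed=21,
    )
    cat = generate_community(cfg).catalog
    scfg = StatConfig(
        thresholds=(0.0, 0.01), n_randomizations=1,
        min_species_per_copy_class=0, master_seed=3,
    )
    res = analyze_subset(cat, "whole", region_map(cat), scfg)
    assert res.fraction_multi[0] == pytest.approx(res.asv_fraction_multi)
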