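import numpy as np
import pandas as pd
import pytest

from rrnsplit.catalog import build_catalog, parse_metadata, parse_sequences
from rrnsplit.simulate import (
    Community,
    SynthConfig,
    compute_ground_truth,
    generate_community,
    inject_shared_variant,
    write_community,
)
from rrnsplit.variants import dereplicate


def derep_community(community):
    return dereplicate(
        [
            (c.unaligned_seq, g.accession, g.species_key)
            for g in community.catalog.genomes
            for c in g.copies
        ]
    )


class TestGenerateCommunity:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SynthConfig(n_species=6, copies_per_genome=3, intragenomic_subs=2, seed=9)
        p1 = write_community(generate_community(cfg), tmp_path / "a")
        p2 = write_community(generate_community(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_identical_copies_give_one_asv_per_genome(self):
        cfg = SynthConfig(n_species=8, copies_per_genome=7, intragenomic_subs=0, seed=3)
        truth = compute_ground_truth(generate_community(cfg), species_pairs=False)
        assert (truth.per_genome.true_n_asvs == 1).all()
        assert (truth.per_genome.copy_number == 7).all()

    def test_configured_substitutions_give_exact_distance(self):
        # one copy at exactly 30 substitutions over length 1500 -> 0.02
        cfg = SynthConfig(
            n_species=4, copies_per_genome=3, intragenomic_subs=[0, 30], seed=5
        )
        community = generate_community(cfg)
        truth = compute_ground_truth(community, species_pairs=False)
        assert truth.per_genome.max_intra_distance.tolist() == pytest.approx([0.02] * 4)
        assert (truth.per_genome.true_n_asvs == 2).all()

    def test_species_templates_respect_minimum_separation(self):
        cfg = SynthConfig(n_species=10, copies_per_genome=1, intragenomic_subs=0,
                          interspecies_subs=150, seed=1)
        truth = compute_ground_truth(generate_community(cfg))
        assert truth.species_pair_min_distance.min_distance.min() >= 150 / 1500

    def test_well_separated_flag_validates_config(self):
        with pytest.raises(ValueError, match="well-separated"):
            SynthConfig(n_species=2, intragenomic_subs=100, interspecies_subs=150)

    def test_copy_number_distribution_bounded(self):
        cfg = SynthConfig(
            n_species=30, copies_per_genome=("uniform", 1, 19),
            intragenomic_subs=1, seed=2,
        )
        truth = compute_ground_truth(generate_community(cfg), species_pairs=False)
        assert truth.per_genome.copy_number.between(1, 19).all()
        assert truth.per_genome.copy_number.nunique() > 5

    def test_mixture_mode_leaves_some_copies_identical(self):
        cfg = SynthConfig(
            n_species=40, copies_per_genome=7,
            intragenomic_subs=("mixture", 0.5, 5), seed=12,
        )
        truth = compute_ground_truth(generate_community(cfg), species_pairs=False)
        # expected distinct ASVs per 7-copy genome: 1 + 6*(1-p) = 4
        mean_asvs = truth.per_genome.true_n_asvs.mean()
        assert 3.0 < mean_asvs < 5.0
        assert truth.per_genome.true_n_asvs.min() >= 1
        assert truth.per_genome.true_n_asvs.max() <= 7

    def test_multiple_genomes_per_species(self):
        cfg = SynthConfig(
            n_species=5, genomes_per_species=[1, 2, 5, 1, 3],
            copies_per_genome=2, intragenomic_subs=1, seed=4,
        )
        community = generate_community(cfg)
        sizes = sorted(len(v) for v in community.catalog.species_index.values())
        assert sizes == [1, 1, 2, 3, 5]


class TestSharedVariants:
    def test_injection_creates_one_multi_species_asv(self):
        cfg = SynthConfig(n_species=6, copies_per_genome=3, intragenomic_subs=1, seed=7)
        community = generate_community(cfg)
        inject_shared_variant(community, 0, 1, seed=11)
        table = derep_community(community)
        multi = [a for a in table.members if len(table.species_of(a)) > 1]
        assert len(multi) == 1

    def test_no_injection_no_multi_species_asvs(self):
        cfg = SynthConfig(n_species=6, copies_per_genome=3, intragenomic_subs=1, seed=7)
        table = derep_community(generate_community(cfg))
        assert table.multi_species_fraction() == 0.0

    def test_links_in_config_are_applied(self):
        cfg = SynthConfig(
            n_species=10, copies_per_genome=2, intragenomic_subs=1,
            shared_variant_links=((0, 1), (2, 3)), seed=8,
        )
        community = generate_community(cfg)
        truth = compute_ground_truth(community, species_pairs=False)
        assert len(truth.shared_variants) == 2
        table = derep_community(community)
        multi = [a for a in table.members if len(table.species_of(a)) > 1]
        assert len(multi) == 2

    def test_missing_species_rejected(self):
        community = generate_community(SynthConfig(n_species=2, seed=1))
        with pytest.raises(KeyError):
            inject_shared_variant(community, 0, 99)


def test_ground_truth_recomputable_from_emitted_files(tmp_path):
    cfg = SynthConfig(
        n_species=5, copies_per_genome=3, intragenomic_subs=[0, 15],
        shared_variant_links=((1, 3),), seed=13,
    )
    community = generate_community(cfg)
    truth = compute_ground_truth(community)
    paths = write_community(community, tmp_path, ground_truth=truth)

    # reload through the catalog parsers and recompute
    seqs = parse_sequences(paths["sequences"])
    meta = parse_metadata(paths["metadata"])
    catalog, orphans = build_catalog(seqs, meta)
    assert not orphans
    reloaded = Community(catalog=catalog, config=cfg, shared_variants=community.shared_variants)
    truth2 = compute_ground_truth(reloaded)
    pd.testing.assert_frame_equal(
        truth.per_genome.sort_values("accession").reset_index(drop=True),
        truth2.per_genome.sort_values("accession").reset_index(drop=True),
    )
    pd.testing.assert_frame_equal(
        truth.species_pair_min_distance, truth2.species_pair_min_distance
    )


def test_indel_and_n_modes_emit_expected_characters():
    cfg = SynthConfig(
        n_species=3, copies_per_genome=2, intragenomic_subs=1,
        indel_rate=0.01, n_rate=0.01, seed=6,
    )
    community = generate_community(cfg)
    joined = "".join(
        c.aligned_seq for g in community.catalog.genomes for c in g.copies
    )
    assert "-" in joined and "N" in joined
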