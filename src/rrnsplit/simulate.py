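"""Synthetic multi-copy-genome communities with analytic ground truth.

The generator emulates the statistical structure of a curated rrn-copy-number
collection: a set of species, each with one or more genome assemblies, each
genome carrying 1-19 copies of the 16S gene.  Within a genome, every mutated
position is used at most once (substitutions are sampled without
replacement from a per-species position pool), so the configured
substitution counts map exactly to Hamming distances and the ground-truth
intragenomic distances are analytic.  Species templates are drawn
independently and rejection-checked against a minimum pairwise separation.

The emitted alignment is columnar (no indels) by default: alignment column i
is position i of every sequence, so region extraction is an exact substring
operation.  An optional indel mode punches gap columns into individual
copies to exercise gap-policy code paths (ground-truth distances are then no
longer analytic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, GenomeRecord, SeqCopy, write_catalog
from .distances import pairwise_distance

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic community.

    ``genomes_per_species`` and ``copies_per_genome`` accept a constant, an
    explicit per-species/per-genome list, or a distribution spec
    (("geometric", p) for genomes; ("uniform", lo, hi) for copies, bounded
    to the observed 1-19 range).  ``intragenomic_subs`` is the substitution
    count of each non-template copy from its genome template (or a per-copy
    list, or ("mixture", p_identical, subs): each non-template copy is
    identical to the template with probability p_identical, else carries
    ``subs`` substitutions — emulating the common pattern where only some
    operon copies have diverged); ``intergenomic_subs`` separates genome
    templates of one species;
    ``interspecies_subs`` is the minimum separation between species
    templates, enforced by rejection sampling.
    """

    n_species: int = 50
    genomes_per_species: int | Sequence[int] | tuple = 1
    copies_per_genome: int | Sequence[int] | tuple = 4
    seq_length: int = 1500
    intragenomic_subs: int | Sequence[int] | tuple = 3
    intergenomic_subs: int = 0
    interspecies_subs: int = 150
    well_separated: bool = True
    shared_variant_links: tuple[tuple[int, int], ...] = ()
    indel_rate: float = 0.0
    n_rate: float = 0.0
    genus: str = "Simulacrum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")
        if self.well_separated:
            intra = self.intragenomic_subs
            if isinstance(intra, int):
                worst = intra
            elif isinstance(intra, tuple) and intra and intra[0] == "mixture":
                worst = int(intra[2])
            else:
                worst = max(intra)
            if self.interspecies_subs <= 2 * worst:
                raise ValueError(
                    "well-separated communities need interspecies_subs >"
                    f" 2*intragenomic_subs ({self.interspecies_subs} vs {worst})"
                )


@dataclass
class Community:
    """A generated community: a catalog plus its generating conditions."""

    catalog: Catalog
    config: SynthConfig
    shared_variants: list[tuple[str, str, str]] = field(default_factory=list)
    #: (species_key_a, species_key_b, shared sequence)


@dataclass
class GroundTruth:
    """Recomputable truths about a community, derived from its sequences."""

    per_genome: pd.DataFrame  # accession, species, copy_number, true_n_asvs, max_intra_distance
    species_pair_min_distance: pd.DataFrame  # species_a, species_b, min_distance
    shared_variants: list[tuple[str, str, str]]


def _resolve_counts(spec, n: int, rng: np.random.Generator, lo: int, hi: int) -> list[int]:
    if isinstance(spec, int):
        counts = [spec] * n
    elif isinstance(spec, tuple) and spec and isinstance(spec[0], str):
        kind = spec[0]
        if kind == "geometric":
            counts = [int(rng.geometric(spec[1])) for _ in range(n)]
        elif kind == "uniform":
            counts = [int(rng.integers(spec[1], spec[2] + 1)) for _ in range(n)]
        else:
            raise ValueError(f"unknown distribution spec {spec!r}")
    else:
        counts = [int(c) for c in spec]
        if len(counts) != n:
            raise ValueError(f"explicit count list has {len(counts)} entries, need {n}")
    counts = [min(max(c, lo), hi) for c in counts]
    return counts


def _min_pairwise_hamming(mat: np.ndarray) -> int:
    best = mat.shape[1]
    for i in range(mat.shape[0] - 1):
        best = min(best, int((mat[i + 1 :] != mat[i]).sum(axis=1).min()))
    return best


def _sample_templates(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    for _ in range(20):
        mat = _BASES[rng.integers(0, 4, size=(cfg.n_species, cfg.seq_length))]
        if cfg.n_species == 1 or _min_pairwise_hamming(mat) >= cfg.interspecies_subs:
            return mat
    raise GenerationError(
        f"could not draw {cfg.n_species} species templates at least"
        f" {cfg.interspecies_subs} substitutions apart in 20 attempts"
    )


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return out


def generate_community(cfg: SynthConfig) -> Community:
    """Deterministically generate a community from its config and seed."""
    rng = np.random.default_rng(cfg.seed)
    templates = _sample_templates(cfg, rng)
    genome_counts = _resolve_counts(cfg.genomes_per_species, cfg.n_species, rng, 1, 10**6)

    genomes: list[GenomeRecord] = []
    for s in range(cfg.n_species):
        species_key = f"{cfg.genus} species{s:04d}"
        pool = rng.permutation(cfg.seq_length)
        cursor = 0

        def take(k: int) -> np.ndarray:
            nonlocal cursor
            if cursor + k > cfg.seq_length:
                raise GenerationError(
                    f"species {species_key}: mutation budget exceeds sequence length"
                )
            out = pool[cursor : cursor + k]
            cursor += k
            return out

        copy_counts = _resolve_counts(
            cfg.copies_per_genome, genome_counts[s], rng, 1, 19
        )
        for g in range(genome_counts[s]):
            acc = f"SYN{s:04d}G{g:02d}"
            g_template = _mutate(templates[s], take(cfg.intergenomic_subs), rng)
            n_copies = copy_counts[g]
            if isinstance(cfg.intragenomic_subs, int):
                subs = [cfg.intragenomic_subs] * (n_copies - 1)
            elif (
                isinstance(cfg.intragenomic_subs, tuple)
                and cfg.intragenomic_subs
                and cfg.intragenomic_subs[0] == "mixture"
            ):
                _, p_identical, k = cfg.intragenomic_subs
                subs = [
                    0 if rng.random() < p_identical else int(k)
                    for _ in range(n_copies - 1)
                ]
            else:
                subs = list(cfg.intragenomic_subs)
                if len(subs) != n_copies - 1:
                    raise ValueError(
                        f"intragenomic_subs list must have copies_per_genome-1"
                        f" = {n_copies - 1} entries, got {len(subs)}"
                    )
            copies_arr = [g_template]
            for k in subs:
                copies_arr.append(_mutate(g_template, take(k), rng))
            copies = []
            for i, arr in enumerate(copies_arr, start=1):
                seq = arr.tobytes().decode()
                if cfg.n_rate > 0:
                    seq = _sprinkle(seq, "N", cfg.n_rate, rng)
                if cfg.indel_rate > 0:
                    seq = _sprinkle(seq, "-", cfg.indel_rate, rng)
                copies.append(
                    SeqCopy(copy_id=f"{acc}|{i}", genome_accession=acc, aligned_seq=seq)
                )
            genomes.append(GenomeRecord(accession=acc, species_key=species_key, copies=copies))

    community = Community(catalog=Catalog(genomes), config=cfg)
    for a, b in cfg.shared_variant_links:
        link_seed = int(rng.integers(2**31))
        inject_shared_variant(community, a, b, seed=link_seed)
    return community


def _sprinkle(seq: str, char: str, rate: float, rng: np.random.Generator) -> str:
    n = int(round(rate * len(seq)))
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = char
    return "".join(out)


def _species_key(cfg: SynthConfig, idx: int) -> str:
    return f"{cfg.genus} species{idx:04d}"


def inject_shared_variant(
    community: Community,
    species_a: int | str,
    species_b: int | str,
    seed: int = 0,
    donor_copy: int | None = None,
    target_copy: int | None = None,
) -> Community:
    """Overwrite one copy in one genome of species_b with an exact copy of a
    sequence from species_a, creating a deliberate multi-species ASV.

    Donor and target copies are chosen at random (seeded) unless the
    0-based ``donor_copy``/``target_copy`` indices pin them down.
    """
    cfg = community.config
    key_a = _species_key(cfg, species_a) if isinstance(species_a, int) else species_a
    key_b = _species_key(cfg, species_b) if isinstance(species_b, int) else species_b
    idx = community.catalog.species_index
    for key in (key_a, key_b):
        if key not in idx:
            raise KeyError(f"species {key!r} not in community")
    rng = np.random.default_rng(seed)
    donor = community.catalog.genome(sorted(idx[key_a])[0])
    di = donor_copy if donor_copy is not None else int(rng.integers(len(donor.copies)))
    donated = donor.copies[di]
    target_acc = sorted(idx[key_b])[int(rng.integers(len(idx[key_b])))]
    target = community.catalog.genome(target_acc)
    slot = target_copy if target_copy is not None else int(rng.integers(len(target.copies)))
    old = target.copies[slot]
    target.copies[slot] = replace(old, aligned_seq=donated.aligned_seq)
    community.shared_variants.append((key_a, key_b, donated.aligned_seq))
    return community


def compute_ground_truth(
    community: Community, species_pairs: bool = True
) -> GroundTruth:
    """Recompute the community's ground truth from its emitted sequences."""
    rows = []
    for g in community.catalog.genomes:
        seqs = [c.aligned_seq for c in g.copies]
        distinct = len({c.unaligned_seq for c in g.copies})
        dmax = 0.0
        for i in range(len(seqs) - 1):
            for j in range(i + 1, len(seqs)):
                dmax = max(dmax, pairwise_distance(seqs[i], seqs[j]))
        rows.append(
            {
                "accession": g.accession,
                "species": g.species_key,
                "copy_number": g.copy_number,
                "true_n_asvs": distinct,
                "max_intra_distance": dmax,
            }
        )
    per_genome = pd.DataFrame(
        rows, columns=["accession", "species", "copy_number", "true_n_asvs", "max_intra_distance"]
    )

    pair_rows = []
    if species_pairs:
        by_species: dict[str, list[str]] = {}
        for g in community.catalog.genomes:
            by_species.setdefault(g.species_key, []).extend(
                c.aligned_seq for c in g.copies
            )
        keys = sorted(by_species)
        widths = {len(s) for seqs in by_species.values() for s in seqs}
        columnar = len(widths) == 1 and community.config.indel_rate == 0
        mats = (
            {
                k: np.frombuffer("".join(v).encode(), dtype=np.uint8).reshape(len(v), -1)
                for k, v in by_species.items()
            }
            if columnar
            else None
        )
        for i in range(len(keys) - 1):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                if mats is not None:
                    ma, mb = mats[a], mats[b]
                    dmin = min(
                        float((mb != row).sum(axis=1).min()) / ma.shape[1] for row in ma
                    )
                else:
                    dmin = min(
                        pairwise_distance(x, y)
                        for x in by_species[a]
                        for y in by_species[b]
                    )
                pair_rows.append({"species_a": a, "species_b": b, "min_distance": dmin})
    pair_df = pd.DataFrame(pair_rows, columns=["species_a", "species_b", "min_distance"])
    return GroundTruth(
        per_genome=per_genome,
        species_pair_min_distance=pair_df,
        shared_variants=list(community.shared_variants),
    )


def write_community(
    community: Community, outdir: str | Path, ground_truth: GroundTruth | None = None
) -> dict[str, Path]:
    """Emit the FASTA/TSV dialects the catalog module reads, plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "metadata": outdir / "metadata.tsv",
    }
    cat = community.catalog
    meta_rows = [
        {
            "accession": g.accession,
            "organism": f"{g.species_key} strain {g.accession}",
        }
        for g in cat.genomes
    ]
    write_catalog(cat, paths["sequences"], outdir / "_catalog_meta.tsv")
    (outdir / "_catalog_meta.tsv").unlink()
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], sep="\t", index=False)

    if ground_truth is not None:
        paths["truth_genomes"] = outdir / "truth_genomes.tsv"
        ground_truth.per_genome.to_csv(
            paths["truth_genomes"], sep="\t", index=False, float_format="%.6f"
        )
        paths["truth_species_pairs"] = outdir / "truth_species_pairs.tsv"
        ground_truth.species_pair_min_distance.to_csv(
            paths["truth_species_pairs"], sep="\t", index=False, float_format="%.6f"
        )
        paths["truth_summary"] = outdir / "truth_summary.txt"
        with open(paths["truth_summary"], "w") as fh:
            fh.write(f"n_species\t{cat.n_species}\n")
            fh.write(f"n_genomes\t{cat.n_genomes}\n")
            fh.write(f"n_shared_variants\t{len(ground_truth.shared_variants)}\n")
            for a, b, _ in ground_truth.shared_variants:
                fh.write(f"shared_variant\t{a}\t{b}\n")
    return paths
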