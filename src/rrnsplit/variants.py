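"""Dereplication into amplicon sequence variants (ASVs) and per-genome /
per-species variant statistics.

An ASV is the cluster of sequences that are exactly identical to one another
(a 0%-distance unit).  Because the inputs here are ideal sequences taken from
assembled genomes, dereplication is exact string equality on degapped,
uppercased, U-to-T normalized sequences; sequences containing N are compared
literally (N != A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Literal

import pandas as pd

from .catalog import Catalog


@dataclass
class AsvTable:
    """Mapping from distinct region sequences to ASV identifiers.

    ``asv_of`` maps each canonical sequence to a dense 1-based integer id,
    assigned by first occurrence in input order.  ``members`` maps each
    asv_id to (genome_accession, species_key, count) tuples.
    """

    region_name: str = ""
    asv_of: dict[str, int] = field(default_factory=dict)
    members: dict[int, list[tuple[str, str, int]]] = field(default_factory=dict)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_of)

    @property
    def n_sequences(self) -> int:
        return sum(n for mem in self.members.values() for _, _, n in mem)

    @property
    def sequences(self) -> list[str]:
        """Canonical sequences ordered by asv_id (1..n)."""
        return [s for s, _ in sorted(self.asv_of.items(), key=lambda kv: kv[1])]

    def species_of(self, asv_id: int) -> set[str]:
        return {sp for _, sp, _ in self.members[asv_id]}

    def genomes_of(self, asv_id: int) -> set[str]:
        return {g for g, _, _ in self.members[asv_id]}

    def asvs_of_genome(self, accession: str) -> set[int]:
        return {
            a for a, mem in self.members.items() if any(g == accession for g, _, _ in mem)
        }

    def multi_species_fraction(self) -> float:
        """Fraction of ASVs whose members span two or more species."""
        if not self.members:
            return 0.0
        multi = sum(1 for a in self.members if len(self.species_of(a)) > 1)
        return multi / len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "asv_id": a,
                "sequence": seq,
                "genome": g,
                "species": sp,
                "count": n,
            }
            for seq, a in sorted(self.asv_of.items(), key=lambda kv: kv[1])
            for g, sp, n in self.members[a]
        ]
        return pd.DataFrame(
            rows, columns=["asv_id", "sequence", "genome", "species", "count"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def dereplicate(
    seqs: Iterable[tuple[str, str, str]], region_name: str = ""
) -> AsvTable:
    """Collapse (sequence, genome_accession, species_key) triples into ASVs.

    Exact string equality defines membership; asv_ids are dense integers from
    1 in order of first occurrence.  Sequences must already be degapped,
    uppercase, U-normalized (the catalog and region modules guarantee this).
    """
    table = AsvTable(region_name=region_name)
    counts: dict[tuple[int, str, str], int] = {}
    for seq, acc, sp in seqs:
        a = table.asv_of.get(seq)
        if a is None:
            a = len(table.asv_of) + 1
            table.asv_of[seq] = a
        counts[(a, acc, sp)] = counts.get((a, acc, sp), 0) + 1
    for (a, acc, sp), n in counts.items():
        table.members.setdefault(a, []).append((acc, sp, n))
    return table


@dataclass(frozen=True)
class GenomeVariantStat:
    """Distinct-variant count for one genome in one region."""

    accession: str
    species_key: str
    copy_number: int  # copies surviving region extraction
    n_asvs: int

    @property
    def variants_per_copy(self) -> float:
        return self.n_asvs / self.copy_number


@dataclass(frozen=True)
class SpeciesAccumulation:
    """Variant accumulation across all sampled genomes of one species."""

    species_key: str
    n_genomes: int
    total_distinct_variants: int
    mean_copy_number: float
    median_copy_number: float

    def variants_per_operon_ratio(self, center: Literal["median", "mean"] = "median") -> float:
        denom = self.median_copy_number if center == "median" else self.mean_copy_number
        return self.total_distinct_variants / denom


def genome_variant_stats(
    catalog: Catalog,
    table: AsvTable,
    region_seqs: dict[str, str],
) -> list[GenomeVariantStat]:
    """Per-genome variant counts for one region.

    ``region_seqs`` maps copy_id to its degapped region sequence (copies
    dropped at region extraction are simply absent).  Genomes with zero
    surviving copies are omitted.
    """
    stats: list[GenomeVariantStat] = []
    for g in catalog.genomes:
        seqs = [region_seqs[c.copy_id] for c in g.copies if c.copy_id in region_seqs]
        if not seqs:
            continue
        distinct = {table.asv_of[s] for s in seqs}
        stats.append(
            GenomeVariantStat(
                accession=g.accession,
                species_key=g.species_key,
                copy_number=len(seqs),
                n_asvs=len(distinct),
            )
        )
    return stats


def mean_variants_per_copy(stats: list[GenomeVariantStat]) -> dict[str, float]:
    """The headline "variants per copy" figure, three ways.

    per_genome_mean: unweighted mean over genomes of n_asvs/copies (the
    headline statistic); per_species_mean: mean over species of the
    per-genome means; pooled_ratio: total ASV count over total copies.
    """
    if not stats:
        return {"per_genome_mean": 0.0, "per_species_mean": 0.0, "pooled_ratio": 0.0}
    per_genome = [s.variants_per_copy for s in stats]
    by_species: dict[str, list[float]] = {}
    for s in stats:
        by_species.setdefault(s.species_key, []).append(s.variants_per_copy)
    per_species = [sum(v) / len(v) for v in by_species.values()]
    total_asvs = sum(s.n_asvs for s in stats)
    total_copies = sum(s.copy_number for s in stats)
    return {
        "per_genome_mean": sum(per_genome) / len(per_genome),
        "per_species_mean": sum(per_species) / len(per_species),
        "pooled_ratio": total_asvs / total_copies,
    }


def species_accumulation(
    catalog: Catalog,
    table: AsvTable,
    region_seqs: dict[str, str],
) -> list[SpeciesAccumulation]:
    """Distinct variants pooled across all genomes of each species.

    The per-operon ratio divides by the median copy number of the species'
    genomes (robust to assembly outliers); the mean is also carried.
    """
    per_species: dict[str, dict[str, list]] = {}
    for g in catalog.genomes:
        seqs = [region_seqs[c.copy_id] for c in g.copies if c.copy_id in region_seqs]
        if not seqs:
            continue
        d = per_species.setdefault(g.species_key, {"asvs": set(), "copies": []})
        d["asvs"].update(table.asv_of[s] for s in seqs)
        d["copies"].append(len(seqs))
    out: list[SpeciesAccumulation] = []
    for sp, d in per_species.items():
        copies = d["copies"]
        out.append(
            SpeciesAccumulation(
                species_key=sp,
                n_genomes=len(copies),
                total_distinct_variants=len(d["asvs"]),
                mean_copy_number=sum(copies) / len(copies),
                median_copy_number=float(median(copies)),
            )
        )
    return out
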