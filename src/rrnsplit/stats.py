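"""Genome-splitting threshold curves and multi-species lumping fractions
under species-controlled resampling.

Two risks trade off against each other as the OTU distance threshold widens:

* *splitting* — the 16S copies of one genome land in several clusters
  (quantified per rrn copy-number class as the fraction of genomes whose
  ASVs all fall in a single OTU, and the smallest threshold at which that
  fraction reaches a confidence level, default 95%);
* *lumping* — one ASV or OTU contains sequences from several species
  (quantified as the fraction of units spanning two or more species keys).

Because species are unevenly represented by genomes, every statistic is
computed on random subsets holding exactly one genome per species, repeated
``n_randomizations`` times; medians and interquartile ranges across the
randomizations are reported.  Clustering is performed on the pooled ASV set
of each subset, so sequences from other genomes can bridge or absorb a
genome's ASVs, exactly as in a de novo analysis of the whole collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, GenomeRecord
from .clustering import Partition, complete_linkage_partition, opticlust_partition
from .distances import DEFAULT_POLICY, GapPolicy, neighbor_pairs
from .variants import AsvTable, dereplicate


def default_threshold_grid() -> tuple[float, ...]:
    """The standard sweep: 0.25% to 10.00% in 0.25-point increments."""
    return tuple(round(0.0025 * k, 4) for k in range(1, 41))


@dataclass(frozen=True)
class StatConfig:
    thresholds: tuple[float, ...] = field(default_factory=default_threshold_grid)
    confidence: float = 0.95
    n_randomizations: int = 100
    min_species_per_copy_class: int = 100
    master_seed: int = 0
    d_max: float = 0.10
    gap_policy: GapPolicy = DEFAULT_POLICY
    clusterer: Literal["opticlust", "complete-linkage"] = "opticlust"
    restarts: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError(f"confidence must be in (0,1): {self.confidence}")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("threshold grid must be strictly increasing")


@dataclass
class ThresholdCurve:
    """Per copy-class fraction of intact genomes along the threshold grid."""

    copy_class: int
    thresholds: tuple[float, ...]
    fraction_intact: tuple[float, ...]
    confidence: float

    @property
    def collapse_threshold(self) -> float | None:
        """Smallest grid threshold at which the intact fraction reaches the
        confidence level, or None when no grid value does."""
        for t, f in zip(self.thresholds, self.fraction_intact):
            if f >= self.confidence:
                return t
        return None


@dataclass
class LumpCurve:
    """Fractions of multi-species units along the threshold grid."""

    thresholds: tuple[float, ...]
    fraction_multi: tuple[float, ...]
    asv_fraction_multi: float


@dataclass
class RandomizationSummary:
    statistic: str
    values: list[float]
    median: float
    iqr: float


def summarize_randomizations(
    name: str, values: Sequence[float]
) -> RandomizationSummary:
    """Median and interquartile range across randomizations (linear-
    interpolation quantiles)."""
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size == 0:
        return RandomizationSummary(name, list(values), float("nan"), float("nan"))
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return RandomizationSummary(name, list(values), float(med), float(q3 - q1))


def sample_one_genome_per_species(catalog: Catalog, seed: int) -> Catalog:
    """One uniformly chosen genome per species key; deterministic per seed."""
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for sp in sorted(catalog.species_index):
        accs = sorted(catalog.species_index[sp])
        chosen.append(accs[int(rng.integers(len(accs)))])
    return catalog.subset(chosen)


def genome_intact(
    genome: GenomeRecord, table: AsvTable, part: Partition
) -> bool:
    """True when all of the genome's ASVs share one OTU.

    Clustering items are 0-based ASV indices (asv_id - 1).
    """
    asvs = table.asvs_of_genome(genome.accession)
    if not asvs:
        raise ValueError(f"genome {genome.accession} has no ASVs in the table")
    otus = set()
    for a in asvs:
        if a - 1 not in part.otu_of:
            raise ValueError(f"ASV {a} unassigned in partition")
        otus.add(part.otu_of[a - 1])
    return len(otus) == 1


@dataclass
class ReplicateResult:
    """All statistics of one randomized subset for one region."""

    replicate: int
    region: str
    # copy_class -> threshold index -> fraction intact
    fraction_intact: dict[int, list[float]]
    n_genomes_per_class: dict[int, int]
    fraction_multi: list[float]
    asv_fraction_multi: float
    thresholds: tuple[float, ...]
    confidence: float

    def collapse_threshold(self, copy_class: int) -> float | None:
        for t, f in zip(self.thresholds, self.fraction_intact[copy_class]):
            if f >= self.confidence:
                return t
        return None


def _cluster(nbrs, threshold: float, cfg: StatConfig, seed: int) -> Partition:
    if cfg.clusterer == "complete-linkage":
        return complete_linkage_partition(nbrs, threshold)
    return opticlust_partition(nbrs, threshold, seed=seed, restarts=cfg.restarts)


def analyze_subset(
    subset: Catalog,
    region_name: str,
    region_seqs: Mapping[str, tuple[str, str]],
    cfg: StatConfig,
    replicate: int = 0,
    cluster_seed: int = 0,
) -> ReplicateResult:
    """Dereplicate, cluster at every grid threshold, and score one subset.

    ``region_seqs`` maps copy_id to (degapped, aligned) region sequences for
    the copies that survived region extraction.
    """
    triples = []
    aligned_by_seq: dict[str, str] = {}
    for g in subset.genomes:
        for c in g.copies:
            if c.copy_id in region_seqs:
                degapped, aligned = region_seqs[c.copy_id]
                triples.append((degapped, g.accession, g.species_key))
                aligned_by_seq.setdefault(degapped, aligned)
    table = dereplicate(triples, region_name=region_name)
    reps = [aligned_by_seq[s] for s in table.sequences]
    nbrs = neighbor_pairs(reps, d_max=cfg.d_max, policy=cfg.gap_policy)

    # genome -> 0-based ASV item indices, and its surviving copy count
    genome_items: dict[str, set[int]] = {}
    copy_class: dict[str, int] = {}
    for g in subset.genomes:
        seqs = [region_seqs[c.copy_id][0] for c in g.copies if c.copy_id in region_seqs]
        if not seqs:
            continue
        genome_items[g.accession] = {table.asv_of[s] - 1 for s in seqs}
        copy_class[g.accession] = len(seqs)

    classes = sorted(set(copy_class.values()))
    n_per_class = {k: sum(1 for v in copy_class.values() if v == k) for k in classes}
    asv_species = {a - 1: table.species_of(a) for a in table.members}

    frac_intact: dict[int, list[float]] = {k: [] for k in classes}
    frac_multi: list[float] = []
    for ti, t in enumerate(cfg.thresholds):
        part = _cluster(nbrs, t, cfg, seed=cluster_seed + ti)
        intact_count = {k: 0 for k in classes}
        for acc, items in genome_items.items():
            if len({part.otu_of[i] for i in items}) == 1:
                intact_count[copy_class[acc]] += 1
        for k in classes:
            frac_intact[k].append(intact_count[k] / n_per_class[k])
        otu_species: dict[int, set[str]] = {}
        for item, otu in part.otu_of.items():
            otu_species.setdefault(otu, set()).update(asv_species[item])
        n_multi = sum(1 for sps in otu_species.values() if len(sps) > 1)
        frac_multi.append(n_multi / len(otu_species) if otu_species else 0.0)

    return ReplicateResult(
        replicate=replicate,
        region=region_name,
        fraction_intact=frac_intact,
        n_genomes_per_class=n_per_class,
        fraction_multi=frac_multi,
        asv_fraction_multi=table.multi_species_fraction(),
        thresholds=cfg.thresholds,
        confidence=cfg.confidence,
    )


def randomized_analysis(
    catalog: Catalog,
    region_seq_maps: Mapping[str, Mapping[str, tuple[str, str]]],
    cfg: StatConfig,
) -> list[ReplicateResult]:
    """Run the full randomization design over every region.

    Each replicate r draws its subset and clustering seeds from
    SeedSequence([master_seed, r]), so any replicate is reproducible in
    isolation.  Only genomes with a resolved species key participate.
    """
    resolved = catalog.resolved()
    results: list[ReplicateResult] = []
    for r in range(cfg.n_randomizations):
        ss = np.random.SeedSequence([cfg.master_seed, r])
        sample_seed, cluster_seed = (int(s) for s in ss.generate_state(2) >> 1)
        subset = sample_one_genome_per_species(resolved, sample_seed)
        for region_name, seq_map in region_seq_maps.items():
            results.append(
                analyze_subset(
                    subset, region_name, seq_map, cfg,
                    replicate=r, cluster_seed=cluster_seed,
                )
            )
    return results


# ---------------------------------------------------------------------------
# tidy-frame exports and summaries

def intact_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    rows = [
        {
            "region": res.region,
            "copy_class": k,
            "threshold": t,
            "replicate": res.replicate,
            "fraction_intact": f,
        }
        for res in results
        for k, fracs in sorted(res.fraction_intact.items())
        for t, f in zip(res.thresholds, fracs)
    ]
    return pd.DataFrame(
        rows, columns=["region", "copy_class", "threshold", "replicate", "fraction_intact"]
    )


def lump_frame(results: list[ReplicateResult]) -> pd.DataFrame:
    rows = [
        {
            "region": res.region,
            "threshold": t,
            "replicate": res.replicate,
            "fraction_multi": f,
            "asv_fraction_multi": res.asv_fraction_multi,
        }
        for res in results
        for t, f in zip(res.thresholds, res.fraction_multi)
    ]
    return pd.DataFrame(
        rows,
        columns=["region", "threshold", "replicate", "fraction_multi", "asv_fraction_multi"],
    )


def _species_filter(results: list[ReplicateResult], cfg: StatConfig) -> set[tuple[str, int]]:
    """(region, copy_class) pairs with more than min_species_per_copy_class
    species (= subset genomes) in every replicate they appear in."""
    keep: set[tuple[str, int]] = set()
    for res in results:
        for k, n in res.n_genomes_per_class.items():
            if n > cfg.min_species_per_copy_class:
                keep.add((res.region, k))
    return keep


def collapse_summary(results: list[ReplicateResult], cfg: StatConfig) -> pd.DataFrame:
    """Median (and IQR) collapse threshold per region and copy class across
    replicates; classes found in too few species are excluded."""
    keep = _species_filter(results, cfg)
    per_key: dict[tuple[str, int], list[float]] = {}
    for res in results:
        for k in res.fraction_intact:
            if (res.region, k) not in keep:
                continue
            ct = res.collapse_threshold(k)
            per_key.setdefault((res.region, k), []).append(
                float("nan") if ct is None else ct
            )
    rows = []
    for (region, k), vals in sorted(per_key.items()):
        summ = summarize_randomizations(f"collapse[{region},{k}]", vals)
        rows.append(
            {
                "region": region,
                "copy_class": k,
                "median_collapse_threshold": summ.median,
                "iqr": summ.iqr,
                "n_replicates": len(vals),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region", "copy_class", "median_collapse_threshold", "iqr", "n_replicates"],
    )


def threshold_curves(
    results: list[ReplicateResult], cfg: StatConfig, region: str
) -> list[ThresholdCurve]:
    """Median intact-fraction curves per copy class for one region."""
    keep = _species_filter(results, cfg)
    sel = [r for r in results if r.region == region]
    classes = sorted(
        {k for r in sel for k in r.fraction_intact if (region, k) in keep}
    )
    curves = []
    for k in classes:
        per_t = []
        for ti in range(len(cfg.thresholds)):
            vals = [r.fraction_intact[k][ti] for r in sel if k in r.fraction_intact]
            per_t.append(summarize_randomizations("fi", vals).median)
        curves.append(
            ThresholdCurve(
                copy_class=k,
                thresholds=cfg.thresholds,
                fraction_intact=tuple(per_t),
                confidence=cfg.confidence,
            )
        )
    return curves


def lump_curve(results: list[ReplicateResult], cfg: StatConfig, region: str) -> LumpCurve:
    """Median multi-species fraction curve for one region."""
    sel = [r for r in results if r.region == region]
    per_t = []
    for ti in range(len(cfg.thresholds)):
        per_t.append(
            summarize_randomizations("fm", [r.fraction_multi[ti] for r in sel]).median
        )
    asv_med = summarize_randomizations(
        "afm", [r.asv_fraction_multi for r in sel]
    ).median
    return LumpCurve(
        thresholds=cfg.thresholds,
        fraction_multi=tuple(per_t),
        asv_fraction_multi=asv_med,
    )


def max_randomization_iqr(results: list[ReplicateResult], cfg: StatConfig) -> float:
    """The largest IQR across all emitted per-threshold statistics — the
    stability measure of the randomization design."""
    worst = 0.0
    regions = sorted({r.region for r in results})
    for region in regions:
        sel = [r for r in results if r.region == region]
        for ti in range(len(cfg.thresholds)):
            worst = max(
                worst,
                summarize_randomizations(
                    "fm", [r.fraction_multi[ti] for r in sel]
                ).iqr,
            )
        worst = max(
            worst,
            summarize_randomizations(
                "afm", [r.asv_fraction_multi for r in sel]
            ).iqr,
        )
        classes = {k for r in sel for k in r.fraction_intact}
        for k in classes:
            for ti in range(len(cfg.thresholds)):
                vals = [r.fraction_intact[k][ti] for r in sel if k in r.fraction_intact]
                worst = max(worst, summarize_randomizations("fi", vals).iqr)
    return worst
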