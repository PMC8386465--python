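"""Staged pipeline: community/catalog -> regions -> ASVs -> distances ->
OTUs -> split/lump statistics.

Each stage reads the files the previous stage wrote and records output
checksums in a run manifest, so an unchanged re-run skips completed stages
and two runs with the same master seed produce byte-identical statistics
tables.  All randomness flows from the single ``seed`` entry of the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .catalog import Catalog, build_catalog, parse_metadata, parse_sequences
from .distances import GapPolicy, neighbor_pairs, NeighborSet
from .regions import (
    DEFAULT_REGIONS,
    RegionSpec,
    extract_catalog_region,
    identity_span,
    map_reference_coordinates,
)
from .simulate import SynthConfig, compute_ground_truth, generate_community, write_community
from .stats import (
    StatConfig,
    collapse_summary,
    intact_frame,
    lump_frame,
    max_randomization_iqr,
    randomized_analysis,
)
from .variants import dereplicate, genome_variant_stats, mean_variants_per_copy

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def _thresholds(cfg: dict[str, Any]) -> tuple[float, ...]:
    spec = cfg.get("thresholds")
    if spec is None:
        from .stats import default_threshold_grid

        return default_threshold_grid()
    if isinstance(spec, dict):
        start, stop, step = spec["start"], spec["stop"], spec["step"]
        n = int(round((stop - start) / step)) + 1
        return tuple(round(start + k * step, 6) for k in range(n))
    return tuple(float(t) for t in spec)


def _gap_policy(cfg: dict[str, Any]) -> GapPolicy:
    gp = cfg.get("gap_policy", {})
    return GapPolicy(
        mode=gp.get("mode", "gap-run-single-difference"),
        count_terminal_gaps=bool(gp.get("count_terminal_gaps", True)),
    )


def _regions(cfg: dict[str, Any]) -> dict[str, RegionSpec]:
    names = cfg.get("regions", list(DEFAULT_REGIONS))
    out: dict[str, RegionSpec] = {}
    for n in names:
        if isinstance(n, dict):
            out[n["name"]] = RegionSpec(n["name"], int(n["start"]), int(n["end"]))
        elif n in DEFAULT_REGIONS:
            out[n] = DEFAULT_REGIONS[n]
        else:
            raise ConfigError(f"unknown region {n!r}")
    return out


def _stat_config(cfg: dict[str, Any]) -> StatConfig:
    return StatConfig(
        thresholds=_thresholds(cfg),
        confidence=float(cfg.get("confidence", 0.95)),
        n_randomizations=int(cfg.get("randomizations", 100)),
        min_species_per_copy_class=int(cfg.get("min_species_per_copy_class", 100)),
        master_seed=int(cfg.get("seed", 0)),
        d_max=float(cfg.get("d_max", 0.10)),
        gap_policy=_gap_policy(cfg),
        clusterer=cfg.get("clusterer", "opticlust"),
        restarts=int(cfg.get("restarts", 1)),
    )


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# file-level helpers shared by stages

def _write_fasta(records: list[tuple[str, str]], path: Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def _read_catalog_files(outdir: Path) -> Catalog:
    seqs = parse_sequences(outdir / "catalog.fasta")
    meta = [
        (str(r["accession"]), str(r["organism"]))
        for _, r in pd.read_csv(outdir / "catalog.tsv", sep="\t").iterrows()
    ]
    catalog, _ = build_catalog(seqs, meta)
    return catalog


def _region_seq_map(outdir: Path, region: str) -> dict[str, tuple[str, str]]:
    degapped = {r.id: str(r.seq) for r in SeqIO.parse(str(outdir / "regions" / f"{region}.fasta"), "fasta")}
    aligned = {r.id: str(r.seq) for r in SeqIO.parse(str(outdir / "regions" / f"{region}.aligned.fasta"), "fasta")}
    return {cid: (degapped[cid], aligned[cid]) for cid in degapped}


# ---------------------------------------------------------------------------
# stages

def stage_generate(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    spec = dict(cfg["community"])
    spec.setdefault("seed", int(cfg.get("seed", 0)))
    # YAML has no tuples: distribution specs like ["uniform", 1, 19] arrive
    # as lists and are coerced to the tuple form the generator expects
    for key in ("genomes_per_species", "copies_per_genome", "intragenomic_subs"):
        val = spec.get(key)
        if isinstance(val, list) and val and isinstance(val[0], str):
            spec[key] = tuple(val)
    if "shared_variant_links" in spec:
        spec["shared_variant_links"] = tuple(
            tuple(link) for link in spec["shared_variant_links"]
        )
    community = generate_community(SynthConfig(**spec))
    truth = compute_ground_truth(community)
    paths = write_community(community, outdir / "data", ground_truth=truth)
    log.info("generated %d genomes in %d species",
             community.catalog.n_genomes, community.catalog.n_species)
    return sorted(paths.values())


def stage_catalog(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    if "community" in cfg:
        seq_path = outdir / "data" / "sequences.fasta"
        meta_path = outdir / "data" / "metadata.tsv"
    else:
        inputs = cfg.get("inputs")
        if not inputs or "sequences" not in inputs or "metadata" not in inputs:
            raise ConfigError("config needs either 'community' or 'inputs' with sequences+metadata")
        seq_path, meta_path = Path(inputs["sequences"]), Path(inputs["metadata"])
        if not seq_path.exists() or not meta_path.exists():
            raise FileNotFoundError(f"missing input files: {seq_path}, {meta_path}")
    seqs = parse_sequences(seq_path, cfg.get("accession_pattern", r"^([^|\s]+)"))
    meta = parse_metadata(
        meta_path,
        accession_column=cfg.get("accession_column", "accession"),
        taxonomy_column=cfg.get("taxonomy_column", "organism"),
    )
    catalog, orphans = build_catalog(seqs, meta)
    _write_fasta(
        [(c.copy_id, c.aligned_seq) for g in catalog.genomes for c in g.copies],
        outdir / "catalog.fasta",
    )
    pd.DataFrame(
        [{"accession": g.accession, "organism": g.species_key} for g in catalog.genomes]
    ).to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    with open(outdir / "catalog_log.txt", "w") as fh:
        fh.write(f"n_sequences\t{sum(g.copy_number for g in catalog.genomes)}\n")
        fh.write(f"n_genomes\t{catalog.n_genomes}\n")
        fh.write(f"n_species\t{catalog.n_species}\n")
        fh.write(f"n_orphans\t{len(orphans)}\n")
    return [outdir / "catalog.fasta", outdir / "catalog.tsv", outdir / "catalog_log.txt"]


def stage_extract(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    catalog = _read_catalog_files(outdir)
    copies = [c for g in catalog.genomes for c in g.copies]
    widths = {len(c.aligned_seq) for c in copies}
    if len(widths) != 1:
        raise ConfigError(f"alignment has mixed widths {sorted(widths)}")
    width = widths.pop()
    ref_id = cfg.get("reference_id")
    ref_aligned = None
    if ref_id:
        for c in copies:
            if c.copy_id.startswith(str(ref_id)) or c.genome_accession == ref_id:
                ref_aligned = c.aligned_seq
                break
        if ref_aligned is None:
            raise ConfigError(f"reference record {ref_id!r} not found in alignment")
    (outdir / "regions").mkdir(exist_ok=True)
    out_paths: list[Path] = []
    for name, region in _regions(cfg).items():
        span = (
            map_reference_coordinates(ref_aligned, region)
            if ref_aligned is not None
            else identity_span(region, width)
        )
        surviving, dropped = extract_catalog_region(
            copies, span, cfg.get("boundary_policy", "drop")
        )
        _write_fasta(
            [(cid, pair[0]) for cid, pair in surviving.items()],
            outdir / "regions" / f"{name}.fasta",
        )
        _write_fasta(
            [(cid, pair[1]) for cid, pair in surviving.items()],
            outdir / "regions" / f"{name}.aligned.fasta",
        )
        with open(outdir / "regions" / f"{name}.drops.txt", "w") as fh:
            fh.write(f"n_dropped\t{len(dropped)}\n")
            for cid in dropped:
                fh.write(f"dropped\t{cid}\n")
        log.info("region %s: %d surviving, %d dropped", name, len(surviving), len(dropped))
        out_paths += [
            outdir / "regions" / f"{name}.fasta",
            outdir / "regions" / f"{name}.aligned.fasta",
            outdir / "regions" / f"{name}.drops.txt",
        ]
    return out_paths


def stage_derep(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    catalog = _read_catalog_files(outdir)
    species_of = {g.accession: g.species_key for g in catalog.genomes}
    (outdir / "asv").mkdir(exist_ok=True)
    out_paths: list[Path] = []
    for name in _regions(cfg):
        seq_map = _region_seq_map(outdir, name)
        triples = [
            (seq_map[c.copy_id][0], g.accession, species_of[g.accession])
            for g in catalog.genomes
            for c in g.copies
            if c.copy_id in seq_map
        ]
        table = dereplicate(triples, region_name=name)
        table.write_tsv(outdir / "asv" / f"{name}.tsv")
        stats = genome_variant_stats(
            catalog, table, {cid: pair[0] for cid, pair in seq_map.items()}
        )
        pd.DataFrame(
            [
                {
                    "accession": s.accession,
                    "species": s.species_key,
                    "copy_number": s.copy_number,
                    "n_asvs": s.n_asvs,
                    "variants_per_copy": s.variants_per_copy,
                }
                for s in stats
            ]
        ).to_csv(outdir / "asv" / f"{name}.genomes.tsv", sep="\t", index=False,
                 float_format=FLOAT_FMT)
        out_paths += [outdir / "asv" / f"{name}.tsv", outdir / "asv" / f"{name}.genomes.tsv"]
    return out_paths


def _asv_reps(outdir: Path, name: str) -> list[str]:
    """Aligned representative per ASV, ordered by asv_id."""
    table = pd.read_csv(outdir / "asv" / f"{name}.tsv", sep="\t")
    seq_map = _region_seq_map(outdir, name)
    aligned_by_seq: dict[str, str] = {}
    for cid, (deg, ali) in seq_map.items():
        aligned_by_seq.setdefault(deg, ali)
    reps = (
        table.drop_duplicates("asv_id").sort_values("asv_id")["sequence"].tolist()
    )
    return [aligned_by_seq[s] for s in reps]


def stage_dist(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    (outdir / "dist").mkdir(exist_ok=True)
    out_paths: list[Path] = []
    for name in _regions(cfg):
        reps = _asv_reps(outdir, name)
        nbrs = neighbor_pairs(reps, d_max=float(cfg.get("d_max", 0.10)), policy=_gap_policy(cfg))
        nbrs.write_tsv(outdir / "dist" / f"{name}.tsv")
        log.info("region %s: %d neighbor pairs over %d ASVs", name, len(nbrs.pairs), nbrs.n_items)
        out_paths.append(outdir / "dist" / f"{name}.tsv")
    return out_paths


def stage_cluster(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    from .clustering import opticlust_partition, complete_linkage_partition, write_list_format

    scfg = _stat_config(cfg)
    (outdir / "otus").mkdir(exist_ok=True)
    out_paths: list[Path] = []
    for name in _regions(cfg):
        n_items = len(_asv_reps(outdir, name))
        nbrs = NeighborSet.read_tsv(outdir / "dist" / f"{name}.tsv", n_items, scfg.d_max)
        parts = []
        for ti, t in enumerate(scfg.thresholds):
            if scfg.clusterer == "complete-linkage":
                parts.append(complete_linkage_partition(nbrs, t))
            else:
                parts.append(
                    opticlust_partition(nbrs, t, seed=scfg.master_seed + ti, restarts=scfg.restarts)
                )
        write_list_format(parts, outdir / "otus" / f"{name}.list")
        out_paths.append(outdir / "otus" / f"{name}.list")
    return out_paths


def stage_stats(cfg: dict[str, Any], outdir: Path) -> list[Path]:
    catalog = _read_catalog_files(outdir)
    scfg = _stat_config(cfg)
    region_maps = {name: _region_seq_map(outdir, name) for name in _regions(cfg)}
    results = randomized_analysis(catalog, region_maps, scfg)
    (outdir / "stats").mkdir(exist_ok=True)
    paths = {
        "intact": outdir / "stats" / "fraction_intact.tsv",
        "lump": outdir / "stats" / "fraction_multi.tsv",
        "collapse": outdir / "stats" / "collapse_summary.tsv",
        "summary": outdir / "stats" / "summary.tsv",
    }
    intact_frame(results).to_csv(paths["intact"], sep="\t", index=False, float_format=FLOAT_FMT)
    lump_frame(results).to_csv(paths["lump"], sep="\t", index=False, float_format=FLOAT_FMT)
    collapse_summary(results, scfg).to_csv(
        paths["collapse"], sep="\t", index=False, float_format=FLOAT_FMT
    )
    # headline per-region variant ratios on the full catalog
    rows = []
    for name in _regions(cfg):
        seq_map = region_maps[name]
        species_of = {g.accession: g.species_key for g in catalog.genomes}
        triples = [
            (seq_map[c.copy_id][0], g.accession, species_of[g.accession])
            for g in catalog.genomes
            for c in g.copies
            if c.copy_id in seq_map
        ]
        table = dereplicate(triples, region_name=name)
        stats = genome_variant_stats(
            catalog, table, {cid: p[0] for cid, p in seq_map.items()}
        )
        ratios = mean_variants_per_copy(stats)
        rows.append(
            {
                "region": name,
                "variants_per_copy_per_genome_mean": ratios["per_genome_mean"],
                "variants_per_copy_per_species_mean": ratios["per_species_mean"],
                "variants_per_copy_pooled": ratios["pooled_ratio"],
                "max_randomization_iqr": max_randomization_iqr(
                    [r for r in results if r.region == name], scfg
                ),
            }
        )
    pd.DataFrame(rows).to_csv(paths["summary"], sep="\t", index=False, float_format=FLOAT_FMT)
    return sorted(paths.values())


STAGES: list[tuple[str, Callable[[dict[str, Any], Path], list[Path]]]] = [
    ("generate", stage_generate),
    ("catalog", stage_catalog),
    ("extract", stage_extract),
    ("derep", stage_derep),
    ("dist", stage_dist),
    ("cluster", stage_cluster),
    ("stats", stage_stats),
]


def run_pipeline(
    config: dict[str, Any] | str | Path,
    outdir: str | Path | None = None,
    resume: bool = False,
) -> dict[str, Any]:
    """Run all stages; returns the manifest (also written to manifest.json).

    With ``resume=True``, stages whose recorded outputs all exist with
    matching checksums (under an unchanged config) are skipped.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    outdir = Path(outdir or cfg.get("outdir", "rrnsplit_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()

    manifest_path = outdir / "manifest.json"
    previous: dict[str, Any] = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)
        if previous.get("config_hash") != cfg_hash:
            previous = {}

    input_checksums = {}
    inputs = cfg.get("inputs") or {}
    for key, p in inputs.items():
        if Path(p).exists():
            input_checksums[key] = _checksum(Path(p))

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "config_hash": cfg_hash,
        "master_seed": int(cfg.get("seed", 0)),
        "input_checksums": input_checksums,
        "stages": {},
    }
    for name, fn in STAGES:
        if name == "generate" and "community" not in cfg:
            continue
        prev = previous.get("stages", {}).get(name)
        if prev:
            ok = all(
                Path(p).exists() and _checksum(Path(p)) == c
                for p, c in prev["outputs"].items()
            )
            if ok:
                log.info("stage %s: up to date, skipped", name)
                manifest["stages"][name] = {**prev, "skipped": True}
                continue
        log.info("stage %s: running", name)
        outputs = fn(cfg, outdir)
        manifest["stages"][name] = {
            "outputs": {str(p): _checksum(p) for p in outputs},
            "skipped": False,
        }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
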