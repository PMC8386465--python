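"""Genome catalog: parse 16S gene sequences plus genome metadata into a
validated catalog of genomes.

A *genome* is the unit that must not be split by clustering: one assembly
accession carrying 1-19 copies of the 16S rRNA gene (its rrn operons).  Each
genome gets a single species label derived from the organism name with
strain-level designations removed, because per-copy taxonomic classifications
of the same genome can disagree.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GAP_CHARS = "-."
_GAP_TABLE = str.maketrans("", "", GAP_CHARS)

#: organism-name tokens that mean the species epithet is not resolved
_UNRESOLVED_EPITHETS = {"sp.", "sp", "unclassified", "bacterium"}
_BRACKETED = re.compile(r"\[[^\]]*\]|\([^)]*\)")

#: default accession pattern: everything before the first '|' or whitespace
DEFAULT_ACCESSION_PATTERN = re.compile(r"^([^|\s]+)")


class CatalogError(ValueError):
    """Validation failure while building or parsing a catalog."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and normalize RNA (U) to DNA (T); keeps gap characters."""
    return seq.upper().replace("U", "T")


def degap(seq: str) -> str:
    """Remove both alignment gap characters ('-' and '.')."""
    return seq.translate(_GAP_TABLE)


@dataclass(frozen=True)
class SeqCopy:
    """One 16S rRNA gene copy of one genome, in alignment coordinates."""

    copy_id: str
    genome_accession: str
    aligned_seq: str

    @property
    def unaligned_seq(self) -> str:
        return normalize_sequence(degap(self.aligned_seq))

    def __post_init__(self) -> None:
        if not self.unaligned_seq:
            raise CatalogError(
                f"copy {self.copy_id!r} of {self.genome_accession!r} is all gaps/empty"
            )


@dataclass
class GenomeRecord:
    """A genome assembly with its 16S gene copies; ``copy_number`` is the
    rrn copy number of the assembly."""

    accession: str
    species_key: str
    copies: list[SeqCopy] = field(default_factory=list)

    @property
    def copy_number(self) -> int:
        return len(self.copies)

    def __post_init__(self) -> None:
        for c in self.copies:
            if c.genome_accession != self.accession:
                raise CatalogError(
                    f"copy {c.copy_id!r} belongs to {c.genome_accession!r},"
                    f" not {self.accession!r}"
                )


@dataclass
class Catalog:
    """All genomes under analysis, indexed by species."""

    genomes: list[GenomeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genomes:
            if g.accession in seen:
                raise CatalogError(f"duplicate genome accession {g.accession!r}")
            seen.add(g.accession)

    @property
    def species_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for g in self.genomes:
            idx.setdefault(g.species_key, []).append(g.accession)
        return idx

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_species(self) -> int:
        return len(self.species_index)

    def genome(self, accession: str) -> GenomeRecord:
        for g in self.genomes:
            if g.accession == accession:
                return g
        raise KeyError(accession)

    def subset(self, accessions: Iterable[str]) -> "Catalog":
        keep = set(accessions)
        return Catalog([g for g in self.genomes if g.accession in keep])

    def resolved(self) -> "Catalog":
        """Genomes whose species label is usable for species-level resampling."""
        return Catalog(
            [g for g in self.genomes if species_key_is_resolved(g.species_key)]
        )


def species_key_from_taxonomy(taxonomy: str) -> str:
    """Reduce an organism name to a species key by dropping strain-level
    designations.

    The rule: remove bracketed qualifiers, then keep the first two
    whitespace-separated tokens — three when the name starts with
    "Candidatus", which is a prefix rather than a genus.
    """
    cleaned = _BRACKETED.sub(" ", taxonomy)
    tokens = cleaned.split()
    if not tokens:
        return ""
    n = 3 if tokens[0].lower() == "candidatus" else 2
    return " ".join(tokens[:n])


def species_key_is_resolved(key: str) -> bool:
    """True when the key carries a genus and a real species epithet."""
    tokens = key.split()
    if len(tokens) < 2:
        return False
    epithet = tokens[-1].lower()
    return epithet not in _UNRESOLVED_EPITHETS


def parse_metadata(
    path: str | Path,
    accession_column: str = "accession",
    taxonomy_column: str = "organism",
    sep: str = "\t",
) -> list[tuple[str, str]]:
    """Read a tabular metadata file into (accession, raw_taxonomy) pairs.

    Raises ``CatalogError`` on a missing column or a duplicated accession.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (accession_column, taxonomy_column):
        if col not in df.columns:
            raise CatalogError(
                f"metadata file {path} lacks required column {col!r};"
                f" available: {list(df.columns)}"
            )
    accs = df[accession_column]
    dup = accs[accs.duplicated()].tolist()
    if dup:
        raise CatalogError(f"duplicate accession(s) in metadata: {sorted(set(dup))}")
    return list(zip(accs.tolist(), df[taxonomy_column].fillna("").tolist()))


def parse_sequences(
    path: str | Path,
    accession_pattern: str | re.Pattern[str] = DEFAULT_ACCESSION_PATTERN,
) -> list[SeqCopy]:
    """Read a (possibly aligned) FASTA file into SeqCopy records.

    The genome accession is extracted from each record id with
    ``accession_pattern`` (group 1); by default everything before the first
    '|' or whitespace.  Sequences are uppercased with U normalized to T;
    '.' and '-' are both alignment gaps.
    """
    pattern = re.compile(accession_pattern)
    copies: list[SeqCopy] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.search(rec.id)
        if not m:
            raise CatalogError(
                f"FASTA header {rec.id!r} does not match accession pattern"
                f" {pattern.pattern!r}"
            )
        seq = normalize_sequence(str(rec.seq))
        if not degap(seq):
            raise CatalogError(f"record {rec.id!r} has an empty sequence")
        copies.append(
            SeqCopy(copy_id=rec.id, genome_accession=m.group(1), aligned_seq=seq)
        )
    return copies


def build_catalog(
    seqs: list[SeqCopy],
    meta: list[tuple[str, str]],
) -> tuple[Catalog, list[SeqCopy]]:
    """Group sequences by genome and attach one species key per genome.

    Returns ``(catalog, orphans)`` where orphans are copies whose accession
    has no metadata row; they are dropped with a logged count.
    """
    tax = {acc: species_key_from_taxonomy(t) for acc, t in meta}
    by_acc: dict[str, list[SeqCopy]] = {}
    orphans: list[SeqCopy] = []
    for c in seqs:
        if c.genome_accession in tax:
            by_acc.setdefault(c.genome_accession, []).append(c)
        else:
            orphans.append(c)
    if orphans:
        log.warning(
            "dropped %d orphan sequence(s) with no metadata (e.g. %s)",
            len(orphans),
            orphans[0].genome_accession,
        )
    genomes = [
        GenomeRecord(accession=acc, species_key=tax[acc], copies=copies)
        for acc, copies in by_acc.items()
    ]
    return Catalog(genomes), orphans


def write_catalog(
    catalog: Catalog, fasta_path: str | Path, meta_path: str | Path
) -> None:
    """Write a normalized catalog back out as FASTA + TSV metadata."""
    records = [
        SeqRecord(Seq(c.aligned_seq), id=c.copy_id, description="")
        for g in catalog.genomes
        for c in g.copies
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"accession": g.accession, "organism": g.species_key}
        for g in catalog.genomes
    ]
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
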