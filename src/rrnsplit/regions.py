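"""Hypervariable-region extraction in reference coordinates.

Region boundaries are given as 1-based inclusive positions on the unaligned
E. coli K-12 MG1655 16S rRNA gene (GenBank NC_000913), the convention used
throughout the microbial-ecology literature.  A region is realized on a
specific multiple alignment by locating the alignment columns that hold the
reference's boundary bases; every aligned sequence is then trimmed to that
column span and degapped.

Sequences with a gap at a boundary column cannot be amplified by a primer
landing there, so the default policy drops them (policy "keep" trims
regardless).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .catalog import GAP_CHARS, SeqCopy, degap


class CoordinateError(ValueError):
    """Reference coordinate outside the reference sequence."""


class AlignmentError(ValueError):
    """Sequence length inconsistent with the alignment."""


@dataclass(frozen=True)
class RegionSpec:
    """A named 16S sub-region in 1-based inclusive reference coordinates."""

    name: str
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.ref_start <= self.ref_end:
            raise CoordinateError(
                f"invalid region {self.name}: {self.ref_start}..{self.ref_end}"
            )

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass(frozen=True)
class ColumnSpan:
    """A 1-based inclusive span of alignment columns."""

    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.col_start <= self.col_end:
            raise CoordinateError(f"invalid column span {self.col_start}..{self.col_end}")


#: the four standard regions, bounded by commonly used PCR primer sites on
#: the E. coli reference gene
DEFAULT_REGIONS: dict[str, RegionSpec] = {
    "full-length": RegionSpec("full-length", 28, 1491),
    "V4": RegionSpec("V4", 534, 786),
    "V3-V4": RegionSpec("V3-V4", 358, 786),
    "V4-V5": RegionSpec("V4-V5", 534, 908),
}

BoundaryPolicy = Literal["drop", "keep"]


def map_reference_coordinates(ref_aligned: str, region: RegionSpec) -> ColumnSpan:
    """Locate the alignment columns holding the reference's boundary bases.

    ``ref_aligned`` is the reference sequence as it appears in the alignment
    (with gaps).  Raises ``CoordinateError`` when the region extends past the
    reference's unaligned length.
    """
    cols: list[int] = []  # 1-based column of each unaligned position
    for i, ch in enumerate(ref_aligned, start=1):
        if ch not in GAP_CHARS:
            cols.append(i)
    if region.ref_end > len(cols):
        raise CoordinateError(
            f"region {region.name} ends at {region.ref_end} but the reference"
            f" has only {len(cols)} bases"
        )
    return ColumnSpan(cols[region.ref_start - 1], cols[region.ref_end - 1])


def identity_span(region: RegionSpec, alignment_width: int) -> ColumnSpan:
    """Column span for an alignment whose columns are reference positions.

    Valid for gap-free (columnar) alignments, where alignment column *i* is
    position *i* of every sequence.
    """
    if region.ref_end > alignment_width:
        raise CoordinateError(
            f"region {region.name} ends at {region.ref_end} but the alignment"
            f" is only {alignment_width} columns wide"
        )
    return ColumnSpan(region.ref_start, region.ref_end)


def extract_region(
    aligned_seq: str,
    span: ColumnSpan,
    policy: BoundaryPolicy = "drop",
    alignment_width: int | None = None,
) -> str | None:
    """Trim one aligned sequence to a column span and degap it.

    Returns the degapped region sequence, or ``None`` when the sequence is
    dropped under the "drop" policy (gap at a boundary column, or nothing
    left after degapping).
    """
    if alignment_width is not None and len(aligned_seq) != alignment_width:
        raise AlignmentError(
            f"sequence length {len(aligned_seq)} != alignment width {alignment_width}"
        )
    if span.col_end > len(aligned_seq):
        raise AlignmentError(
            f"column span {span.col_start}..{span.col_end} exceeds sequence"
            f" length {len(aligned_seq)}"
        )
    sub = aligned_seq[span.col_start - 1 : span.col_end]
    if policy == "drop" and (sub[0] in GAP_CHARS or sub[-1] in GAP_CHARS):
        return None
    out = degap(sub)
    return out or None


def extract_catalog_region(
    copies: list[SeqCopy],
    span: ColumnSpan,
    policy: BoundaryPolicy = "drop",
) -> tuple[dict[str, tuple[str, str]], list[str]]:
    """Trim every copy to the span.

    Returns ``(surviving, dropped)``: surviving maps copy_id to
    ``(degapped_region_seq, aligned_region_seq)``; dropped lists copy_ids
    removed under the boundary policy.
    """
    surviving: dict[str, tuple[str, str]] = {}
    dropped: list[str] = []
    for c in copies:
        out = extract_region(c.aligned_seq, span, policy)
        if out is None:
            dropped.append(c.copy_id)
        else:
            aligned = c.aligned_seq[span.col_start - 1 : span.col_end]
            surviving[c.copy_id] = (out, aligned)
    return surviving, dropped


def load_region_table(path: str | Path) -> dict[str, RegionSpec]:
    """Read a region table (TSV with columns name, start, end)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["name"]): RegionSpec(str(r["name"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    }
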