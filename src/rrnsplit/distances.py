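"""Pairwise distances between aligned sequences under explicit gap policies.

Distances are uncorrected (no evolutionary model): differences divided by the
number of compared units.  Columns where both sequences have a gap are never
compared.  Three gap-handling modes are provided, mirroring the conventions
of the standard distance calculators used in 16S pipelines:

``each-gap-a-difference``
    every column where exactly one sequence is gapped counts as one
    difference and one compared unit.
``gap-run-single-difference``
    a maximal run of gaps in one sequence (opposite bases in the other)
    counts as a single difference and a single compared unit — an indel of
    any length is one event.  This is the default.
``ignore-gap-columns``
    only columns where both sequences have a base are compared.

With ``count_terminal_gaps=False``, leading/trailing gap overhangs (columns
before the first or after the last base of either sequence) are excluded
before any of the above applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catalog import GAP_CHARS

GapMode = Literal[
    "each-gap-a-difference", "gap-run-single-difference", "ignore-gap-columns"
]


@dataclass(frozen=True)
class GapPolicy:
    mode: GapMode = "gap-run-single-difference"
    count_terminal_gaps: bool = True


DEFAULT_POLICY = GapPolicy()


class AlignmentLengthError(ValueError):
    pass


def _trim_window(a: str, b: str) -> tuple[int, int]:
    """[start, end) column window after terminal-gap exclusion."""
    def first_base(s: str) -> int:
        for i, ch in enumerate(s):
            if ch not in GAP_CHARS:
                return i
        return len(s)

    def last_base(s: str) -> int:
        for i in range(len(s) - 1, -1, -1):
            if s[i] not in GAP_CHARS:
                return i
        return -1

    start = max(first_base(a), first_base(b))
    end = min(last_base(a), last_base(b)) + 1
    return start, max(start, end)


def pairwise_distance(a: str, b: str, policy: GapPolicy = DEFAULT_POLICY) -> float:
    """Uncorrected pairwise distance in [0, 1] between two aligned sequences."""
    if len(a) != len(b):
        raise AlignmentLengthError(
            f"aligned lengths differ: {len(a)} vs {len(b)}"
        )
    if policy.count_terminal_gaps:
        start, end = 0, len(a)
    else:
        start, end = _trim_window(a, b)

    diffs = 0
    units = 0
    in_gap_run: str | None = None  # which side ('a'/'b') an open gap run is on
    for i in range(start, end):
        ca, cb = a[i], b[i]
        ga, gb = ca in GAP_CHARS, cb in GAP_CHARS
        if ga and gb:
            continue  # shared gap columns are never compared
        if policy.mode == "ignore-gap-columns":
            if ga or gb:
                continue
            units += 1
            if ca != cb:
                diffs += 1
        elif policy.mode == "each-gap-a-difference":
            units += 1
            if ga or gb or ca != cb:
                diffs += 1
        else:  # gap-run-single-difference
            if ga or gb:
                side = "a" if ga else "b"
                if in_gap_run != side:
                    units += 1
                    diffs += 1
                    in_gap_run = side
                continue
            in_gap_run = None
            units += 1
            if ca != cb:
                diffs += 1
    return diffs / units if units else 0.0


@dataclass
class NeighborSet:
    """Sparse carrier of the item pairs within a maximum distance.

    Items are 0-based indices into the input sequence list.  ``pairs`` holds
    (i, j, distance) with i < j, sorted by (i, j), containing exactly the
    pairs with distance <= d_max.
    """

    n_items: int
    d_max: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def pairs_within(self, threshold: float) -> list[tuple[int, int, float]]:
        if threshold > self.d_max + 1e-12:
            raise ValueError(
                f"threshold {threshold} exceeds neighbor-set d_max {self.d_max}"
            )
        return [(i, j, d) for i, j, d in self.pairs if d <= threshold]

    def write_tsv(self, path: str | Path) -> None:
        # phylip-style column-distance convention: id_i, id_j, distance
        with open(path, "w") as fh:
            for i, j, d in self.pairs:
                fh.write(f"{i}\t{j}\t{d:.6f}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, n_items: int, d_max: float) -> "NeighborSet":
        pairs: list[tuple[int, int, float]] = []
        with open(path) as fh:
            for line in fh:
                i, j, d = line.split("\t")
                pairs.append((int(i), int(j), float(d)))
        return cls(n_items=n_items, d_max=d_max, pairs=pairs)


def _has_gaps(seqs: Sequence[str]) -> bool:
    return any(any(g in s for g in GAP_CHARS) for s in seqs)


def _hamming_neighbor_pairs(seqs: Sequence[str], d_max: float) -> list[tuple[int, int, float]]:
    """Vectorized all-pairs mismatch fractions for gap-free equal-width input."""
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), len(seqs[0])
    )
    length = mat.shape[1]
    pairs: list[tuple[int, int, float]] = []
    for i in range(len(seqs) - 1):
        diffs = (mat[i + 1 :] != mat[i]).sum(axis=1)
        for off in np.nonzero(diffs <= d_max * length + 1e-9)[0]:
            pairs.append((i, int(i + 1 + off), float(diffs[off]) / length))
    return pairs


def neighbor_pairs(
    seqs: Sequence[str],
    d_max: float = 0.10,
    policy: GapPolicy = DEFAULT_POLICY,
) -> NeighborSet:
    """All pairs of aligned sequences with distance <= d_max.

    Gap-free inputs (the common case for columnar alignments) take a
    vectorized path; all three gap modes coincide there.
    """
    n = len(seqs)
    if n == 0:
        return NeighborSet(n_items=0, d_max=d_max)
    widths = {len(s) for s in seqs}
    if len(widths) != 1:
        raise AlignmentLengthError(f"mixed aligned lengths: {sorted(widths)}")
    if not _has_gaps(seqs):
        pairs = _hamming_neighbor_pairs(seqs, d_max)
    else:
        pairs = []
        for i in range(n - 1):
            for j in range(i + 1, n):
                d = pairwise_distance(seqs[i], seqs[j], policy)
                if d <= d_max + 1e-12:
                    pairs.append((i, j, d))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return NeighborSet(n_items=n, d_max=d_max, pairs=pairs)


def dense_distance_matrix(
    seqs: Sequence[str], policy: GapPolicy = DEFAULT_POLICY
) -> pd.DataFrame:
    """Full symmetric distance matrix; intended for small inputs."""
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_distance(seqs[i], seqs[j], policy)
    return pd.DataFrame(mat)
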