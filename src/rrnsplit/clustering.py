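"""De novo OTU assignment by iterative MCC maximization, with
furthest-neighbor and exhaustive oracles.

The objective treats clustering as a binary classifier over item pairs: a
pair is a true positive when it is within the distance threshold and
co-clustered, a false positive when co-clustered beyond the threshold, and
so on.  The Matthews correlation coefficient (MCC) balances splitting
(false negatives) against lumping (false positives).  Starting from all
singletons, items are visited in seeded random order and each is moved to
the cluster (existing, or a new singleton) that maximizes the global MCC;
iteration stops when a full pass makes no move.

Pairs at exactly the threshold count as within it (a "3% threshold" includes
pairs at 3.0%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .distances import NeighborSet

_EPS = 1e-10  # minimum MCC gain that justifies a move


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    """Pair-level confusion counts of a partition against the <=-threshold truth."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total_pairs(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient with the boundary conventions:
    a partition with no false calls scores 1.0; otherwise a zero
    denominator factor scores 0.0."""
    return _mcc(c.TP, c.TN, c.FP, c.FN)


def _mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    if fp == 0 and fn == 0:
        return 1.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class Partition:
    """Assignment of items to OTUs at one threshold.

    ``otu_of`` maps 0-based item index to a dense 1-based OTU id, canonical
    by order of each OTU's smallest member.
    """

    otu_of: dict[int, int]
    threshold: float
    confusion: ConfusionCounts
    mcc: float
    mcc_history: list[float] | None = None

    @property
    def n_items(self) -> int:
        return len(self.otu_of)

    @property
    def n_otus(self) -> int:
        return len(set(self.otu_of.values()))

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for item, otu in self.otu_of.items():
            out.setdefault(otu, []).append(item)
        for m in out.values():
            m.sort()
        return out

    def as_sets(self) -> frozenset[frozenset[int]]:
        return frozenset(frozenset(m) for m in self.clusters().values())


def _adjacency(nbrs: NeighborSet, threshold: float) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(nbrs.n_items)]
    for i, j, d in nbrs.pairs:
        if d <= threshold + 1e-12:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def confusion_from_assignment(
    otu_of: dict[int, int] | list[int], adj: list[set[int]], n_items: int
) -> ConfusionCounts:
    """Recompute confusion counts from scratch for an assignment."""
    labels = [otu_of[i] for i in range(n_items)]
    total = n_items * (n_items - 1) // 2
    n_pos = sum(len(a) for a in adj) // 2
    tp = fp = 0
    by_label: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        by_label.setdefault(lab, []).append(i)
    for members in by_label.values():
        for i, j in combinations(members, 2):
            if j in adj[i]:
                tp += 1
            else:
                fp += 1
    fn = n_pos - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _components(adj: list[set[int]]) -> list[int]:
    """Connected-component labels of the threshold graph."""
    n = len(adj)
    labels = [-1] * n
    comp = 0
    for s in range(n):
        if labels[s] != -1:
            continue
        stack = [s]
        labels[s] = comp
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if labels[v] == -1:
                    labels[v] = comp
                    stack.append(v)
        comp += 1
    return labels


def _canonicalize(labels: list[int], threshold: float, adj: list[set[int]],
                  history: list[float] | None = None) -> Partition:
    n = len(labels)
    order: dict[int, int] = {}
    otu_of: dict[int, int] = {}
    for i in range(n):
        lab = labels[i]
        if lab not in order:
            order[lab] = len(order) + 1
        otu_of[i] = order[lab]
    conf = confusion_from_assignment(otu_of, adj, n)
    return Partition(
        otu_of=otu_of, threshold=threshold, confusion=conf, mcc=mcc(conf),
        mcc_history=history,
    )


def opticlust_partition(
    nbrs: NeighborSet,
    threshold: float,
    seed: int = 0,
    restarts: int = 1,
) -> Partition:
    """Iterative MCC-maximizing clustering.

    Deterministic for fixed (seed, restarts); the best of ``restarts``
    independent runs is returned.  The first restart (the only
    run when ``restarts=1``) starts from all singletons; the second from
    the connected components of the threshold graph; further restarts from
    random coarse partitions — diversified starts reach optima that
    single-item moves cannot assemble from below.  Moves are accepted on a strict MCC gain
    (> 1e-10), or on an MCC tie that strictly gains true-positive pairs
    (which escapes the flat-MCC plateaus created by the zero-denominator
    convention); the objective is non-decreasing throughout, and otherwise
    ties keep the current assignment, then prefer the smallest OTU id.
    """
    if threshold > nbrs.d_max + 1e-12:
        raise ClusteringError(
            f"threshold {threshold} exceeds neighbor-set d_max {nbrs.d_max}"
        )
    n = nbrs.n_items
    adj = _adjacency(nbrs, threshold)
    if n == 0:
        return Partition({}, threshold, ConfusionCounts(0, 0, 0, 0), 1.0, [1.0])

    rng = np.random.default_rng(seed)
    total = n * (n - 1) // 2
    n_pos = sum(len(a) for a in adj) // 2

    best: tuple[float, list[int], list[float]] | None = None
    for restart in range(max(1, restarts)):
        if restart == 0:
            labels = list(range(n))  # all singletons
        elif restart == 1:
            # maximally lumped start: connected components of the graph
            labels = _components(adj)
        else:
            # remaining restarts diversify from random coarse partitions
            labels = [int(rng.integers(max(1, n // 2))) for _ in range(n)]
        members: dict[int, set[int]] = {}
        for i, lab in enumerate(labels):
            members.setdefault(lab, set()).add(i)
        next_label = n
        conf0 = confusion_from_assignment(labels, adj, n)
        tp, fp = conf0.TP, conf0.FP
        history = [mcc(conf0)]

        for _pass in range(100):
            moved = False
            for x in rng.permutation(n):
                x = int(x)
                cur = labels[x]
                cur_members = members[cur]
                k0 = len(adj[x] & cur_members)  # x not in adj[x]
                m0 = len(cur_members) - 1 - k0
                tp_out, fp_out = tp - k0, fp - m0

                def score(tp_n: int, fp_n: int) -> float:
                    fn_n = n_pos - tp_n
                    tn_n = total - tp_n - fp_n - fn_n
                    return _mcc(tp_n, tn_n, fp_n, fn_n)

                cur_mcc = score(tp, fp)
                # candidate clusters: those holding a neighbor, plus a new singleton
                cand_labels = sorted({labels[y] for y in adj[x]} - {cur})
                best_mcc, best_lab, best_tp, best_fp = cur_mcc, cur, tp, fp

                def better(s: float, tp_n: int) -> bool:
                    # strict MCC gain, or an MCC tie that gains true-positive
                    # pairs: the zero-denominator convention flattens whole
                    # neighborhoods to MCC 0, and preferring TP on ties walks
                    # off those plateaus; (MCC, TP) strictly increases per
                    # move, so convergence is preserved
                    if s > best_mcc + _EPS:
                        return True
                    return abs(s - best_mcc) <= _EPS and tp_n > best_tp

                for lab in cand_labels:
                    mem = members[lab]
                    k = len(adj[x] & mem)
                    m = len(mem) - k
                    s = score(tp_out + k, fp_out + m)
                    if better(s, tp_out + k):
                        best_mcc, best_lab = s, lab
                        best_tp, best_fp = tp_out + k, fp_out + m
                if len(cur_members) > 1:  # new-singleton move
                    s = score(tp_out, fp_out)
                    if better(s, tp_out):
                        best_mcc, best_lab = s, next_label
                        best_tp, best_fp = tp_out, fp_out
                if best_lab != cur:
                    cur_members.discard(x)
                    if not cur_members:
                        del members[cur]
                    if best_lab == next_label:
                        members[next_label] = set()
                        next_label += 1
                    members[best_lab].add(x)
                    labels[x] = best_lab
                    tp, fp = best_tp, best_fp
                    assert best_mcc >= history[-1] - 1e-9, "MCC decreased"
                    history.append(best_mcc)
                    moved = True
            if not moved:
                break
        run_mcc = history[-1]
        if best is None or run_mcc > best[0] + _EPS:
            best = (run_mcc, labels.copy(), history)
    assert best is not None
    return _canonicalize(best[1], threshold, adj, history=best[2])


def complete_linkage_partition(nbrs: NeighborSet, threshold: float) -> Partition:
    """Furthest-neighbor agglomeration cut at ``threshold``.

    Clusters merge only when every cross pair is within the threshold
    (pairs absent from the neighbor set count as beyond d_max).  Merges
    proceed in order of increasing complete-linkage distance with
    lexicographic tie-breaking, so partitions at increasing thresholds are
    nested.
    """
    if threshold > nbrs.d_max + 1e-12:
        raise ClusteringError(
            f"threshold {threshold} exceeds neighbor-set d_max {nbrs.d_max}"
        )
    n = nbrs.n_items
    dist = {(i, j): d for i, j, d in nbrs.pairs if d <= threshold + 1e-12}
    clusters: list[list[int]] = [[i] for i in range(n)]

    def linkage(a: list[int], b: list[int]) -> float | None:
        worst = 0.0
        for i in a:
            for j in b:
                key = (i, j) if i < j else (j, i)
                d = dist.get(key)
                if d is None:
                    return None
                worst = max(worst, d)
        return worst

    while True:
        best_key: tuple[float, list[int], list[int]] | None = None
        ai = bi = -1
        for p in range(len(clusters) - 1):
            for q in range(p + 1, len(clusters)):
                d = linkage(clusters[p], clusters[q])
                if d is None:
                    continue
                a, b = sorted((clusters[p], clusters[q]))
                key = (d, a, b)
                if best_key is None or key < best_key:
                    best_key, ai, bi = key, p, q
        if best_key is None:
            break
        merged = sorted(clusters[ai] + clusters[bi])
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(merged)

    labels = [0] * n
    for lab, mem in enumerate(clusters):
        for i in mem:
            labels[i] = lab
    return _canonicalize(labels, threshold, _adjacency(nbrs, threshold))


def _set_partitions(n: int):
    """All set partitions of range(n) as label lists (restricted growth strings)."""
    def rec(i: int, labels: list[int], k: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(k + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, k + 1 if lab == k else k)
            labels.pop()

    yield from rec(0, [], 0)


def brute_force_optimal(nbrs: NeighborSet, threshold: float) -> Partition:
    """MCC-optimal partition by exhaustive enumeration (n_items <= 10).

    Ties prefer fewer clusters, then the lexicographically smallest
    restricted-growth labeling.
    """
    n = nbrs.n_items
    if n > 10:
        raise ClusteringError(f"exhaustive search refused for n_items={n} > 10")
    adj = _adjacency(nbrs, threshold)
    best_labels: list[int] | None = None
    best_score: tuple[float, int] | None = None
    for labels in _set_partitions(n):
        conf = confusion_from_assignment(labels, adj, n)
        score = (mcc(conf), -len(set(labels)))
        if (
            best_score is None
            or score[0] > best_score[0] + 1e-12
            or (abs(score[0] - best_score[0]) <= 1e-12 and score[1] > best_score[1])
        ):
            best_score, best_labels = score, labels
    assert best_labels is not None
    return _canonicalize(best_labels, threshold, adj)


def write_list_format(partitions: list[Partition], path: str | Path) -> None:
    """Write OTU memberships in list-format text: one line per threshold with
    the label, the OTU count, then tab-separated comma-joined member ids."""
    with open(path, "w") as fh:
        fh.write("label\tnum_otus\totus\n")
        for part in partitions:
            groups = [
                ",".join(str(i) for i in mem)
                for _, mem in sorted(part.clusters().items())
            ]
            fh.write(f"{part.threshold:.4f}\t{part.n_otus}\t" + "\t".join(groups) + "\n")
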