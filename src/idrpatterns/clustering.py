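"""Sequence-identity clustering into nested levels C100 ⊇ C75 ⊇ C50 ⊇ C25 ⊇ C5.

Identity between two chains is the alignment-based Jaccard-style measure

    Id = I / (L1 + L2 - I) * 100,

where ``I`` is the number of identical residue pairs in the optimal local
alignment (BLOSUM62, gap open 11 / extend 1) and ``L1``, ``L2`` are the
full chain lengths.  C100 groups byte-identical sequences; each coarser
level merges clusters of the previous level by single linkage (any
cross-cluster pair at or above the threshold merges), iterated to a
fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .chains import ChainRecord

__all__ = [
    "ClusterForest",
    "pairwise_identity",
    "build_clusters",
    "cluster_summary",
]

DEFAULT_LEVELS = (100, 75, 50, 25, 5)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity Id = I/(L1+L2-I)*100 from the best local alignment.

    Symmetric; 100 iff the sequences are identical; 0 when the best
    alignment contains no identical pair.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if seq_a == seq_b:
        return 100.0
    # co-optimal alignments may differ in identity count; canonicalize the
    # argument order so the measure is symmetric by construction
    if (len(seq_a), seq_a) > (len(seq_b), seq_b):
        seq_a, seq_b = seq_b, seq_a
    alignments = _ALIGNER.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0
    identical = best.counts().identities
    return identical / (len(seq_a) + len(seq_b) - identical) * 100.0


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller root wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


@dataclass
class ClusterForest:
    """Nested partition of chains at decreasing identity thresholds.

    ``assignment[level]`` maps chain key -> cluster id (int).  Cluster
    ids are deterministic: clusters at each level are numbered 0.. in
    order of their lexicographically smallest member key.
    """

    levels: tuple[int, ...]
    assignment: dict[int, dict[str, int]] = field(default_factory=dict)

    def clusters_at(self, level: int) -> dict[int, list[str]]:
        """Cluster id -> sorted member keys at the given level."""
        if level not in self.assignment:
            raise KeyError(f"level {level} not in forest (has {self.levels})")
        out: dict[int, list[str]] = {}
        for key, cid in self.assignment[level].items():
            out.setdefault(cid, []).append(key)
        for members in out.values():
            members.sort()
        return out

    def subclusters(self, coarse: int, fine: int) -> dict[int, dict[int, list[str]]]:
        """Coarse cluster id -> {fine cluster id -> member keys}."""
        fine_assign = self.assignment[fine]
        out: dict[int, dict[int, list[str]]] = {}
        for key, cid in self.assignment[coarse].items():
            out.setdefault(cid, {}).setdefault(fine_assign[key], []).append(key)
        return out

    def check_nesting(self) -> None:
        """Raise if any finer cluster spans two coarser clusters."""
        for hi, lo in zip(self.levels, self.levels[1:]):
            coarse = self.assignment[lo]
            seen: dict[int, int] = {}
            for key, fine_id in self.assignment[hi].items():
                cid = coarse[key]
                if seen.setdefault(fine_id, cid) != cid:
                    raise AssertionError(
                        f"nesting violated: C{hi} cluster {fine_id} spans "
                        f"C{lo} clusters {seen[fine_id]} and {cid}"
                    )

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.assignment[self.levels[0]])
        return pd.DataFrame(
            {"chain": keys}
            | {f"C{lvl}": [self.assignment[lvl][k] for k in keys] for lvl in self.levels}
        )


def _renumber(groups: dict[str, int]) -> dict[str, int]:
    """Relabel cluster ids 0.. by smallest member key (deterministic)."""
    members: dict[int, str] = {}
    for key, cid in groups.items():
        if cid not in members or key < members[cid]:
            members[cid] = key
    order = {cid: rank for rank, (_, cid) in enumerate(sorted((v, k) for k, v in members.items()))}
    return {key: order[cid] for key, cid in groups.items()}


def build_clusters(
    records: list[ChainRecord],
    thresholds: tuple[int, ...] = DEFAULT_LEVELS,
) -> ClusterForest:
    """Build the nested cluster forest over the given chains.

    Identity depends only on the sequence, so byte-identical chains are
    deduplicated first (they form the 100% level) and alignments are
    computed between unique sequences only; this is exact, not an
    approximation.
    """
    thresholds = tuple(thresholds)
    if not thresholds or thresholds[0] != 100 or list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must start at 100 and be strictly decreasing")
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate chain keys in records")

    # C100: identical sequences
    seq_of = {r.key: r.sequence for r in records}
    unique_seqs = sorted(set(seq_of.values()))
    seq_group = {s: i for i, s in enumerate(unique_seqs)}

    # identity between unique sequences, computed once
    ident: dict[tuple[int, int], float] = {}
    for (ia, sa), (ib, sb) in combinations(enumerate(unique_seqs), 2):
        ident[(ia, ib)] = pairwise_identity(sa, sb)

    forest = ClusterForest(levels=thresholds)
    group_of_key = {k: seq_group[s] for k, s in seq_of.items()}
    forest.assignment[100] = _renumber(group_of_key)

    # single linkage over sequence groups, level by level
    uf = _UnionFind(range(len(unique_seqs)))
    for level in thresholds[1:]:
        for (ia, ib), idv in ident.items():
            if idv >= level:
                uf.union(ia, ib)
        merged = {k: uf.find(g) for k, g in group_of_key.items()}
        forest.assignment[level] = _renumber(merged)
    return forest


def cluster_summary(forest: ClusterForest) -> pd.DataFrame:
    """Per-level cluster count and mean cluster size."""
    rows = []
    for level in forest.levels:
        clusters = forest.clusters_at(level)
        sizes = [len(v) for v in clusters.values()]
        rows.append(
            {
                "level": level,
                "n_clusters": len(clusters),
                "mean_size": sum(sizes) / len(sizes) if sizes else 0.0,
            }
        )
    return pd.DataFrame(rows)
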