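"""Two-level weighted disorder statistics.

Chains are never counted raw: counts are first averaged over identical
sequences (the C100 sub-clusters), then over the C100 sub-clusters of a
C75 cluster.  This stops heavily redeposited proteins from dominating
the statistics.  The same weighting yields positional disorder
frequencies per amino acid in the N-terminal, middle and C-terminal
regions of the chain.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .chains import ChainRecord
from .clustering import ClusterForest

__all__ = [
    "WeightedCounts",
    "two_level_average",
    "classify_regions",
    "positional_disorder_frequencies",
    "round_half_up",
]

REGIONS = ("N-terminal", "middle", "C-terminal")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


class WeightedCounts(NamedTuple):
    """Mean numbers of unstructured (u) and structured (s) residues."""

    u: float
    s: float


def two_level_average(
    groups: Sequence[Sequence[tuple[float, float]]],
) -> WeightedCounts:
    """Average (u, s) count pairs within each group, then across groups.

    Each inner sequence holds the per-chain counts of one C100
    sub-cluster; the outer sequence is one C75 cluster.  Both averages
    are unweighted means, so a sub-cluster contributes equally no matter
    how many identical chains it holds.
    """
    if not groups:
        raise ValueError("two_level_average requires at least one group")
    u_means = []
    s_means = []
    for i, group in enumerate(groups):
        if not group:
            raise ValueError(f"group {i} is empty")
        u_means.append(sum(u for u, _ in group) / len(group))
        s_means.append(sum(s for _, s in group) / len(group))
    return WeightedCounts(sum(u_means) / len(u_means), sum(s_means) / len(s_means))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, for report formatting (17.125 -> 17.13)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_regions(mask: str, terminal_window: int | None = None) -> list[str]:
    """Label each residue N-terminal, middle or C-terminal.

    By default the terminal regions are the maximal disordered runs
    touching the first and last residue: terminal missing density is
    what distinguishes chain ends from internal disorder.  A fully
    disordered chain is assigned N-terminal as a whole (deterministic
    tie-break).  With ``terminal_window=K`` a fixed-width rule is used
    instead: first K residues N-terminal, last K C-terminal.
    """
    n = len(mask)
    if n == 0:
        return []
    if terminal_window is not None:
        k = min(terminal_window, n)
        labels = ["middle"] * n
        labels[:k] = ["N-terminal"] * k
        # N-terminal wins where windows overlap
        for i in range(max(n - k, k), n):
            labels[i] = "C-terminal"
        return labels
    labels = ["middle"] * n
    if mask[0] == "U":
        i = 0
        while i < n and mask[i] == "U":
            labels[i] = "N-terminal"
            i += 1
        if i == n:
            return labels  # fully disordered: N-terminal by convention
    if mask[-1] == "U":
        j = n - 1
        while j >= 0 and mask[j] == "U":
            labels[j] = "C-terminal"
            j -= 1
    return labels


def _chain_weights(
    forest: ClusterForest, level: int
) -> dict[str, float]:
    """Per-chain weight implementing the two-level average at ``level``.

    A chain in a C100 sub-cluster of size m inside a cluster with k
    sub-clusters carries weight 1/(m*k); summing weighted counts over
    chains then equals summing per-cluster two-level means.
    """
    weights: dict[str, float] = {}
    for _, subs in forest.subclusters(level, 100).items():
        k = len(subs)
        for members in subs.values():
            for key in members:
                weights[key] = 1.0 / (len(members) * k)
    return weights


def positional_disorder_frequencies(
    records: Iterable[ChainRecord],
    forest: ClusterForest,
    level: int = 75,
    terminal_window: int | None = None,
) -> pd.DataFrame:
    """Disorder frequency per amino acid and chain region.

    For each of the 20 amino acids and each region the frequency is the
    two-level-weighted count of its disordered occurrences divided by
    the two-level-weighted count of all its occurrences there.
    Returns a tidy frame with columns ``aa, region, weighted_u,
    weighted_total, frequency`` (frequency is NaN where the amino acid
    never occurs in the region).
    """
    if level not in forest.assignment:
        raise KeyError(f"level {level} not present in forest")
    weights = _chain_weights(forest, level)
    u_w: dict[tuple[str, str], float] = {}
    tot_w: dict[tuple[str, str], float] = {}
    for rec in records:
        w = weights[rec.key]
        labels = classify_regions(rec.disorder_mask, terminal_window)
        for aa, m, region in zip(rec.sequence, rec.disorder_mask, labels):
            if aa not in AA20:
                continue
            k = (aa, region)
            tot_w[k] = tot_w.get(k, 0.0) + w
            if m == "U":
                u_w[k] = u_w.get(k, 0.0) + w
    rows = []
    for aa in AA20:
        for region in REGIONS:
            tot = tot_w.get((aa, region), 0.0)
            u = u_w.get((aa, region), 0.0)
            rows.append(
                {
                    "aa": aa,
                    "region": region,
                    "weighted_u": u,
                    "weighted_total": tot,
                    "frequency": (u / tot) if tot > 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
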