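"""Pattern mining: candidates, X-masking of homologues, greedy selection.

The library-construction algorithm works on a clustered chain set:

1. every C100 cluster proposes *candidates* — maximal runs of positions
   disordered in at least half of the member chains (length >= 3);
2. near-identical candidates (>= 80% identity, i.e. at most
   ceil(L/5) - 1 substitutions) are merged by masking the diverging
   positions with the wildcard ``X``, and the X-masks are combined
   pairwise to a fixed point;
3. low-complexity candidates (homo-repeats and two-amino-acid
   patterns) are set aside;
4. an iterative greedy procedure repeatedly picks the candidate with
   the largest score D = N_u - N_f, where N_u/N_f sum the two-level
   cluster means of disordered/ordered residues its matches cover, and
   marks those residues as consumed so later patterns cannot re-count
   them.  Selection requires C_u >= 5 clusters, C_u > C_f and
   N_u > N_f; the final library keeps patterns with D >= 25.

A pattern matches a sequence wherever every non-X letter coincides;
``X`` positions match any residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chains import ChainRecord
from .clustering import ClusterForest
from .disorder_stats import two_level_average
from .lowcomplexity import find_homorepeats

__all__ = [
    "Pattern",
    "PatternStats",
    "match",
    "extract_candidates",
    "allowed_substitutions",
    "synthesize_xpatterns",
    "expand_candidates",
    "filter_lowcomplexity",
    "pattern_stats",
    "greedy_select",
    "histag_proximity",
    "mine_library",
]

MIN_CANDIDATE_LENGTH = 3


@dataclass(frozen=True)
class Pattern:
    """A library pattern over the 20 amino acids plus the wildcard X."""

    letters: str

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError("empty pattern")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters

    @property
    def effective_length(self) -> int:
        """Number of non-X (specific) positions."""
        return sum(1 for c in self.letters if c != "X")


@dataclass(frozen=True)
class PatternStats:
    """Cluster-weighted match statistics of one pattern.

    ``n_u``/``n_f`` sum, over C75 clusters containing a match, the
    two-level mean number of disordered/ordered residues the pattern
    covers; ``c_u``/``c_f`` count the clusters whose mean is
    majority-disordered / not; ``d = n_u - n_f`` is the greedy score.
    """

    n_u: float
    n_f: float
    c_u: int
    c_f: int

    @property
    def d(self) -> float:
        return self.n_u - self.n_f


def match(pattern: Pattern | str, sequence: str) -> list[int]:
    """All 0-based start positions where the pattern matches.

    Overlapping matches are all reported.  A non-X pattern letter must
    equal the sequence letter exactly; in particular an unknown residue
    (X) in the sequence matches only X pattern positions.
    """
    letters = pattern.letters if isinstance(pattern, Pattern) else pattern
    m, n = len(letters), len(sequence)
    if m > n:
        return []
    if "X" not in letters:
        out = []
        start = sequence.find(letters)
        while start != -1:
            out.append(start)
            start = sequence.find(letters, start + 1)
        return out
    fixed = [(i, c) for i, c in enumerate(letters) if c != "X"]
    return [
        s
        for s in range(n - m + 1)
        if all(sequence[s + i] == c for i, c in fixed)
    ]


def extract_candidates(
    records: Sequence[ChainRecord],
    forest: ClusterForest,
    min_fraction: float = 0.5,
    min_length: int = MIN_CANDIDATE_LENGTH,
) -> list[Pattern]:
    """Candidate fragments from per-position disorder within C100 clusters.

    Member chains of a C100 cluster share one sequence; a position is
    candidate material when it is disordered in at least
    ``min_fraction`` of the members (inclusive).  Maximal such runs of
    at least ``min_length`` residues become candidates; duplicate
    letter strings are dropped, first occurrence kept (clusters
    processed in deterministic id order).
    """
    by_key = {r.key: r for r in records}
    seen: set[str] = set()
    out: list[Pattern] = []
    for cid, members in sorted(forest.clusters_at(100).items()):
        recs = [by_key[k] for k in members if k in by_key]
        if not recs:
            continue
        seq = recs[0].sequence
        if any(r.sequence != seq for r in recs):
            raise ValueError(f"C100 cluster {cid} members have differing sequences")
        n = len(seq)
        frac = [
            sum(r.disorder_mask[i] == "U" for r in recs) / len(recs)
            for i in range(n)
        ]
        i = 0
        while i < n:
            if frac[i] >= min_fraction:
                j = i
                while j < n and frac[j] >= min_fraction:
                    j += 1
                if j - i >= min_length:
                    frag = seq[i:j]
                    if frag not in seen:
                        seen.add(frag)
                        out.append(Pattern(frag))
                i = j
            else:
                i += 1
    return out


def allowed_substitutions(length: int) -> int:
    """Substitutions allowed in a homologue of a length-L candidate.

    Lengths 3-5 allow none (no homologue search), 6-10 one, 11-15 two,
    and so on: ceil(L/5) - 1, i.e. homologues stay above 80% identity.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return math.ceil(length / 5) - 1


def synthesize_xpatterns(
    candidate: Pattern,
    homologs: Iterable[Pattern | str],
) -> list[Pattern]:
    """X-mask the candidate against its homologues and combine the masks.

    Each homologue contributes the pattern with ``X`` at its mismatch
    positions; mask position-sets are then combined pairwise (set
    union) to a fixed point, and the candidate itself is retained.
    The result is deduplicated and sorted by (number of X positions,
    positions), which makes the output order deterministic.
    """
    base = candidate.letters
    limit = allowed_substitutions(len(base))
    mask_sets: set[frozenset[int]] = {frozenset()}
    for hom in homologs:
        letters = hom.letters if isinstance(hom, Pattern) else hom
        if len(letters) != len(base):
            raise ValueError(
                f"homolog length {len(letters)} != candidate length {len(base)}"
            )
        mismatches = frozenset(
            i for i, (a, b) in enumerate(zip(base, letters)) if a != b
        )
        if len(mismatches) > limit:
            raise ValueError(
                f"homolog {letters} has {len(mismatches)} substitutions; "
                f"at most {limit} allowed for length {len(base)}"
            )
        if mismatches:
            mask_sets.add(mismatches)
    # pairwise-union closure
    frontier = set(mask_sets)
    while frontier:
        new = {
            a | b for a in frontier for b in mask_sets if (a | b) not in mask_sets
        }
        mask_sets |= new
        frontier = new
    out = []
    for mask in sorted(mask_sets, key=lambda s: (len(s), sorted(s))):
        letters = "".join("X" if i in mask else c for i, c in enumerate(base))
        out.append(Pattern(letters))
    return out


def expand_candidates(candidates: Sequence[Pattern]) -> list[Pattern]:
    """Grow the candidate list with X-patterns from mutual homologues.

    Homologues of a candidate are sought among the candidates
    themselves: equal length, Hamming distance between 1 and
    ``allowed_substitutions``.  Candidates shorter than 6 residues are
    passed through unchanged.  Deterministic: candidates are processed
    in input order, results deduplicated keeping first occurrence.
    """
    by_length: dict[int, list[Pattern]] = {}
    for c in candidates:
        by_length.setdefault(len(c.letters), []).append(c)
    seen: set[str] = set()
    out: list[Pattern] = []

    def _add(p: Pattern) -> None:
        if p.letters not in seen:
            seen.add(p.letters)
            out.append(p)

    for cand in candidates:
        limit = allowed_substitutions(len(cand.letters))
        if limit == 0:
            _add(cand)
            continue
        homs = []
        for other in by_length[len(cand.letters)]:
            if other.letters == cand.letters:
                continue
            dist = sum(a != b for a, b in zip(cand.letters, other.letters))
            if 1 <= dist <= limit:
                homs.append(other)
        for p in synthesize_xpatterns(cand, homs):
            _add(p)
    return out


def filter_lowcomplexity(candidates: Sequence[Pattern]) -> list[Pattern]:
    """Drop homo-repeat and two-amino-acid (AC2) candidates.

    A fully specific candidate (no X) written with at most two residue
    types belongs to the homo-repeat / AC2 catalogues, which are built
    separately, not to the unique-pattern list.
    """
    out = []
    for c in candidates:
        if "X" not in c.letters and len(set(c.letters)) <= 2:
            continue
        out.append(c)
    return out


ConsumedMap = Mapping[str, frozenset[int] | set[int]]


def _covered_positions(
    pattern: Pattern, sequence: str, consumed: frozenset[int] | set[int]
) -> set[int]:
    positions: set[int] = set()
    for s in match(pattern, sequence):
        positions.update(range(s, s + len(pattern.letters)))
    return positions - set(consumed)


def pattern_stats(
    pattern: Pattern,
    records: Sequence[ChainRecord],
    forest: ClusterForest,
    consumed: ConsumedMap | None = None,
    level: int = 75,
) -> PatternStats:
    """Two-level weighted match statistics of a pattern.

    Within each cluster at ``level``: per chain, the residues covered
    by the pattern's matches (all pattern positions, X included) and
    not yet consumed are split into disordered/ordered counts; counts
    are averaged within C100 sub-clusters, then across sub-clusters.
    Clusters without any match are skipped entirely.
    """
    consumed = consumed or {}
    by_key = {r.key: r for r in records}
    n_u = n_f = 0.0
    c_u = c_f = 0
    for _, subs in sorted(forest.subclusters(level, 100).items()):
        cluster_hit = False
        groups = []
        for _, members in sorted(subs.items()):
            pairs = []
            for key in members:
                rec = by_key.get(key)
                if rec is None:
                    continue
                if match(pattern, rec.sequence):
                    cluster_hit = True
                covered = _covered_positions(
                    pattern, rec.sequence, consumed.get(key, frozenset())
                )
                u = sum(rec.disorder_mask[i] == "U" for i in covered)
                pairs.append((u, len(covered) - u))
            if pairs:
                groups.append(pairs)
        if not cluster_hit or not groups:
            continue
        mean = two_level_average(groups)
        n_u += mean.u
        n_f += mean.s
        if mean.u > mean.s:
            c_u += 1
        else:
            c_f += 1
    return PatternStats(n_u=n_u, n_f=n_f, c_u=c_u, c_f=c_f)


def greedy_select(
    candidates: Sequence[Pattern],
    records: Sequence[ChainRecord],
    forest: ClusterForest,
    c1_min: int = 5,
    d_min: float = 25.0,
    level: int = 75,
) -> list[tuple[Pattern, PatternStats]]:
    """Iterative greedy library selection.

    Each round recomputes every candidate's statistics on the residues
    not yet consumed, keeps candidates passing the three conditions
    (C1: c_u >= ``c1_min``; C2: c_u > c_f; C3: n_u > n_f), and selects
    the one with the largest D (ties: longer effective length, then
    lexicographically smaller letters).  Its matched residues are then
    consumed.  Iteration stops when no candidate passes or the best
    remaining D is <= 0; the returned library keeps selections whose
    at-selection D is at least ``d_min``, in selection order.
    """
    consumed: dict[str, set[int]] = {r.key: set() for r in records}
    remaining = list(dict.fromkeys(candidates))  # dedupe, keep order
    selected: list[tuple[Pattern, PatternStats]] = []
    while remaining:
        best: tuple | None = None
        for pat in remaining:
            st = pattern_stats(pat, records, forest, consumed, level)
            if st.c_u < c1_min or st.c_u <= st.c_f or st.n_u <= st.n_f:
                continue
            key = (-st.d, -pat.effective_length, pat.letters)
            if best is None or key < best[0]:
                best = (key, pat, st)
        if best is None or best[2].d <= 0:
            break
        _, pat, st = best
        for rec in records:
            for s in match(pat, rec.sequence):
                consumed[rec.key].update(range(s, s + len(pat.letters)))
        selected.append((pat, st))
        remaining = [p for p in remaining if p.letters != pat.letters]
    return [(p, st) for p, st in selected if st.d >= d_min]


_PC_BINS = (
    (lambda pc: pc == 0.0, "PC = 0% (far)"),
    (lambda pc: 0.0 < pc < 33.0, "0% < PC < 33%"),
    (lambda pc: 33.0 <= pc <= 67.0, "33% <= PC <= 67%"),
    (lambda pc: 67.0 < pc < 100.0, "67% < PC < 100%"),
    (lambda pc: pc == 100.0, "PC = 100% (near)"),
)


def histag_proximity(
    pattern: Pattern,
    records: Sequence[ChainRecord],
    tag_min_run: int = 4,
    window: int = 40,
) -> tuple[float | None, str]:
    """Fraction of a pattern's occurrences near a histidine run.

    An occurrence is *near* when fewer than ``window`` residues
    separate it from the closest His run of length >= ``tag_min_run``
    in the same chain (overlap counts as distance 0).  Returns the
    percentage PC and its bin label; a pattern without occurrences
    gives (None, "n/a").  His tags are purification artifacts that are
    usually unresolved, so high-PC patterns are suspect.
    """
    total = near = 0
    for rec in records:
        tags = find_homorepeats(rec.sequence, tag_min_run)
        his = [(s, e) for s, e, aa in tags if aa == "H"]
        for s in match(pattern, rec.sequence):
            e = s + len(pattern.letters)
            total += 1
            for ts, te in his:
                gap = max(ts - e, s - te, 0)
                if gap < window:
                    near += 1
                    break
    if total == 0:
        return None, "n/a"
    pc = 100.0 * near / total
    for test, label in _PC_BINS:
        if test(pc):
            return pc, label
    raise AssertionError("unreachable")


def mine_library(
    records: Sequence[ChainRecord],
    forest: ClusterForest,
    c1_min: int = 5,
    d_min: float = 25.0,
    min_fraction: float = 0.5,
    level: int = 75,
) -> pd.DataFrame:
    """Full mining pipeline; returns the library as a table.

    Columns: pattern, effective_length, n_u, n_f, c_u, c_f, d, pc,
    histag_bin.  Rows are in selection order (descending D at
    selection time).
    """
    candidates = extract_candidates(records, forest, min_fraction=min_fraction)
    candidates = expand_candidates(candidates)
    candidates = filter_lowcomplexity(candidates)
    library = greedy_select(
        candidates, records, forest, c1_min=c1_min, d_min=d_min, level=level
    )
    rows = []
    for pat, st in library:
        pc, bin_label = histag_proximity(pat, records)
        rows.append(
            {
                "pattern": pat.letters,
                "effective_length": pat.effective_length,
                "n_u": st.n_u,
                "n_f": st.n_f,
                "c_u": st.c_u,
                "c_f": st.c_f,
                "d": st.d,
                "pc": pc,
                "histag_bin": bin_label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pattern",
            "effective_length",
            "n_u",
            "n_f",
            "c_u",
            "c_f",
            "d",
            "pc",
            "histag_bin",
        ],
    )
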