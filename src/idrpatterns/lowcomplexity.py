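"""Low-complexity segments: AC2 runs, homo-repeats, and their null model.

An AC2 segment is a maximal stretch of sequence written with exactly
two amino-acid types (e.g. ``GSGSGSGSGSSG``).  Each segment is
abstracted to a binary template over {0, 1} (first-seen type -> 0) and
classified into three groups: a homo-repeat with one adjacent foreign
residue, an internal (period-2 or period-4) repeat, or other.  The
closed-form probability that a random length-L sequence is AC2,

    P_AC2(L) = sum_{i<j} ((p_i + p_j)^L - p_i^L - p_j^L),

gives the expected abundance of such segments under independently drawn
residues; with uniform frequencies (p = 1/20) it reduces to
190 * (0.1^L - 2 * 0.05^L).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, groupby
from typing import Mapping, Sequence

__all__ = [
    "AC2Run",
    "find_ac2_runs",
    "find_homorepeats",
    "classify_ac2",
    "prob_ac2",
    "prob_ac2_uniform",
    "coverage",
]

GROUP_HOMO_ADJACENT = "homo_adjacent"
GROUP_INTERNAL_REPEAT = "internal_repeat"
GROUP_OTHER = "other"


@dataclass(frozen=True)
class AC2Run:
    """A maximal two-amino-acid segment.

    ``start``/``end`` are a 0-based half-open interval into the source
    sequence; ``pair`` is the alphabetically ordered amino-acid pair;
    ``template`` encodes the segment over {0, 1}, 0 for the first-seen
    type; ``group`` is the template classification.
    """

    start: int
    end: int
    pair: tuple[str, str]
    template: str
    group: str

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_ac2(template: str) -> str:
    """Classify a binary AC2 template into one of the three groups.

    ``homo_adjacent``: one symbol occurs exactly once, at either end
    (a homo-repeat plus a single adjacent foreign residue).
    ``internal_repeat``: the template is a whole or truncated
    repetition of a 2- or 4-letter word (dipeptide and tetrapeptide
    repeats such as 01010101 or 0001001).  Everything else: ``other``.
    Precedence: homo_adjacent > internal_repeat > other.
    """
    for sym in "01":
        if template.count(sym) == 1 and (template[0] == sym or template[-1] == sym):
            return GROUP_HOMO_ADJACENT
    for period in (2, 4):
        word = template[:period]
        if len(set(word)) < 2:
            continue
        if all(template[i] == word[i % period] for i in range(len(template))):
            return GROUP_INTERNAL_REPEAT
    return GROUP_OTHER


def _segments(sequence: str):
    """Maximal X-free segments as (offset, run-length encoding)."""
    offset = 0
    for is_x, chunk in groupby(sequence, key=lambda c: c == "X"):
        chunk = "".join(chunk)
        if not is_x:
            runs = [(aa, len("".join(g))) for aa, g in groupby(chunk)]
            yield offset, runs
        offset += len(chunk)


def find_ac2_runs(sequence: str, min_length: int = 8) -> list[AC2Run]:
    """All maximal segments built from exactly two amino-acid types.

    Overlapping maximal segments with different pairs are all reported
    (``WWWWGGGGSSSS`` yields both the WG and the GS segment).  Unknown
    residues (X) break segments.  ``min_length`` defaults to 8, the
    basis length of the pattern library.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    out: list[AC2Run] = []
    for offset, runs in _segments(sequence):
        starts = [offset]
        for _, ln in runs:
            starts.append(starts[-1] + ln)
        n = len(runs)
        j_prev = -1
        for i in range(n):
            # widest window of runs starting at i with <= 2 types
            types = set()
            j = i
            while j < n and len(types | {runs[j][0]}) <= 2:
                types.add(runs[j][0])
                j += 1
            if len(types) != 2 or j <= j_prev:
                continue  # single type, or nested in the previous window
            j_prev = j
            start, end = starts[i], starts[j]
            if end - start < min_length:
                continue
            seg = sequence[start:end]
            first = seg[0]
            template = "".join("0" if c == first else "1" for c in seg)
            pair = tuple(sorted(types))
            out.append(
                AC2Run(
                    start=start,
                    end=end,
                    pair=pair,  # type: ignore[arg-type]
                    template=template,
                    group=classify_ac2(template),
                )
            )
    return out


def find_homorepeats(sequence: str, min_length: int = 4) -> list[tuple[int, int, str]]:
    """Maximal single-amino-acid runs of at least ``min_length``.

    Returns (start, end, amino acid) with 0-based half-open intervals.
    X runs are not reported.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    out = []
    pos = 0
    for aa, g in groupby(sequence):
        ln = len("".join(g))
        if ln >= min_length and aa != "X":
            out.append((pos, pos + ln, aa))
        pos += ln
    return out


def coverage(runs: Sequence, seq_length: int) -> int:
    """Number of residues covered by at least one run (counted once)."""
    covered = bytearray(seq_length)
    for run in runs:
        start, end = (run.start, run.end) if hasattr(run, "start") else run[:2]
        for i in range(start, end):
            covered[i] = 1
    return sum(covered)


def prob_ac2(L: int, freqs: Mapping[str, float]) -> float:
    """Probability that a random length-L sequence uses exactly two types.

    Inclusion-exclusion over unordered pairs: (p_i + p_j)^L counts
    sequences confined to {i, j}; subtracting p_i^L and p_j^L removes
    the single-type ones.  ``freqs`` may cover any alphabet; values
    must be non-negative and sum to 1.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    p = list(freqs.values())
    if any(v < 0 for v in p) or abs(sum(p) - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return sum(
        (pi + pj) ** L - pi**L - pj**L for pi, pj in combinations(p, 2)
    )


def prob_ac2_uniform(L: int) -> float:
    """Uniform-frequency closed form: 190 * (0.1^L - 2 * 0.05^L)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return 190.0 * (0.1**L - 2.0 * 0.05**L)
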