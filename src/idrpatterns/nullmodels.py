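"""Null models: expected pattern counts and random proteomes.

The expected number of occurrences of a pattern with effective (non-X)
length L in a residue corpus of size n_res is

    N_o = n_res * (1/20)^L            (uniform frequencies)
    N_o = n_res * prod_i p(letter_i)  (observed frequencies)

with the product over the pattern's non-X positions.  A matched random
proteome keeps the real protein lengths but draws every residue
independently from the amino-acid frequency vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .mining import Pattern, match

__all__ = [
    "ProteomeSummary",
    "expected_count",
    "count_in_proteome",
    "random_proteome",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteomeSummary:
    """Size and composition summary of a proteome set."""

    n_res: int
    n_prot: int
    freqs: Mapping[str, float]
    length_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_res != sum(self.length_list):
            raise ValueError("n_res != sum of protein lengths")
        if self.n_prot != len(self.length_list):
            raise ValueError("n_prot != number of proteins")

    @classmethod
    def from_sequences(cls, sequences: Sequence[str]) -> "ProteomeSummary":
        lengths = tuple(len(s) for s in sequences)
        counts: dict[str, int] = {}
        total = 0
        for seq in sequences:
            for c in seq:
                if c in AA20:
                    counts[c] = counts.get(c, 0) + 1
                    total += 1
        freqs = {aa: counts.get(aa, 0) / total for aa in AA20} if total else {}
        return cls(
            n_res=sum(lengths),
            n_prot=len(lengths),
            freqs=freqs,
            length_list=lengths,
        )


def expected_count(
    pattern: Pattern | str,
    summary: ProteomeSummary,
    uniform: bool = True,
) -> float:
    """Expected occurrences N_o of the pattern in the summarized corpus.

    Uniform mode uses (1/20) per specific position; otherwise the
    summary's observed amino-acid frequencies.  X positions contribute
    factor 1 (an all-X pattern is expected everywhere: N_o = n_res).
    """
    letters = pattern.letters if isinstance(pattern, Pattern) else pattern
    p = 1.0
    for c in letters:
        if c == "X":
            continue
        p *= 0.05 if uniform else summary.freqs.get(c, 0.0)
    return summary.n_res * p


def count_in_proteome(
    pattern: Pattern | str,
    sequences: Sequence[str],
    overlap: bool = True,
) -> tuple[int, int]:
    """Observed occurrences and the number of proteins containing them.

    Returns ``(occurrences, n_p)``.  Overlapping occurrences are
    counted by default; with ``overlap=False`` matches are taken
    greedily left to right without sharing residues.
    """
    pat = pattern if isinstance(pattern, Pattern) else Pattern(pattern)
    occurrences = 0
    n_p = 0
    width = len(pat.letters)
    for seq in sequences:
        starts = match(pat, seq)
        if not overlap:
            kept, limit = [], -1
            for s in starts:
                if s >= limit:
                    kept.append(s)
                    limit = s + width
            starts = kept
        if starts:
            n_p += 1
            occurrences += len(starts)
    return occurrences, n_p


def random_proteome(
    length_list: Sequence[int],
    freqs: Mapping[str, float],
    seed: int,
) -> list[str]:
    """Length-matched random proteome.

    One sequence per requested length, residues drawn independently
    from ``freqs`` with numpy's PCG64 generator; a fixed seed gives a
    byte-identical proteome on any platform.
    """
    if any(n < 0 for n in length_list):
        raise ValueError("negative sequence length")
    letters = sorted(freqs)
    p = np.asarray([freqs[c] for c in letters], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    p = p / p.sum()
    rng = np.random.Generator(np.random.PCG64(seed))
    alphabet = np.asarray(list(letters))
    return [
        "".join(rng.choice(alphabet, size=n, p=p)) if n else ""
        for n in length_list
    ]
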