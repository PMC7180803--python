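"""Synthetic fixtures: toy structure files, chain families, planted motifs.

Everything downstream — parsing, clustering, statistics, mining — is
exercised on data generated here, with ground truth emitted alongside,
so the whole pipeline is testable without any database download.  All
generators are deterministic functions of their explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from .chains import ChainRecord
from .clustering import ClusterForest
from .mining import match

__all__ = [
    "FixtureSpec",
    "Family",
    "make_pdb_fixture",
    "make_family",
    "plant_motifs",
    "random_sequence",
    "build_family_records",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_THREE = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def random_sequence(
    rng: np.random.Generator, length: int, avoid: Sequence[str] = ()
) -> str:
    """Random 20-letter sequence avoiding given substrings and His runs.

    Rejection-samples until none of the ``avoid`` strings occurs and no
    histidine run of length >= 4 is present (so fixtures do not trip
    the His-tag proximity analysis by accident).
    """
    letters = np.asarray(list(AA20))
    for _ in range(1000):
        seq = "".join(rng.choice(letters, size=length))
        if "HHHH" in seq:
            continue
        if any(a in seq for a in avoid):
            continue
        return seq
    raise RuntimeError("could not generate an avoiding random sequence")


def make_pdb_fixture(
    sequence: str,
    missing_intervals: Sequence[tuple[int, int]] = (),
    entry_id: str = "1ABC",
    chain_id: str = "A",
    resolution: float = 2.0,
) -> str:
    """PDB-format text for one chain with controlled missing residues.

    ``missing_intervals`` are 1-based inclusive residue ranges that get
    REMARK 465 lines and no ATOM record; every other residue gets a
    CA-only ATOM record.  Parsing the output recovers exactly the
    intended U/S mask.
    """
    n = len(sequence)
    missing: set[int] = set()
    for lo, hi in missing_intervals:
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"interval ({lo}, {hi}) outside chain 1..{n}")
        missing.update(range(lo, hi + 1))
    entry_id = entry_id.upper()[:4].ljust(4)

    lines = [
        f"HEADER    SYNTHETIC PROTEIN                       01-JAN-20   {entry_id}",
        "EXPDTA    X-RAY DIFFRACTION",
        f"REMARK   2 RESOLUTION.    {resolution:4.2f} ANGSTROMS.",
    ]
    if missing:
        lines += [
            "REMARK 465",
            "REMARK 465 MISSING RESIDUES",
            "REMARK 465   M RES C SSSEQI",
        ]
        for i in sorted(missing):
            res3 = _THREE.get(sequence[i - 1], "UNK")
            lines.append(f"REMARK 465     {res3} {chain_id}{i:6d}")
    # SEQRES, 13 residues per line
    for row, start in enumerate(range(0, n, 13), start=1):
        chunk = sequence[start : start + 13]
        names = " ".join(_THREE.get(c, "UNK") for c in chunk)
        lines.append(f"SEQRES {row:3d} {chain_id} {n:4d}  {names}")
    serial = 1
    for i, aa in enumerate(sequence, start=1):
        if i in missing:
            continue
        res3 = _THREE.get(aa, "UNK")
        x = 1.3 * i
        lines.append(
            f"ATOM  {serial:5d}  CA  {res3} {chain_id}{i:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{20.00:6.2f}           C"
        )
        serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_family(
    base_sequence: str,
    n: int,
    target_identity: float,
    seed: int,
) -> list[str]:
    """``n`` mutated copies with controlled pairwise identity.

    All copies are substituted at the same positions but with mutually
    distinct replacement letters, so every pair differs at exactly k
    positions, where k is chosen so the alignment-based identity
    (L-k)/(L+k)*100 lands on ``target_identity`` (within 3 points for
    feasible lengths).  ``target_identity=100`` returns identical
    copies.  Deterministic under ``seed``.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 19:
        raise ValueError("at most 19 mutually distinct members supported")
    L = len(base_sequence)
    k = round(L * (100.0 - target_identity) / (100.0 + target_identity))
    if k == 0:
        return [base_sequence] * n
    rng = _rng(seed)
    positions = sorted(rng.choice(L, size=k, replace=False).tolist())
    out = []
    for member in range(n):
        seq = list(base_sequence)
        for q in positions:
            orig = AA20.index(base_sequence[q]) if base_sequence[q] in AA20 else 0
            seq[q] = AA20[(orig + 1 + member) % 20]
        out.append("".join(seq))
    return out


@dataclass(frozen=True)
class Family:
    """One synthetic chain family for a fixture."""

    base_sequence: str
    n_members: int
    target_identity: float = 100.0
    disordered_intervals: tuple[tuple[int, int], ...] = ()  # 1-based inclusive


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible set of chain families."""

    families: tuple[Family, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam.n_members < 1:
                raise ValueError("family member count must be >= 1")


def build_family_records(spec: FixtureSpec) -> list[ChainRecord]:
    """Chain records for every family member of a fixture spec.

    Member sequences come from :func:`make_family`; the disorder mask
    marks the family's disordered intervals U and everything else S.
    Entries are named ``f{family}{member}`` deterministically.
    """
    records = []
    for fi, fam in enumerate(spec.families):
        seqs = make_family(
            fam.base_sequence, fam.n_members, fam.target_identity, spec.seed + fi
        )
        mask = ["S"] * len(fam.base_sequence)
        for lo, hi in fam.disordered_intervals:
            for i in range(lo - 1, hi):
                mask[i] = "U"
        for mi, seq in enumerate(seqs):
            records.append(
                ChainRecord(
                    entry_id=f"f{fi:02d}{mi:x}",
                    chain_id="A",
                    sequence=seq,
                    disorder_mask="".join(mask),
                )
            )
    return records


def plant_motifs(
    motifs: Sequence[tuple[str, int, bool]],
    seed: int,
    chain_length: int = 120,
    chains_per_cluster: int = 1,
) -> tuple[list[ChainRecord], ClusterForest, pd.DataFrame]:
    """Chains with motifs planted in known clusters, plus ground truth.

    ``motifs`` is a list of ``(letters, n_clusters, disordered)``.
    Each motif is inserted once into the (identical) chains of
    ``n_clusters`` dedicated synthetic clusters; the insertion is
    disordered iff flagged, the random background is structured.
    Backgrounds avoid every motif string, so each motif matches its own
    clusters exactly once per chain and nowhere else.  Returns the
    records, a two-level (C100 = C75) forest, and the placement table
    with columns ``motif, cluster, chain, start`` (0-based start).
    """
    for letters, n_clusters, _ in motifs:
        if len(letters) < 3:
            raise ValueError(f"motif {letters!r} shorter than 3")
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
    strings = [m[0] for m in motifs]
    for a in strings:
        for b in strings:
            if a != b and a in b:
                raise ValueError(f"motif {a!r} is a substring of {b!r}")
    rng = _rng(seed)
    all_motifs = [m[0] for m in motifs]
    records: list[ChainRecord] = []
    assignment: dict[str, int] = {}
    rows = []
    cluster_idx = 0
    for letters, n_clusters, disordered in motifs:
        width = len(letters)
        if chain_length < width + 4:
            raise ValueError("chain_length too short for motif")
        for _ in range(n_clusters):
            for _attempt in range(100):
                back = random_sequence(rng, chain_length - width, avoid=all_motifs)
                start = int(rng.integers(2, chain_length - width - 1))
                seq = back[:start] + letters + back[start:]
                # the insertion may create spurious occurrences at the seams
                hits = sum(len(match(m, seq)) for m in all_motifs)
                if hits == 1 and "HHHH" not in seq:
                    break
            else:
                raise RuntimeError("could not place motif without collisions")
            mask = "S" * start + ("U" if disordered else "S") * width
            mask += "S" * (chain_length - len(mask))
            for member in range(chains_per_cluster):
                key_entry = f"p{cluster_idx:03d}"
                rec = ChainRecord(
                    entry_id=key_entry,
                    chain_id=chr(ord("A") + member),
                    sequence=seq,
                    disorder_mask=mask,
                )
                records.append(rec)
                assignment[rec.key] = cluster_idx
                rows.append(
                    {
                        "motif": letters,
                        "cluster": cluster_idx,
                        "chain": rec.key,
                        "start": start,
                    }
                )
            cluster_idx += 1
    forest = ClusterForest(
        levels=(100, 75),
        assignment={100: dict(assignment), 75: dict(assignment)},
    )
    truth = pd.DataFrame(rows, columns=["motif", "cluster", "chain", "start"])
    return records, forest, truth
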