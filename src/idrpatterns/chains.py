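"""Chain records: parsing structures, disorder annotation, chain-table I/O.

A residue of a crystallographic chain is *disordered* (``U``) when it is
declared in the full sequence (SEQRES) but has no resolved coordinates —
either listed under the missing-residue remark or simply absent from the
ATOM records.  Every other declared residue is *structured* (``S``).
Residues with any resolved atom count as structured.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace

import gemmi
import pandas as pd

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "ChainRecord",
    "ParseError",
    "parse_entry",
    "filter_chains",
    "write_chain_table",
    "read_chain_table",
    "write_fasta",
]


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


@dataclass(frozen=True)
class ChainRecord:
    """One protein chain with its per-residue disorder annotation.

    Parameters
    ----------
    entry_id : str
        Four-character structure accession.
    chain_id : str
        Chain label (one or more characters).
    sequence : str
        Uppercase amino-acid sequence over the 20 canonical letters plus
        ``X`` for unknown / unmapped residues.
    disorder_mask : str
        Same length as ``sequence``, over ``{U, S}``: ``U`` means the
        residue has no resolved coordinates, ``S`` means it does.
    method : str
        Experimental method label (e.g. ``"X-RAY DIFFRACTION"``).
    resolution : float or None
        Resolution in angstroms; ``None`` for methods without one.
    """

    entry_id: str
    chain_id: str
    sequence: str
    disorder_mask: str
    method: str = "X-RAY DIFFRACTION"
    resolution: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.key}: empty sequence")
        if len(self.sequence) != len(self.disorder_mask):
            raise ValueError(
                f"{self.key}: sequence length {len(self.sequence)} != "
                f"mask length {len(self.disorder_mask)}"
            )
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.key}: invalid sequence letters {sorted(bad)}")
        if set(self.disorder_mask) - {"U", "S"}:
            raise ValueError(f"{self.key}: mask letters must be U or S")

    @property
    def key(self) -> str:
        """Stable chain identifier, e.g. ``1abc_A``."""
        return f"{self.entry_id}_{self.chain_id}"

    @property
    def n_disordered(self) -> int:
        return self.disorder_mask.count("U")

    @property
    def n_structured(self) -> int:
        return self.disorder_mask.count("S")


def _one_letter(code: str, modres_parent: dict[str, str]) -> str:
    """Map a 3-letter residue code to one canonical letter or X.

    Modified residues are resolved through the entry's MODRES mapping
    first, then through the tabulated chemical-component list.
    """
    code = modres_parent.get(code, code)
    info = gemmi.find_tabulated_residue(code)
    if info is not None and info.is_amino_acid():
        letter = info.one_letter_code.upper()
        if letter in AA_ALPHABET and letter != "X":
            return letter
    return "X"


def parse_entry(structure_text: str) -> list[ChainRecord]:
    """Parse one PDB-format entry into per-chain disorder records.

    One record is returned per protein (L-peptide) chain; nucleic-acid
    and other non-protein chains are skipped.  A chain that has ATOM
    records but no SEQRES declaration is reconstructed from coordinates
    (all residues structured) with a warning.

    Raises
    ------
    ParseError
        If the text is not parseable PDB or contains no protein chain.
    """
    try:
        st = gemmi.read_pdb_string(structure_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"malformed PDB text: {exc}") from exc
    if len(st) == 0:
        raise ParseError("no model found in structure text")

    info = dict(st.info)
    entry_id = (info.get("_entry.id") or st.name or "XXXX").lower()
    method = info.get("_exptl.method") or "UNKNOWN"
    resolution = st.resolution if st.resolution > 0 else None

    modres_parent = {m.res_id.name: m.parent_comp_id for m in st.mod_residues}

    st.setup_entities()
    st.assign_label_seq_id()

    records: list[ChainRecord] = []
    for chain in st[0]:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        ent = st.get_entity_of(polymer)
        full_seq3 = list(ent.full_sequence) if ent is not None else []
        if full_seq3:
            if ent.polymer_type != gemmi.PolymerType.PeptideL:
                continue
            # label_seq aligns resolved residues to the SEQRES index (1-based)
            resolved = {
                res.label_seq
                for res in polymer
                if res.label_seq is not None and len(res) > 0
            }
            seq = []
            mask = []
            for i, code3 in enumerate(full_seq3, start=1):
                # microheterogeneity ("A,B") — keep the first variant
                code3 = code3.split(",")[0]
                seq.append(_one_letter(code3, modres_parent))
                mask.append("S" if i in resolved else "U")
        else:
            ptype = polymer.check_polymer_type()
            if ptype not in (
                gemmi.PolymerType.PeptideL,
                gemmi.PolymerType.PeptideD,
                gemmi.PolymerType.Unknown,
            ):
                continue
            warnings.warn(
                f"{entry_id} chain {chain.name}: no SEQRES record; "
                "sequence reconstructed from coordinates (all structured)",
                stacklevel=2,
            )
            seq = [_one_letter(res.name, modres_parent) for res in polymer]
            mask = ["S"] * len(seq)
            if all(s == "X" for s in seq):
                continue
        if not seq:
            continue
        records.append(
            ChainRecord(
                entry_id=entry_id,
                chain_id=chain.name,
                sequence="".join(seq),
                disorder_mask="".join(mask),
                method=method,
                resolution=resolution,
            )
        )
    # a fully unresolved chain exists only as its SEQRES entity
    seen_chains = {r.chain_id for r in records}
    for ent in st.entities:
        if (
            ent.entity_type != gemmi.EntityType.Polymer
            or not ent.full_sequence
            or ent.subchains
            or ent.name in seen_chains
        ):
            continue
        codes = [c.split(",")[0] for c in ent.full_sequence]
        letters = [_one_letter(c, modres_parent) for c in codes]
        n_aa = sum(
            1
            for c in codes
            if (info := gemmi.find_tabulated_residue(c)) is not None
            and info.is_amino_acid()
        )
        if n_aa < len(codes) / 2:
            continue
        records.append(
            ChainRecord(
                entry_id=entry_id,
                chain_id=ent.name,
                sequence="".join(letters),
                disorder_mask="U" * len(letters),
                method=method,
                resolution=resolution,
            )
        )
    if not records:
        raise ParseError(f"{entry_id}: no protein chain found")
    return records


def filter_chains(
    records: list[ChainRecord],
    max_resolution: float = 3.0,
    min_length: int = 40,
    method: str = "x-ray",
) -> list[ChainRecord]:
    """Apply the database inclusion filters.

    Keeps chains solved by the given method (case-insensitive substring
    match on the method label) at resolution <= ``max_resolution`` with
    at least ``min_length`` residues.  Chains without a stated
    resolution are excluded.
    """
    needle = method.lower()
    return [
        r
        for r in records
        if needle in r.method.lower()
        and r.resolution is not None
        and r.resolution <= max_resolution
        and len(r.sequence) >= min_length
    ]


_COLUMNS = ["entry", "chain", "sequence", "mask", "method", "resolution"]


def write_chain_table(records: list[ChainRecord]) -> str:
    """Serialize records to the chain-table TSV (lossless round-trip)."""
    df = pd.DataFrame(
        [
            {
                "entry": r.entry_id,
                "chain": r.chain_id,
                "sequence": r.sequence,
                "mask": r.disorder_mask,
                "method": r.method,
                "resolution": "" if r.resolution is None else repr(r.resolution),
            }
            for r in records
        ],
        columns=_COLUMNS,
    )
    return df.to_csv(sep="\t", index=False)


def read_chain_table(text: str) -> list[ChainRecord]:
    """Parse a chain-table TSV back into records.

    Raises
    ------
    ValueError
        If a row violates the record invariants; the message names the
        1-based data row.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chain table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                ChainRecord(
                    entry_id=row.entry,
                    chain_id=row.chain,
                    sequence=row.sequence,
                    disorder_mask=row.mask,
                    method=row.method,
                    resolution=float(row.resolution) if row.resolution else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"chain table row {i}: {exc}") from exc
    return records


def write_fasta(records: list[ChainRecord], masks: bool = False) -> str:
    """FASTA export of sequences, or of U/S masks when ``masks`` is true."""
    out = []
    for r in records:
        out.append(f">{r.key}")
        out.append(r.disorder_mask if masks else r.sequence)
    return "\n".join(out) + "\n" if out else ""


def relabel(record: ChainRecord, **fields) -> ChainRecord:
    """Return a copy of ``record`` with the given fields replaced."""
    return replace(record, **fields)
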