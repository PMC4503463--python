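"""Sequence and structure I/O.

FASTA reading/writing is delegated to Biopython (:mod:`Bio.SeqIO`); PDB
coordinate files are parsed with a strict fixed-column reader because the
downstream geometry only consumes ``ATOM`` records of the twenty standard
amino acids (first model, first alternate location) and we want line-numbered
errors for malformed input.

Column dialect (1-based PDB columns): atom name 13-16, altLoc 17, resName
18-20, chain 22, resSeq 23-26, iCode 27, x/y/z 31-54 (%8.3f each).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 3-letter -> 1-letter for the 20 standard residues
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

#: ambiguity / nonstandard one-letter codes a "drop" policy removes
AMBIGUOUS_CODES = frozenset("XBZUO*")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the 20 standard codes."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a group label."""

    id: str
    sequence: str
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise SequenceAlphabetError(
                f"record {self.id!r}: invalid residue code(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Atom:
    name: str
    coords: np.ndarray  # shape (3,), Angstrom
    element: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: Iterable[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """Chains of residues with named atoms, in file order."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    n_nonprotein_residues: int = 0  # HETATM residues excluded by the reader

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


# ---------------------------------------------------------------------------
# FASTA


def normalize_sequence(seq: str, record_id: str, policy: str = "strict") -> str:
    """Uppercase and apply the ambiguity-code policy.

    ``strict`` raises on any non-standard code; ``drop`` removes ambiguity
    codes (X, B, Z, U, O, *) with a logged count and raises only on characters
    that are neither standard nor recognised ambiguity codes.
    """
    seq = "".join(seq.split()).upper()
    extra = set(seq) - set(AMINO_ACIDS)
    if not extra:
        return seq
    if policy == "strict":
        raise SequenceAlphabetError(
            f"record {record_id!r}: invalid residue code(s) {sorted(extra)} "
            "(use policy='drop' to remove ambiguity codes)"
        )
    if policy == "drop":
        unknown = extra - AMBIGUOUS_CODES
        if unknown:
            raise SequenceAlphabetError(
                f"record {record_id!r}: invalid residue code(s) {sorted(unknown)}"
            )
        dropped = sum(1 for c in seq if c in AMBIGUOUS_CODES)
        logger.warning("record %r: dropped %d ambiguity-code residue(s)", record_id, dropped)
        return "".join(c for c in seq if c not in AMBIGUOUS_CODES)
    raise ValueError(f"unknown normalization policy {policy!r}")


def read_fasta(path: str | Path, group: str = "", policy: str = "strict") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), rec.id, policy=policy)
        if not seq:
            raise SequenceAlphabetError(f"record {rec.id!r}: empty after normalization")
        records.append(ProteinRecord(id=rec.id, sequence=seq, group=group))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqrecs, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# PDB


def _parse_atom_line(line: str, lineno: int) -> tuple[str, str, str, str, int, str, np.ndarray, str]:
    name = line[12:16].strip()
    altloc = line[16:17].strip()
    res_name = line[17:20].strip()
    chain_id = line[21:22]
    icode = line[26:27].strip()
    try:
        res_seq = int(line[22:26])
        coords = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed PDB coordinate/resSeq columns") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    return name, altloc, res_name, chain_id, res_seq, icode, coords, element


def read_pdb(path: str | Path) -> Structure:
    """Parse a PDB file: standard-residue ATOM records, model 1, first altLoc.

    HETATM records (waters, ligands) are excluded; the count of distinct
    excluded residues is kept on ``Structure.n_nonprotein_residues``.
    """
    path = Path(path)
    chains: dict[str, Chain] = {}
    chain_order: list[str] = []
    current: Residue | None = None
    hetero_seen: set[tuple[str, int, str, str]] = set()
    in_first_model = True
    model_seen = False
    n_atoms = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                if model_seen:
                    in_first_model = False
                model_seen = True
                continue
            if rec.startswith("ENDMDL"):
                in_first_model = False
                continue
            if not in_first_model:
                continue
            if rec == "HETATM":
                _, _, res_name, chain_id, res_seq, icode, _, _ = _parse_atom_line(line, lineno)
                hetero_seen.add((chain_id, res_seq, icode, res_name))
                continue
            if rec != "ATOM  ":
                continue
            name, altloc, res_name, chain_id, res_seq, icode, coords, element = _parse_atom_line(
                line, lineno
            )
            if altloc not in ("", "A"):
                continue
            if res_name not in STANDARD_RESIDUES:
                hetero_seen.add((chain_id, res_seq, icode, res_name))
                continue
            if chain_id not in chains:
                chains[chain_id] = Chain(id=chain_id)
                chain_order.append(chain_id)
            chain = chains[chain_id]
            key = (res_seq, icode, res_name)
            if (
                current is None
                or current.chain_id != chain_id
                or (current.seq_number, current.insertion_code, current.res_name) != key
            ):
                current = Residue(
                    chain_id=chain_id, seq_number=res_seq, res_name=res_name, insertion_code=icode
                )
                chain.residues.append(current)
            if current.atom(name) is None:  # first altLoc occurrence wins
                current.atoms.append(Atom(name=name, coords=coords, element=element))
                n_atoms += 1

    if n_atoms == 0:
        raise ValueError(f"{path}: no standard-residue ATOM records found")
    return Structure(
        id=path.stem,
        chains=[chains[c] for c in chain_order],
        n_nonprotein_residues=len(hetero_seen),
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column ATOM records; round-trips coordinates to 3 decimals."""
    if structure.n_residues == 0:
        raise ValueError("cannot write an empty structure")
    serial = 1
    lines = []
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.res_name:>3s} {chain.id:1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"  1.00  0.00          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
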