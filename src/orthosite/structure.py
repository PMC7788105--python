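"""Macromolecular structure and sequence I/O.

Coordinates are held in a small chain → residue → atom hierarchy that keeps
*author* residue numbering (the numbering deposited with a crystal
structure, e.g. Tyr56 of PD-L1) — site labels throughout the package refer
to these numbers and no renumbering is ever applied silently.

Parsing is delegated to :mod:`gemmi`; on load hydrogens and waters are
dropped and alternate locations are resolved to a single atom per atom
name (highest occupancy, ties broken by altloc letter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "StructureError",
    "read_structure",
    "write_pdb",
    "count_polymer_chains",
    "extract_sequence",
    "read_fasta",
    "write_fasta",
    "STANDARD_AA3",
]

#: Three-letter → one-letter codes for the 20 standard amino acids.
STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common modified residues mapped to their parent one-letter code.
_MODIFIED_AA3 = {"MSE": "M", "SEC": "U", "PYL": "O", "HYP": "P", "SEP": "S", "TPO": "T", "PTR": "Y"}

_WATER_NAMES = {"HOH", "DOD", "WAT"}


class StructureError(ValueError):
    """Raised for unreadable files, unknown formats and bad selections."""


@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Å."""

    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.xyz):
            raise StructureError(f"non-finite coordinates for atom {self.name!r}: {self.xyz}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.name!r}")


@dataclass
class Residue:
    """A residue identified by (author number, insertion code)."""

    name3: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        """First atom with the given name, or ``None``."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_standard_aa(self) -> bool:
        return self.name3 in STANDARD_AA3

    def one_letter(self) -> str:
        """One-letter code; modified residues map to their parent, unknowns to 'X'."""
        if self.name3 in STANDARD_AA3:
            return STANDARD_AA3[self.name3]
        if self.name3 in _MODIFIED_AA3:
            return _MODIFIED_AA3[self.name3]
        info = gemmi.find_tabulated_residue(self.name3)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
        return "X"


@dataclass
class Chain:
    """An ordered residue collection under one author chain id."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    @property
    def is_polymer(self) -> bool:
        """True if the chain holds ≥1 standard amino acid with a CA atom."""
        return any(r.is_standard_aa and r.atom("CA") is not None for r in self.residues)

    def polymer_residues(self) -> list[Residue]:
        """Amino-acid residues (standard or modified polymer residues), in order."""
        return [r for r in self.residues if not _is_ligand_residue(r)]


def _is_ligand_residue(r: Residue) -> bool:
    """Hetero groups that are not (possibly modified) amino acids."""
    if r.is_standard_aa:
        return False
    if r.name3 in _MODIFIED_AA3:
        return False
    info = gemmi.find_tabulated_residue(r.name3)
    if info is not None and info.is_amino_acid():
        return False
    return True


@dataclass
class Structure:
    """A parsed coordinate entry."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids in structure {self.id!r}: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureError(f"no chain {chain_id!r} in structure {self.id!r} (have {[c.id for c in self.chains]})")

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        best = group[0]
        best.altloc = ""
        kept.append(best)
    return kept


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All heavy ATOM/HETATM records of the first model are loaded; hydrogens
    and waters are dropped and alternate locations resolved (highest
    occupancy wins, ties broken by altloc letter).

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from contents/extension).
    """
    path = Path(path)
    if format not in _FORMATS:
        raise StructureError(f"unknown structure format {format!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")

    detected = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    chains: list[Chain] = []
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATER_NAMES or gres.is_water():
                continue
            atoms: list[Atom] = []
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name,
                        xyz=(gatom.pos.x, gatom.pos.y, gatom.pos.z),
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        altloc=gatom.altloc if gatom.altloc != "\x00" else "",
                        is_hetero=gres.het_flag == "H",
                    )
                )
            if not atoms:
                continue
            seqid = gres.seqid
            residues.append(
                Residue(
                    name3=gres.name,
                    number=seqid.num,
                    icode=seqid.icode.strip(),
                    atoms=_resolve_altlocs(atoms),
                )
            )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if not chains:
        raise StructureError(f"{path}: no non-water heavy atoms found")
    return Structure(id=st.name or path.stem, chains=chains, source_format=detected)


# ---------------------------------------------------------------------------
# writing


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as fixed-column (v3.3) PDB text."""
    path = Path(path)
    lines: list[str] = []
    serial = 1
    for chain in s.chains:
        for res in chain.residues:
            for a in res.atoms:
                record = "HETATM" if a.is_hetero else "ATOM  "
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                x, y, z = a.xyz
                lines.append(
                    f"{record}{serial:5d} {name:<4.4s}{a.altloc or ' ':1s}{res.name3:>3s} "
                    f"{chain.id[:1]:1s}{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2.2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name3:>3s} {chain.id[:1]:1s}"
                     f"{chain.residues[-1].number:4d}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# derived quantities


def count_polymer_chains(s: Structure) -> int:
    """Number of chains holding at least one standard amino acid with a CA atom."""
    return sum(1 for c in s.chains if c.is_polymer)


def extract_sequence(c: Chain) -> str:
    """One-letter sequence of a polymer chain in residue order.

    Non-standard residues that are not recognizable amino-acid variants
    map to ``'X'``.  Ligand/ion hetero groups sitting in the same author
    chain are excluded.
    """
    if not c.is_polymer:
        raise StructureError(f"chain {c.id!r} is not polymeric")
    seq = "".join(r.one_letter() for r in c.polymer_residues())
    if not seq:
        raise StructureError(f"chain {c.id!r} yields an empty sequence")
    return seq


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as standard 60-column FASTA."""
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise StructureError(f"duplicate FASTA ids: {ids}")
    for rid, seq in records:
        if not seq:
            raise StructureError(f"empty sequence for FASTA record {rid!r}")
    seqrecords = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
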