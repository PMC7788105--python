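"""Distance-based extraction of receptor residues contacting a ligand.

An interface site (the structural epitope of an antibody, or the binding
site of a small molecule or peptide) is defined as the set of receptor
residues with at least one heavy atom within a distance cutoff of any
heavy atom of the ligand entity.  The default cutoff is 4.5 Å, the common
heavy-atom contact convention; because published residue lists depend on
the exact criterion, reports can be generated at several cutoffs.

Distances are evaluated with a k-d tree (:class:`scipy.spatial.cKDTree`);
the result is required to equal an all-pairs scan exactly, a property the
test suite enforces on randomized fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from orthosite.structure import Atom, Residue, Structure, StructureError

__all__ = [
    "InterfaceError",
    "LigandSelection",
    "InterfaceSite",
    "interface_residues",
    "shared_site",
    "min_interatomic_distance",
    "select_atoms",
    "write_site_json",
    "read_site_json",
]

#: Crystallization additives never treated as ligands unless explicitly named.
_ADDITIVES = {"GOL", "EDO", "PEG", "PG4", "SO4", "PO4", "ACT", "DMS", "FMT", "MPD",
              "NA", "CL", "K", "MG", "CA", "ZN", "NI", "CD", "BR", "IOD"}


class InterfaceError(ValueError):
    """Raised for empty/overlapping selections and frame mismatches."""


@dataclass(frozen=True)
class LigandSelection:
    """Which atoms constitute the ligand entity.

    ``mode="chain"`` selects whole chains (antibody Fab heavy+light
    chains, or a peptide chain); ``mode="het"`` selects one hetero group
    by 3-letter code, chain and residue number (a small molecule).
    """

    mode: str
    chain_ids: tuple[str, ...] = ()
    het_code: str = ""
    het_chain: str = ""
    het_number: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("chain", "het"):
            raise InterfaceError(f"unknown ligand selection mode {self.mode!r}")
        if self.mode == "chain" and not self.chain_ids:
            raise InterfaceError("chain-mode ligand selection needs at least one chain id")
        if self.mode == "het" and not self.het_code:
            raise InterfaceError("het-mode ligand selection needs a 3-letter code")

    @classmethod
    def chains(cls, *chain_ids: str) -> "LigandSelection":
        return cls(mode="chain", chain_ids=tuple(chain_ids))

    @classmethod
    def het(cls, code: str, chain: str = "", number: int | None = None) -> "LigandSelection":
        return cls(mode="het", het_code=code.upper(), het_chain=chain, het_number=number)

    def resolve(self, s: Structure, receptor_chain: str) -> list[Atom]:
        """Ligand heavy atoms, validated against the receptor chain."""
        atoms: list[Atom] = []
        if self.mode == "chain":
            if receptor_chain in self.chain_ids:
                raise InterfaceError(
                    f"ligand chains {self.chain_ids} overlap receptor chain {receptor_chain!r}"
                )
            for cid in self.chain_ids:
                chain = s.chain(cid)
                for res in chain.residues:
                    if res.name3 in _ADDITIVES:
                        continue
                    atoms.extend(res.atoms)
        else:
            for chain in s.chains:
                if self.het_chain and chain.id != self.het_chain:
                    continue
                for res in chain.residues:
                    if res.name3 != self.het_code:
                        continue
                    if self.het_number is not None and res.number != self.het_number:
                        continue
                    atoms.extend(res.atoms)
        if not atoms:
            raise InterfaceError(f"ligand selection {self} matches no atoms in {s.id}")
        return atoms


@dataclass(frozen=True)
class InterfaceSite:
    """Receptor residues in heavy-atom contact with a ligand entity."""

    receptor_chain: str
    cutoff: float
    residues: tuple[tuple[int, str, str], ...]  # (number, icode, name3), sorted
    per_residue_min_dist: dict[tuple[int, str], float] = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        for num, icode, _ in self.residues:
            d = self.per_residue_min_dist.get((num, icode))
            if d is not None and d > self.cutoff + 1e-9:
                raise InterfaceError(f"residue {num}{icode} min distance {d:.2f} exceeds cutoff {self.cutoff}")

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(num for num, _, _ in self.residues)

    def keys(self) -> set[tuple[int, str]]:
        return {(num, icode) for num, icode, _ in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, number: int) -> bool:
        return number in self.numbers


def _receptor_residues(s: Structure, receptor_chain: str) -> list[Residue]:
    chain = s.chain(receptor_chain)
    if not chain.is_polymer:
        raise InterfaceError(f"receptor chain {receptor_chain!r} is not polymeric")
    return chain.polymer_residues()


def interface_residues(
    s: Structure,
    receptor_chain: str,
    ligand: LigandSelection,
    cutoff: float = 4.5,
) -> InterfaceSite:
    """Receptor residues with any heavy atom within ``cutoff`` Å of the ligand.

    A residue is included iff the minimum heavy-atom distance between any
    of its atoms and any ligand atom is ≤ cutoff.  Evaluated with a k-d
    tree over the ligand atoms; identical to an all-pairs scan.
    """
    if cutoff <= 0:
        raise InterfaceError(f"cutoff must be positive, got {cutoff}")
    residues = _receptor_residues(s, receptor_chain)
    lig_atoms = ligand.resolve(s, receptor_chain)
    lig_ids = {id(a) for a in lig_atoms}
    tree = cKDTree(np.array([a.xyz for a in lig_atoms], dtype=float))

    picked: list[tuple[int, str, str]] = []
    min_dists: dict[tuple[int, str], float] = {}
    for res in residues:
        coords = np.array([a.xyz for a in res.atoms if id(a) not in lig_ids], dtype=float)
        if coords.size == 0:
            continue
        d, _ = tree.query(coords, k=1)
        dmin = float(np.min(d))
        if dmin <= cutoff:
            picked.append((res.number, res.icode, res.name3))
            min_dists[(res.number, res.icode)] = dmin
    picked.sort(key=lambda r: (r[0], r[1]))
    return InterfaceSite(
        receptor_chain=receptor_chain,
        cutoff=cutoff,
        residues=tuple(picked),
        per_residue_min_dist=min_dists,
    )


def shared_site(a: InterfaceSite, b: InterfaceSite) -> InterfaceSite:
    """Set intersection of two sites on the same receptor chain.

    The per-residue minimum distance of the intersection is the max of
    the two parents' (the distance at which the residue is guaranteed to
    be in contact in both complexes).
    """
    if a.receptor_chain != b.receptor_chain:
        raise InterfaceError(
            f"sites on different receptor chains: {a.receptor_chain!r} vs {b.receptor_chain!r}"
        )
    keys_b = b.keys()
    residues = tuple(r for r in a.residues if (r[0], r[1]) in keys_b)
    min_dists = {
        (num, icode): max(a.per_residue_min_dist.get((num, icode), 0.0),
                          b.per_residue_min_dist.get((num, icode), 0.0))
        for num, icode, _ in residues
    }
    return InterfaceSite(
        receptor_chain=a.receptor_chain,
        cutoff=max(a.cutoff, b.cutoff),
        residues=residues,
        per_residue_min_dist=min_dists,
    )


def select_atoms(
    s: Structure,
    chain: str | None = None,
    number: int | None = None,
    icode: str = "",
    atom: str | None = None,
    element: str | None = None,
) -> list[Atom]:
    """Flat atom selection by chain / residue number / atom name / element."""
    out: list[Atom] = []
    for ch in s.chains:
        if chain is not None and ch.id != chain:
            continue
        for res in ch.residues:
            if number is not None and (res.number != number or res.icode != icode):
                continue
            for a in res.atoms:
                if atom is not None and a.name != atom:
                    continue
                if element is not None and a.element.upper() != element.upper():
                    continue
                out.append(a)
    return out


def min_interatomic_distance(
    sel_a: list[Atom],
    sel_b: list[Atom],
    element_pair: tuple[str, str] | None = None,
) -> tuple[float, tuple[str, str]]:
    """Minimum heavy-atom distance between two selections.

    Returns ``(distance, (atom_name_a, atom_name_b))`` for the closest
    pair.  With ``element_pair`` (e.g. ``("C", "C")``) only that element
    combination is considered.  When the selections share atoms (self
    comparison), identical-atom pairs are excluded.
    """
    if element_pair is not None:
        ea, eb = (e.upper() for e in element_pair)
        sel_a = [a for a in sel_a if a.element.upper() == ea]
        sel_b = [b for b in sel_b if b.element.upper() == eb]
    if not sel_a or not sel_b:
        raise InterfaceError("empty atom selection")
    xa = np.array([a.xyz for a in sel_a], dtype=float)
    xb = np.array([b.xyz for b in sel_b], dtype=float)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    for i, a in enumerate(sel_a):  # mask self-pairs
        for j, b in enumerate(sel_b):
            if a is b:
                d[i, j] = np.inf
    if not np.isfinite(d).any():
        raise InterfaceError("no distinct atom pairs in selections")
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (sel_a[i].name, sel_b[j].name)


# ---------------------------------------------------------------------------
# serialization


def write_site_json(site: InterfaceSite, path: str | Path) -> None:
    """Write an interface site as JSON (numbers, codes, min distances)."""
    payload = {
        "receptor_chain": site.receptor_chain,
        "cutoff": site.cutoff,
        "residues": [
            {
                "number": num,
                "icode": icode,
                "name3": name3,
                "min_dist": site.per_residue_min_dist.get((num, icode)),
            }
            for num, icode, name3 in site.residues
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_site_json(path: str | Path) -> InterfaceSite:
    payload = json.loads(Path(path).read_text())
    residues = tuple(
        (int(r["number"]), r.get("icode", ""), r["name3"]) for r in payload["residues"]
    )
    min_dists = {
        (int(r["number"]), r.get("icode", "")): float(r["min_dist"])
        for r in payload["residues"]
        if r.get("min_dist") is not None
    }
    return InterfaceSite(
        receptor_chain=payload["receptor_chain"],
        cutoff=float(payload["cutoff"]),
        residues=residues,
        per_residue_min_dist=min_dists,
    )
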