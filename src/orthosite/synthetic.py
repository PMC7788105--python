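"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments (equal arguments give
bit-identical output) and returns a *truth record* carrying the planted
ground truth, so each pipeline stage can be asserted against bookkeeping
rather than external reference data:

* :func:`make_toy_domain` — an ideal-geometry peptide backbone,
* :func:`perturb_copy` — a rigid-body-transformed, optionally noisy copy
  (superposition fixtures),
* :func:`plant_ligand` — a pseudo-ligand placed at an exact distance from
  a chosen epitope (co-crystal / interface-extraction fixtures),
* :func:`make_ortholog` — a mutated sequence at a target percent identity
  (ortholog-alignment fixtures),
* :func:`simulate_titration` — a 1:1 binding dilution series with
  Gaussian noise (K_D-fitting fixtures).

Geometries are topological stand-ins, not force-field realistic; the
pseudo-ligand is written as HETATM records (code ``LIG``) so fixtures can
round-trip through the real file readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from orthosite.binding import TitrationDataset, bound_fraction
from orthosite.structure import STANDARD_AA3, Atom, Chain, Residue, Structure

__all__ = [
    "GenerationError",
    "SyntheticComplexTruth",
    "SyntheticOrthologTruth",
    "make_toy_domain",
    "perturb_copy",
    "plant_ligand",
    "make_ortholog",
    "simulate_titration",
    "random_rotation",
]

_AA1_TO_3 = {v: k for k, v in STANDARD_AA3.items()}
_AA20 = "".join(sorted(STANDARD_AA3.values()))


class GenerationError(RuntimeError):
    """Raised when a generator cannot satisfy its geometric guarantees."""


@dataclass(frozen=True)
class SyntheticComplexTruth:
    """A receptor + pseudo-ligand complex with planted-contact bookkeeping."""

    structure: Structure
    planted_epitope: tuple[int, ...]
    planted_distance: float
    transform: tuple[np.ndarray, np.ndarray] | None
    seed: int


@dataclass(frozen=True)
class SyntheticOrthologTruth:
    """A parent/ortholog sequence pair with mutation bookkeeping."""

    seq_parent: str
    seq_ortholog: str
    mutated_positions: tuple[int, ...]  # 0-based positions in the parent
    realized_identity: float  # percent
    seed: int

    def __post_init__(self) -> None:
        n = len(self.seq_parent)
        expected = 100.0 * (n - len(self.mutated_positions)) / n
        if abs(expected - self.realized_identity) > 1e-9:
            raise GenerationError("mutation bookkeeping inconsistent with realized identity")


# ---------------------------------------------------------------------------
# structures


def make_toy_domain(
    sequence: str,
    geometry: str = "helix",
    seed: int = 0,
    chain_id: str = "A",
    first_number: int = 1,
) -> Structure:
    """Ideal-geometry peptide with N, CA, C, O and CB (except Gly) atoms.

    ``helix``: 1.5 Å rise and 100° twist per residue around the z axis
    (Cα–Cα ≈ 3.8 Å); ``strand``: 3.3 Å rise with alternating ±y pleat.
    Deterministic for equal arguments; ``seed`` is carried for symmetry
    with the other generators but introduces no randomness here.
    """
    sequence = sequence.upper()
    if len(sequence) < 5:
        raise GenerationError(f"sequence too short ({len(sequence)}); need at least 5 residues")
    bad = set(sequence) - set(_AA20)
    if bad:
        raise GenerationError(f"non-standard letters in sequence: {sorted(bad)}")
    if geometry not in ("helix", "strand"):
        raise GenerationError(f"unknown geometry {geometry!r}; expected 'helix' or 'strand'")

    residues: list[Residue] = []
    for i, aa in enumerate(sequence):
        if geometry == "helix":
            theta = np.deg2rad(100.0 * i)
            ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
            out = np.array([np.cos(theta), np.sin(theta), 0.0])  # radially outward
        else:
            ca = np.array([3.3 * i, 1.0 * (-1) ** i, 0.0])
            out = np.array([0.0, (-1) ** i, 0.0])
        axis = np.array([0.0, 0.0, 1.0])
        side = np.cross(out, axis)
        atoms = [
            Atom(name="N", element="N", xyz=tuple(ca - 0.8 * side - 0.9 * out * 0.3)),
            Atom(name="CA", element="C", xyz=tuple(ca)),
            Atom(name="C", element="C", xyz=tuple(ca + 0.8 * side - 0.9 * out * 0.3)),
            Atom(name="O", element="O", xyz=tuple(ca + 1.2 * side + 0.7 * axis * 0.5)),
        ]
        if aa != "G":
            atoms.insert(2, Atom(name="CB", element="C", xyz=tuple(ca + 1.53 * out)))
        residues.append(
            Residue(name3=_AA1_TO_3[aa], number=first_number + i, atoms=atoms)
        )
    return Structure(id=f"toy-{geometry}-{seed}", chains=[Chain(id=chain_id, residues=residues)])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def perturb_copy(
    s: Structure,
    rotation_seed: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, tuple[np.ndarray, np.ndarray]]:
    """A rigid-body-transformed, optionally noisy copy of a structure.

    A random proper rotation R and translation t (drawn from
    ``rotation_seed``) are applied to every atom, then isotropic Gaussian
    coordinate noise of standard deviation ``noise_sd`` Å (drawn from
    ``seed``) is added.  Returns the copy and the applied ``(R, t)``.
    """
    if noise_sd < 0:
        raise GenerationError("noise_sd must be non-negative")
    rot_rng = np.random.default_rng(rotation_seed)
    R = random_rotation(rot_rng)
    t = rot_rng.uniform(-20.0, 20.0, size=3)
    noise_rng = np.random.default_rng(seed)

    chains = []
    for chain in s.chains:
        residues = []
        for res in chain.residues:
            atoms = []
            for a in res.atoms:
                xyz = R @ np.array(a.xyz) + t
                if noise_sd > 0:
                    xyz = xyz + noise_rng.normal(0.0, noise_sd, size=3)
                atoms.append(
                    Atom(name=a.name, element=a.element, xyz=tuple(xyz),
                         occupancy=a.occupancy, altloc=a.altloc, is_hetero=a.is_hetero)
                )
            residues.append(Residue(name3=res.name3, number=res.number, icode=res.icode, atoms=atoms))
        chains.append(Chain(id=chain.id, residues=residues))
    return Structure(id=f"{s.id}-copy", chains=chains, source_format=s.source_format), (R, t)


def plant_ligand(
    s: Structure,
    epitope: tuple[int, ...] | list[int],
    distance: float = 3.5,
    seed: int = 0,
    clearance: float = 2.0,
    max_retries: int = 20,
) -> SyntheticComplexTruth:
    """Plant one pseudo-ligand atom per epitope residue at an exact distance.

    Each ligand atom sits exactly ``distance`` Å from the outermost heavy
    atom of its epitope residue (CB, or CA for glycine), along the
    outward normal pointing away from the local backbone (the centroid
    of the five nearest CA positions); placements are retried with
    seeded angular jitter
    until every non-epitope residue is farther than
    ``distance + clearance`` from every ligand atom and no ligand atom
    undercuts ``distance`` at a foreign epitope residue.

    The ligand is appended as chain ``L``, HETATM residue ``LIG 1``.
    """
    epitope = tuple(sorted(set(int(n) for n in epitope)))
    if not epitope:
        raise GenerationError("epitope must name at least one residue")
    receptor = s.chains[0]
    by_number = {r.number: r for r in receptor.residues}
    missing = [n for n in epitope if n not in by_number]
    if missing:
        raise GenerationError(f"epitope residues not in receptor: {missing}")

    rng = np.random.default_rng(seed)
    res_coords = {r.number: np.array([a.xyz for a in r.atoms], dtype=float) for r in receptor.residues}

    ordered = receptor.residues
    ca_xyz = {
        r.number: np.array(r.atom("CA").xyz)
        for r in ordered
        if r.atom("CA") is not None
    }

    def _anchor_and_normal(resnum: int) -> tuple[np.ndarray, np.ndarray]:
        res = by_number[resnum]
        atom = res.atom("CB") or res.atom("CA") or res.atoms[0]
        anchor = np.array(atom.xyz)
        # local backbone centroid: this residue's CA window (±2 in chain order)
        idx = next(i for i, r in enumerate(ordered) if r.number == resnum)
        window = [
            ca_xyz[ordered[j].number]
            for j in range(max(0, idx - 2), min(len(ordered), idx + 3))
            if ordered[j].number in ca_xyz
        ]
        origin = np.mean(window, axis=0) if window else res_coords[resnum].mean(axis=0)
        normal = anchor - origin
        norm = np.linalg.norm(normal)
        if norm < 1e-9:
            normal, norm = np.array([1.0, 0.0, 0.0]), 1.0
        return anchor, normal / norm

    for attempt in range(max_retries):
        lig_xyz = []
        for n in epitope:
            anchor, direction = _anchor_and_normal(n)
            if attempt > 0:
                jitter = rng.normal(0.0, 0.05 * attempt, size=3)
                direction = direction + jitter
                direction = direction / np.linalg.norm(direction)
            lig_xyz.append(anchor + distance * direction)
        lig = np.array(lig_xyz, dtype=float)

        ok = True
        for r in receptor.residues:
            d = np.linalg.norm(res_coords[r.number][:, None, :] - lig[None, :, :], axis=2)
            dmin = float(d.min())
            if r.number in epitope:
                if dmin < distance - 1e-6:
                    ok = False
                    break
            elif dmin <= distance + clearance:
                ok = False
                break
        if ok:
            atoms = [
                Atom(name=f"C{i + 1}", element="C", xyz=tuple(x), is_hetero=True)
                for i, x in enumerate(lig)
            ]
            complex_chains = list(s.chains) + [
                Chain(id="L", residues=[Residue(name3="LIG", number=1, atoms=atoms)])
            ]
            structure = Structure(id=f"{s.id}-complex", chains=complex_chains)
            return SyntheticComplexTruth(
                structure=structure,
                planted_epitope=epitope,
                planted_distance=distance,
                transform=None,
                seed=seed,
            )
    raise GenerationError(
        f"could not satisfy clearance {clearance} Å for epitope {epitope} "
        f"after {max_retries} retries"
    )


# ---------------------------------------------------------------------------
# sequences


def make_ortholog(
    seq: str,
    target_identity: float,
    matrix: str = "BLOSUM62",
    seed: int = 0,
    minor_fraction: float = 0.5,
) -> SyntheticOrthologTruth:
    """Mutate a sequence to a target percent identity (no indels).

    ``round(L * (1 - identity/100))`` positions are sampled without
    replacement and substituted; a ``minor_fraction`` share of them get a
    conservative (matrix-score > 0) replacement, the rest a
    non-conservative one.  Realized identity is within one residue of the
    target.
    """
    from orthosite.alignment import load_matrix  # local import to avoid cycle at import time

    seq = seq.upper()
    if not 0 < target_identity <= 100:
        raise GenerationError(f"target identity must be in (0, 100], got {target_identity}")
    n = len(seq)
    n_mut = int(round(n * (1.0 - target_identity / 100.0)))
    rng = np.random.default_rng(seed)
    positions = tuple(sorted(rng.choice(n, size=n_mut, replace=False).tolist())) if n_mut else ()

    mat = load_matrix(matrix)
    out = list(seq)
    for pos in positions:
        aa = seq[pos]
        minors = [b for b in _AA20 if b != aa and mat[aa, b] > 0]
        majors = [b for b in _AA20 if b != aa and mat[aa, b] <= 0]
        want_minor = rng.random() < minor_fraction
        pool = minors if (want_minor and minors) else (majors or minors)
        out[pos] = pool[int(rng.integers(len(pool)))]
    realized = 100.0 * (n - n_mut) / n
    return SyntheticOrthologTruth(
        seq_parent=seq,
        seq_ortholog="".join(out),
        mutated_positions=positions,
        realized_identity=realized,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# titrations


def simulate_titration(
    kd: float,
    target_conc: float,
    n_points: int = 16,
    dilution_factor: float = 2.0,
    top_conc: float = 1e-4,
    response_free: float = 850.0,
    response_bound: float = 900.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_series: int = 1,
) -> TitrationDataset:
    """A serial-dilution 1:1 binding series with Gaussian response noise.

    Defaults mimic a thermophoresis experiment: 16-point two-fold
    dilution from 100 µM, labeled target in the nM range, response on an
    Fnorm-like scale (‰).  ``n_series`` > 1 pools that many independent
    noisy replicates of the same dilution series.
    """
    if n_points < 6:
        raise GenerationError(f"need at least 6 points, got {n_points}")
    if kd <= 0 or target_conc <= 0 or top_conc <= 0 or dilution_factor <= 1:
        raise GenerationError("kd, concentrations must be positive; dilution_factor > 1")
    rng = np.random.default_rng(seed)
    lig_single = top_conc / dilution_factor ** np.arange(n_points)
    lig = np.tile(lig_single, n_series)
    series = np.repeat(np.arange(n_series), n_points)
    f = bound_fraction(kd, target_conc, lig)
    resp = response_free + (response_bound - response_free) * f
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return TitrationDataset(
        target_conc=target_conc,
        ligand_conc=lig,
        response=resp,
        replicate_id=series if n_series > 1 else None,
    )
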