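"""Rigid-body least-squares superposition of alignment-paired Cα atoms.

The fit is the classical Kabsch solution: given paired coordinate sets A
(reference) and B (mobile), find the proper rotation R and translation t
minimizing ``RMSD = sqrt(mean |A_i - (R B_i + t)|²)``.  R is obtained from
the SVD of the cross-covariance of the centered sets; a reflection in the
least-squares optimum is corrected by flipping the smallest singular
direction, so det(R) = +1 always (protein chains are chiral).

Multi-copy crystals are handled by fitting the reference chain against
every polymer chain of the other entry and reporting per-chain RMSDs plus
the best match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from orthosite.alignment import PairwiseAlignment, global_align
from orthosite.structure import Chain, Structure, StructureError, extract_sequence

__all__ = [
    "SuperpositionError",
    "Superposition",
    "paired_calpha",
    "kabsch_fit",
    "transform_coords",
    "atom_displacement",
    "superpose_chains",
    "superpose_all_chains",
]


class SuperpositionError(ValueError):
    """Raised for degenerate geometry or unusable pairings."""


@dataclass(frozen=True)
class Superposition:
    """A fitted rigid-body transform mapping set B onto set A."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over the fitted pairs
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise SuperpositionError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise SuperpositionError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise SuperpositionError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise SuperpositionError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the transform to an (n, 3) coordinate array."""
        return transform_coords(self, coords)


def transform_coords(sup: Superposition, coords: np.ndarray) -> np.ndarray:
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return coords @ sup.rotation.T + sup.translation


def paired_calpha(
    struct_a: Structure,
    chain_a: str,
    struct_b: Structure,
    chain_b: str,
    aln: PairwiseAlignment,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Cα coordinate pairs for the non-gap columns of an alignment.

    The alignment must have been built from the chains' extracted
    sequences (sequence a from ``chain_a``, sequence b from ``chain_b``);
    columns where either residue lacks a CA atom are skipped.

    Returns ``(coords_a, coords_b, residue_number_pairs)``.
    """
    ca_res = struct_a.chain(chain_a).polymer_residues()
    cb_res = struct_b.chain(chain_b).polymer_residues()
    if len(ca_res) != len(aln.seq_a) or len(cb_res) != len(aln.seq_b):
        raise SuperpositionError(
            "alignment does not match chain lengths "
            f"({len(ca_res)} vs {len(aln.seq_a)} and {len(cb_res)} vs {len(aln.seq_b)})"
        )
    xa, xb, pairs = [], [], []
    for pa, pb in aln.column_map:
        if pa is None or pb is None:
            continue
        atom_a = ca_res[pa].atom("CA")
        atom_b = cb_res[pb].atom("CA")
        if atom_a is None or atom_b is None:
            continue
        xa.append(atom_a.xyz)
        xb.append(atom_b.xyz)
        pairs.append((ca_res[pa].number, cb_res[pb].number))
    if len(xa) < 3:
        raise SuperpositionError(f"only {len(xa)} Cα pairs; need at least 3")
    return np.array(xa, dtype=float), np.array(xb, dtype=float), pairs


def kabsch_fit(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares proper rotation + translation fitting B onto A.

    Raises :class:`SuperpositionError` for fewer than 3 pairs or
    degenerate (collinear) geometry, where the rotation about the
    common axis is undetermined.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError(f"coordinate shapes differ or are not (n, 3): {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired atoms, got {n}")

    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    A0 = A - cen_a
    B0 = B - cen_b
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) coordinates; rotation undetermined")

    H = B0.T @ A0  # cross-covariance, mobile -> reference
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cen_a - R @ cen_b
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def trimmed_kabsch_fit(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    n_sigma: float = 2.0,
    max_iter: int = 10,
) -> tuple[Superposition, np.ndarray]:
    """Iterative outlier-trimmed fit (off by default in all pipelines).

    Refits after dropping pairs whose residual exceeds ``n_sigma`` times
    the residual RMS, until stable or ``max_iter``.  Returns the final
    fit and the boolean mask of retained pairs.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    keep = np.ones(len(A), dtype=bool)
    sup = kabsch_fit(A, B)
    for _ in range(max_iter):
        resid = np.linalg.norm(A - sup.apply(B), axis=1)
        thresh = n_sigma * np.sqrt((resid[keep] ** 2).mean())
        new_keep = resid <= thresh
        if new_keep.sum() < 3 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
        sup = kabsch_fit(A[keep], B[keep])
    return sup, keep


def atom_displacement(
    sup: Superposition,
    struct_a: Structure,
    atom_sel_a: tuple[str, int, str],
    struct_b: Structure,
    atom_sel_b: tuple[str, int, str],
) -> float:
    """Distance in Å between an atom of A and a transformed atom of B.

    Selections are ``(chain_id, residue_number, atom_name)``.  Used to
    measure the post-superposition displacement of corresponding
    side-chain atoms (e.g. a tyrosine hydroxyl) between orthologs.
    """

    def _get(st: Structure, sel: tuple[str, int, str]):
        chain_id, resnum, atom_name = sel
        res = st.chain(chain_id).residue(resnum)
        if res is None:
            raise StructureError(f"residue {resnum} not in chain {chain_id} of {st.id}")
        atom = res.atom(atom_name)
        if atom is None:
            raise StructureError(f"atom {atom_name!r} not in {res.name3}{resnum} of {st.id}:{chain_id}")
        return np.array(atom.xyz, dtype=float)

    xa = _get(struct_a, atom_sel_a)
    xb = transform_coords(sup, _get(struct_b, atom_sel_b))[0]
    return float(np.linalg.norm(xa - xb))


def superpose_chains(
    struct_a: Structure,
    chain_a: str,
    struct_b: Structure,
    chain_b: str,
    aln: PairwiseAlignment | None = None,
    **align_kwargs,
) -> Superposition:
    """Align (if needed) and superpose one chain pair on matched Cα atoms."""
    if aln is None:
        aln = global_align(
            extract_sequence(struct_a.chain(chain_a)),
            extract_sequence(struct_b.chain(chain_b)),
            **align_kwargs,
        )
    xa, xb, _ = paired_calpha(struct_a, chain_a, struct_b, chain_b, aln)
    return kabsch_fit(xa, xb)


def superpose_all_chains(
    struct_a: Structure,
    chain_a: str,
    struct_b: Structure,
    **align_kwargs,
) -> dict[str, Superposition]:
    """Fit a reference chain against every polymer chain of another entry.

    Returns per-chain fits keyed by chain id; the minimum-RMSD entry is
    the best structural match among the crystal copies.
    """
    fits: dict[str, Superposition] = {}
    for chain in struct_b.chains:
        if not chain.is_polymer:
            continue
        try:
            fits[chain.id] = superpose_chains(struct_a, chain_a, struct_b, chain.id, **align_kwargs)
        except SuperpositionError:
            continue
    if not fits:
        raise SuperpositionError(f"no polymer chain of {struct_b.id} could be fitted")
    return fits
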