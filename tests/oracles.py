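"""Independent oracle implementations used only by the test suite.

Each oracle solves the same problem as a package operation by a different
route (exhaustive enumeration, closed form, or generic root finding) and
is deliberately slow and simple.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


# ---------------------------------------------------------------------------
# global alignment by exhaustive enumeration


def enumerate_alignment_score(
    seq_a: str,
    seq_b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
    free_end_gaps: bool = True,
) -> float:
    """Optimal global alignment score by enumerating every alignment.

    An alignment is a string of ops: 'M' (column with both residues),
    'A' (gap in a), 'B' (gap in b).  A gap run of length L costs
    ``gap_open + gap_extend * (L - 1)``, except runs touching either end
    when ``free_end_gaps`` is set, which cost nothing.
    """

    def score_ops(ops: list[str]) -> float:
        total = 0.0
        ia = ib = 0
        i = 0
        n = len(ops)
        while i < n:
            op = ops[i]
            if op == "M":
                total += score_fn(seq_a[ia], seq_b[ib])
                ia += 1
                ib += 1
                i += 1
            else:
                j = i
                while j < n and ops[j] == op:
                    if op == "A":
                        ib += 1
                    else:
                        ia += 1
                    j += 1
                length = j - i
                at_end = i == 0 or j == n
                if not (free_end_gaps and at_end):
                    total -= gap_open + gap_extend * (length - 1)
                i = j
        return total

    best = -np.inf
    stack: list[tuple[int, int, list[str]]] = [(0, 0, [])]
    while stack:
        ia, ib, ops = stack.pop()
        if ia == len(seq_a) and ib == len(seq_b):
            best = max(best, score_ops(ops))
            continue
        if ia < len(seq_a) and ib < len(seq_b):
            stack.append((ia + 1, ib + 1, ops + ["M"]))
        if ib < len(seq_b):
            stack.append((ia, ib + 1, ops + ["A"]))
        if ia < len(seq_a):
            stack.append((ia + 1, ib, ops + ["B"]))
    return float(best)


# ---------------------------------------------------------------------------
# rigid superposition by Horn's quaternion method


def quaternion_fit(coords_a: np.ndarray, coords_b: np.ndarray):
    """Closed-form least-squares fit of B onto A via the quaternion eigenproblem.

    Returns ``(R, t, rmsd)``.  Independent of the SVD route: builds the
    4x4 symmetric key matrix from the cross-covariance and converts its
    leading eigenvector to a rotation matrix.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    cen_a = A.mean(axis=0)
    cen_b = B.mean(axis=0)
    A0 = A - cen_a
    B0 = B - cen_b
    S = B0.T @ A0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]
    q0, q1, q2, q3 = q
    R = np.array(
        [
            [q0**2 + q1**2 - q2**2 - q3**2, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0**2 - q1**2 + q2**2 - q3**2, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0**2 - q1**2 - q2**2 + q3**2],
        ]
    )
    t = cen_a - R @ cen_b
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / len(A)))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# interface extraction by all-pairs scan


def brute_force_interface(structure, receptor_chain: str, ligand_atoms, cutoff: float):
    """Receptor residue numbers within cutoff of any ligand atom, O(N*M)."""
    lig = np.array([a.xyz for a in ligand_atoms], dtype=float)
    hits = set()
    chain = structure.chain(receptor_chain)
    for res in chain.polymer_residues():
        coords = np.array([a.xyz for a in res.atoms], dtype=float)
        d = np.linalg.norm(coords[:, None, :] - lig[None, :, :], axis=2)
        if d.min() <= cutoff:
            hits.add((res.number, res.icode))
    return hits


# ---------------------------------------------------------------------------
# 1:1 binding equilibrium by root finding


def mass_action_bound_fraction(kd: float, target_total: float, ligand_total: float) -> float:
    """Bound fraction from the mass-action equilibrium solved numerically.

    Finds free ligand Lf such that complex C = T*Lf/(Kd+Lf) satisfies
    Lf + C = L_total, then returns C / T.
    """

    def residual(lf: float) -> float:
        c = target_total * lf / (kd + lf)
        return lf + c - ligand_total

    lf = brentq(residual, 0.0, ligand_total, xtol=1e-30, rtol=1e-15)
    c = target_total * lf / (kd + lf)
    return c / target_total
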