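"""Global pairwise alignment of ortholog domains.

Alignment is global with affine gap costs (a gap of length L costs
``gap_open + gap_extend * (L - 1)``) and, by default, free end gaps — the
convention of EMBOSS ``needle``, the standard tool for ortholog-domain
pairs.  The optimal alignment is computed by Biopython's
:class:`Bio.Align.PairwiseAligner`; the first alignment it reports is used,
which makes outputs deterministic for fixed inputs and parameters.

Substitutions between the two orthologs are binned into three classes,
the scheme used when coloring ortholog alignments:

* ``conserved``   — identical residues,
* ``minor``       — different residues with a positive substitution-matrix
  score (a conservative replacement),
* ``significant`` — non-positive score, or a gap.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentError",
    "SubstitutionClass",
    "PairwiseAlignment",
    "AlignmentStats",
    "global_align",
    "alignment_stats",
    "classify_substitution",
    "map_position",
    "matrix_score",
    "write_aligned_fasta",
    "alignment_table",
    "GAP",
]

#: Marker returned by :func:`map_position` for a gapped counterpart.
GAP = None


class AlignmentError(ValueError):
    """Raised for empty sequences, unknown matrices and range errors."""


class SubstitutionClass(enum.Enum):
    """Three-class conservation label for one alignment column."""

    CONSERVED = "conserved"
    MINOR = "minor"
    SIGNIFICANT = "significant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two sequences.

    ``column_map`` holds, per alignment column, the 0-based residue index
    in each sequence or ``None`` where that sequence has a gap.
    """

    gapped_a: str
    gapped_b: str
    score: float
    matrix: str
    column_map: tuple[tuple[int | None, int | None], ...]

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise AlignmentError("gapped sequences differ in length")
        if any(ca == "-" and cb == "-" for ca, cb in zip(self.gapped_a, self.gapped_b)):
            raise AlignmentError("gap-gap column in alignment")

    @property
    def seq_a(self) -> str:
        return self.gapped_a.replace("-", "")

    @property
    def seq_b(self) -> str:
        return self.gapped_b.replace("-", "")

    @property
    def n_columns(self) -> int:
        return len(self.gapped_a)


@dataclass(frozen=True)
class AlignmentStats:
    """Identity/similarity percentages over all alignment columns."""

    pct_identity: float
    pct_similarity: float
    n_columns: int
    n_gaps: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= self.pct_similarity <= 100.0:
            raise AlignmentError(
                f"inconsistent stats: identity {self.pct_identity}, similarity {self.pct_similarity}"
            )


_AA = "ACDEFGHIKLMNPQRSTVWYBZX*"


@functools.lru_cache(maxsize=8)
def load_matrix(name: str) -> substitution_matrices.Array:
    """Load a named substitution matrix with 'X' rescored to 0 vs everything."""
    try:
        mat = substitution_matrices.load(name.upper())
    except FileNotFoundError as exc:
        raise AlignmentError(f"unknown substitution matrix {name!r}") from exc
    mat = mat.copy()
    if "X" in mat.alphabet:
        for aa in mat.alphabet:
            mat["X", aa] = 0.0
            mat[aa, "X"] = 0.0
    return mat


def matrix_score(aa_a: str, aa_b: str, matrix: str = "BLOSUM62") -> float:
    """Substitution score of two one-letter residues under a named matrix."""
    mat = load_matrix(matrix)
    try:
        return float(mat[aa_a.upper(), aa_b.upper()])
    except (KeyError, IndexError) as exc:
        raise AlignmentError(f"residue pair ({aa_a!r}, {aa_b!r}) not in matrix") from exc


def _validate_seq(seq: str, label: str) -> str:
    if not seq:
        raise AlignmentError(f"sequence {label} is empty")
    seq = seq.upper()
    bad = set(seq) - set(_AA)
    if bad:
        raise AlignmentError(f"sequence {label} has non-amino-acid letters: {sorted(bad)}")
    return seq


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    free_end_gaps: bool = True,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Parameters
    ----------
    seq_a, seq_b:
        Plain one-letter sequences ('X' allowed; it scores 0 vs everything).
    matrix:
        Substitution matrix name (e.g. ``"BLOSUM62"``).
    gap_open, gap_extend:
        Affine gap penalties (positive numbers); a gap of length L costs
        ``gap_open + gap_extend * (L - 1)``.
    free_end_gaps:
        If true (default), terminal gaps are not penalized.
    """
    seq_a = _validate_seq(seq_a, "a")
    seq_b = _validate_seq(seq_b, "b")
    if gap_open < 0 or gap_extend < 0:
        raise AlignmentError("gap penalties must be non-negative")

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    if free_end_gaps:
        try:
            aligner.open_end_gap_score = 0.0
            aligner.extend_end_gap_score = 0.0
        except AttributeError:  # older attribute spelling
            aligner.end_open_gap_score = 0.0
            aligner.end_extend_gap_score = 0.0

    aln = aligner.align(seq_a, seq_b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])

    column_map: list[tuple[int | None, int | None]] = []
    ia = ib = 0
    for ca, cb in zip(gapped_a, gapped_b):
        pa = ia if ca != "-" else None
        pb = ib if cb != "-" else None
        column_map.append((pa, pb))
        ia += ca != "-"
        ib += cb != "-"
    return PairwiseAlignment(
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        score=float(aln.score),
        matrix=matrix,
        column_map=tuple(column_map),
    )


def classify_substitution(aa_a: str, aa_b: str, matrix: str = "BLOSUM62") -> SubstitutionClass:
    """Classify one alignment column as conserved / minor / significant.

    Identical residues are conserved; a positive matrix score marks a
    minor (conservative) change; anything else — including a gap on
    either side — is a significant difference.
    """
    if aa_a == "-" or aa_b == "-":
        return SubstitutionClass.SIGNIFICANT
    aa_a, aa_b = aa_a.upper(), aa_b.upper()
    if aa_a == aa_b:
        return SubstitutionClass.CONSERVED
    if matrix_score(aa_a, aa_b, matrix) > 0:
        return SubstitutionClass.MINOR
    return SubstitutionClass.SIGNIFICANT


def alignment_stats(aln: PairwiseAlignment, matrix: str | None = None) -> AlignmentStats:
    """Identity and similarity over all alignment columns (gaps included).

    Identity counts identical non-gap columns; similarity additionally
    counts columns whose matrix score is positive.
    """
    mat_name = matrix or aln.matrix
    n_id = 0
    n_sim = 0
    n_gaps = 0
    for ca, cb in zip(aln.gapped_a, aln.gapped_b):
        if ca == "-" or cb == "-":
            n_gaps += 1
            continue
        if ca == cb:
            n_id += 1
            n_sim += 1
        elif matrix_score(ca, cb, mat_name) > 0:
            n_sim += 1
    n_cols = aln.n_columns
    return AlignmentStats(
        pct_identity=100.0 * n_id / n_cols,
        pct_similarity=100.0 * n_sim / n_cols,
        n_columns=n_cols,
        n_gaps=n_gaps,
    )


def map_position(
    aln: PairwiseAlignment,
    number_a: int,
    offset_a: int = 1,
    offset_b: int = 1,
) -> int | None:
    """Map an author residue number of sequence a to its counterpart in b.

    ``offset_a``/``offset_b`` give the author number of each sequence's
    first residue (e.g. 19 for an IgV domain construct starting at residue
    19).  Returns the counterpart author number, or :data:`GAP` (``None``)
    when the column is gapped in b.
    """
    idx_a = number_a - offset_a
    if not 0 <= idx_a < len(aln.seq_a):
        raise AlignmentError(
            f"residue {number_a} outside aligned domain "
            f"[{offset_a}, {offset_a + len(aln.seq_a) - 1}]"
        )
    for pa, pb in aln.column_map:
        if pa == idx_a:
            return None if pb is None else pb + offset_b
    raise AlignmentError(f"residue index {idx_a} missing from column map")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization


def write_aligned_fasta(aln: PairwiseAlignment, ids: tuple[str, str], path: str | Path) -> None:
    """Write the gapped pair as aligned FASTA."""
    text = f">{ids[0]}\n{aln.gapped_a}\n>{ids[1]}\n{aln.gapped_b}\n"
    Path(path).write_text(text)


def alignment_table(
    aln: PairwiseAlignment,
    offset_a: int = 1,
    offset_b: int = 1,
) -> list[dict]:
    """Per-column records: column, residues, author numbers and class."""
    rows = []
    for col, ((pa, pb), ca, cb) in enumerate(zip(aln.column_map, aln.gapped_a, aln.gapped_b)):
        rows.append(
            {
                "column": col,
                "aa_a": ca,
                "num_a": pa + offset_a if pa is not None else None,
                "aa_b": cb,
                "num_b": pb + offset_b if pb is not None else None,
                "class": classify_substitution(ca, cb, aln.matrix).value,
            }
        )
    return rows
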