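"""Mapping of interface sites onto an ortholog and conservation bookkeeping.

Each residue of an interface site (defined on the reference species, in
author numbering) is mapped through the ortholog alignment to its
counterpart, classified as conserved / minor / significant, and summed
into per-site mismatch counts.  The headline "mismatch" count is binary —
any non-identical counterpart, whether the change is conservative or not —
while the three-class breakdown is always reported alongside.

The numbering frame is the reference (sequence a) author numbering; all
residue labels in reports use it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from orthosite.alignment import (
    AlignmentError,
    PairwiseAlignment,
    SubstitutionClass,
    classify_substitution,
    map_position,
)
from orthosite.interface import InterfaceSite, shared_site
from orthosite.structure import STANDARD_AA3

__all__ = [
    "PositionRecord",
    "EpitopeComparison",
    "compare_site",
    "comparison_report",
    "write_report_tsv",
    "write_report_json",
]


@dataclass(frozen=True)
class PositionRecord:
    """One interface residue and its ortholog counterpart."""

    num_a: int
    aa_a: str
    num_b: int | None  # None = counterpart is a gap
    aa_b: str | None
    substitution: SubstitutionClass

    @property
    def is_mismatch(self) -> bool:
        return self.substitution is not SubstitutionClass.CONSERVED


@dataclass(frozen=True)
class EpitopeComparison:
    """Per-position conservation records and mismatch summary for one site."""

    site: InterfaceSite
    records: tuple[PositionRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.site):
            raise ValueError(
                f"{len(self.records)} records for a {len(self.site)}-residue site"
            )

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_conserved(self) -> int:
        return sum(r.substitution is SubstitutionClass.CONSERVED for r in self.records)

    @property
    def n_minor(self) -> int:
        return sum(r.substitution is SubstitutionClass.MINOR for r in self.records)

    @property
    def n_significant(self) -> int:
        return sum(r.substitution is SubstitutionClass.SIGNIFICANT for r in self.records)

    @property
    def n_mismatch(self) -> int:
        """Binary mismatch count: minor + significant."""
        return self.n_minor + self.n_significant

    @property
    def mismatch_positions(self) -> tuple[int, ...]:
        return tuple(r.num_a for r in self.records if r.is_mismatch)

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_conserved": self.n_conserved,
            "n_minor": self.n_minor,
            "n_significant": self.n_significant,
            "n_mismatch": self.n_mismatch,
            "mismatch_positions": list(self.mismatch_positions),
        }


def compare_site(
    site: InterfaceSite,
    aln: PairwiseAlignment,
    offset_a: int = 1,
    offset_b: int = 1,
) -> EpitopeComparison:
    """Map every site residue onto the ortholog and classify it.

    ``offset_a``/``offset_b`` are the author numbers of the first residue
    of each aligned sequence.  A gapped counterpart classifies as a
    significant difference.  Site residues outside the aligned domain
    raise :class:`~orthosite.alignment.AlignmentError` naming the residue.
    """
    records: list[PositionRecord] = []
    for num, icode, name3 in site.residues:
        try:
            num_b = map_position(aln, num, offset_a, offset_b)
        except AlignmentError as exc:
            raise AlignmentError(f"site residue {name3}{num}{icode}: {exc}") from exc
        idx_a = num - offset_a
        aa_a = aln.seq_a[idx_a]
        expected = STANDARD_AA3.get(name3)
        if expected is not None and expected != aa_a:
            raise AlignmentError(
                f"site residue {name3}{num} disagrees with alignment letter {aa_a!r}; "
                "check numbering offsets"
            )
        if num_b is None:
            records.append(
                PositionRecord(num_a=num, aa_a=aa_a, num_b=None, aa_b=None,
                               substitution=SubstitutionClass.SIGNIFICANT)
            )
        else:
            aa_b = aln.seq_b[num_b - offset_b]
            records.append(
                PositionRecord(
                    num_a=num, aa_a=aa_a, num_b=num_b, aa_b=aa_b,
                    substitution=classify_substitution(aa_a, aa_b, aln.matrix),
                )
            )
    return EpitopeComparison(site=site, records=tuple(records))


def comparison_report(
    comparisons: dict[str, EpitopeComparison],
    aln: PairwiseAlignment | None = None,
    offsets: tuple[int, int] = (1, 1),
) -> dict:
    """Per-drug conservation tables plus pairwise shared-site summaries.

    ``comparisons`` maps a drug/entity name to its
    :class:`EpitopeComparison`.  When the ortholog alignment is supplied,
    every pairwise intersection of sites on the same receptor chain is
    also mapped and summarized.
    """
    if not comparisons:
        raise ValueError("no comparisons given")
    report: dict = {"sites": {}, "shared": {}}
    for name, comp in comparisons.items():
        entry = comp.summary()
        entry["receptor_chain"] = comp.site.receptor_chain
        entry["cutoff"] = comp.site.cutoff
        entry["records"] = [
            {
                "num_a": r.num_a,
                "aa_a": r.aa_a,
                "num_b": r.num_b,
                "aa_b": r.aa_b,
                "class": r.substitution.value,
            }
            for r in comp.records
        ]
        report["sites"][name] = entry

    names = sorted(comparisons)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            ca, cb = comparisons[na], comparisons[nb]
            if ca.site.receptor_chain != cb.site.receptor_chain:
                continue
            inter = shared_site(ca.site, cb.site)
            entry = {"n_shared": len(inter), "residues": list(inter.numbers)}
            if aln is not None:
                shared_comp = compare_site(inter, aln, *offsets)
                entry.update(shared_comp.summary())
            report["shared"][f"{na} & {nb}"] = entry
    return report


def write_report_tsv(report: dict, path: str | Path) -> None:
    """Flat TSV: one row per site residue plus per-site summary rows."""
    lines = ["site\tnum_a\taa_a\tnum_b\taa_b\tclass"]
    for name, entry in report["sites"].items():
        for r in entry["records"]:
            nb = r["num_b"] if r["num_b"] is not None else "-"
            ab = r["aa_b"] if r["aa_b"] is not None else "-"
            lines.append(f"{name}\t{r['num_a']}\t{r['aa_a']}\t{nb}\t{ab}\t{r['class']}")
    lines.append("")
    lines.append("site\tn_total\tn_conserved\tn_minor\tn_significant\tn_mismatch\tmismatches")
    for name, entry in report["sites"].items():
        mm = ",".join(str(p) for p in entry["mismatch_positions"])
        lines.append(
            f"{name}\t{entry['n_total']}\t{entry['n_conserved']}\t{entry['n_minor']}"
            f"\t{entry['n_significant']}\t{entry['n_mismatch']}\t{mm}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
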