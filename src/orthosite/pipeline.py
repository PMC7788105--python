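"""End-to-end driver chaining all analysis stages.

One call runs: ortholog alignment → (optional) rigid superposition →
per-drug interface extraction → cross-species site comparison → report.
Reports are plain dicts written as JSON and TSV; for fixed configuration
and inputs the JSON report is byte-identical modulo its timestamp field.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from orthosite import __version__
from orthosite.alignment import alignment_stats, global_align
from orthosite.comparison import compare_site, comparison_report, write_report_tsv
from orthosite.interface import LigandSelection, interface_residues
from orthosite.structure import read_fasta, read_structure
from orthosite.superposition import superpose_all_chains

__all__ = ["RunConfig", "LigandSpec", "PipelineInputs", "run_pipeline", "PipelineError"]

logger = logging.getLogger("orthosite")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and its input."""


@dataclass
class RunConfig:
    """Configuration shared by all pipeline stages."""

    cutoff: float = 4.5
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    offset_a: int = 1
    offset_b: int = 1
    seed: int = 0
    output_dir: str = "orthosite_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a flat ``key=value`` config file; keyword overrides win."""
        values: dict = {}
        casts = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            ftype = casts[key]
            if ftype in ("float", float):
                values[key] = float(val)
            elif ftype in ("int", int):
                values[key] = int(val)
            else:
                values[key] = val
        values.update(overrides)
        return cls(**values)


@dataclass
class LigandSpec:
    """One drug entity: its co-crystal structure and ligand selection."""

    name: str
    structure_path: str
    receptor_chain: str
    ligand_chains: tuple[str, ...] = ()
    het_code: str = ""
    het_chain: str = ""
    het_number: int | None = None

    def selection(self) -> LigandSelection:
        if self.ligand_chains:
            return LigandSelection.chains(*self.ligand_chains)
        return LigandSelection.het(self.het_code, self.het_chain, self.het_number)


@dataclass
class PipelineInputs:
    """Input files for one run.

    ``seq_a_fasta``/``seq_b_fasta`` hold the reference and ortholog
    domain sequences (single-record FASTA each).  ``struct_a``/
    ``struct_b`` plus chain ids drive the superposition stage (optional).
    ``ligands`` lists co-crystal entries to extract interfaces from.
    """

    seq_a_fasta: str
    seq_b_fasta: str
    struct_a: str | None = None
    chain_a: str = "A"
    struct_b: str | None = None
    ligands: list[LigandSpec] = field(default_factory=list)


def run_pipeline(config: RunConfig, inputs: PipelineInputs) -> dict:
    """Execute all stages and write the report bundle to ``config.output_dir``.

    Returns the report dict; also writes ``report.json``, ``report.tsv``
    and ``run.log`` under the output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("orthosite %s", __version__)
    logger.info(
        "config: cutoff=%.2f matrix=%s gap_open=%.2f gap_extend=%.2f seed=%d",
        config.cutoff, config.matrix, config.gap_open, config.gap_extend, config.seed,
    )

    report: dict = {
        "schema_version": 1,
        "tool_version": __version__,
        "config": asdict(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # --- stage: alignment
    try:
        recs_a = read_fasta(inputs.seq_a_fasta)
        recs_b = read_fasta(inputs.seq_b_fasta)
        if not recs_a or not recs_b:
            raise ValueError("empty FASTA input")
        (id_a, seq_a), (id_b, seq_b) = recs_a[0], recs_b[0]
        aln = global_align(seq_a, seq_b, config.matrix, config.gap_open, config.gap_extend)
        stats = alignment_stats(aln)
    except Exception as exc:
        raise PipelineError(f"alignment stage failed on {inputs.seq_a_fasta}/{inputs.seq_b_fasta}: {exc}") from exc
    report["alignment"] = {
        "id_a": id_a,
        "id_b": id_b,
        "score": aln.score,
        "pct_identity": stats.pct_identity,
        "pct_similarity": stats.pct_similarity,
        "n_columns": stats.n_columns,
        "n_gaps": stats.n_gaps,
    }
    logger.info("alignment: %.1f%% identity, %.1f%% similarity", stats.pct_identity, stats.pct_similarity)

    # --- stage: superposition (optional)
    if inputs.struct_a and inputs.struct_b:
        try:
            sa = read_structure(inputs.struct_a)
            sb = read_structure(inputs.struct_b)
            fits = superpose_all_chains(
                sa, inputs.chain_a, sb,
                matrix=config.matrix, gap_open=config.gap_open, gap_extend=config.gap_extend,
            )
        except Exception as exc:
            raise PipelineError(f"superposition stage failed on {inputs.struct_b}: {exc}") from exc
        per_chain = {cid: {"rmsd": f.rmsd, "n_pairs": f.n_pairs} for cid, f in fits.items()}
        best = min(fits, key=lambda cid: fits[cid].rmsd)
        report["superposition"] = {
            "reference": f"{inputs.struct_a}:{inputs.chain_a}",
            "per_chain": per_chain,
            "best_chain": best,
            "best_rmsd": fits[best].rmsd,
        }
        logger.info("superposition: best chain %s, rmsd %.2f Å", best, fits[best].rmsd)
    else:
        logger.info("superposition stage skipped (need both struct_a and struct_b)")

    # --- stage: interfaces + cross-species comparison (optional)
    if inputs.ligands:
        comparisons = {}
        for spec in inputs.ligands:
            try:
                s = read_structure(spec.structure_path)
                site = interface_residues(s, spec.receptor_chain, spec.selection(), config.cutoff)
                comparisons[spec.name] = compare_site(site, aln, config.offset_a, config.offset_b)
            except Exception as exc:
                raise PipelineError(f"interface stage failed on {spec.name} ({spec.structure_path}): {exc}") from exc
            logger.info(
                "interface %s: %d residues, %d mismatches",
                spec.name, comparisons[spec.name].n_total, comparisons[spec.name].n_mismatch,
            )
        try:
            site_report = comparison_report(
                comparisons, aln, offsets=(config.offset_a, config.offset_b)
            )
        except Exception as exc:
            raise PipelineError(f"comparison stage failed: {exc}") from exc
        report["sites"] = site_report["sites"]
        report["shared"] = site_report["shared"]
        write_report_tsv(site_report, outdir / "report.tsv")
    else:
        logger.info("interface stage skipped (no ligand specs)")

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    with open(outdir / "run.log", "a") as fh:
        fh.write(
            f"{report['timestamp']} orthosite {__version__} "
            f"cutoff={config.cutoff} matrix={config.matrix} "
            f"gap={config.gap_open}/{config.gap_extend} seed={config.seed}\n"
        )
    return report
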