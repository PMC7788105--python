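# Methods

This note describes the models and procedures implemented in `orthosite`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical choices that affect results.

## Scientific setting

PD-L1 is the ligand of the PD-1 immune checkpoint; blocking the
PD-1/PD-L1 interaction with antibodies (e.g. atezolizumab, durvalumab),
biphenyl small molecules (BMS series) or macrocyclic peptides reactivates
T cells against tumors. Drugs are developed against *human* PD-L1, but
pre-clinical efficacy testing is cheapest in immunocompetent mice, where
the drug meets *mouse* PD-L1 — an ortholog with roughly 70% sequence
identity in the PD-1-binding IgV domain. Whether a given drug still binds
the mouse protein cannot be read off the sequence alone; the pipeline
quantifies the structural and sequence evidence: how similar the domains
are (RMSD), which residues each drug contacts (interface sites), and how
many of those contacts are substituted in the ortholog (mismatch counts).
It deliberately stops short of predicting binding outcomes: conservation
evidence is reported, verdicts are not computed.

## Structure model

Structures are parsed with gemmi (PDB v3.3 fixed columns and mmCIF
`atom_site` categories) into a minimal chain → residue → atom hierarchy.

* Residue identity is (author number, insertion code); no renumbering is
  ever applied, so site labels match deposited numbering (e.g. Tyr56).
* Hydrogens and waters are dropped at parse time; ions and organic
  hetero groups are kept because they serve as ligand entities.
* Alternate locations are resolved per atom name: highest occupancy
  wins, ties break on the lexicographically smallest altloc letter.
  Altloc resolution changes atom multiplicity only, never residue counts.
* A chain counts as polymeric if it holds at least one standard amino
  acid with a CA atom — this separates protein copies from hetero-only
  "chains" in multi-copy crystals.
* Both PDB and mmCIF are accepted (deposits may be analyzed from either
  dialect; results are identical because only atoms, numbering and
  occupancies are consumed).

## Ortholog alignment and substitution classes

Global pairwise alignment with affine gaps via Biopython's
`PairwiseAligner`. Defaults: BLOSUM62, gap open 10, gap extend 0.5
(a gap of length L costs 10 + 0.5·(L−1)), free end gaps — the EMBOSS
needle convention, standard for ortholog domain pairs. At ~70% identity
the alignment is robust to reasonable parameter changes. 'X' residues
score 0 against everything.

Determinism: among co-optimal alignments the first alignment reported by
the aligner is used, which is deterministic for fixed inputs and
parameters (outputs are bit-stable). The specific traceback preference
order is the library's own; no result in this package depends on the
choice among co-optimal alignments, only on the optimal score, which the
test suite pins to an exhaustive-enumeration oracle.

Identity and similarity are computed over **all** alignment columns
including gap columns (needle convention): identity = identical columns /
columns; similarity additionally counts columns with positive matrix
score. Published similarity figures for this protein pair depend on an
unstated criterion; the positive-BLOSUM62-score rule used here is the
standard reproducible proxy, and the denominator convention is stated
rather than tuned.

Each aligned column is classified three ways: *conserved* (identical),
*minor* (different, matrix score > 0 — a conservative replacement),
*significant* (score ≤ 0, or a gap). For headline "mismatch" counts a
binary rule is used — any non-identical counterpart is a mismatch,
whether minor or significant — because published per-site difference
counts for this system are binary; the three-class breakdown is always
reported alongside.

## Rigid superposition

The Kabsch solution: center both coordinate sets, take the SVD of the
cross-covariance H = B₀ᵀA₀, and form R = V·diag(1,1,d)·Uᵀ with
d = sign(det(V·Uᵀ)), which corrects a least-squares reflection by
flipping the smallest singular direction — rotations are always proper
(det +1) because protein chains are chiral. Translation is
t = ā − R·b̄; RMSD is computed after applying the transform.

* Pairing: alignment-matched Cα atoms only, skipping columns where
  either residue lacks a CA. No outlier trimming by default, because the
  headline quantity is a single global Cα RMSD; an optional iterative
  2σ trim (`trimmed_kabsch_fit`) exists but is off everywhere.
* Multi-copy crystals: the reference chain is fitted against every
  polymer chain of the other entry and per-chain RMSDs are reported plus
  the best (minimum). Published single-number RMSDs for multi-copy
  entries rarely state which copy was used; reporting the spectrum
  answers the question regardless.
* Degenerate geometry (fewer than 3 pairs, or collinear point sets,
  where the rotation about the common axis is undetermined) raises an
  error rather than returning an arbitrary fit.
* The test suite checks the fit against an independent quaternion
  (Horn) closed-form solution and against apply-and-invert round trips
  at 1e-9 Å.

## Interface sites

A residue belongs to the interface iff any of its heavy atoms lies
within the cutoff of any ligand heavy atom. Distances use a k-d tree
over ligand atoms; the result is required (and property-tested) to equal
an all-pairs scan exactly — the tree is an acceleration, never an
approximation.

* Default cutoff 4.5 Å, the common heavy-atom contact convention;
  published residue lists depend on the (often unstated) criterion, so
  sensitivity should be examined by re-running at 4.0/5.0 Å rather than
  trusting one number. Interface sets are monotone in the cutoff, which
  the suite asserts.
* Ligand entities: whole chains (antibody Fab heavy+light chains,
  peptide chains) or one hetero group by code/chain/number (small
  molecules). Crystallization additives (glycerol, PEG, sulfate, common
  ions, …) are never treated as ligand unless explicitly named.
* Shared epitopes are set intersections by (number, icode) on the same
  numbering frame; the per-residue minimum distance of an intersection
  is the maximum of the parents' (the guaranteed-contact distance).
* `min_interatomic_distance` reports the closest atom pair between two
  selections, optionally restricted to an element pair (e.g. C–C), for
  steric-clash measurements after superposition.

## Cross-species site comparison

Each interface residue (author numbering of the reference species) is
mapped through the ortholog alignment with explicit numbering offsets
(the author number of each sequence's first residue, e.g. 19 for an IgV
construct), classified with the same three-class scheme, and summed.
A gapped counterpart counts as a significant difference. A consistency
guard rejects sites whose residue names disagree with the alignment
letter at the mapped position — this catches numbering-frame errors
before they silently corrupt mismatch counts. The reference-species
numbering is the canonical frame of all reports.

## Binding isotherm

The 1:1 ligand-depletion ("quadratic") model: with labeled target at
total concentration T and titrant at L,

    f(L) = ((L + T + K_D) − √((L + T + K_D)² − 4·L·T)) / (2·T)
    response(L) = R_free + (R_bound − R_free) · f(L)

This exact mass-action form is required whenever T is not negligible
against K_D — the typical MST regime (target at tens of nM, titrant
spanning µM). In the T ≪ K_D limit it reduces to the hyperbola
L/(L+K_D), available as an explicit `hyperbola` model. All
concentrations are molar internally; CSV input may declare nM/µM/mM in
the column header.

Fitting: bounded least squares on (log₁₀K_D, R_free, R_bound); the log
parameterization keeps K_D positive by construction. Starting values:
R_free/R_bound from the responses at the lowest/highest concentrations,
K_D from the mid-transition concentration. The K_D standard error comes
from the Gauss–Newton covariance at the optimum, propagated from the log
scale. Replicate dilution series are pooled into one fit (matching how
such experiments are usually analyzed); per-series fits are possible by
filtering the table first. Degenerate data (flat response, singular
curvature) are *flagged* (`converged=False`, infinite stderr), never
raised, so batch analyses keep running. A ligand range under two decades
triggers a warning because K_D is then poorly constrained.

Recovery characteristics, measured by the suite and the acceptance
script on simulated experiments (two pooled 16-point 2-fold dilution
series, noise at 5% of the response amplitude, K_D 3.2 µM, target
20 nM): noiseless round trips recover K_D to better than 1e-6 relative;
over 200 noisy experiments the median relative error is ≈8% and ±2σ
coverage ≈93–94%. A single 16-point series at the same noise has an
intrinsic (Fisher-information-limited) median error of ≈11%, which is
why the two-series pooled design is the reference condition.

## Synthetic data

The generators are pure functions of their arguments (equal arguments ⇒
bit-identical output; one seed parameter each, no global state) and
return truth records sufficient to assert each stage without external
data. Fixtures pass through the real file readers (the pseudo-ligand is
written as HETATM records with code `LIG`), so tests exercise I/O, not
in-memory shortcuts.

* `make_toy_domain`: ideal helix (1.5 Å rise, 100° twist; Cα–Cα ≈ 3.8 Å)
  or strand (3.3 Å rise, alternating pleat) with N, CA, C, O and CB
  (except Gly) pseudo-atoms. Topological stand-ins only — no force-field
  realism, no side chains beyond CB.
* `perturb_copy`: uniform random proper rotation (QR of a Gaussian
  matrix) + translation, then isotropic Gaussian coordinate noise.
* `plant_ligand`: one pseudo-ligand atom per epitope residue at
  *exactly* the requested distance from the residue's outermost heavy
  atom (CB, or CA for glycine), along the outward normal away from the
  local backbone (centroid of the five nearest CA positions); non-epitope
  residues are guaranteed ≥ 2 Å of clearance beyond the contact
  distance, with seeded angular retries and a hard failure if the
  geometry cannot be satisfied.
* `make_ortholog`: substitutions (no indels) at positions sampled
  without replacement, a configurable fraction conservative
  (matrix-positive); realized identity is within one residue of the
  target.
* `simulate_titration`: serial dilution, depletion-model responses,
  Gaussian noise, optional pooled replicate series. Defaults mimic an
  MST experiment (16-point 2-fold dilution from 100 µM, Fnorm-like
  response scale).

What passing synthetic tests shows — and does not. They verify the
algorithms (contact geometry, alignment bookkeeping, transform recovery,
estimator calibration) exactly, because the truth is planted. They do
not exercise the messiness of real deposits: missing loops and side
chains, insertion codes, altloc-heavy regions, non-standard residues
beyond MSE, or real binding-response baselines. The replication tests
against the public deposits cover that ground whenever
`data/reference/` is populated (`scripts/fetch_data.py`).

## Problem sizes and determinism

Test and acceptance workloads use a 25-residue toy domain, 109-residue
synthetic ortholog pairs (IgV-domain-sized), 50–100 interface fixtures,
and 200 simulated titration experiments — sizes chosen so the whole
suite runs in well under a minute while keeping the statistical
envelopes (median error, coverage) meaningful. All randomness flows
from explicit seeds; `scripts/acceptance.py --seed N` is reproducible
end to end.

## Known limitations

* No solvent-accessible-surface-area epitope definition; contact cutoff
  only. Published epitope residue lists derived under other criteria can
  differ by one or two residues.
* No interaction typing (H-bonds, salt bridges), no ΔΔG or binding
  prediction, no docking, no flexible superposition, no multiple
  alignment.
* The binding module fits 1:1 models only — no Hill cooperativity, no
  competition (Ki) formats, no raw thermophoresis-trace processing.
* Sequence-based mismatch counts ignore conformational differences;
  a conserved residue can still be displaced (the package measures such
  displacements via `atom_displacement`, but does not fold them into
  mismatch counts).
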