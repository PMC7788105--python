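# orthosite

Cross-species conservation analysis of drug-binding sites on protein
receptors, built around the human/mouse PD-L1 case: a drug developed
against the human immune-checkpoint ligand PD-L1 may or may not engage the
mouse ortholog, and whether it does determines if ordinary syngeneic mouse
models can be used for pre-clinical testing. `orthosite` provides the
structural-bioinformatics half of that question as a reusable, tested
pipeline:

1. **Structure I/O** — PDB/mmCIF parsing into a chain → residue → atom
   hierarchy that keeps author residue numbering (so "Tyr56" means the
   same thing everywhere); hydrogens/waters dropped, altlocs resolved.
2. **Ortholog alignment** — global affine-gap alignment (BLOSUM62,
   gap open 10 / extend 0.5, free end gaps) with identity/similarity
   statistics and a three-class substitution scheme: *conserved*
   (identical), *minor* (matrix score > 0), *significant* (score ≤ 0 or
   gap).
3. **Superposition** — Kabsch least-squares rigid-body fit of
   alignment-paired Cα atoms, RMSD = √(mean‖aᵢ − (R·bᵢ + t)‖²), with
   per-chain reports for multi-copy crystals and per-atom displacement
   measurements.
4. **Interface extraction** — the binding site / structural epitope as
   the set of receptor residues with any heavy atom within a cutoff
   (default 4.5 Å) of any ligand heavy atom, for small molecules,
   peptides and antibody Fabs; plus set algebra (shared epitopes) and
   minimum interatomic distances (steric-clash measurement).
5. **Cross-species mapping** — every interface residue mapped through the
   ortholog alignment to its counterpart and classified; mismatch counts
   per drug and for shared epitopes.
6. **Binding affinity** — 1:1 ligand-depletion isotherm fits of titration
   data (MicroScale-Thermophoresis-style): the bound fraction is
   f = ((L+T+K_D) − √((L+T+K_D)² − 4LT)) / 2T and the response is
   R_free + (R_bound − R_free)·f, fitted by bounded least squares with a
   curvature-based standard error on K_D.

A seeded synthetic-data module (`orthosite.synthetic`) generates every
input class with ground-truth bookkeeping — ideal toy domains, rigidly
transformed noisy copies, co-crystals with planted contact epitopes,
orthologs at a target percent identity, noisy dilution series — so the
entire pipeline is testable without any downloads.

## Worked example

Generate a toy co-crystal (pseudo-ligand planted 3.5 Å from residues
5, 11, 14 and 18), a 69.4%-identity ortholog pair, and run the pipeline:

```sh
orthosite simulate complex --sequence ACDEFGHIKLMNPQRSTVWYARNDC \
    --epitope 5,11,14,18 --seed 11 -o complex.pdb
orthosite simulate ortholog --sequence ACDEFGHIKLMNPQRSTVWYARNDC \
    --identity 69.4 --seed 11 -o pair.fasta
# split pair.fasta into parent.fasta / ortholog.fasta, then:
orthosite run --seq-a parent.fasta --seq-b ortholog.fasta \
    --ligand drug:complex.pdb:A:het=LIG --output-dir out
```

prints

```
INFO:orthosite:alignment: 68.0% identity, 72.0% similarity
INFO:orthosite:interface drug: 4 residues, 3 mismatches
report written to out/report.json
  drug: 4 residues, 3 mismatches (11,14,18)
```

The generator mutated 8 of 25 positions (realized identity 68.0%, within
one residue of the 69.4% target); three of them (11, 14, 18) fall inside
the planted 4-residue interface, and the pipeline recovers exactly those
as cross-species mismatches. A binding fit on a simulated noisy
two-series titration:

```sh
orthosite simulate titration --kd 3.2e-6 --noise-sd 2.5 --n-series 2 \
    --seed 11 -o titration.csv
orthosite fitkd titration.csv --target-conc 2e-8
```

```
K_D = 3.716e-06 ± 3.58e-07 M over 32 points (depletion model)
```

i.e. the true K_D of 3.2 µM is recovered within the fit's 2σ band from
data with noise at 5% of the response amplitude.

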