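# Reference inputs

This directory holds the public inputs used by the replication checks in
`tests/test_acceptance.py` and, when present, by `scripts/acceptance.py`:

| file               | contents                                              |
|--------------------|-------------------------------------------------------|
| `6sru.cif`         | mouse apo PD-L1 IgV domain, 10 copies per asymmetric unit |
| `5c3t.cif`         | human apo PD-L1                                       |
| `6r3k.cif`         | human PD-L1 with the biphenyl inhibitor BMS-1166      |
| `5o4y.cif`         | human PD-L1 with macrocyclic peptide-57               |
| `5xxy.cif`         | human PD-L1 with the atezolizumab Fab                 |
| `5x8m.cif`         | human PD-L1 with the durvalumab Fab                   |
| `hpdl1_igv.fasta`  | human PD-L1 (UniProt Q9NZQ7) residues 19–127          |
| `mpdl1_igv.fasta`  | mouse PD-L1 (UniProt Q9EP73) residues 19–134          |

Populate it with:

    python scripts/fetch_data.py

The download needs network access; nothing else in the package fetches
anything. The whole pipeline is otherwise exercised on synthetic,
ground-truthed data generated by `orthosite.synthetic`.
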