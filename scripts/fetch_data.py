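#!/usr/bin/env python
"""Fetch the public reference inputs for the replication checks.

Downloads six PDB entries (mmCIF) and the two PD-L1 ortholog sequences
(UniProt), slices the IgV domains (human 19-127, mouse 19-134) and writes
everything under ``data/reference/``.  Requires network access; nothing
else in the package or test suite performs downloads.

Usage::

    python scripts/fetch_data.py [--outdir data/reference]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

PDB_IDS = ["6sru", "5c3t", "6r3k", "5o4y", "5xxy", "5x8m"]
UNIPROT = {
    "hpdl1": ("Q9NZQ7", 19, 127),  # human PD-L1, IgV domain
    "mpdl1": ("Q9EP73", 19, 134),  # mouse PD-L1, IgV domain
}

PDB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"
UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def _get(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", default="data/reference", type=Path)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for pdb_id in PDB_IDS:
        dest = args.outdir / f"{pdb_id}.cif"
        if dest.exists():
            print(f"{dest} already present")
            continue
        print(f"fetching {pdb_id} ...")
        dest.write_bytes(_get(PDB_URL.format(pdb_id=pdb_id)))

    for name, (acc, start, end) in UNIPROT.items():
        dest = args.outdir / f"{name}_igv.fasta"
        if dest.exists():
            print(f"{dest} already present")
            continue
        print(f"fetching {acc} ...")
        text = _get(UNIPROT_URL.format(acc=acc)).decode()
        seq = "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))
        domain = seq[start - 1:end]
        if len(domain) != end - start + 1:
            print(f"unexpected sequence length for {acc}", file=sys.stderr)
            return 1
        lines = [f">{name}_igv {acc} residues {start}-{end}"]
        lines += [domain[i:i + 60] for i in range(0, len(domain), 60)]
        dest.write_text("\n".join(lines) + "\n")

    print(f"reference data ready under {args.outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
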