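#!/usr/bin/env python
"""Fetch the pinned reference protein sequences from UniProt (network needed).

The conservation analyses compare the C. elegans ryanodine receptor UNC-68
and FKB-2 with human RyR1 and FKBP12 (calstabin1).  No accessions are
deposited with the assay itself, so canonical UniProt entries must be chosen
and pinned here.  Human entries are well established; verify the worm
entries against WormBase (genes unc-68 and fkb-2) before relying on them,
and record the release you fetched.

Usage:
    python scripts/fetch_sequences.py [--outdir data/sequences]

Writes unc68.fasta, ryr1.fasta, fkb2.fasta, fkbp12.fasta.
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

# pinned accessions (UniProt); verify worm entries against WormBase
ACCESSIONS = {
    "ryr1": "P21817",    # human RYR1
    "fkbp12": "P62942",  # human FKBP1A / calstabin1
    "unc68": "Q09454",   # C. elegans unc-68 (verify against WormBase)
    "fkb2": "P52015",    # C. elegans fkb-2 (verify against WormBase)
}

URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("data/sequences"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for name, acc in ACCESSIONS.items():
        dest = args.outdir / f"{name}.fasta"
        with urllib.request.urlopen(URL.format(acc=acc), timeout=30) as resp:
            data = resp.read()
        if not data.startswith(b">"):
            raise RuntimeError(f"unexpected response for {acc}")
        dest.write_bytes(data)
        print(f"{name}: {acc} -> {dest}")


if __name__ == "__main__":
    main()
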