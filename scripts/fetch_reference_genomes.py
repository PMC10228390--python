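#!/usr/bin/env python
"""Download the reference organelle genomes used by the accession-exact
acceptance checks into data/reference/ (requires network access).

Usage: python scripts/fetch_reference_genomes.py [--outdir data/reference]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "NC_000932",  # Arabidopsis thaliana chloroplast
    "MW007721",   # Onobrychis viciifolia chloroplast
    "NC_001320",  # Oryza sativa chloroplast
    "NC_024511",  # Drosophila melanogaster mitochondrion
    "NC_012920",  # Homo sapiens mitochondrion
]

EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="data/reference")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = outdir / f"{acc}.fasta"
        if dest.exists():
            print(f"{dest} already present", file=sys.stderr)
            continue
        url = EUTILS.format(acc=acc)
        print(f"fetching {acc} ...", file=sys.stderr)
        with urllib.request.urlopen(url, timeout=60) as resp:
            data = resp.read()
        if not data.startswith(b">"):
            print(f"unexpected response for {acc}", file=sys.stderr)
            return 1
        dest.write_bytes(data)
        print(f"wrote {dest} ({len(data)} bytes)", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
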