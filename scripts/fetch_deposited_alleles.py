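"""Fetch the deposited loggerhead MHC class I allele sequences from GenBank.

Downloads accessions KF021627-KF021666 via NCBI E-utilities and writes them
to data/deposited_alleles.fasta, enabling the deposited-allele acceptance
test. Requires network access; the sequences are not redistributed with the
package.

Usage:
    python scripts/fetch_deposited_alleles.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

ACCESSIONS = [f"KF{n:06d}" for n in range(21627, 21667)]  # KF021627-KF021666
OUT = Path(__file__).resolve().parent.parent / "data" / "deposited_alleles.fasta"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="anonymous@example.org",
                        help="contact email passed to NCBI E-utilities")
    args = parser.parse_args()
    Entrez.email = args.email
    with Entrez.efetch(db="nuccore", id=",".join(ACCESSIONS),
                       rettype="fasta", retmode="text") as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise SystemExit("no records returned; check network access")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{str(rec.seq).upper()}\n")
    print(f"wrote {len(records)} records to {OUT}")


if __name__ == "__main__":
    main()
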