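#!/usr/bin/env python
"""Download the COI records behind the acceptance targets (network needed).

Writes data/genbank/coi_records.fasta and data/genbank/species_map.tsv,
which scripts/acceptance.py then uses to recompute targets t2-t5.  The
library itself never downloads anything; this helper only documents and
fetches the accession list:

    19 Cervidae COI fragments: KX377310-KX377326, KX388145, KX388146
    5 reindeer records:        JF443386, JF443512, KJ205574, JF443413, KY385852

Usage:  python scripts/fetch_accessions.py [--out data/genbank]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = (
    [f"KX3773{i}" for i in range(10, 27)]
    + ["KX388145", "KX388146", "JF443386", "JF443512", "KJ205574", "JF443413", "KY385852"]
)


def fetch(accessions) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(accessions), "rettype": "fasta",
         "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path,
                        default=Path(__file__).resolve().parent.parent / "data" / "genbank")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    text = fetch(ACCESSIONS)
    (args.out / "coi_records.fasta").write_text(text)

    # organism = first two words of the definition line after the accession
    rows = []
    for line in text.splitlines():
        if line.startswith(">"):
            parts = line[1:].split()
            acc = parts[0].split(".")[0]
            species = " ".join(parts[1:3])
            rows.append(f"{acc}\t{species}")
    (args.out / "species_map.tsv").write_text("\n".join(rows) + "\n")
    print(f"wrote {len(rows)} records to {args.out}", file=sys.stderr)
    time.sleep(0)  # be polite if extended to batched fetches
    return 0


if __name__ == "__main__":
    sys.exit(main())
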