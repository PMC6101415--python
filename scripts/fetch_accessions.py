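"""Fetch the deposited barcode records used by the published assay.

The library itself never touches the network; this helper downloads the
GenBank records once, on a machine with internet access, and writes the
per-locus FASTA files that the reproduction tests in
``tests/test_acceptance.py`` look for under ``data/accessions/``:

    python scripts/fetch_accessions.py --out data/accessions

Headers follow the ``id|species|locus`` convention so the files feed
directly into :func:`barcodiag.read_fasta`.
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

_ARISTOLOCHIA = [
    # species, rbcL, matK, trnH-psbA, ITS
    ("Aristolochia_pierrei", "KP998768", "KP998782", "KP998810", "KP998796"),
    ("Aristolochia_pothieri", "KP998769", "KP998783", "KP998811", "KP998797"),
    ("Aristolochia_tagala", "KP998772", "KP998786", "KP998814", "KP998800"),
    ("Aristolochia_anguicida", "KP903720", "KP998777", "KP998805", "KP998791"),
    ("Aristolochia_gigantea", "KP998764", "KP998778", "KP998806", "KP998792"),
    ("Aristolochia_grandiflora", "KP998765", "KP998779", "KP998807", "KP998793"),
    ("Aristolochia_kerrii", "KP998766", "KP998780", "KP998808", "KP998794"),
    ("Aristolochia_littoralis", "KP998767", "KP998781", "KP998809", "KP998795"),
    ("Aristolochia_ringens", "KP998770", "KP998784", "KP998812", "KP998798"),
    ("Aristolochia_tentaculata", "KP998773", "KP998787", "KP998815", "KP998801"),
    ("Aristolochia_sp", "KP998771", "KP998785", "KP998813", "KP998799"),
]

# locus -> {accession: species}
ACCESSIONS: dict[str, dict[str, str]] = {
    "rbcL": {row[1]: row[0] for row in _ARISTOLOCHIA}
    | {"AB205604": "Thottea_borneensis", "AB205606": "Thottea_tomentosa"},
    "matK": {row[2]: row[0] for row in _ARISTOLOCHIA}
    | {"JN415668": "Thottea_borneensis", "JN415674": "Thottea_tomentosa"},
    "trnH-psbA": {row[3]: row[0] for row in _ARISTOLOCHIA},
    "ITS": {row[4]: row[0] for row in _ARISTOLOCHIA}
    | {
        "MG870094": "Raphistemma_pulchellum",
        "MG870090": "Gymnopetalum_integrifolium",
        "MG870093": "Jasminum_sambac",
        "MG870091": "Jasminum_adenophyllum",
        "MG870092": "Jasminum_sp",
        "KJ888492.1": "Asarum_caudatum",
        "AB699853.1": "Asarum_yakusimense",
    },
}


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EFETCH}?{query}", timeout=60) as resp:
        return resp.read().decode()


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="data/accessions", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for locus, table in ACCESSIONS.items():
        path = args.out / f"{locus}.fasta"
        with open(path, "w") as fh:
            for accession, species in table.items():
                raw = fetch(accession)
                seq = "".join(raw.splitlines()[1:])
                fh.write(f">{accession}|{species}|{locus}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
                time.sleep(0.4)  # NCBI rate limit
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
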