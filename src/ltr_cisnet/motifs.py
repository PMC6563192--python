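"""Domain motif table shared by the simulator and the domain annotator.

Internal protein domains of LTR retrotransposons (gag, pro, pol, env) are
represented by short fixed peptide motifs.  Each motif echoes a hallmark of
the real domain (DTG of the aspartic protease, YxDD of reverse
transcriptase, an RxxR furin site followed by the fusion-peptide consensus
for env) but the strings themselves are synthetic: deterministic substring
matching against six-frame translations stands in for profile-HMM search.
"""

from __future__ import annotations

import csv
from pathlib import Path

#: domain name -> peptide motif searched in six-frame translations
DEFAULT_MOTIFS: dict[str, str] = {
    "gag": "MGASKSKLNQVW",
    "pro": "ALLDTGADDTVI",
    "pol": "KAYVDDLLIFSG",
    # RVKR furin site, a 2-aa spacer, then the fusion-peptide consensus
    # G-x(5)-G-x(3)-K-x(3)-G-x(2)-D-x(2)-D realised with fixed x residues
    "env": "RVKRSSGAAFLIGSTLKVADGLSDTWD",
}

#: one unambiguous codon per amino acid, used to back-translate motifs
CODON_OF: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def back_translate(peptide: str) -> str:
    """Deterministic DNA realisation of a peptide (one codon per residue)."""
    try:
        return "".join(CODON_OF[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}") from None


def read_motif_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (domain, peptide_motif); header optional."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].lower() in {"domain", "name"}:
                continue
            if len(row) < 2:
                raise ValueError(f"malformed motif row: {row}")
            table[row[0]] = row[1].upper()
    if not table:
        raise ValueError(f"no motifs found in {path}")
    return table


def write_motif_table(table: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("domain\tmotif\n")
        for name, motif in table.items():
            fh.write(f"{name}\t{motif}\n")
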